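"""Condition/module similarity on eigengene space, SVD imputation of
missing scores, seed-module expansion and Ward-D2 module clustering."""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr

from .types import (
    DEFAULT_META_PATTERN,
    EigengeneMatrix,
    SeedClusterResult,
    ValidationError,
    parse_condition_meta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "condition_similarity",
    "impute_conditions",
    "expand_seed_modules",
    "cluster_modules",
]


def condition_similarity(
    egs: EigengeneMatrix, a: str, b: str, method: str = "pearson"
) -> float:
    """Correlation of two conditions' module-score vectors."""
    for cid in (a, b):
        if cid not in egs.scores.columns:
            raise ValidationError(f"condition {cid!r} not in the score matrix")
    if egs.scores.shape[0] < 3:
        raise ValidationError("need at least 3 modules for a condition correlation")
    x = egs.scores[a].to_numpy(dtype=float)
    y = egs.scores[b].to_numpy(dtype=float)
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def _pick_rank(X: np.ndarray, var_target: float = 0.9) -> int:
    s = np.linalg.svd(X, compute_uv=False)
    var = np.cumsum(s**2) / np.sum(s**2)
    return int(np.searchsorted(var, var_target) + 1)


def impute_conditions(
    egs: EigengeneMatrix,
    drop_time: str | None = "2 hr",
    condition_times: pd.Series | None = None,
    rank: int | None = None,
    tol: float = 0.01,
    max_iter: int = 100,
) -> EigengeneMatrix:
    """Drop conditions at one time point, then fill remaining missing scores
    by iterative rank-truncated SVD reconstruction.

    Missing entries are initialized with per-module means and refilled from
    the rank-``rank`` reconstruction until the relative change drops below
    ``tol``; observed entries are never altered. ``rank=None`` picks the
    smallest rank explaining >= 90% of the variance of the fully observed
    conditions (falling back to the initialized matrix when too few are
    complete).
    """
    scores = egs.scores.copy()
    if drop_time is not None:
        if condition_times is None:
            meta = parse_condition_meta(list(scores.columns), DEFAULT_META_PATTERN)
            condition_times = meta["time"]
        keep = [c for c in scores.columns if condition_times.get(c) != drop_time]
        scores = scores.loc[:, keep]
    X = scores.to_numpy(dtype=float)
    mask = np.isnan(X)
    if mask.all(axis=1).any():
        mid = scores.index[mask.all(axis=1)][0]
        raise ValidationError(f"module {mid} has no observed score")
    if mask.all(axis=0).any():
        cid = scores.columns[mask.all(axis=0)][0]
        raise ValidationError(f"condition {cid!r} has no observed score")
    if mask.mean() >= 0.5:
        raise ValidationError("more than half of the remaining scores are missing")
    if not mask.any():
        return EigengeneMatrix(scores=scores)
    row_means = np.nanmean(X, axis=1)
    filled = np.where(mask, row_means[:, None], X)
    if rank is None:
        complete_cols = ~mask.any(axis=0)
        base = X[:, complete_cols] if complete_cols.sum() >= 5 else filled
        rank = _pick_rank(base)
    rank = int(min(rank, min(filled.shape)))
    for it in range(max_iter):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
        new = np.where(mask, recon, X)
        denom = np.sqrt(np.sum(filled[mask] ** 2))
        change = np.sqrt(np.sum((new[mask] - filled[mask]) ** 2)) / max(denom, 1e-12)
        filled = new
        if change < tol:
            break
    else:
        logger.warning("SVD imputation did not converge in %d iterations", max_iter)
    return EigengeneMatrix(scores=pd.DataFrame(filled, index=scores.index, columns=scores.columns))


def _module_correlation(scores: pd.DataFrame, method: str) -> pd.DataFrame:
    if method == "pearson":
        C = np.corrcoef(scores.to_numpy(dtype=float))
    elif method == "spearman":
        C = spearmanr(scores.to_numpy(dtype=float).T).statistic
        C = np.atleast_2d(C)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(np.clip(C, -1, 1), index=scores.index, columns=scores.index)


def expand_seed_modules(
    egs: EigengeneMatrix,
    seeds: list[int],
    r_min: float = 0.7,
    candidate_filter: list[int] | None = None,
    method: str = "pearson",
) -> SeedClusterResult:
    """Expanded set = seeds plus every candidate whose best seed correlation
    is >= ``r_min``."""
    if not 0 < r_min <= 1:
        raise ValueError("r_min must be in (0,1]")
    have = set(egs.module_ids)
    for s in seeds:
        if s not in have:
            raise ValidationError(f"seed module {s} absent from the score matrix")
    candidates = [m for m in (candidate_filter or egs.module_ids) if m not in set(seeds)]
    C = _module_correlation(egs.scores, method)
    addins = []
    for c in candidates:
        best = float(C.loc[c, list(seeds)].max())
        if best >= r_min - 1e-12:
            addins.append(c)
    return SeedClusterResult(seed_ids=sorted(seeds), addin_ids=sorted(addins))


def cluster_modules(
    egs: EigengeneMatrix,
    members: list[int] | None = None,
    k: int | None = None,
    height: float | None = None,
    method: str = "pearson",
    seeds: list[int] | None = None,
) -> SeedClusterResult:
    """Ward-D2 clustering of modules on the 1 - correlation distance.

    Exactly one of ``k`` (number of clusters) and ``height`` (cut height)
    must be given. Cluster ids are assigned by decreasing cluster size, ties
    broken by the smallest member module id.
    """
    if (k is None) == (height is None):
        raise ValueError("supply exactly one of k / height")
    members = sorted(members if members is not None else egs.module_ids)
    if len(members) < 2:
        raise ValidationError("need at least 2 modules to cluster")
    scores = egs.scores.loc[members]
    sds = scores.std(axis=1, ddof=1)
    if (sds <= 0).any():
        mid = sds.index[sds <= 0][0]
        raise ValidationError(f"module {mid} has a constant score vector")
    C = _module_correlation(scores, method)
    D = 1.0 - C.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    Z = linkage(squareform(D, checks=False), method="ward")
    if k is not None:
        raw = fcluster(Z, t=int(k), criterion="maxclust")
    else:
        raw = fcluster(Z, t=float(height), criterion="distance")
    groups: dict[int, list[int]] = {}
    for mid, lab in zip(members, raw):
        groups.setdefault(int(lab), []).append(mid)
    order = sorted(groups, key=lambda l: (-len(groups[l]), min(groups[l])))
    labels: dict[int, int] = {}
    for new, old in enumerate(order, start=1):
        for mid in groups[old]:
            labels[mid] = new
    seed_ids = sorted(seeds) if seeds else sorted(members)
    addin_ids = [m for m in members if m not in set(seed_ids)]
    return SeedClusterResult(
        seed_ids=seed_ids, addin_ids=addin_ids, cluster_labels=labels, linkage=Z
    )
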