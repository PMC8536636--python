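"""Cross-dataset module preservation statistics.

Four statistics are computed per module on the genes shared between the
reference and test datasets: two density statistics (mean within-module
adjacency in the test data; mean |kME| against the module's test-data
eigengene) and two connectivity statistics (correlation of the ref/test
intramodular connectivity vectors; correlation of the vectorized ref/test
within-module correlation matrices). Permutation Z-scores use size-matched
random gene sets from the shared universe; the summary is the mean of the
density and connectivity class medians. medianRank is the per-module median
of the across-module ranks of the observed statistics (rank 1 = strongest).
"""

from __future__ import annotations

import contextlib
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .eigengenes import module_raw_score
from .types import FoldChangeMatrix, ModuleSet, PreservationStats, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["map_orthologs", "compute_preservation", "classify_preservation"]

STAT_NAMES = ("mean_adjacency", "mean_abs_kme", "cor_kim", "cor_cor")


@contextlib.contextmanager
def warnings_ignored():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield



DENSITY_STATS = ("mean_adjacency", "mean_abs_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_cor")


def map_orthologs(fc: FoldChangeMatrix, ortholog_map: pd.DataFrame) -> FoldChangeMatrix:
    """Translate gene ids through a one-to-one ortholog map.

    Many-to-one / one-to-many entries are dropped entirely; genes without a
    mapping are dropped with a count logged.
    """
    m = ortholog_map.iloc[:, :2].copy()
    m.columns = ["source_id", "target_id"]
    m = m.dropna()
    m = m[~m["source_id"].duplicated(keep=False) & ~m["target_id"].duplicated(keep=False)]
    n_ambiguous = len(ortholog_map) - len(m)
    if n_ambiguous:
        logger.warning("dropped %d non-one-to-one ortholog entries", n_ambiguous)
    lookup = dict(zip(m["source_id"], m["target_id"]))
    keep = [g for g in fc.gene_ids if g in lookup]
    if not keep:
        raise ValidationError("no gene in the matrix has an ortholog mapping")
    logger.info("mapped %d/%d genes via orthologs", len(keep), len(fc.gene_ids))
    values = fc.values.loc[:, keep].copy()
    values.columns = [lookup[g] for g in keep]
    adj_p = None
    if fc.adj_p is not None:
        adj_p = fc.adj_p.loc[:, keep].copy()
        adj_p.columns = list(values.columns)
    return FoldChangeMatrix(values=values, adj_p=adj_p, meta=fc.meta.copy())


def _corr(X: np.ndarray) -> np.ndarray:
    C = np.corrcoef(X, rowvar=False)
    return np.clip(C, -1.0, 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def _module_stats(
    idx: np.ndarray,
    C_ref: np.ndarray,
    C_test: np.ndarray,
    A_test: np.ndarray,
    A_ref: np.ndarray,
    Z_test: np.ndarray,
) -> dict[str, float]:
    n = len(idx)
    iu = np.triu_indices(n, k=1)
    sub_test_c = C_test[np.ix_(idx, idx)]
    sub_ref_c = C_ref[np.ix_(idx, idx)]
    sub_test_a = A_test[np.ix_(idx, idx)]
    sub_ref_a = A_ref[np.ix_(idx, idx)]
    eig = module_raw_score(Z_test[:, idx])
    eigc = eig - eig.mean()
    block = Z_test[:, idx] - Z_test[:, idx].mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = (block * eigc[:, None]).sum(axis=0) / np.sqrt(
            (block**2).sum(axis=0) * (eigc**2).sum()
        )
    kim_ref = sub_ref_a.sum(axis=0) - 1.0
    kim_test = sub_test_a.sum(axis=0) - 1.0
    return {
        "mean_adjacency": float(sub_test_a[iu].mean()),
        "mean_abs_kme": float(np.abs(kme).mean()),
        "cor_kim": _pearson(kim_ref, kim_test),
        "cor_cor": _pearson(sub_ref_c[iu], sub_test_c[iu]),
    }


def _safe_z(obs: float, null: np.ndarray) -> float:
    """Permutation Z; NaN when the statistic is uninformative under this
    dataset pairing (e.g. cor-type statistics are identically 1 when the
    test data equal the reference, for any gene set)."""
    mean = float(np.mean(null))
    sd = float(np.std(null, ddof=1))
    if sd < 1e-12:
        return np.nan if abs(obs - mean) < 1e-9 else np.sign(obs - mean) * np.inf
    return (obs - mean) / sd


def compute_preservation(
    ref_fc: FoldChangeMatrix,
    test_fc: FoldChangeMatrix,
    modules: ModuleSet,
    n_perm: int = 200,
    seed: int = 0,
    beta: int = 5,
    min_shared: int = 3,
) -> list[PreservationStats]:
    """Permutation preservation statistics for every module with at least
    ``min_shared`` genes present in both datasets."""
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    rng = np.random.default_rng(seed)
    shared = [g for g in ref_fc.gene_ids if g in set(test_fc.gene_ids)]
    shared = [g for g in shared if g in set(modules.universe)]
    if len(shared) < min_shared:
        raise ValidationError("too few shared genes between datasets")
    pos = {g: i for i, g in enumerate(shared)}
    Xr = ref_fc.values.loc[:, shared].to_numpy(dtype=float)
    Xt = test_fc.values.loc[:, shared].to_numpy(dtype=float)
    for name, X in (("reference", Xr), ("test", Xt)):
        if np.isnan(X).any():
            raise ValidationError(f"{name} matrix has missing values on shared genes")
    sd_t = Xt.std(axis=0, ddof=1)
    sd_r = Xr.std(axis=0, ddof=1)
    if (sd_t <= 0).any() or (sd_r <= 0).any():
        raise ValidationError("zero-variance gene among the shared genes")
    C_ref = _corr(Xr)
    C_test = _corr(Xt)
    A_ref = np.abs(C_ref) ** beta
    A_test = np.abs(C_test) ** beta
    np.fill_diagonal(A_ref, 1.0)
    np.fill_diagonal(A_test, 1.0)
    Z_test = (Xt - Xt.mean(axis=0)) / sd_t

    scorable: list[tuple[int, np.ndarray]] = []
    results: list[PreservationStats] = []
    for m in modules.modules:
        idx = np.array([pos[g] for g in m.gene_ids if g in pos], dtype=int)
        if len(idx) < min_shared:
            logger.warning(
                "module %d has %d shared genes (< %d); statistics set to missing",
                m.id,
                len(idx),
                min_shared,
            )
            results.append(PreservationStats(module_id=m.id, n_shared=len(idx)))
            continue
        scorable.append((m.id, idx))

    if len(scorable) < 2:
        raise ValidationError("need >= 2 modules with enough shared genes")

    n_shared_total = len(shared)
    observed: dict[int, dict[str, float]] = {}
    nulls: dict[int, dict[str, np.ndarray]] = {}
    for mid, idx in scorable:
        observed[mid] = _module_stats(idx, C_ref, C_test, A_test, A_ref, Z_test)
        null = {s: np.empty(n_perm) for s in STAT_NAMES}
        for p in range(n_perm):
            draw = rng.choice(n_shared_total, size=len(idx), replace=False)
            stats = _module_stats(np.sort(draw), C_ref, C_test, A_test, A_ref, Z_test)
            for s in STAT_NAMES:
                null[s][p] = stats[s]
        nulls[mid] = null

    # observed-statistic ranks across modules (rank 1 = strongest)
    obs_frame = pd.DataFrame({mid: observed[mid] for mid, _ in scorable}).T
    ranks = pd.DataFrame(
        {s: rankdata(-obs_frame[s].to_numpy(), method="average") for s in STAT_NAMES},
        index=obs_frame.index,
    )

    scored: dict[int, PreservationStats] = {}
    for mid, idx in scorable:
        z = {s: _safe_z(observed[mid][s], nulls[mid][s]) for s in STAT_NAMES}
        with warnings_ignored():
            z_density = float(np.nanmedian([z[s] for s in DENSITY_STATS]))
            z_connectivity = float(np.nanmedian([z[s] for s in CONNECTIVITY_STATS]))
            z_summary = float(np.nanmean([z_density, z_connectivity]))
        scored[mid] = PreservationStats(
            module_id=mid,
            n_shared=len(idx),
            observed=observed[mid],
            z=z,
            z_density=z_density,
            z_connectivity=z_connectivity,
            z_summary=z_summary,
            median_rank=float(np.median(ranks.loc[mid].to_numpy())),
        )
    ordered = []
    for m in modules.modules:
        if m.id in scored:
            ordered.append(scored[m.id])
        else:
            ordered.append(next(r for r in results if r.module_id == m.id))
    return ordered


def preservation_frame(stats: list[PreservationStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        row = {"module": s.module_id, "n_shared": s.n_shared}
        row.update({f"obs_{k}": v for k, v in s.observed.items()})
        row.update({f"z_{k}": v for k, v in s.z.items()})
        row.update(
            {
                "z_density": s.z_density,
                "z_connectivity": s.z_connectivity,
                "z_summary": s.z_summary,
                "median_rank": s.median_rank,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")


def classify_preservation(
    stats_a: list[PreservationStats],
    stats_b: list[PreservationStats],
    z_min: float = 2.0,
    rank_top: int = 100,
) -> pd.Series:
    """Preserved iff z_summary strictly above ``z_min`` in BOTH test systems
    OR median_rank <= ``rank_top`` in BOTH."""
    a = {s.module_id: s for s in stats_a}
    b = {s.module_id: s for s in stats_b}
    if set(a) != set(b):
        only = set(a) ^ set(b)
        raise ValidationError(f"module {sorted(only)[0]} present in one list only")
    out = {}
    for mid in a:
        sa, sb = a[mid], b[mid]
        z_rule = sa.z_summary > z_min and sb.z_summary > z_min
        rank_rule = sa.median_rank <= rank_top and sb.median_rank <= rank_top
        out[mid] = bool(z_rule or rank_rule)
    return pd.Series(out).sort_index()
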