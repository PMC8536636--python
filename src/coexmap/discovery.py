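"""Unsigned co-expression module construction.

Pipeline: filter genes on the adjusted-p grid, pick a soft power by
scale-free fit, raise |correlation| to that power, form the topological
overlap dissimilarity, cluster with average linkage, cut, dissolve small
clusters into the gray pool, then iteratively merge modules whose
eigengenes correlate at or above the merge threshold and relabel by size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress, spearmanr

from . import eigengenes
from .types import FoldChangeMatrix, ModuleSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "ModuleAssignment",
    "filter_genes",
    "scale_free_fit",
    "select_soft_power",
    "build_network",
    "detect_modules",
    "merge_and_label",
    "build_modules",
]


@dataclass
class CoexpressionNetwork:
    gene_ids: list[str]
    beta: int
    adjacency: np.ndarray  # symmetric, unit diagonal, entries in [0,1]
    tom_dissimilarity: np.ndarray  # symmetric, zero diagonal, entries in [0,1]


@dataclass
class ModuleAssignment:
    gene_ids: list[str]
    labels: np.ndarray  # int per gene; 0 = gray

    def module_sizes(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts)}


def filter_genes(fc: FoldChangeMatrix, alpha: float = 0.001) -> list[str]:
    """Genes with BH-adjusted p strictly below ``alpha`` in >= 1 condition,
    in input order."""
    if fc.adj_p is None:
        raise ValidationError(
            "gene filtering requires an adjusted-p grid; supply one or skip "
            "filtering explicitly"
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    hit = (fc.adj_p < alpha).any(axis=0)
    return [g for g in fc.gene_ids if bool(hit[g])]


def _correlation(X: np.ndarray, method: str) -> np.ndarray:
    if method == "pearson":
        C = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        C = spearmanr(X).statistic
        C = np.atleast_2d(C)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return np.clip(C, -1.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10(frequency) ~ log10(mean connectivity)
    regression over equal-width connectivity bins.

    Positive values require a negative slope (scale-free-like decay);
    degenerate distributions return -1.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k.min(), k.max()):
        return -1.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return -1.0
    fit = linregress(xs, ys)
    r2 = fit.rvalue**2
    return r2 if fit.slope < 0 else -r2


def select_soft_power(
    fc: FoldChangeMatrix,
    candidates: list[int] | None = None,
    r2_target: float = 0.8,
    method: str = "pearson",
    n_bins: int = 10,
) -> int:
    """Smallest candidate power whose scale-free fit reaches ``r2_target``;
    falls back (with a warning) to the best-fitting candidate."""
    if candidates is None:
        candidates = list(range(1, 21))
    if not candidates:
        raise ValueError("candidate list is empty")
    if len(fc.gene_ids) < 10:
        raise ValidationError("scale-free fit undefined for fewer than 10 genes")
    if not fc.is_complete():
        raise ValidationError("soft-power selection requires a complete matrix")
    if len(candidates) == 1:
        return int(candidates[0])
    absC = np.abs(_correlation(fc.values.to_numpy(dtype=float), method))
    np.fill_diagonal(absC, 0.0)
    fits = {}
    for beta in sorted(candidates):
        k = (absC**beta).sum(axis=0)
        fits[beta] = scale_free_fit(k, n_bins=n_bins)
        if fits[beta] >= r2_target:
            return int(beta)
    best = max(fits, key=lambda b: fits[b])
    warnings.warn(
        f"no candidate power reached R^2 >= {r2_target}; using beta={best} "
        f"(R^2 = {fits[best]:.3f})",
        stacklevel=2,
    )
    return int(best)


def build_network(
    fc: FoldChangeMatrix,
    genes: list[str] | None = None,
    beta: int = 5,
    method: str = "pearson",
) -> CoexpressionNetwork:
    """Adjacency a_ij = |cor(i,j)|^beta and the unsigned topological-overlap
    dissimilarity 1 - (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu."""
    if genes is None:
        genes = fc.gene_ids
    sub = fc.values.loc[:, list(genes)]
    if sub.shape[0] < 3:
        raise ValidationError("need at least 3 conditions to build a network")
    if sub.isna().any().any():
        raise ValidationError("network construction requires a complete matrix")
    sd = sub.std(axis=0, ddof=1)
    if (sd <= 0).any():
        g = sd.index[sd <= 0][0]
        raise ValidationError(f"gene {g!r} has zero variance")
    X = sub.to_numpy(dtype=float)
    A = np.abs(_correlation(X, method)) ** beta
    np.fill_diagonal(A, 1.0)
    A = (A + A.T) / 2.0
    k = A.sum(axis=0) - 1.0
    L = A @ A - 2.0 * A  # off-diagonal: sum over u != i,j
    numer = L + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.clip(tom, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    return CoexpressionNetwork(
        gene_ids=list(genes), beta=int(beta), adjacency=A, tom_dissimilarity=dissim
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel positive labels 1..K by decreasing member count (ties keep
    the order of the original labels)."""
    out = np.zeros_like(labels)
    labs, counts = np.unique(labels[labels > 0], return_counts=True)
    order = sorted(range(len(labs)), key=lambda i: (-counts[i], labs[i]))
    for new, i in enumerate(order, start=1):
        out[labels == labs[i]] = new
    return out


def detect_modules(
    net: CoexpressionNetwork,
    min_size: int = 5,
    cut_height: float | None = 0.99,
    cut_q: float | None = None,
) -> ModuleAssignment:
    """Average-linkage clustering of the TOM dissimilarity with a static
    height cut; clusters below ``min_size`` dissolve into the gray pool.

    The cut is at the absolute dissimilarity ``cut_height`` (default 0.99);
    passing ``cut_q`` instead cuts at that quantile of the merge heights.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    n = len(net.gene_ids)
    condensed = squareform(net.tom_dissimilarity, checks=False)
    Z = linkage(condensed, method="average")
    if cut_q is not None:
        height = float(np.quantile(Z[:, 2], cut_q))
    elif cut_height is not None:
        height = float(cut_height)
    else:
        raise ValueError("supply cut_height or cut_q")
    raw = fcluster(Z, t=height, criterion="distance")
    labels = np.asarray(raw, dtype=int)
    labs, counts = np.unique(labels, return_counts=True)
    keep = {int(l) for l, c in zip(labs, counts) if c >= min_size}
    labels = np.where(np.isin(labels, list(keep)), labels, 0)
    if len(keep) == 1 and (labels > 0).sum() == n:
        warnings.warn("all genes fell into a single indivisible cluster", stacklevel=2)
    labels = _relabel_by_size(labels)
    return ModuleAssignment(gene_ids=list(net.gene_ids), labels=labels)


def merge_and_label(
    assign: ModuleAssignment,
    fc: FoldChangeMatrix,
    merge_cor: float = 0.8,
    hub: str = "signed",
    reference_label: str = "",
) -> ModuleSet:
    """Iteratively merge the module pair with the highest eigengene
    correlation >= ``merge_cor`` (recomputing eigengenes after each merge),
    then relabel 1..K by decreasing size and populate corEG/hub/projection
    constants on the reference corpus."""
    if not 0 < merge_cor <= 1:
        raise ValueError("merge_cor must be in (0,1]")
    zfc = eigengenes.standardize_reference(fc.subset_genes(assign.gene_ids))
    members: dict[int, list[str]] = {}
    for g, lab in zip(assign.gene_ids, assign.labels):
        if lab > 0:
            members.setdefault(int(lab), []).append(g)
    if not members:
        raise ValidationError("no modules to merge: every gene is gray")
    while len(members) > 1:
        egs, _ = eigengenes.compute_module_scores(members, zfc)
        C = np.corrcoef(egs.scores.to_numpy(dtype=float))
        ids = list(egs.scores.index)
        qualifying = [
            (float(C[i, j]), (ids[i], ids[j]))
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if C[i, j] >= merge_cor - 1e-12
        ]
        if not qualifying:
            break
        best_cor = max(c for c, _ in qualifying)
        # ties: merge the pair containing the smallest module id
        lo, hi = min(pair for c, pair in qualifying if c >= best_cor - 1e-12)
        logger.info("merging module %d into %d (eigengene cor %.3f)", hi, lo, best_cor)
        members[lo] = members[lo] + members.pop(hi)
    # relabel by decreasing size; ties keep smaller original label first
    order = sorted(members, key=lambda m: (-len(members[m]), m))
    final = {new: members[old] for new, old in enumerate(order, start=1)}
    egs, raw_sd = eigengenes.compute_module_scores(final, zfc)
    fc_used = fc.subset_genes(assign.gene_ids)
    return eigengenes.compute_gene_stats(
        final, fc_used, egs, raw_sd=raw_sd, hub=hub, reference_label=reference_label
    )


def build_modules(
    fc: FoldChangeMatrix,
    alpha: float | None = 0.001,
    beta: int | None = None,
    min_size: int = 5,
    merge_cor: float = 0.8,
    cut_height: float | None = 0.99,
    cut_q: float | None = None,
    hub: str = "signed",
    reference_label: str = "",
) -> tuple[ModuleSet, dict]:
    """Full discovery pipeline; returns the frozen ModuleSet and a build
    report (genes filtered, beta, module count, gray fraction)."""
    genes = filter_genes(fc, alpha) if alpha is not None else fc.gene_ids
    if not genes:
        raise ValidationError("no gene passed the adjusted-p filter")
    fc_f = fc.subset_genes(genes)
    if beta is None:
        beta = select_soft_power(fc_f)
    net = build_network(fc_f, beta=beta)
    assign = detect_modules(net, min_size=min_size, cut_height=cut_height, cut_q=cut_q)
    modules = merge_and_label(
        assign, fc_f, merge_cor=merge_cor, hub=hub, reference_label=reference_label
    )
    n_assigned = sum(m.size for m in modules.modules)
    report = {
        "n_genes_input": len(fc.gene_ids),
        "n_genes_filtered": len(genes),
        "beta": int(beta),
        "n_modules": len(modules.modules),
        "n_genes_assigned": n_assigned,
        "gray_fraction": 1.0 - n_assigned / len(genes),
    }
    return modules, report
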