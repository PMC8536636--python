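"""Module eigengene scores, per-gene corEG statistics and reference
normalization constants.

The raw module score is the first principal component of the standardized
conditions x member-genes submatrix, oriented so that it correlates
positively with the per-condition mean of member z-values; the reported
score is that raw component scaled to unit sample variance across the
reference conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    EigengeneMatrix,
    FoldChangeMatrix,
    Module,
    ModuleSet,
    ValidationError,
)

__all__ = [
    "standardize_reference",
    "module_raw_score",
    "compute_module_scores",
    "compute_gene_stats",
    "flag_perturbations",
    "dimensionality_reduction_pct",
]


def standardize_reference(fc: FoldChangeMatrix) -> FoldChangeMatrix:
    """Per-gene z-score transform (x - mean) / sd with sample (n-1) SD."""
    if not fc.is_complete():
        raise ValidationError("standardization requires a complete matrix")
    X = fc.values
    sd = X.std(axis=0, ddof=1)
    if (sd <= 0).any():
        g = sd.index[sd <= 0][0]
        raise ValidationError(f"gene {g!r} has zero variance across conditions")
    z = (X - X.mean(axis=0)) / sd
    return FoldChangeMatrix(values=z, adj_p=None, meta=fc.meta.copy())


def module_raw_score(Z: np.ndarray) -> np.ndarray:
    """First principal component score of a conditions x genes block,
    sign-oriented to the member-mean profile."""
    if Z.shape[1] == 1:
        raw = Z[:, 0].astype(float).copy()
    else:
        u, s, _ = np.linalg.svd(Z, full_matrices=False)
        raw = u[:, 0] * s[0]
    mean_profile = Z.mean(axis=1)
    num = float(np.dot(raw - raw.mean(), mean_profile - mean_profile.mean()))
    if num < 0:
        raw = -raw
    return raw


def _module_gene_lists(modules) -> list[tuple[int, list[str]]]:
    """Accept a ModuleSet or a {label: genes} style assignment."""
    if isinstance(modules, ModuleSet):
        return [(m.id, list(m.gene_ids)) for m in modules.modules]
    if isinstance(modules, dict):
        return [(int(k), list(v)) for k, v in modules.items()]
    # ModuleAssignment duck-type: has gene_ids + labels
    labels = pd.Series(modules.labels, index=modules.gene_ids)
    out = []
    for lab in sorted(set(labels) - {0}):
        out.append((int(lab), list(labels.index[labels == lab])))
    return out


def compute_module_scores(
    modules, zfc: FoldChangeMatrix
) -> tuple[EigengeneMatrix, dict[int, float]]:
    """Unit-variance eigengene scores per module on the reference corpus.

    Returns the score matrix together with each module's raw-score SD
    (the alternative projection denominator).
    """
    if zfc.shape[0] < 2:
        raise ValidationError("need at least 2 conditions to compute eigengenes")
    gene_index = {g: i for i, g in enumerate(zfc.gene_ids)}
    X = zfc.values.to_numpy(dtype=float)
    rows = {}
    raw_sd: dict[int, float] = {}
    for mid, genes in _module_gene_lists(modules):
        present = [g for g in genes if g in gene_index]
        if not present:
            raise ValidationError(f"module {mid}: no member gene present in the matrix")
        raw = module_raw_score(X[:, [gene_index[g] for g in present]])
        sd = float(np.std(raw, ddof=1))
        if sd <= 0:
            raise ValidationError(f"module {mid}: degenerate (constant) raw score")
        rows[mid] = raw / sd
        raw_sd[mid] = sd
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=zfc.condition_ids)
    scores = scores.sort_index()
    return EigengeneMatrix(scores=scores), raw_sd


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X with y."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Xc * yc[:, None]).sum(axis=0) / denom


def compute_gene_stats(
    modules,
    fc: FoldChangeMatrix,
    egs: EigengeneMatrix,
    raw_sd: dict[int, float] | None = None,
    hub: str = "signed",
    reference_label: str = "",
) -> ModuleSet:
    """Populate corEG, hub genes and projection constants on the reference.

    corEG is the Pearson correlation between each member gene's raw log2FC
    profile and the module score. ``hub='signed'`` picks the member with the
    highest corEG (ties broken lexicographically by gene id); ``hub='abs'``
    picks the highest |corEG|.
    """
    if hub not in ("signed", "abs"):
        raise ValueError(f"hub must be 'signed' or 'abs', got {hub!r}")
    if list(egs.condition_ids) != list(fc.condition_ids):
        raise ValidationError("eigengene matrix and fold-change matrix conditions differ")
    gene_index = {g: i for i, g in enumerate(fc.gene_ids)}
    X = fc.values.to_numpy(dtype=float)
    built: list[Module] = []
    if raw_sd is None:
        raw_sd = {}
    for mid, genes in _module_gene_lists(modules):
        cols = [gene_index[g] for g in genes]
        sub = X[:, cols]
        sd = np.std(sub, axis=0, ddof=1)
        if (sd <= 0).any():
            g = genes[int(np.argwhere(sd <= 0)[0][0])]
            raise ValidationError(f"module {mid}: gene {g!r} is constant; corEG undefined")
        eg = egs.scores.loc[mid].to_numpy(dtype=float)
        cor = _pearson_columns(sub, eg)
        cor_s = pd.Series(cor, index=genes)
        key = cor_s if hub == "signed" else cor_s.abs()
        best = key.max()
        hub_gene = min(g for g in genes if key[g] >= best - 1e-15)
        z_weighted = (sub / sd) @ cor
        sumz_sd = float(np.std(z_weighted, ddof=1))
        if sumz_sd <= 0:
            raise ValidationError(f"module {mid}: degenerate weighted Z sum")
        built.append(
            Module(
                id=int(mid),
                gene_ids=list(genes),
                cor_eg=cor_s,
                hub_gene=hub_gene,
                ref_gene_sd=pd.Series(sd, index=genes),
                ref_sumz_sd=sumz_sd,
                ref_rawscore_sd=float(raw_sd.get(mid, sumz_sd)),
            )
        )
    return ModuleSet(
        modules=built, universe=list(fc.gene_ids), reference_label=reference_label
    )


def flag_perturbations(egs: EigengeneMatrix, threshold: float = 2.0) -> pd.DataFrame:
    """Boolean grid of biologically relevant perturbations: |score| strictly
    above ``threshold``."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    return (egs.scores > threshold) | (egs.scores < -threshold)


def dimensionality_reduction_pct(n_genes: int, n_modules: int, decimals: int = 1) -> float:
    """Percentage reduction from per-gene columns to per-module scores."""
    if n_genes <= 0 or n_modules < 0:
        raise ValueError("counts must be positive")
    return round(100.0 * (1.0 - n_modules / n_genes), decimals)
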