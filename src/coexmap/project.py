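"""Score external datasets against a frozen ModuleSet.

Per member gene present in the external data, a modified Z-score is the
log2FC divided by the gene's reference-corpus SD and weighted by corEG;
absent (or missing) members contribute zero. The module score is the sum of
those Z-scores divided by the module's stored reference denominator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import FoldChangeMatrix, ModuleSet, ProjectedScores, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "project_external",
    "coverage_report",
    "panel_coreg_quality",
    "collapse_duplicate_genes",
]


def collapse_duplicate_genes(
    values: pd.DataFrame, adj_p: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Resolve duplicate gene columns (e.g. multiple probes per gene).

    Keeps, per duplicated gene, the column with the smallest minimum
    companion adj-p when supplied, otherwise the largest maximum |log2FC|.
    """
    if not values.columns.has_duplicates:
        return values, adj_p
    keep: list[int] = []
    cols = values.columns.to_numpy()
    for gene in pd.unique(cols):
        idx = np.flatnonzero(cols == gene)
        if len(idx) == 1:
            keep.append(int(idx[0]))
            continue
        if adj_p is not None:
            crit = [adj_p.iloc[:, i].min() for i in idx]
            chosen = int(idx[int(np.argmin(crit))])
        else:
            crit = [values.iloc[:, i].abs().max() for i in idx]
            chosen = int(idx[int(np.argmax(crit))])
        logger.info("gene %r measured %d times; keeping one entry", gene, len(idx))
        keep.append(chosen)
    keep = sorted(keep)
    return values.iloc[:, keep], None if adj_p is None else adj_p.iloc[:, keep]


def project_external(
    modules: ModuleSet,
    ext: FoldChangeMatrix,
    denominator: str = "sumz",
) -> ProjectedScores:
    """Project an external fold-change matrix onto frozen modules.

    ``denominator='sumz'`` divides by the stored SD of the corEG-weighted Z
    sum (the default); ``'rawscore'`` divides by the stored raw first-
    component SD instead.
    """
    if denominator not in ("sumz", "rawscore"):
        raise ValueError(f"unknown denominator {denominator!r}")
    ext_genes = set(ext.gene_ids)
    if not ext_genes & set(modules.assigned_genes()):
        raise ValidationError(
            "external data shares no gene with any module in the set"
        )
    X = ext.values
    rows: dict[int, np.ndarray] = {}
    cov: dict[int, float] = {}
    for m in modules.modules:
        present = [g for g in m.gene_ids if g in ext_genes]
        cov[m.id] = len(present) / m.size
        denom = m.ref_sumz_sd if denominator == "sumz" else m.ref_rawscore_sd
        if not present:
            rows[m.id] = np.zeros(X.shape[0])
            continue
        sub = X.loc[:, present].to_numpy(dtype=float)
        w = (m.cor_eg[present] / m.ref_gene_sd[present]).to_numpy(dtype=float)
        z = sub * w  # NaN (missing per-condition) contributes zero
        rows[m.id] = np.nansum(z, axis=1) / denom
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=ext.condition_ids)
    scores = scores.sort_index()
    coverage = pd.Series(cov).sort_index()
    return ProjectedScores(scores=scores, coverage=coverage)


def coverage_report(
    modules: ModuleSet,
    panel: list[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-module panel coverage plus a corEG gene-quality comparison.

    The observed mean |corEG| of a module's covered members is compared with
    ``n_draws`` random same-size draws from the pooled |corEG| values of all
    module members; the empirical upper-tail p is Bonferroni-adjusted across
    the modules tested.
    """
    rng = np.random.default_rng(seed)
    panel_set = set(panel)
    pool = np.concatenate(
        [m.cor_eg.abs().to_numpy(dtype=float) for m in modules.modules]
    )
    rows = []
    for m in modules.modules:
        present = [g for g in m.gene_ids if g in panel_set]
        row = {
            "module": m.id,
            "size": m.size,
            "n_in_panel": len(present),
            "coverage": len(present) / m.size,
            "hub_in_panel": m.hub_gene in panel_set,
            "mean_abs_coreg": np.nan,
            "p_empirical": np.nan,
        }
        if present:
            obs = float(m.cor_eg[present].abs().mean())
            draws = rng.choice(pool, size=(n_draws, len(present)), replace=True)
            null_means = draws.mean(axis=1)
            row["mean_abs_coreg"] = obs
            row["p_empirical"] = (1 + int((null_means >= obs).sum())) / (n_draws + 1)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("module")
    n_tested = int(out["p_empirical"].notna().sum())
    out["p_bonferroni"] = np.minimum(out["p_empirical"] * max(n_tested, 1), 1.0)
    return out


def panel_coreg_quality(
    modules: ModuleSet,
    panel: list[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> dict:
    """Panel-level gene-quality comparison: mean |corEG| of all covered
    module members vs random same-size draws from the pooled module genes.

    Returns the observed mean, null mean and the empirical upper-tail p.
    """
    rng = np.random.default_rng(seed)
    panel_set = set(panel)
    coreg = pd.concat([m.cor_eg.abs() for m in modules.modules])
    covered = coreg[coreg.index.isin(panel_set)]
    if covered.empty:
        raise ValidationError("panel covers no module gene")
    pool = coreg.to_numpy(dtype=float)
    obs = float(covered.mean())
    draws = np.array(
        [pool[rng.choice(len(pool), size=len(covered), replace=False)].mean()
         for _ in range(n_draws)]
    )
    p = (1 + int((draws >= obs).sum())) / (n_draws + 1)
    return {
        "n_covered": int(len(covered)),
        "observed_mean_abs_coreg": obs,
        "null_mean": float(draws.mean()),
        "p_empirical": float(p),
    }
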