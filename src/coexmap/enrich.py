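"""Hypergeometric over-representation of gene sets and TF regulons per
module, plus a condition-level TF activity surrogate score.

The activity score is a signed, sqrt(m)-normalized mean of standardized
target fold-changes ("surrogate-NES"); it is NOT the published regulon-rank
NES algorithm and is labeled accordingly in outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import (
    FoldChangeMatrix,
    GeneSetCollection,
    ModuleSet,
    RegulonCollection,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["ora_module", "enrich_modules", "tf_enrichment", "tf_activity"]

CONFIDENCE_TIERS = {
    "high_confidence": ("A", "B", "C"),
    "high_coverage": ("A", "B", "C", "D"),
}


def ora_module(
    module_genes: list[str], gene_set: list[str], universe: list[str]
) -> dict:
    """Exact hypergeometric upper-tail P(X >= k) for the overlap between a
    module and a gene set, both intersected with the universe."""
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    mod = set(module_genes)
    if not mod:
        raise ValidationError("empty module")
    if not mod <= uni:
        g = sorted(mod - uni)[0]
        raise ValidationError(f"module gene {g!r} not in the universe")
    gs = set(gene_set) & uni
    N, K, n = len(uni), len(gs), len(mod)
    k = len(mod & gs)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return {"k": k, "K": K, "n": n, "N": N, "p": min(max(p, 0.0), 1.0)}


def enrich_modules(
    modules: ModuleSet,
    collection: GeneSetCollection,
    p_cut: float = 0.01,
    top_n: int = 10,
    fdr_cut: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ORA of every module against every set in one collection.

    Returns (full table of rows with p < p_cut, per-module annotation of the
    top ``top_n`` rows by ascending p restricted to fdr < fdr_cut). BH is
    applied jointly across all module x set tests within the collection.
    """
    universe = list(modules.universe)
    rows = []
    for m in modules.modules:
        for name, genes in collection.sets.items():
            r = ora_module(m.gene_ids, genes, universe)
            r["module"] = m.id
            r["set_name"] = name
            rows.append(r)
    full = pd.DataFrame(rows)
    full["fdr"] = multipletests(full["p"].to_numpy(), method="fdr_bh")[1]
    full = full[["module", "set_name", "k", "K", "n", "N", "p", "fdr"]]
    table = full[full["p"] < p_cut].sort_values(["module", "p"]).reset_index(drop=True)
    ann_rows = []
    for m in modules.modules:
        sub = table[(table["module"] == m.id) & (table["fdr"] < fdr_cut)]
        sub = sub.nsmallest(top_n, "p")
        if sub.empty:
            ann_rows.append(
                {"module": m.id, "set_name": None, "p": np.nan, "fdr": np.nan}
            )
        else:
            ann_rows.extend(sub[["module", "set_name", "p", "fdr"]].to_dict("records"))
    return table, pd.DataFrame(ann_rows)


def tf_enrichment(
    modules: ModuleSet,
    regulons: RegulonCollection,
    confidence: str = "high_confidence",
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric regulon enrichment per (module, TF), ignoring the mode
    sign; targets restricted to the chosen confidence tier."""
    if confidence not in CONFIDENCE_TIERS:
        raise ValidationError(f"unknown confidence label {confidence!r}")
    classes = CONFIDENCE_TIERS[confidence]
    universe = set(modules.universe)
    rows = []
    for tf in regulons.regulons:
        targets = [t for t, _ in regulons.targets(tf, classes)]
        targets = [t for t in targets if t in universe]
        if not targets:
            logger.info("TF %r has no target in the universe; skipped", tf)
            continue
        for m in modules.modules:
            r = ora_module(m.gene_ids, targets, list(universe))
            r["module"] = m.id
            r["tf"] = tf
            rows.append(r)
    if not rows:
        return pd.DataFrame(columns=["module", "tf", "k", "K", "n", "N", "p", "fdr"])
    full = pd.DataFrame(rows)
    full["fdr"] = multipletests(full["p"].to_numpy(), method="fdr_bh")[1]
    full = full[["module", "tf", "k", "K", "n", "N", "p", "fdr"]]
    return full[full["p"] < p_cut].sort_values(["module", "p"]).reset_index(drop=True)


def tf_activity(
    regulons: RegulonCollection,
    fc: FoldChangeMatrix,
    ref_sd: pd.Series | None = None,
    confidence: str = "high_coverage",
    min_targets: int = 3,
) -> pd.DataFrame:
    """Surrogate-NES TF activity: per condition and TF,
    sum(mode * log2FC / sd) / sqrt(m) over the m measured targets.

    ``ref_sd`` supplies reference-corpus per-gene SDs; genes without one use
    their own SD across ``fc``. TFs with zero measured targets score 0;
    with 1..min_targets-1 measured targets the score is missing.
    """
    if confidence not in CONFIDENCE_TIERS:
        raise ValidationError(f"unknown confidence label {confidence!r}")
    classes = CONFIDENCE_TIERS[confidence]
    own_sd = fc.values.std(axis=0, ddof=1)
    sd = own_sd.copy()
    if ref_sd is not None:
        common = [g for g in sd.index if g in ref_sd.index]
        sd.loc[common] = ref_sd.loc[common]
    Z = fc.values / sd
    out = {}
    for tf in regulons.regulons:
        targets = regulons.targets(tf, classes)
        measured = [(t, m) for t, m in targets if t in Z.columns]
        if not measured:
            out[tf] = pd.Series(0.0, index=fc.condition_ids)
            continue
        genes = [t for t, _ in measured]
        modes = np.array([m for _, m in measured], dtype=float)
        sub = Z.loc[:, genes].to_numpy(dtype=float)
        signed = sub * modes
        m_per_cond = (~np.isnan(sub)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            nes = np.nansum(signed, axis=1) / np.sqrt(m_per_cond)
        nes = np.where(m_per_cond >= min_targets, nes, np.nan)
        nes = np.where(m_per_cond == 0, 0.0, nes)
        out[tf] = pd.Series(nes, index=fc.condition_ids)
    res = pd.DataFrame(out).T
    res.index.name = "tf_surrogate_nes"
    return res
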