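"""Readers and writers for the delimited-text exchange formats.

Fold-change / adjusted-p grids are TSV or CSV with a header row; gene sets
are GMT; regulons a 4-column TSV (tf, target, mode, confidence); ortholog
maps a 2-column TSV; traits a donor x trait TSV of {0,1,NA}. Frozen module
sets round-trip through a versioned JSON document.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_META_PATTERN,
    FoldChangeMatrix,
    GeneSetCollection,
    Module,
    ModuleSet,
    RegulonCollection,
    TraitMatrix,
    ValidationError,
    parse_condition_meta,
)

logger = logging.getLogger(__name__)

MODULE_SCHEMA_VERSION = "1.0"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_grid(
    path: str | Path, missing_token: str, allow_duplicate_columns: bool = False
) -> pd.DataFrame:
    # pandas mangles duplicate header fields (g1 -> g1.1); check the raw line
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split(_sep_for(path))[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen and not allow_duplicate_columns:
            raise ValidationError(f"duplicate column id: {name!r}")
        seen.add(name)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=[missing_token],
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    df.columns = pd.Index(header)  # restore un-mangled names
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate row id: {dup!r}")
    cols = []
    for i in range(df.shape[1]):
        raw = df.iloc[:, i]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric cell {raw[bad].iloc[0]!r} in column "
                f"{df.columns[i]!r}, row {raw.index[bad][0]!r}"
            )
        cols.append(num.astype(float))
    out = pd.concat(cols, axis=1) if cols else df.astype(float)
    out.columns = df.columns
    return out


def read_foldchange_table(
    path: str | Path,
    orientation: str = "conditions-as-rows",
    adjp_path: str | Path | None = None,
    missing_token: str = "NA",
    meta_pattern: str = DEFAULT_META_PATTERN,
    on_duplicate_genes: str = "error",
) -> FoldChangeMatrix:
    """Read a log2 fold-change grid (and optional companion adj-p grid).

    ``orientation`` declares the layout on disk; the returned matrix is
    always conditions x genes. Duplicate ids and non-numeric cells (other
    than ``missing_token``) are rejected with the offending id, unless
    ``on_duplicate_genes='resolve'`` which keeps one measurement per gene
    (smallest companion adj-p, else largest |log2FC|).
    """
    if orientation not in ("conditions-as-rows", "genes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if on_duplicate_genes not in ("error", "resolve"):
        raise ValueError(f"unknown duplicate policy {on_duplicate_genes!r}")
    allow_dup = on_duplicate_genes == "resolve"
    values = _read_grid(path, missing_token, allow_duplicate_columns=allow_dup)
    if orientation == "genes-as-rows":
        values = values.T
    adj_p = None
    if adjp_path is not None:
        adj_p = _read_grid(adjp_path, missing_token, allow_duplicate_columns=allow_dup)
        if orientation == "genes-as-rows":
            adj_p = adj_p.T
        if list(adj_p.index) != list(values.index) or list(adj_p.columns) != list(
            values.columns
        ):
            raise ValidationError("adj_p table axes differ from the fold-change table")
    if allow_dup and values.columns.has_duplicates:
        from .project import collapse_duplicate_genes

        values, adj_p = collapse_duplicate_genes(values, adj_p)
    meta = parse_condition_meta(list(values.index), meta_pattern)
    return FoldChangeMatrix(values=values, adj_p=adj_p, meta=meta)


def write_foldchange_table(fc: FoldChangeMatrix, path: str | Path) -> None:
    fc.values.to_csv(path, sep=_sep_for(path), na_rep="NA")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Empty sets are dropped with a warning; duplicate names and lines with
    fewer than two fields are rejected with the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"malformed GMT line {lineno}: fewer than 2 fields")
            name = fields[0]
            members = [g for g in fields[2:] if g]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r} (line {lineno})")
            if not members:
                warnings.warn(f"gene set {name!r} has no members; dropped", stacklevel=2)
                continue
            sets[name] = members
    return GeneSetCollection(sets=sets, source=str(path))


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


_MODE_TOKENS = {"+1": 1, "1": 1, "-1": -1, "A": 1, "I": -1}


def read_regulons(path: str | Path) -> RegulonCollection:
    """Read a 4-column TSV (tf, target, mode, confidence).

    Mode accepts ``+1``/``-1`` or ``A`` (activating) / ``I`` (inhibiting).
    """
    regulons: dict[str, list[tuple[str, int, str]]] = {}
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 4:
        raise ValidationError("regulon table needs 4 columns: tf, target, mode, confidence")
    for _, row in df.iterrows():
        tf, target, mode_tok, conf = (str(row.iloc[i]).strip() for i in range(4))
        if mode_tok not in _MODE_TOKENS:
            raise ValidationError(f"regulon {tf!r}: unknown mode token {mode_tok!r}")
        regulons.setdefault(tf, []).append((target, _MODE_TOKENS[mode_tok], conf))
    return RegulonCollection(regulons=regulons)


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Read a 2-column (source_id, target_id) TSV."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("ortholog map needs 2 columns: source_id, target_id")
    df = df.iloc[:, :2]
    df.columns = ["source_id", "target_id"]
    return df


def read_traits(path: str | Path, missing_token: str = "NA") -> TraitMatrix:
    values = _read_grid(path, missing_token)
    return TraitMatrix(values=values)


def write_traits(traits: TraitMatrix, path: str | Path) -> None:
    traits.values.to_csv(path, sep=_sep_for(path), na_rep="NA")


# ---------------------------------------------------------------------------
# module-set JSON serialization


def _module_to_dict(m: Module) -> dict:
    return {
        "id": int(m.id),
        "gene_ids": list(m.gene_ids),
        "cor_eg": [float(m.cor_eg[g]) for g in m.gene_ids],
        "hub_gene": m.hub_gene,
        "ref_gene_sd": [float(m.ref_gene_sd[g]) for g in m.gene_ids],
        "ref_sumz_sd": float(m.ref_sumz_sd),
        "ref_rawscore_sd": float(m.ref_rawscore_sd),
    }


def _module_from_dict(d: dict) -> Module:
    genes = list(d["gene_ids"])
    return Module(
        id=int(d["id"]),
        gene_ids=genes,
        cor_eg=pd.Series(d["cor_eg"], index=genes, dtype=float),
        hub_gene=d["hub_gene"],
        ref_gene_sd=pd.Series(d["ref_gene_sd"], index=genes, dtype=float),
        ref_sumz_sd=float(d["ref_sumz_sd"]),
        ref_rawscore_sd=float(d["ref_rawscore_sd"]),
    )


def write_modules(modules: ModuleSet, path: str | Path) -> None:
    doc = {
        "schema_version": MODULE_SCHEMA_VERSION,
        "reference_label": modules.reference_label,
        "universe": list(modules.universe),
        "modules": [_module_to_dict(m) for m in modules.modules],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_modules(path: str | Path) -> ModuleSet:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    version = str(doc.get("schema_version", ""))
    if version.split(".")[0] != MODULE_SCHEMA_VERSION.split(".")[0]:
        raise ValidationError(
            f"unsupported module schema version {version!r} "
            f"(reader supports {MODULE_SCHEMA_VERSION})"
        )
    return ModuleSet(
        modules=[_module_from_dict(d) for d in doc["modules"]],
        universe=list(doc["universe"]),
        reference_label=doc.get("reference_label", ""),
    )


def serialize_modules(
    modules: ModuleSet | None, path: str | Path, direction: str = "write"
) -> ModuleSet:
    """Write or read a frozen ModuleSet; write∘read is the identity."""
    if direction == "write":
        assert modules is not None
        write_modules(modules, path)
        return modules
    if direction == "read":
        return read_modules(path)
    raise ValueError(f"direction must be 'write' or 'read', got {direction!r}")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a modules x conditions score frame as TSV."""
    out = scores.copy()
    out.index.name = "module"
    out.to_csv(path, sep=_sep_for(path), na_rep="NA")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = pd.Index([int(i) for i in df.index], name="module")
    return df
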