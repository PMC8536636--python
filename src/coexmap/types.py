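"""Shared domain types.

All tabular payloads are thin dataclass wrappers around pandas objects so
that axis labels travel with the numbers. Conventions used throughout:

* fold-change matrices are oriented conditions x genes;
* eigengene / projected score matrices are oriented modules x conditions;
* missing values are ``NaN`` in the underlying frames.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FoldChangeMatrix",
    "Module",
    "ModuleSet",
    "EigengeneMatrix",
    "ProjectedScores",
    "GeneSetCollection",
    "RegulonCollection",
    "TraitMatrix",
    "PreservationStats",
    "SeedClusterResult",
    "ValidationError",
    "DEFAULT_META_PATTERN",
    "parse_condition_meta",
]

#: default condition-id layout: ``<compound>_<dose>_<time>``; any field may
#: contain spaces but not underscores (e.g. ``C001_MED_24 hr``).
DEFAULT_META_PATTERN = r"^(?P<compound>[^_]+)_(?P<dose>[^_]+)_(?P<time>[^_]+)$"

META_COLUMNS = ("compound", "dose", "time")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def parse_condition_meta(
    condition_ids: Sequence[str], pattern: str = DEFAULT_META_PATTERN
) -> pd.DataFrame:
    """Parse per-condition (compound, dose, time) metadata from condition ids.

    Ids not matching ``pattern`` get all-null metadata rather than failing.
    """
    rx = re.compile(pattern)
    rows = []
    for cid in condition_ids:
        m = rx.match(cid)
        if m:
            g = m.groupdict()
            rows.append([g.get(c) for c in META_COLUMNS])
        else:
            rows.append([None] * len(META_COLUMNS))
    return pd.DataFrame(rows, index=list(condition_ids), columns=list(META_COLUMNS))


@dataclass
class FoldChangeMatrix:
    """Conditions x genes grid of log2 fold-changes.

    ``adj_p`` (optional) is a BH-adjusted p-value grid with identical axes.
    ``meta`` indexes per-condition compound/dose/time labels; unparsed
    conditions carry nulls.
    """

    values: pd.DataFrame
    adj_p: pd.DataFrame | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()
        if self.meta is None:
            self.meta = parse_condition_meta(self.condition_ids)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def validate(self) -> None:
        _check_unique(self.values.index, "condition")
        _check_unique(self.values.columns, "gene")
        arr = self.values.to_numpy(dtype=float)
        bad = ~np.isfinite(arr) & ~np.isnan(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at condition {self.values.index[i]!r}, "
                f"gene {self.values.columns[j]!r}"
            )
        if self.adj_p is not None:
            if list(self.adj_p.index) != list(self.values.index) or list(
                self.adj_p.columns
            ) != list(self.values.columns):
                raise ValidationError("adj_p axes differ from the value grid")
            p = self.adj_p.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                out = (p < 0) | (p > 1)
            if out.any():
                i, j = np.argwhere(out)[0]
                raise ValidationError(
                    f"adj_p outside [0,1] at condition {self.adj_p.index[i]!r}, "
                    f"gene {self.adj_p.columns[j]!r}"
                )

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def subset_genes(self, genes: Sequence[str]) -> "FoldChangeMatrix":
        return FoldChangeMatrix(
            values=self.values.loc[:, list(genes)].copy(),
            adj_p=None if self.adj_p is None else self.adj_p.loc[:, list(genes)].copy(),
            meta=None if self.meta is None else self.meta.copy(),
        )


@dataclass
class Module:
    """One frozen co-expression module with its projection constants.

    corEG weights and per-gene reference SDs are keyed by gene id;
    ``ref_sumz_sd`` is the reference-corpus SD of the corEG-weighted Z sum
    (the default projection denominator) and ``ref_rawscore_sd`` the SD of
    the raw first-component score (the alternative denominator).
    """

    id: int
    gene_ids: list[str]
    cor_eg: pd.Series
    hub_gene: str
    ref_gene_sd: pd.Series
    ref_sumz_sd: float
    ref_rawscore_sd: float

    def __post_init__(self) -> None:
        self.validate()

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        if not (isinstance(self.id, (int, np.integer)) and self.id > 0):
            raise ValidationError(f"module id must be a positive integer, got {self.id!r}")
        _check_unique(self.gene_ids, f"gene (module {self.id})")
        if self.hub_gene not in self.gene_ids:
            raise ValidationError(
                f"module {self.id}: hub gene {self.hub_gene!r} not in member list"
            )
        for name, series in (("cor_eg", self.cor_eg), ("ref_gene_sd", self.ref_gene_sd)):
            missing = set(self.gene_ids) - set(series.index)
            if missing:
                raise ValidationError(
                    f"module {self.id}: {name} missing for gene {sorted(missing)[0]!r}"
                )
        if (self.cor_eg.abs() > 1 + 1e-9).any():
            g = self.cor_eg.index[(self.cor_eg.abs() > 1 + 1e-9)][0]
            raise ValidationError(f"module {self.id}: |corEG| > 1 for gene {g!r}")
        if not (self.ref_gene_sd > 0).all():
            g = self.ref_gene_sd.index[~(self.ref_gene_sd > 0)][0]
            raise ValidationError(f"module {self.id}: ref_gene_sd <= 0 for gene {g!r}")
        if not self.ref_sumz_sd > 0:
            raise ValidationError(f"module {self.id}: ref_sumz_sd must be > 0")
        if not self.ref_rawscore_sd > 0:
            raise ValidationError(f"module {self.id}: ref_rawscore_sd must be > 0")


@dataclass
class ModuleSet:
    """Hard partition of (a subset of) the universe genes into modules.

    Genes in ``universe`` but in no module form the implicit gray pool
    (label 0).
    """

    modules: list[Module]
    universe: list[str]
    reference_label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(self.universe, "universe gene")
        ids = [m.id for m in self.modules]
        _check_unique([str(i) for i in ids], "module")
        seen: dict[str, int] = {}
        uni = set(self.universe)
        for m in self.modules:
            for g in m.gene_ids:
                if g in seen:
                    raise ValidationError(
                        f"gene {g!r} assigned to modules {seen[g]} and {m.id}"
                    )
                seen[g] = m.id
                if g not in uni:
                    raise ValidationError(
                        f"module {m.id}: gene {g!r} not in the build universe"
                    )

    @property
    def module_ids(self) -> list[int]:
        return [m.id for m in self.modules]

    def __getitem__(self, module_id: int) -> Module:
        for m in self.modules:
            if m.id == module_id:
                return m
        raise KeyError(module_id)

    def labels(self) -> pd.Series:
        """Per-universe-gene module label; 0 = gray."""
        lab = pd.Series(0, index=self.universe, dtype=int)
        for m in self.modules:
            lab.loc[m.gene_ids] = m.id
        return lab

    def assigned_genes(self) -> list[str]:
        out: list[str] = []
        for m in self.modules:
            out.extend(m.gene_ids)
        return out


@dataclass
class EigengeneMatrix:
    """Modules x conditions score matrix (unit variance per module on the
    reference corpus; projected/external scores need not be unit variance)."""

    scores: pd.DataFrame  # index = module ids (int), columns = condition ids

    @property
    def module_ids(self) -> list[int]:
        return list(self.scores.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class ProjectedScores:
    """External-data module scores plus per-module gene coverage."""

    scores: pd.DataFrame  # modules x external conditions
    coverage: pd.Series  # per module, fraction of members measured

    @property
    def module_ids(self) -> list[int]:
        return list(self.scores.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RegulonCollection:
    """TF -> list of (target, mode, confidence) with mode in {+1,-1} and
    confidence class in A..E."""

    regulons: dict[str, list[tuple[str, int, str]]]

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            pairs = set()
            for target, mode, conf in targets:
                if mode not in (1, -1):
                    raise ValidationError(
                        f"regulon {tf!r}: mode must be +1/-1, got {mode!r} for {target!r}"
                    )
                if conf not in ("A", "B", "C", "D", "E"):
                    raise ValidationError(
                        f"regulon {tf!r}: unknown confidence class {conf!r}"
                    )
                if (tf, target) in pairs:
                    raise ValidationError(f"duplicate (TF, target) pair ({tf!r}, {target!r})")
                pairs.add((tf, target))

    def targets(self, tf: str, classes: Sequence[str]) -> list[tuple[str, int]]:
        cls = set(classes)
        return [(t, m) for t, m, c in self.regulons[tf] if c in cls]


@dataclass
class TraitMatrix:
    """Donors x binary traits; NaN = missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "donor")
        _check_unique(self.values.columns, "trait")
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | (arr == 0) | (arr == 1)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"trait value not in {{0,1,NA}} at donor {self.values.index[i]!r}, "
                f"trait {self.values.columns[j]!r}"
            )

    @property
    def donor_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PreservationStats:
    """Per-module preservation summary against one test dataset."""

    module_id: int
    n_shared: int
    observed: dict[str, float] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    z_density: float = float("nan")
    z_connectivity: float = float("nan")
    z_summary: float = float("nan")
    median_rank: float = float("nan")


@dataclass
class SeedClusterResult:
    """Seed/add-in expansion plus (optionally) a Ward clustering of the
    expanded module set."""

    seed_ids: list[int]
    addin_ids: list[int]
    cluster_labels: dict[int, int] = field(default_factory=dict)
    linkage: np.ndarray | None = None

    @property
    def member_ids(self) -> list[int]:
        return list(self.seed_ids) + list(self.addin_ids)

    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for mid, cid in self.cluster_labels.items():
            out.setdefault(cid, []).append(mid)
        return {c: sorted(ms) for c, ms in sorted(out.items())}
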