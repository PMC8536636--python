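"""Seeded generators for synthetic reference corpora, targeted-panel
studies, degraded test datasets and donor cohorts with planted trait
effects.

All generators follow a factor model: gene g in planted module m has
log2FC(c, g) = loading_g * activity_m(c) + noise, background genes are pure
noise. First-component eigengene scoring is exact for this model in the
noiseless limit, which makes recovery behavior analytically predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import FoldChangeMatrix, TraitMatrix, ValidationError

__all__ = [
    "FixtureTruth",
    "generate_reference",
    "generate_panel_study",
    "shuffle_gene_labels",
    "generate_donor_cohort",
    "stack_fold_changes",
]

DOSE_LEVELS = ("LO", "MED", "HI")
DOSE_MULT = {"LO": 0.5, "MED": 1.0, "HI": 1.5}
TIME_LEVELS = ("2 hr", "8 hr", "24 hr")
TIME_MULT = {"2 hr": 0.4, "8 hr": 0.8, "24 hr": 1.2}


@dataclass
class FixtureTruth:
    """Ground truth behind a generated dataset."""

    module_partition: pd.Series  # gene -> planted module id (0 = background)
    latent_activity: pd.DataFrame  # planted module x condition
    loadings: pd.Series  # gene -> loading (0 for background)
    seed: int
    trait_effects: dict = field(default_factory=dict)

    def module_sizes(self) -> dict[int, int]:
        counts = self.module_partition[self.module_partition > 0].value_counts()
        return {int(k): int(v) for k, v in counts.items()}

    def planted_modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, m in self.module_partition.items():
            if m > 0:
                out.setdefault(int(m), []).append(g)
        return out


def _draw_sizes(
    rng: np.random.Generator,
    n_modules: int,
    size_range: tuple[int, int],
    target_total: int,
) -> np.ndarray:
    lo, hi = size_range
    if n_modules * lo > target_total:
        raise ValidationError("module sizes exceed the number of assignable genes")
    sizes = rng.integers(lo, hi + 1, size=n_modules).astype(float)
    sizes = np.clip(np.round(sizes * target_total / sizes.sum()), lo, hi).astype(int)
    # distribute the rounding remainder within bounds
    diff = target_total - int(sizes.sum())
    step = 1 if diff > 0 else -1
    guard = 0
    while diff != 0 and guard < 10 * n_modules:
        i = guard % n_modules
        if lo <= sizes[i] + step <= hi:
            sizes[i] += step
            diff -= step
        guard += 1
    return sizes


def _condition_grid(n_conditions: int, prefix: str = "C") -> pd.DataFrame:
    """Condition ids laid out as compound x dose x time blocks."""
    per_compound = len(DOSE_LEVELS) * len(TIME_LEVELS)
    n_compounds = int(np.ceil(n_conditions / per_compound))
    rows = []
    for i in range(n_compounds):
        for dose in DOSE_LEVELS:
            for time in TIME_LEVELS:
                rows.append((f"{prefix}{i:03d}_{dose}_{time}", f"{prefix}{i:03d}", dose, time))
    rows = rows[:n_conditions]
    return pd.DataFrame(
        rows, columns=["condition", "compound", "dose", "time"]
    ).set_index("condition")


def _activities(
    rng: np.random.Generator, n_modules: int, grid: pd.DataFrame, structured: bool
) -> pd.DataFrame:
    if not structured:
        act = rng.standard_normal((n_modules, len(grid)))
    else:
        compounds = list(dict.fromkeys(grid["compound"]))
        theta = {c: rng.standard_normal(n_modules) for c in compounds}
        cols = []
        for cid, row in grid.iterrows():
            base = theta[row["compound"]]
            cols.append(base * DOSE_MULT[row["dose"]] * TIME_MULT[row["time"]])
        act = np.column_stack(cols)
    return pd.DataFrame(act, index=range(1, n_modules + 1), columns=grid.index)


def _synthesize(
    rng: np.random.Generator,
    truth_partition: pd.Series,
    loadings: pd.Series,
    activity: pd.DataFrame,
    noise_sd: float,
) -> pd.DataFrame:
    genes = list(truth_partition.index)
    n_cond = activity.shape[1]
    X = rng.normal(0.0, noise_sd, size=(n_cond, len(genes)))
    act = activity.to_numpy(dtype=float)
    mod_row = {int(m): i for i, m in enumerate(activity.index)}
    for j, g in enumerate(genes):
        m = int(truth_partition[g])
        if m > 0:
            X[:, j] += loadings[g] * act[mod_row[m]]
    return pd.DataFrame(X, index=activity.columns, columns=genes)


def _adj_p_grid(
    rng: np.random.Generator,
    values: pd.DataFrame,
    truth_partition: pd.Series,
    alpha: float = 0.001,
    background_hit_frac: float = 0.02,
) -> pd.DataFrame:
    """Companion adjusted-p grid: planted-module genes pass the filter at
    their strongest condition; most background genes never do."""
    p = pd.DataFrame(
        rng.uniform(alpha * 2, 1.0, size=values.shape),
        index=values.index,
        columns=values.columns,
    )
    for g in values.columns:
        if truth_partition[g] > 0:
            c = values[g].abs().idxmax()
            p.loc[c, g] = rng.uniform(alpha * 1e-3, alpha * 0.5)
        elif rng.uniform() < background_hit_frac:
            c = values.index[rng.integers(len(values.index))]
            p.loc[c, g] = rng.uniform(alpha * 1e-3, alpha * 0.5)
    return p


def generate_reference(
    n_genes: int = 2000,
    n_modules: int = 20,
    module_size_range: tuple[int, int] = (5, 100),
    n_conditions: int = 200,
    loading_range: tuple[float, float] = (0.6, 0.95),
    noise_sd: float = 0.5,
    background_frac: float = 0.3,
    seed: int = 0,
    structured: bool = True,
) -> tuple[FoldChangeMatrix, FixtureTruth]:
    """Reference corpus with planted co-expressed modules and a companion
    adjusted-p grid; condition ids encode compound/dose/time metadata."""
    if min(n_genes, n_modules, n_conditions) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0 < loading_range[0] <= loading_range[1] <= 1:
        raise ValueError("loading_range must sit within (0, 1]")
    rng = np.random.default_rng(seed)
    n_assigned = int(round((1.0 - background_frac) * n_genes))
    sizes = _draw_sizes(rng, n_modules, module_size_range, n_assigned)
    if sizes.sum() > n_genes:
        raise ValidationError("module sizes exceed the number of genes")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    labels = np.zeros(n_genes, dtype=int)
    order = rng.permutation(n_genes)
    at = 0
    for m, size in enumerate(sizes, start=1):
        labels[order[at : at + size]] = m
        at += size
    partition = pd.Series(labels, index=genes)
    loadings = pd.Series(
        np.where(labels > 0, rng.uniform(*loading_range, size=n_genes), 0.0), index=genes
    )
    grid = _condition_grid(n_conditions)
    activity = _activities(rng, n_modules, grid, structured)
    values = _synthesize(rng, partition, loadings, activity, noise_sd)
    adj_p = _adj_p_grid(rng, values, partition)
    fc = FoldChangeMatrix(values=values, adj_p=adj_p, meta=grid[["compound", "dose", "time"]])
    truth = FixtureTruth(
        module_partition=partition, latent_activity=activity, loadings=loadings, seed=seed
    )
    return fc, truth


def generate_panel_study(
    ref_truth: FixtureTruth,
    panel_frac: float = 0.2,
    bias_high_coreg: bool = False,
    n_conditions: int = 60,
    noise_sd: float = 0.5,
    seed: int = 0,
    bias_strength: float = 8.0,
) -> FoldChangeMatrix:
    """New conditions from the same planted model, with gene columns
    subsampled to ``panel_frac`` (optionally biased toward high-loading,
    i.e. high-corEG, genes)."""
    if not 0 < panel_frac <= 1:
        raise ValueError("panel_frac must be in (0,1]")
    rng = np.random.default_rng(seed)
    genes = list(ref_truth.module_partition.index)
    n_panel = max(1, int(round(panel_frac * len(genes))))
    if bias_high_coreg:
        w = np.exp(bias_strength * ref_truth.loadings.to_numpy(dtype=float))
        w = w / w.sum()
        panel = list(rng.choice(genes, size=n_panel, replace=False, p=w))
    else:
        panel = list(rng.choice(genes, size=n_panel, replace=False))
    if not panel:
        raise ValidationError("empty panel")
    panel = [g for g in genes if g in set(panel)]  # keep reference order
    grid = _condition_grid(n_conditions, prefix="P")
    n_modules = ref_truth.latent_activity.shape[0]
    activity = _activities(rng, n_modules, grid, structured=True)
    values = _synthesize(rng, ref_truth.module_partition, ref_truth.loadings, activity, noise_sd)
    return FoldChangeMatrix(
        values=values.loc[:, panel], adj_p=None, meta=grid[["compound", "dose", "time"]]
    )


def shuffle_gene_labels(fc: FoldChangeMatrix, seed: int = 0) -> FoldChangeMatrix:
    """Destroy module structure by permuting the gene column labels."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(fc.gene_ids))
    values = fc.values.copy()
    values.columns = [fc.gene_ids[i] for i in perm]
    return FoldChangeMatrix(values=values, adj_p=None, meta=fc.meta.copy())


def generate_donor_cohort(
    ref_truth: FixtureTruth,
    n_donors: int = 50,
    traits_spec: dict | None = None,
    concentrations: tuple[str, ...] = DOSE_LEVELS,
    time_label: str = "24 hr",
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, FoldChangeMatrix], TraitMatrix, FixtureTruth]:
    """Donor cohort from the planted model with per-trait planted effects.

    ``traits_spec`` maps trait name -> {"prevalence": float,
    "modules": [planted module ids], "d": {concentration: effect}}; module
    activities of trait-positive donors shift by d (activities have unit
    within-group SD). Returns one FoldChangeMatrix per donor with condition
    ids ``<donor>_<concentration>_<time_label>``.
    """
    if n_donors < 6:
        raise ValueError("n_donors must be >= 6")
    traits_spec = traits_spec or {}
    rng = np.random.default_rng(seed)
    donors = [f"D{i:03d}" for i in range(n_donors)]
    trait_values = {}
    for trait, spec in traits_spec.items():
        prev = float(spec.get("prevalence", 0.5))
        lab = (rng.uniform(size=n_donors) < prev).astype(float)
        if lab.sum() < 3 or (1 - lab).sum() < 3:
            raise ValidationError(
                f"trait {trait!r}: prevalence {prev} left a group below 3 donors"
            )
        trait_values[trait] = lab
    traits = TraitMatrix(values=pd.DataFrame(trait_values, index=donors))

    module_ids = list(ref_truth.latent_activity.index)
    per_donor: dict[str, FoldChangeMatrix] = {}
    effects_used: dict = {}
    for d_i, donor in enumerate(donors):
        cond_ids = [f"{donor}_{conc}_{time_label}" for conc in concentrations]
        act = rng.standard_normal((len(module_ids), len(concentrations)))
        activity = pd.DataFrame(act, index=module_ids, columns=cond_ids)
        for trait, spec in traits_spec.items():
            if traits.values.loc[donor, trait] != 1:
                continue
            for c_i, conc in enumerate(concentrations):
                d_planted = float(spec.get("d", {}).get(conc, 0.0))
                if d_planted:
                    for m in spec.get("modules", []):
                        activity.loc[m, cond_ids[c_i]] += d_planted
                        effects_used[(trait, int(m), conc)] = d_planted
        values = _synthesize(
            rng, ref_truth.module_partition, ref_truth.loadings, activity, noise_sd
        )
        per_donor[donor] = FoldChangeMatrix(values=values, adj_p=None)
    truth = FixtureTruth(
        module_partition=ref_truth.module_partition.copy(),
        latent_activity=ref_truth.latent_activity.copy(),
        loadings=ref_truth.loadings.copy(),
        seed=seed,
        trait_effects=effects_used,
    )
    return per_donor, traits, truth


def stack_fold_changes(matrices: dict[str, FoldChangeMatrix]) -> FoldChangeMatrix:
    """Stack per-donor matrices (identical gene axes) into one matrix."""
    frames = [m.values for m in matrices.values()]
    return FoldChangeMatrix(values=pd.concat(frames, axis=0))
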