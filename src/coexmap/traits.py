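"""Donor-trait association of module/cluster response scores.

Each (unit, trait, concentration) slice at a fixed time point yields a
pooled-SD Cohen's d and a logistic regression of the trait on the unit
score with the per-donor avgAbsEG (overall transcriptional activity) as a
covariate; unit Wald p-values are BH-adjusted across units within the
slice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .types import SeedClusterResult, TraitMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["compute_summary_scores", "cohen_d", "associate_traits"]


def compute_summary_scores(
    scores: pd.DataFrame, clusters: SeedClusterResult
) -> tuple[pd.DataFrame, pd.Series]:
    """Cluster scores (mean of member module scores) and avgAbsEG (mean
    |score| over ALL modules) per condition."""
    groups = clusters.clusters()
    rows = {}
    for cid, mids in groups.items():
        if not mids:
            raise ValidationError(f"cluster {cid} is empty")
        missing = [m for m in mids if m not in scores.index]
        if missing:
            raise ValidationError(f"cluster {cid}: module {missing[0]} has no score row")
        rows[cid] = scores.loc[mids].mean(axis=0)
    cluster_scores = pd.DataFrame(rows).T
    cluster_scores.index.name = "cluster"
    avg_abs_eg = scores.abs().mean(axis=0)
    avg_abs_eg.name = "avgAbsEG"
    return cluster_scores, avg_abs_eg


def cohen_d(pos: np.ndarray, neg: np.ndarray) -> float:
    """Pooled-SD standardized mean difference (positives minus negatives)."""
    n1, n2 = len(pos), len(neg)
    if n1 < 2 or n2 < 2:
        return np.nan
    s1, s2 = np.var(pos, ddof=1), np.var(neg, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        return 0.0 if np.mean(pos) == np.mean(neg) else np.inf * np.sign(np.mean(pos) - np.mean(neg))
    return float((np.mean(pos) - np.mean(neg)) / pooled)


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = 1e-4, n_iter: int = 100):
    """Newton IRLS with a small ridge penalty; returns (coef, se)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None]) + lam * np.eye(p)
        grad = X.T @ (y - mu) - lam * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    H = X.T @ (X * W[:, None]) + lam * np.eye(p)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


@dataclass
class _FitResult:
    coef: float
    p: float
    separation: bool


def _logistic_unit_p(score: np.ndarray, covariate: np.ndarray, y: np.ndarray) -> _FitResult:
    """Wald p of the unit-score coefficient in trait ~ score + avgAbsEG."""
    X = sm.add_constant(np.column_stack([score, covariate]))
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef, p = float(fit.params[1]), float(fit.pvalues[1])
        if not np.isfinite(p) or abs(coef) > 20:
            raise PerfectSeparationError
    except (
        PerfectSeparationError,
        ConvergenceWarning,
        np.linalg.LinAlgError,
        ValueError,
        RuntimeError,
    ):
        separation = True
        beta, se = _ridge_logit(X, y)
        coef = float(beta[1])
        z = coef / se[1] if se[1] > 0 else 0.0
        p = float(2 * norm.sf(abs(z)))
    return _FitResult(coef=coef, p=min(max(p, np.finfo(float).tiny), 1.0), separation=separation)


def associate_traits(
    unit_scores: pd.DataFrame,
    avg_abs_eg: pd.Series,
    traits: TraitMatrix,
    meta: pd.DataFrame,
    time_label: str | None = "24 hr",
    min_group: int = 3,
) -> pd.DataFrame:
    """Associate per-donor unit scores with binary donor traits, one
    concentration at a time.

    ``unit_scores`` is units x conditions; ``meta`` maps each condition to a
    donor (``compound`` column), ``dose`` and ``time``. Conditions are
    restricted to ``time_label`` and analyzed separately per dose; each
    donor must contribute exactly one condition per analyzed slice.
    """
    conditions = [c for c in unit_scores.columns if c in meta.index]
    sel = meta.loc[conditions]
    if time_label is not None:
        sel = sel[sel["time"] == time_label]
    if sel.empty:
        raise ValidationError(f"no condition at time point {time_label!r}")
    rows = []
    for conc in sorted(sel["dose"].dropna().unique()):
        slice_meta = sel[sel["dose"] == conc]
        if slice_meta["compound"].duplicated().any():
            d = slice_meta["compound"][slice_meta["compound"].duplicated()].iloc[0]
            raise ValidationError(
                f"donor {d!r} contributes more than one condition at dose {conc!r}"
            )
        donor_of = dict(zip(slice_meta.index, slice_meta["compound"]))
        cond_ids = list(slice_meta.index)
        donors = [donor_of[c] for c in cond_ids]
        scores = unit_scores.loc[:, cond_ids]
        scores.columns = donors
        activity = avg_abs_eg.loc[cond_ids]
        activity.index = donors
        for trait in traits.trait_names:
            tvals = traits.values[trait].reindex(donors)
            ok = tvals.notna()
            y = tvals[ok].to_numpy(dtype=float)
            used = list(tvals.index[ok])
            n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
            if n_pos < min_group or n_neg < min_group:
                logger.warning(
                    "trait %r at dose %r: group sizes %d/%d below %d; skipped",
                    trait,
                    conc,
                    n_pos,
                    n_neg,
                    min_group,
                )
                continue
            slice_rows = []
            for unit in unit_scores.index:
                s = scores.loc[unit, used].to_numpy(dtype=float)
                d = cohen_d(s[y == 1], s[y == 0])
                fit = _logistic_unit_p(s, activity.loc[used].to_numpy(dtype=float), y)
                slice_rows.append(
                    {
                        "unit": unit,
                        "trait": trait,
                        "concentration": conc,
                        "n_pos": n_pos,
                        "n_neg": n_neg,
                        "cohen_d": d,
                        "coef": fit.coef,
                        "p": fit.p,
                        "separation_flag": fit.separation,
                    }
                )
            sub = pd.DataFrame(slice_rows)
            sub["p_adj"] = multipletests(sub["p"].to_numpy(), method="fdr_bh")[1]
            sub["p_adj"] = sub["p_adj"].clip(lower=np.finfo(float).tiny)
            sub["signed_log10_p_adj"] = -np.log10(sub["p_adj"]) * np.sign(sub["coef"])
            rows.append(sub)
    if not rows:
        raise ValidationError("no analyzable (trait, concentration) slice")
    return pd.concat(rows, ignore_index=True)
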