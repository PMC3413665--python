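"""Per-probeset survival screening and the Wald-weighted risk test.

Pipeline order: administratively censor the cohort at the endpoint
horizon, fit a univariate proportional-hazards model per candidate
probeset, keep the significant ones and bin them into nested Wald-
threshold groups (|S_i| >= 3, 2.5, 2), score patients with the weighted
sum p53RS_j = sum_i S_i * x_ij, pick the group with the best ROC
behaviour on the discovery cohort, and fix sextile score thresholds
(1/6 low | 2/6 intermediate | 3/6 high) for later cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import coxmodel
from .types import (
    AnnotationTable,
    CoxFit,
    ExpressionMatrix,
    RiskThresholds,
    RocResult,
    WeightedSignature,
    as_score_table,
)

__all__ = [
    "censor_at_horizon",
    "fit_univariate_cox",
    "screen_probesets",
    "select_wald_groups",
    "compute_p53rs",
    "roc_evaluate",
    "choose_optimal_group",
    "derive_sextile_thresholds",
    "assign_risk_groups",
]

log = logging.getLogger(__name__)

DEFAULT_WALD_THRESHOLDS = (3.0, 2.5, 2.0)
GROUP_LABELS = ("i", "ii", "iii")


def censor_at_horizon(cohort: AnnotationTable, horizon: float) -> pd.DataFrame:
    """Administrative censoring: events after ``horizon`` years become
    censorings at the horizon; an event exactly at the horizon is kept.

    Returns a fresh (time, event) DataFrame; the input is untouched.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    surv = cohort.survival().copy()
    late = surv["survival_time"] > horizon
    surv.loc[late, "survival_time"] = horizon
    surv.loc[late, "event"] = 0
    return surv


def fit_univariate_cox(
    x: pd.Series, cohort: pd.DataFrame, ties: str = "breslow"
) -> CoxFit:
    """One-probeset proportional-hazards fit on a pre-censored cohort.

    ``cohort`` is a (time, event) frame as returned by
    :func:`censor_at_horizon`; ``x`` is the probeset's expression across
    (a superset of) the cohort samples.  Positive beta means higher
    expression tracks higher hazard.
    """
    common = [s for s in cohort.index if s in x.index]
    xv = x.loc[common].to_numpy(dtype=float)
    if not np.isfinite(xv).all():
        raise ValueError("expression vector contains missing values")
    if np.std(xv) == 0:
        raise ValueError("degenerate covariate")
    res = coxmodel.fit_cox(
        xv,
        cohort.loc[common, "survival_time"].to_numpy(),
        cohort.loc[common, "event"].to_numpy(),
        ties=ties,
    )
    return CoxFit(
        probeset_id=str(x.name),
        beta=float(res.beta[0]),
        se=float(res.se[0]),
        p_value=float(res.p_values[0]),
        flagged=res.flagged,
    )


def screen_probesets(
    expr: ExpressionMatrix,
    cohort: pd.DataFrame,
    probesets: list[str] | None = None,
    ties: str = "breslow",
) -> list[CoxFit]:
    """Univariate screen of each candidate probeset against the endpoint."""
    ids = probesets if probesets is not None else expr.probeset_ids
    fits = []
    for pid in ids:
        if pid not in expr.values.index:
            continue
        try:
            fits.append(fit_univariate_cox(expr.values.loc[pid], cohort, ties=ties))
        except ValueError:
            log.warning("screen: skipping degenerate probeset %s", pid)
    return fits


def select_wald_groups(
    fits: list[CoxFit],
    thresholds: tuple[float, ...] = DEFAULT_WALD_THRESHOLDS,
    alpha: float = 0.05,
    endpoint: dict | None = None,
) -> list[WeightedSignature]:
    """Nested |S_i| >= t groups of significant, non-flagged probesets.

    Thresholds must be strictly decreasing, so group(t1) ⊆ group(t2) for
    t1 > t2.  Probesets enter with their Wald statistics as weights.
    """
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("wald thresholds must be strictly decreasing")
    usable = [f for f in fits if not f.flagged and f.p_value < alpha]
    n_flagged = sum(f.flagged for f in fits)
    if n_flagged:
        log.warning("select_wald_groups: %d flagged fits excluded", n_flagged)
    groups = []
    for label, t in zip(GROUP_LABELS, thresholds):
        members = {f.probeset_id: f.wald for f in usable if abs(f.wald) >= t}
        if not members:
            log.warning("select_wald_groups: group %s (|S|>=%g) is empty", label, t)
        groups.append(
            WeightedSignature(
                walds=pd.Series(members, dtype=float),
                group_label=label,
                endpoint=endpoint or {},
                threshold=t,
            )
        )
    return groups


def compute_p53rs(
    expr: ExpressionMatrix,
    sig: WeightedSignature,
    coverage_floor: float = 0.5,
) -> pd.Series:
    """Wald-weighted risk score: p53RS_j = sum_i S_i * x_ij.

    Signature probesets absent from the matrix are omitted without
    rescaling (coverage logged, error below ``coverage_floor``); missing
    cells fall back to the probeset's within-dataset mean.
    """
    if len(sig) == 0:
        raise ValueError("empty signature")
    present = [p for p in sig.probeset_ids if p in expr.values.index]
    coverage = len(present) / len(sig)
    if coverage < coverage_floor:
        raise ValueError(
            f"signature coverage {coverage:.2f} below floor {coverage_floor}"
        )
    log.info(
        "compute_p53rs: coverage %d/%d probesets on dataset %s",
        len(present),
        len(sig),
        expr.dataset_id,
    )
    sub = expr.values.loc[present]
    n_missing = int(sub.isna().to_numpy().sum())
    if n_missing:
        log.warning("compute_p53rs: imputing %d missing cells with probeset means", n_missing)
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    w = sig.walds.loc[present]
    return as_score_table(sub.mul(w, axis=0).sum(axis=0), "p53RS")


def _binary_outcome(
    scores: pd.Series, cohort: pd.DataFrame, horizon: float, censored_as_negative: bool
) -> tuple[np.ndarray, np.ndarray, int]:
    common = [s for s in cohort.index if s in scores.index]
    t = cohort.loc[common, "survival_time"].to_numpy(dtype=float)
    e = cohort.loc[common, "event"].to_numpy(dtype=int)
    s = scores.loc[common].to_numpy(dtype=float)
    pos = (e == 1) & (t <= horizon)
    neg = (t >= horizon) if not censored_as_negative else ~pos
    usable = pos | neg
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.info("roc: excluded %d samples censored before the horizon", n_excluded)
    return s[usable], pos[usable], n_excluded


def roc_evaluate(
    scores: pd.Series,
    cohort: pd.DataFrame,
    horizon: float,
    sensitivity_floor: float = 1.0,
    censored_as_negative: bool = False,
) -> RocResult:
    """ROC behaviour of a score against event-within-horizon.

    AUC via the Mann–Whitney pair-counting identity (ties count 1/2)
    with a normal-approximation p-value; specificity-at-sensitivity is
    the best specificity achievable by any threshold ("score >= t
    predicts event") whose sensitivity is at least the floor, in percent.
    Samples censored before the horizon have an unknowable outcome and
    are excluded by default.
    """
    if not 0.0 < sensitivity_floor <= 1.0:
        raise ValueError("sensitivity_floor must be a fraction in (0, 1]")
    s, pos, n_excl = _binary_outcome(scores, cohort, horizon, censored_as_negative)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both an event and a non-event class")

    # Mann-Whitney AUC via midranks
    ranks = stats.rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    # normal approximation with tie correction
    n = n1 + n0
    _, counts = np.unique(s, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n0 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        p_auc = 1.0
    else:
        z = (u - n1 * n0 / 2.0) / np.sqrt(var_u)
        p_auc = float(2.0 * stats.norm.sf(abs(z)))

    # exhaustive threshold scan for specificity at the sensitivity floor
    best_spec = 0.0
    for thr in np.unique(s):
        sens = (s[pos] >= thr).mean()
        if sens >= sensitivity_floor - 1e-12:
            spec = (s[~pos] < thr).mean()
            best_spec = max(best_spec, spec)
    return RocResult(
        auc=auc,
        auc_p_value=p_auc,
        specificity_at_sensitivity=float(100.0 * best_spec),
        sensitivity_floor=sensitivity_floor,
        n_positive=n1,
        n_negative=n0,
        n_excluded=n_excl,
    )


def choose_optimal_group(
    groups: list[WeightedSignature],
    expr: ExpressionMatrix,
    cohort: pd.DataFrame,
    horizon: float,
    sensitivity_floor: float = 1.0,
    coverage_floor: float = 0.5,
) -> tuple[WeightedSignature, RocResult]:
    """Score every non-empty group on the discovery cohort and pick the
    winner: highest AUC, then higher specificity at the floor, then the
    smaller probeset count.
    """
    candidates = []
    for g in groups:
        if len(g) == 0:
            continue
        scores = compute_p53rs(expr, g, coverage_floor=coverage_floor)
        roc = roc_evaluate(scores, cohort, horizon, sensitivity_floor)
        candidates.append((g, roc))
    if not candidates:
        raise ValueError("all candidate groups are empty")
    best = max(
        candidates,
        key=lambda gr: (gr[1].auc, gr[1].specificity_at_sensitivity, -len(gr[0])),
    )
    log.info(
        "choose_optimal_group: selected group %s (%d probesets, AUC=%.3f, spec=%.1f%%)",
        best[0].group_label,
        len(best[0]),
        best[1].auc,
        best[1].specificity_at_sensitivity,
    )
    return best


def derive_sextile_thresholds(scores: pd.Series) -> RiskThresholds:
    """Sextile cutoffs on the derivation cohort: lower = 1/6 quantile,
    upper = 3/6 quantile, type-1 (inverse empirical CDF) so cutoffs are
    observed scores.
    """
    if len(scores) < 6:
        raise ValueError("need >=6 samples for sextile thresholds")
    vals = scores.to_numpy(dtype=float)
    lower = float(np.quantile(vals, 1.0 / 6.0, method="inverted_cdf"))
    upper = float(np.quantile(vals, 3.0 / 6.0, method="inverted_cdf"))
    if lower >= upper:
        raise ValueError("degenerate score distribution (tied sextile cutoffs)")
    return RiskThresholds(lower=lower, upper=upper, scale="raw")


def assign_risk_groups(
    scores: pd.Series, thr: RiskThresholds, score_scale: str = "raw"
) -> pd.DataFrame:
    """Label samples low / intermediate / high.

    Boundary convention (lower-closed on intermediate and high):
    low < lower <= intermediate < upper <= high.
    """
    if score_scale != thr.scale:
        raise ValueError(
            f"score scale {score_scale!r} does not match threshold scale {thr.scale!r}"
        )
    s = scores.astype(float)
    group = pd.Series("intermediate", index=s.index, dtype=object)
    group[s < thr.lower] = "low"
    group[s >= thr.upper] = "high"
    return pd.DataFrame({"score": s, "group": group})
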