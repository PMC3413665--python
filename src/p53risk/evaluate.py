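"""Survival evaluation of risk assignments.

Kaplan–Meier product-limit curves (deaths processed before censorings at
tied times), the k-group log-rank test with hypergeometric variance,
and proportional-hazards summaries of risk-group contrasts — univariate
or multivariable and optionally stratified by dataset, in which case the
partial likelihood is computed within strata and summed so each dataset
keeps its own baseline hazard.  95% CIs are Wald intervals on the
log-hazard scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import coxmodel
from .types import AssociationResult, KmCurve

__all__ = [
    "kaplan_meier",
    "logrank_test",
    "group_hazard_ratio",
    "stratified_multivariate_cox",
    "evaluation_report",
]

log = logging.getLogger(__name__)


def kaplan_meier(time, event) -> KmCurve:
    """Product-limit estimator of the survival function."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("empty group")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    uniq = np.unique(time[event == 1])
    surv, at_risk, n_events = [], [], []
    s = 1.0
    for t in uniq:
        # deaths before censorings at equal times: at risk = everyone with time >= t
        n = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n
        surv.append(s)
        at_risk.append(n)
        n_events.append(d)
    return KmCurve(
        times=uniq,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_events, dtype=int),
        censor_times=np.sort(time[event == 0]),
    )


def logrank_test(time, event, group) -> tuple[float, int, float]:
    """k-group log-rank test.

    Returns (chi-square statistic, df = k-1, p).  Tied event times are
    handled jointly through the hypergeometric mean and variance of the
    per-group death counts.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels, gidx = np.unique(np.asarray(group), return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs >=2 non-empty groups")

    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        d = int(((time == t) & (event == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(time == t) & (event == 1)], minlength=k).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            hyper = d * (n - d) / (n - 1)
            V += hyper * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _contrast_results(
    res: coxmodel.CoxModelResult, names: list[str], flagged_extra: bool = False
) -> list[AssociationResult]:
    lo, hi = res.ci(0.95)
    out = []
    with np.errstate(over="ignore"):  # unstable fits legitimately yield inf bounds
        for j, name in enumerate(names):
            out.append(
                AssociationResult(
                    label=name,
                    hr=float(np.exp(res.beta[j])),
                    ci_low=float(np.exp(lo[j])),
                    ci_high=float(np.exp(hi[j])),
                    p_value=float(res.p_values[j]),
                    flagged=res.flagged or flagged_extra,
                )
            )
    return out


def _group_dummies(
    assignment: pd.DataFrame, reference_group: str
) -> tuple[pd.DataFrame, list[str]]:
    groups = assignment["group"]
    levels = [g for g in pd.unique(groups) if g != reference_group]
    if reference_group not in set(groups):
        raise ValueError(f"reference group {reference_group!r} is empty")
    # stable, interpretable order: low < intermediate < high < anything else
    rank = {"low": 0, "intermediate": 1, "high-intermediate": 2, "high": 3}
    levels = sorted(levels, key=lambda g: (rank.get(g, 9), g))
    X = pd.DataFrame(
        {f"{g} vs {reference_group}": (groups == g).astype(float) for g in levels},
        index=assignment.index,
    )
    return X, list(X.columns)


def group_hazard_ratio(
    cohort: pd.DataFrame,
    assignment: pd.DataFrame,
    reference_group: str = "low",
    ties: str = "breslow",
) -> list[AssociationResult]:
    """Univariate risk-group hazard ratios vs a reference group.

    ``cohort`` is a pre-censored (time, event) frame.  Groups with no
    events yield flagged (unstable) estimates rather than an error.
    """
    common = [s for s in cohort.index if s in assignment.index]
    X, names = _group_dummies(assignment.loc[common], reference_group)
    ev = cohort.loc[common, "event"]
    no_event_groups = [
        g for g in pd.unique(assignment.loc[common, "group"])
        if ev[assignment.loc[common, "group"] == g].sum() == 0
    ]
    if no_event_groups:
        log.warning("group_hazard_ratio: no events in groups %s", no_event_groups)
    res = coxmodel.fit_cox(
        X.to_numpy(),
        cohort.loc[common, "survival_time"].to_numpy(),
        ev.to_numpy(),
        ties=ties,
    )
    return _contrast_results(res, names, flagged_extra=bool(no_event_groups))


def stratified_multivariate_cox(
    cohort: pd.DataFrame,
    assignment: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    strata: pd.Series | None = None,
    reference_group: str = "low",
    ties: str = "breslow",
) -> list[AssociationResult]:
    """Multivariable fit of risk group (as indicator contrasts) plus
    clinical covariates, optionally stratified by dataset.

    One stratum reduces exactly to the unstratified fit.  Covariates
    constant across the whole design raise an error.
    """
    common = [s for s in cohort.index if s in assignment.index]
    X, names = _group_dummies(assignment.loc[common], reference_group)
    if covariates is not None:
        cov = covariates.loc[common].astype(float)
        X = pd.concat([X, cov], axis=1)
        names = names + list(cov.columns)
    arr = X.to_numpy()
    if np.any(arr.std(axis=0) == 0):
        bad = [names[j] for j in np.nonzero(arr.std(axis=0) == 0)[0]]
        raise ValueError(f"covariates constant across the cohort: {bad}")
    strat = None if strata is None else strata.loc[common].to_numpy()
    res = coxmodel.fit_cox(
        arr,
        cohort.loc[common, "survival_time"].to_numpy(),
        cohort.loc[common, "event"].to_numpy(),
        strata=strat,
        ties=ties,
    )
    return _contrast_results(res, names)


def _fmt(x) -> object:
    if isinstance(x, (float, np.floating)):
        return float(f"{float(x):.12g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_fmt(v) for v in x.tolist()]
    return x


def evaluation_report(
    results: dict,
    tsv_path,
    json_path,
    config_echo: dict | None = None,
) -> None:
    """Write association results / log-rank / ROC summaries as TSV + JSON.

    ``results`` maps section name to either a list of
    :class:`AssociationResult`, a mapping of scalars, or a DataFrame.
    Outputs use fixed 12-significant-digit float formatting so a rerun
    on the same inputs is byte-identical.
    """
    if not results:
        log.warning("evaluation_report: empty result set")
    rows = []
    payload: dict = {"config": config_echo or {}, "sections": {}}
    for section, value in sorted(results.items()):
        if isinstance(value, list) and all(isinstance(v, AssociationResult) for v in value):
            sec = [
                {k: _fmt(v) for k, v in asdict(item).items()} for item in value
            ]
            for item in sec:
                rows.append({"section": section, **item})
            payload["sections"][section] = sec
        elif isinstance(value, pd.DataFrame):
            recs = value.reset_index().to_dict(orient="records")
            recs = [{k: _fmt(v) for k, v in r.items()} for r in recs]
            for r in recs:
                rows.append({"section": section, **r})
            payload["sections"][section] = recs
        elif isinstance(value, dict):
            sec = {k: _fmt(v) for k, v in value.items()}
            rows.append({"section": section, **sec})
            payload["sections"][section] = sec
        else:
            rows.append({"section": section, "value": _fmt(value)})
            payload["sections"][section] = _fmt(value)
    frame = pd.DataFrame(rows)
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.12g")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
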