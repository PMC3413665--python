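"""Scoring FFPE qRT-PCR cohorts with the genomic(-clinical) test.

Ct values are normalised against the per-sample mean of the housekeeping
panel (reference set: ACTB, GAPDH, GUSB, RPLP0, TBP, TFRC); the ΔCt is
oriented so that larger values mean more transcript and behave like log2
expression, which lets the array-derived Wald weights keep their signs.
Samples whose housekeeping panel failed (too few amplifications, or a
housekeeping mean far from the cohort's) are excluded before scoring.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import MERGED_LABEL, QpcrTable, RiskThresholds, as_score_table
from .screen import assign_risk_groups

__all__ = [
    "normalize_ct",
    "exclude_failed_samples",
    "compute_pcr_p53rs",
    "stratify_two_group",
]

log = logging.getLogger(__name__)

REFERENCE_HOUSEKEEPING = ("ACTB", "GAPDH", "GUSB", "RPLP0", "TBP", "TFRC")


def exclude_failed_samples(
    tbl: QpcrTable,
    k_mad: float = 3.0,
    min_housekeeping: int = 2,
) -> tuple[QpcrTable, pd.DataFrame]:
    """Drop samples with failed or aberrant housekeeping amplification.

    Rules: (a) fewer than ``min_housekeeping`` housekeeping Ct values;
    (b) housekeeping mean Ct further than ``k_mad`` normal-consistent
    MADs from the cohort median.  Returns the retained table plus an
    exclusion report (sample, reason).
    """
    hk = tbl.ct[tbl.housekeeping]
    n_ok = hk.notna().sum(axis=1)
    hk_mean = hk.mean(axis=1)

    reasons: dict[str, str] = {}
    for s in tbl.ct.index[n_ok < min_housekeeping]:
        reasons[s] = "insufficient housekeeping amplification"

    valid_means = hk_mean[n_ok >= min_housekeeping]
    if len(valid_means) >= 3:
        center = valid_means.median()
        mad = stats.median_abs_deviation(valid_means, scale="normal")
        cut = k_mad * mad if mad > 0 else 0.0
        for s, m in valid_means.items():
            if abs(m - center) > cut + 1e-12:
                reasons[s] = "aberrant housekeeping Ct level"
    if len(reasons) == len(tbl.ct):
        raise ValueError("every sample excluded by housekeeping QC")
    report = pd.DataFrame(
        sorted(reasons.items()), columns=["sample_id", "reason"]
    )
    retained = QpcrTable(
        ct=tbl.ct.drop(index=list(reasons)), housekeeping=list(tbl.housekeeping)
    )
    if reasons:
        log.warning("exclude_failed_samples: dropped %d samples", len(reasons))
    return retained, report


def normalize_ct(tbl: QpcrTable) -> pd.DataFrame:
    """ΔCt expression surrogate: e_gj = mean(housekeeping Ct_j) - Ct_gj.

    Invariant to any per-sample additive Ct shift.  Samples with fewer
    than two housekeeping values are dropped with a warning (run
    :func:`exclude_failed_samples` first to get a report).
    """
    hk = tbl.ct[tbl.housekeeping]
    ok = hk.notna().sum(axis=1) >= 2
    if (~ok).any():
        log.warning(
            "normalize_ct: dropping %d samples with <2 housekeeping values",
            int((~ok).sum()),
        )
    ref = hk.loc[ok].mean(axis=1)
    expr = tbl.ct.loc[ok, tbl.test_genes].rsub(ref, axis=0)
    return expr


def compute_pcr_p53rs(
    norm_expr: pd.DataFrame,
    gene_weights: pd.Series,
    coverage_floor: float = 0.5,
) -> tuple[pd.Series, list[str]]:
    """Wald-weighted PCR risk score over measured genes.

    PCR-p53RS_j = sum_g W_g * e_gj.  Samples measuring fewer than
    ``coverage_floor`` of the signature genes are flagged and returned
    separately (excluded from stratification).
    """
    genes = [g for g in gene_weights.index if g in norm_expr.columns]
    if len(genes) / len(gene_weights) < coverage_floor:
        raise ValueError(
            f"only {len(genes)}/{len(gene_weights)} signature genes measured"
        )
    sub = norm_expr[genes]
    frac = sub.notna().mean(axis=1)
    flagged = list(sub.index[frac < coverage_floor])
    if flagged:
        log.warning("compute_pcr_p53rs: %d samples below gene-coverage floor", len(flagged))
    w = gene_weights.loc[genes]
    scores = sub.mul(w, axis=1).sum(axis=1, min_count=1)
    scores = scores.drop(index=flagged)
    return as_score_table(scores, "PCR-p53RS"), flagged


def stratify_two_group(scores: pd.Series, thr: RiskThresholds) -> pd.DataFrame:
    """Three-group assignment with intermediate and high merged.

    Used for small cohorts: the usual low/intermediate/high labels are
    computed on the z scale first, then intermediate and high collapse
    into a single "high-intermediate" group.  Idempotent.
    """
    assignment = assign_risk_groups(scores, thr, score_scale=thr.scale)
    merged = assignment["group"].replace(
        {"intermediate": MERGED_LABEL, "high": MERGED_LABEL}
    )
    out = assignment.copy()
    out["group"] = merged
    return out
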