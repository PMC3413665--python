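"""Tumour-vs-normal centroid template and per-sample centroid correlation.

The comparison works in three moves: per-probeset z-scoring within a
dataset, a two-sample Student t comparison of tumour vs normal to build a
T-value centroid, and a per-sample Pearson correlation of each z-scored
profile against that centroid, with a t-transform p-value.  Also houses
the RLE per-sample quality summary.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AnnotationTable, CentroidTemplate, ExpressionMatrix

__all__ = [
    "standardize",
    "derive_centroid",
    "centroid_correlation",
    "group_mean_correlation",
    "order_for_heatmap",
    "rle_qc",
]

log = logging.getLogger(__name__)

#: smallest representable positive double, reported when |r| = 1 exactly
_TINY_P = float(np.nextafter(0.0, 1.0))


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-probeset z-scores within the dataset (sample sd, denominator n-1).

    Probesets with zero variance or fewer than 2 non-missing values are
    dropped with a logged warning, never silently zeroed.
    """
    v = expr.values
    mean = v.mean(axis=1, skipna=True)
    sd = v.std(axis=1, ddof=1, skipna=True)
    n_ok = v.notna().sum(axis=1)
    bad = (sd == 0) | sd.isna() | (n_ok < 2)
    if bad.any():
        log.warning(
            "standardize: dropping %d zero-variance/undersampled probesets: %s",
            int(bad.sum()),
            list(v.index[bad])[:10],
        )
    z = v.loc[~bad].sub(mean[~bad], axis=0).div(sd[~bad], axis=0)
    return ExpressionMatrix(z, expr.dataset_id)


def derive_centroid(
    expr: ExpressionMatrix,
    labels: AnnotationTable,
    t_threshold: float = 3.0,
    max_fdr: float = 0.05,
    tumour_label: str = "carcinoma",
    normal_label: str = "normal",
    welch: bool = False,
) -> CentroidTemplate:
    """Two-class T-value template (tumour vs normal, positive = up in tumour).

    Probesets pass selection when their Benjamini–Hochberg FDR is at most
    ``max_fdr`` *and* |T| is at least ``t_threshold``.  Student's pooled-
    variance t is the default; ``welch=True`` drops the equal-variance
    assumption.
    """
    cls = labels.df["class_label"]
    tum = [s for s in expr.sample_ids if cls.get(s) == tumour_label]
    nor = [s for s in expr.sample_ids if cls.get(s) == normal_label]
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError(
            f"need >=2 samples per class, got {len(tum)} tumour / {len(nor)} normal"
        )
    t, p = stats.ttest_ind(
        expr.values[tum], expr.values[nor], axis=1, equal_var=not welch
    )
    ok = np.isfinite(t)
    reject = np.zeros(len(t), dtype=bool)
    if ok.any():
        reject[ok] = multipletests(p[ok], alpha=max_fdr, method="fdr_bh")[0]
    selected = reject & (np.abs(t) >= t_threshold)
    if not selected.any():
        raise ValueError(
            "no probeset passed selection; relax t_threshold and/or max_fdr"
        )
    t_values = pd.Series(t[selected], index=expr.values.index[selected])
    log.info(
        "derive_centroid: selected %d/%d probesets (|T|>=%g, FDR<=%g)",
        len(t_values),
        len(t),
        t_threshold,
        max_fdr,
    )
    return CentroidTemplate(
        t_values,
        metadata={
            "source_dataset": expr.dataset_id,
            "t_threshold": t_threshold,
            "max_fdr": max_fdr,
            "tumour_label": tumour_label,
            "normal_label": normal_label,
            "welch": welch,
        },
    )


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r over pairwise-complete entries, p from the t-transform."""
    ok = np.isfinite(x) & np.isfinite(y)
    m = int(ok.sum())
    if m < 3:
        raise ValueError(f"need >=3 shared finite values, got {m}")
    xv, yv = x[ok], y[ok]
    xv = xv - xv.mean()
    yv = yv - yv.mean()
    denom = np.sqrt((xv @ xv) * (yv @ yv))
    if denom == 0:
        raise ValueError("zero variance in correlation input")
    r = float(np.clip((xv @ yv) / denom, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, _TINY_P, m
    t = r * np.sqrt((m - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), m - 2))
    return r, max(p, _TINY_P), m


def centroid_correlation(
    z_expr: ExpressionMatrix, centroid: CentroidTemplate
) -> pd.DataFrame:
    """Per-sample Pearson correlation against the centroid T-vector.

    Returns a DataFrame indexed by sample id with columns ``pearson_r``,
    ``p_value``, ``n_probesets_used``.  Missing values are excluded
    pairwise, with the degrees of freedom adjusted per sample.
    """
    shared = [p for p in centroid.probeset_ids if p in z_expr.values.index]
    if len(shared) < 3:
        raise ValueError(
            f"need >=3 probesets shared with the centroid, got {len(shared)}"
        )
    tv = centroid.t_values.loc[shared].to_numpy()
    sub = z_expr.values.loc[shared]
    arr = sub.to_numpy()

    rows = []
    if np.isfinite(arr).all():
        # vectorised path (no missing values)
        m = len(shared)
        x = arr - arr.mean(axis=0)
        y = tv - tv.mean()
        denom = np.sqrt((x * x).sum(axis=0) * (y @ y))
        if (denom == 0).any():
            raise ValueError("zero variance in correlation input")
        r = np.clip((x.T @ y) / denom, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((m - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), m - 2)
        p = np.where(np.abs(r) >= 1.0, _TINY_P, np.maximum(p, _TINY_P))
        for j, s in enumerate(sub.columns):
            rows.append((s, float(r[j]), float(p[j]), m))
    else:
        for s in sub.columns:
            r, p, m = _pearson_with_p(sub[s].to_numpy(), tv)
            rows.append((s, r, p, m))
    return pd.DataFrame(
        rows, columns=["sample_id", "pearson_r", "p_value", "n_probesets_used"]
    ).set_index("sample_id")


def group_mean_correlation(
    results: pd.DataFrame, grouping: dict[str, str]
) -> pd.DataFrame:
    """Arithmetic mean correlation per group (e.g. genotype x tissue).

    Every sample in ``results`` must be assigned; groups that end up
    empty are omitted with a warning.
    """
    missing = [s for s in results.index if s not in grouping]
    if missing:
        raise ValueError(f"samples without group assignment: {missing[:10]}")
    g = pd.Series({s: grouping[s] for s in results.index})
    out = (
        results["pearson_r"]
        .groupby(g)
        .agg(mean_r="mean", n="size")
        .reset_index(names="group")
        .sort_values("group", kind="stable")
        .reset_index(drop=True)
    )
    for name in set(grouping.values()) - set(out["group"]):
        log.warning("group_mean_correlation: empty group %r omitted", name)
    return out


def order_for_heatmap(
    z_expr: ExpressionMatrix,
    centroid: CentroidTemplate,
    results: pd.DataFrame,
) -> tuple[list[str], list[str]]:
    """Display ordering: samples by increasing r, probesets by decreasing T.

    Ties in r break lexicographically by sample id so the layout is
    reproducible.  Rendering is left to the caller.
    """
    missing = set(z_expr.sample_ids) - set(results.index)
    if missing:
        raise ValueError(f"correlation results missing for samples: {sorted(missing)[:10]}")
    r = results.loc[list(z_expr.sample_ids), "pearson_r"]
    sample_order = sorted(r.index, key=lambda s: (r[s], s))
    shared = [p for p in centroid.probeset_ids if p in z_expr.values.index]
    tv = centroid.t_values.loc[shared]
    probe_order = list(tv.sort_values(ascending=False, kind="stable").index)
    return sample_order, probe_order


def rle_qc(
    expr: ExpressionMatrix,
    median_limit: float = 1.0,
    iqr_limit: float = 1.0,
) -> pd.DataFrame:
    """Relative log expression per-sample QC.

    RLE_ij = x_ij - median_i(x); a sample is flagged when the absolute
    median or the IQR of its RLE distribution exceeds the limits.
    Returns a DataFrame indexed by sample id with ``rle_median``,
    ``rle_iqr``, ``flagged``.
    """
    if expr.shape[1] < 3:
        raise ValueError("RLE QC needs >=3 samples")
    rle = expr.values.sub(expr.values.median(axis=1), axis=0)
    med = rle.median(axis=0)
    iqr = rle.quantile(0.75, axis=0) - rle.quantile(0.25, axis=0)
    flagged = (med.abs() > median_limit) | (iqr > iqr_limit)
    return pd.DataFrame(
        {"rle_median": med, "rle_iqr": iqr, "flagged": flagged},
        index=expr.values.columns,
    )
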