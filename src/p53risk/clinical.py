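"""Clinical risk model: covariate coding, CRS, and the combined GRS.

Gender is coded female = -1 / male = +1 and stage IA = 1, IB = 2, II or
later = 3; age stays continuous.  Each coded variable is z-scored within
the cohort, a multivariable proportional-hazards fit supplies per-
variable Wald weights, CRS_j = sum_v Wald_v * z_vj, and the combined
score GRS_j = z(p53RS)_j + z(CRS)_j lives on the z scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import coxmodel
from .types import AnnotationTable, as_score_table

__all__ = [
    "encode_clinical",
    "fit_clinical_weights",
    "compute_crs",
    "combine_grs",
    "zscore",
]

log = logging.getLogger(__name__)

CLINICAL_VARS = ("age", "gender", "stage")
_STAGE_CODE = {"IA": 1.0, "IB": 2.0}
_GENDER_CODE = {"female": -1.0, "male": 1.0}


def _code_stage(token: str, sample: str) -> float:
    if token in _STAGE_CODE:
        return _STAGE_CODE[token]
    # any stage II or later collapses to 3
    if isinstance(token, str) and (token.startswith("II") or token in ("IV", "III")):
        return 3.0
    raise ValueError(f"unrecognised stage token {token!r} for sample {sample!r}")


def zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot z-score degenerate column {s.name!r}")
    return (s - s.mean()) / sd


def encode_clinical(cohort: AnnotationTable) -> pd.DataFrame:
    """Numeric coding plus within-cohort z-scores of age/gender/stage.

    Returns a DataFrame indexed by sample id with columns ``age``,
    ``gender_code``, ``stage_code`` and ``z_age``, ``z_gender``,
    ``z_stage``.  Missing covariates are an error, not imputed.
    """
    df = cohort.df
    for col in ("age", "gender", "stage"):
        if col not in df.columns:
            raise ValueError(f"annotation table lacks clinical column {col!r}")
        if df[col].isna().any():
            bad = df.index[df[col].isna()].tolist()
            raise ValueError(f"missing {col} for samples {bad[:10]}")
    bad_gender = sorted(set(df["gender"]) - set(_GENDER_CODE))
    if bad_gender:
        raise ValueError(f"unrecognised gender tokens: {bad_gender}")
    enc = pd.DataFrame(
        {
            "age": df["age"].astype(float),
            "gender_code": df["gender"].map(_GENDER_CODE),
            "stage_code": [
                _code_stage(tok, s) for s, tok in df["stage"].items()
            ],
        },
        index=df.index,
    )
    enc["z_age"] = zscore(enc["age"])
    enc["z_gender"] = zscore(enc["gender_code"])
    enc["z_stage"] = zscore(enc["stage_code"])
    return enc


def fit_clinical_weights(
    encoding: pd.DataFrame, cohort: pd.DataFrame, ties: str = "breslow"
) -> pd.Series:
    """Multivariable proportional-hazards Wald weights for age, gender, stage.

    ``cohort`` is a pre-censored (time, event) frame; the fit runs on the
    z-scored columns so the weights are per-SD log-hazard Walds.
    """
    common = [s for s in cohort.index if s in encoding.index]
    if len(common) < len(cohort):
        log.warning(
            "fit_clinical_weights: %d cohort samples lack encoding",
            len(cohort) - len(common),
        )
    Z = encoding.loc[common, ["z_age", "z_gender", "z_stage"]].to_numpy()
    res = coxmodel.fit_cox(
        Z,
        cohort.loc[common, "survival_time"].to_numpy(),
        cohort.loc[common, "event"].to_numpy(),
        ties=ties,
    )
    if res.flagged:
        raise ValueError("clinical fit unstable (singular design or separation)")
    return pd.Series(res.wald, index=list(CLINICAL_VARS), name="wald")


def compute_crs(encoding: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """CRS_j = sum_v Wald_v * z_vj over age, gender, stage."""
    zcols = encoding[["z_age", "z_gender", "z_stage"]]
    incomplete = zcols.isna().any(axis=1)
    if incomplete.any():
        log.warning(
            "compute_crs: skipping %d samples with missing covariates",
            int(incomplete.sum()),
        )
        zcols = zcols.loc[~incomplete]
    w = weights.loc[list(CLINICAL_VARS)].to_numpy()
    return as_score_table(pd.Series(zcols.to_numpy() @ w, index=zcols.index), "CRS")


def combine_grs(p53rs: pd.Series, crs: pd.Series) -> pd.Series:
    """GRS_j = z(p53RS)_j + z(CRS)_j, z-scored within the cohort being combined."""
    only_a = sorted(set(p53rs.index) - set(crs.index))
    only_b = sorted(set(crs.index) - set(p53rs.index))
    if only_a or only_b:
        raise ValueError(
            f"sample sets differ: {len(only_a)} only in p53RS (e.g. {only_a[:5]}), "
            f"{len(only_b)} only in CRS (e.g. {only_b[:5]})"
        )
    crs = crs.loc[p53rs.index]
    return as_score_table(zscore(p53rs) + zscore(crs), "GRS")
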