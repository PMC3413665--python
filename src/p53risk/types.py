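"""Domain containers shared across the pipeline.

Conventions used throughout the package:

* expression matrices are log2-scale, rows = probesets, columns = samples;
* survival times are in **years**; an endpoint horizon (e.g. distant
  metastasis at 5 years) is also in years;
* risk scores are plain :class:`pandas.Series` indexed by sample id, with
  ``name`` set to the score kind (``p53RS``, ``CRS``, ``GRS``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "AnnotationTable",
    "CentroidTemplate",
    "WeightedSignature",
    "CoxFit",
    "RiskThresholds",
    "RocResult",
    "ProbeMap",
    "QpcrTable",
    "KmCurve",
    "AssociationResult",
    "FormatError",
]

RISK_LABELS = ("low", "intermediate", "high")
MERGED_LABEL = "high-intermediate"


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    index = pd.Index(ids)
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """Log2 expression values, probesets x samples."""

    values: pd.DataFrame
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "probeset id")
        _check_unique(self.values.columns, "sample id")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise FormatError(
                f"expression matrix needs >=2 probesets and >=2 samples, "
                f"got shape {self.values.shape}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        if np.isinf(arr).any():
            raise FormatError("expression matrix contains non-finite values")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probesets(self, ids: Sequence[str]) -> "ExpressionMatrix":
        present = [i for i in ids if i in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.dataset_id)


VALID_STAGE_TOKENS = frozenset(
    ["IA", "IB", "II", "IIA", "IIB", "III", "IIIA", "IIIB", "IV", "II+"]
)
VALID_GENDERS = frozenset(["female", "male"])


@dataclass
class AnnotationTable:
    """Per-sample class labels, survival and clinical covariates.

    ``df`` is indexed by sample id.  Recognised columns: ``class_label``,
    ``survival_time`` (years), ``event`` ({0,1}), ``age`` (years),
    ``gender`` ({female, male}), ``stage`` (IA / IB / II and later).
    """

    df: pd.DataFrame
    dataset_id: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "sample id")
        cols = self.df.columns
        if "survival_time" in cols:
            if "event" not in cols:
                raise FormatError("survival_time present without event column")
            t = self.df["survival_time"].dropna()
            if (t < 0).any():
                bad = t[t < 0].index.tolist()
                raise FormatError(f"negative survival_time for samples {bad}")
            ev = self.df.loc[t.index, "event"]
            if ev.isna().any():
                raise FormatError("event missing where survival_time is present")
            if not ev.isin([0, 1]).all():
                raise FormatError("event must be 0/1")
        if "age" in cols:
            a = self.df["age"].dropna()
            if (a <= 0).any():
                raise FormatError("age must be positive")
        if "gender" in cols:
            g = self.df["gender"].dropna()
            bad = sorted(set(g) - VALID_GENDERS)
            if bad:
                raise FormatError(f"unrecognised gender tokens: {bad}")
        if "stage" in cols:
            s = self.df["stage"].dropna()
            bad = sorted(set(s) - VALID_STAGE_TOKENS)
            if bad:
                raise FormatError(f"unrecognised stage tokens: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def survival(self) -> pd.DataFrame:
        """Return the (time, event) columns for samples that have them."""
        if "survival_time" not in self.df.columns:
            raise FormatError("annotation table has no survival columns")
        out = self.df[["survival_time", "event"]].dropna()
        return out.astype({"survival_time": float, "event": int})


@dataclass
class CentroidTemplate:
    """Per-probeset T-values of a tumour-vs-normal comparison.

    Samples are later compared to this template by Pearson correlation.
    """

    t_values: pd.Series  # index = probeset ids
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_values = pd.Series(self.t_values, dtype=float)
        _check_unique(self.t_values.index, "centroid probeset id")
        if not np.isfinite(self.t_values.to_numpy()).all():
            raise FormatError("centroid T-values must be finite")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.t_values.index)

    def by_abs_t(self) -> pd.Series:
        """View ordered by descending |T| (stable for ties)."""
        order = (-self.t_values.abs()).sort_values(kind="stable").index
        return self.t_values.loc[order]

    def __len__(self) -> int:
        return len(self.t_values)


@dataclass
class WeightedSignature:
    """Probeset -> Cox Wald statistic weights of a risk test."""

    walds: pd.Series  # index = probeset ids, values = S_i
    group_label: str = ""
    endpoint: dict = field(default_factory=dict)  # {"event": ..., "horizon_years": ...}
    threshold: float | None = None  # |S_i| floor that defined the group

    def __post_init__(self) -> None:
        self.walds = pd.Series(self.walds, dtype=float)
        _check_unique(self.walds.index, "signature probeset id")
        if self.threshold is not None and len(self.walds):
            if (self.walds.abs() < self.threshold - 1e-12).any():
                raise FormatError(
                    f"signature group '{self.group_label}' contains |S_i| below "
                    f"its threshold {self.threshold}"
                )

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.walds.index)

    def __len__(self) -> int:
        return len(self.walds)


@dataclass
class CoxFit:
    """Single-covariate proportional-hazards fit summary."""

    probeset_id: str
    beta: float
    se: float
    p_value: float
    flagged: bool = False  # monotone likelihood / unstable

    @property
    def wald(self) -> float:
        return self.beta / self.se

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class RiskThresholds:
    """Lower/upper score cutoffs separating low / intermediate / high risk."""

    lower: float
    upper: float
    scale: str = "raw"  # "raw" or "z"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise FormatError(
                f"thresholds must satisfy lower < upper, got {self.lower}, {self.upper}"
            )
        if self.scale not in ("raw", "z"):
            raise FormatError(f"unknown threshold scale {self.scale!r}")


@dataclass
class RocResult:
    auc: float
    auc_p_value: float
    specificity_at_sensitivity: float  # percent in [0, 100]
    sensitivity_floor: float  # fraction in (0, 1]
    n_positive: int = 0
    n_negative: int = 0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC out of range: {self.auc}")


@dataclass
class ProbeMap:
    """Source probe -> gene -> target platform probes mapping.

    ``records`` columns: ``source_probe`` (unique), ``gene``,
    ``target_probes`` (list of str, may be empty when the gene is absent
    on the target platform).
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        need = {"source_probe", "gene", "target_probes"}
        missing = need - set(self.records.columns)
        if missing:
            raise FormatError(f"probe map missing columns {sorted(missing)}")
        _check_unique(self.records["source_probe"], "source probe")
        self.records = self.records.reset_index(drop=True)

    def gene_of(self) -> pd.Series:
        return self.records.set_index("source_probe")["gene"]

    def targets_of_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for _, row in self.records.iterrows():
            out.setdefault(row["gene"], [])
            for t in row["target_probes"]:
                if t not in out[row["gene"]]:
                    out[row["gene"]].append(t)
        return out


@dataclass
class QpcrTable:
    """qRT-PCR Ct values, samples x genes (lower Ct = more transcript)."""

    ct: pd.DataFrame  # rows = samples, columns = genes; NaN = not amplified
    housekeeping: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.ct.index, "sample id")
        _check_unique(self.ct.columns, "gene id")
        missing_hk = [g for g in self.housekeeping if g not in self.ct.columns]
        if missing_hk:
            raise FormatError(f"housekeeping genes absent from table: {missing_hk}")

    @property
    def test_genes(self) -> list[str]:
        hk = set(self.housekeeping)
        return [g for g in self.ct.columns if g not in hk]


@dataclass
class KmCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray  # event times where S drops
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class AssociationResult:
    """Hazard-ratio contrast with Wald 95% CI."""

    label: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError(
                f"CI must bracket HR: {self.ci_low}, {self.hr}, {self.ci_high}"
            )


def as_score_table(scores: Mapping[str, float] | pd.Series, kind: str) -> pd.Series:
    """Coerce to a named risk-score Series (one score per sample)."""
    s = pd.Series(scores, dtype=float)
    _check_unique(s.index, "sample id")
    s.name = kind
    return s
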