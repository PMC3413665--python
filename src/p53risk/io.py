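"""On-disk formats: TSV/GCT expression, annotations, signatures,
centroids, probe maps, thresholds, qPCR tables, scores and assignments.

All tabular artifacts are plain TSV with a JSON metadata sidecar where
the object carries metadata; reals are serialised with 12 significant
digits so write-then-read round-trips are deterministic.  Decimal point
only; scientific notation accepted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    AnnotationTable,
    CentroidTemplate,
    ExpressionMatrix,
    FormatError,
    ProbeMap,
    QpcrTable,
    RiskThresholds,
    WeightedSignature,
)

__all__ = [
    "PipelineConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation_table",
    "write_annotation_table",
    "read_signature",
    "write_signature",
    "read_centroid",
    "write_centroid",
    "read_probe_map",
    "write_probe_map",
    "read_thresholds",
    "write_thresholds",
    "read_qpcr_table",
    "write_qpcr_table",
    "read_scores",
    "write_scores",
    "read_assignment",
    "write_assignment",
]

FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Tunable constants of the whole pipeline, with the printed defaults."""

    endpoint_horizon: float = 5.0  # years
    wald_thresholds: tuple[float, ...] = (3.0, 2.5, 2.0)
    screen_alpha: float = 0.05
    t_threshold: float = 3.0
    max_fdr: float = 0.05
    sensitivity_floor: float = 1.0  # fraction in (0, 1]
    coverage_floor: float = 0.5
    rng_seed: int = 0
    rle_median_limit: float = 1.0
    rle_iqr_limit: float = 1.0
    qpcr_k_mad: float = 3.0
    qpcr_min_housekeeping: int = 2

    def __post_init__(self) -> None:
        self.wald_thresholds = tuple(float(t) for t in self.wald_thresholds)
        if any(b >= a for a, b in zip(self.wald_thresholds, self.wald_thresholds[1:])):
            raise FormatError("wald_thresholds must be strictly decreasing")
        if self.endpoint_horizon <= 0:
            raise FormatError("endpoint_horizon must be positive")
        if not 0.0 < self.sensitivity_floor <= 1.0:
            raise FormatError("sensitivity_floor must lie in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**{k: tuple(v) if k == "wald_thresholds" else v for k, v in data.items()})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wald_thresholds"] = list(self.wald_thresholds)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _read_table(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _coerce_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.nonzero(bad.to_numpy())
        raise FormatError(
            f"{path}: non-numeric cell at probeset {df.index[r[0]]!r}, "
            f"sample {df.columns[c[0]]!r}"
        )
    return out.astype(float)


def read_expression_matrix(path, dialect: str = "tsv", dataset_id: str | None = None) -> ExpressionMatrix:
    """Read a probesets x samples log2 matrix from TSV or minimal GCT."""
    if dialect == "tsv":
        df = _read_table(path, index_col=0)
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            df = pd.read_csv(fh, sep="\t")
        if {"Name", "Description"} - set(df.columns[:2]):
            raise FormatError(f"{path}: GCT needs Name and Description columns")
        df = df.set_index("Name").drop(columns=["Description"])
        if len(dims) >= 2 and (int(dims[0]), int(dims[1])) != df.shape:
            raise FormatError(
                f"{path}: GCT dims {dims[:2]} disagree with table shape {df.shape}"
            )
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    df.index = df.index.astype(str)
    df = _coerce_numeric(df, path)
    return ExpressionMatrix(df, dataset_id or Path(path).stem)


def write_expression_matrix(expr: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        expr.values.rename_axis("probeset_id").to_csv(path, sep="\t", float_format=FLOAT_FMT)
    elif dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            out = expr.values.copy()
            out.insert(0, "Description", "na")
            out.rename_axis("Name").to_csv(fh, sep="\t", float_format=FLOAT_FMT)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def read_annotation_table(path, dataset_id: str | None = None) -> AnnotationTable:
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: annotation table needs a sample_id column")
    df = df.set_index("sample_id")
    for col in ("survival_time", "event", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return AnnotationTable(df, dataset_id or Path(path).stem)


def write_annotation_table(ann: AnnotationTable, path) -> None:
    ann.df.rename_axis("sample_id").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_signature(sig: WeightedSignature, path) -> None:
    if len(sig) == 0:
        raise FormatError("refusing to write an empty signature")
    frame = sig.walds.rename("wald").rename_axis("probeset_id").reset_index()
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {
        "group_label": sig.group_label,
        "endpoint": sig.endpoint,
        "threshold": sig.threshold,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_signature(path) -> WeightedSignature:
    frame = _read_table(path)
    if {"probeset_id", "wald"} - set(frame.columns):
        raise FormatError(f"{path}: signature needs probeset_id and wald columns")
    walds = frame.set_index("probeset_id")["wald"].astype(float)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return WeightedSignature(
        walds=walds,
        group_label=meta.get("group_label", ""),
        endpoint=meta.get("endpoint", {}),
        threshold=meta.get("threshold"),
    )


def write_centroid(centroid: CentroidTemplate, path) -> None:
    frame = centroid.t_values.rename("t_value").rename_axis("probeset_id").reset_index()
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    _sidecar(path).write_text(json.dumps(centroid.metadata, indent=2, sort_keys=True) + "\n")


def read_centroid(path) -> CentroidTemplate:
    frame = _read_table(path)
    if {"probeset_id", "t_value"} - set(frame.columns):
        raise FormatError(f"{path}: centroid needs probeset_id and t_value columns")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return CentroidTemplate(frame.set_index("probeset_id")["t_value"].astype(float), meta)


def write_probe_map(pm: ProbeMap, path) -> None:
    out = pm.records.copy()
    out["target_probes"] = out["target_probes"].map(",".join)
    out.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> ProbeMap:
    frame = _read_table(path, keep_default_na=False)
    if {"source_probe", "gene", "target_probes"} - set(frame.columns):
        raise FormatError(f"{path}: probe map needs source_probe, gene, target_probes")
    frame["target_probes"] = frame["target_probes"].map(
        lambda s: [t for t in str(s).split(",") if t]
    )
    return ProbeMap(frame)


def write_thresholds(thr: RiskThresholds, path) -> None:
    Path(path).write_text(
        json.dumps(
            {"lower": thr.lower, "upper": thr.upper, "scale": thr.scale},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def read_thresholds(path) -> RiskThresholds:
    data = json.loads(Path(path).read_text())
    return RiskThresholds(**data)


def write_qpcr_table(tbl: QpcrTable, path) -> None:
    tbl.ct.rename_axis("sample_id").to_csv(path, sep="\t", float_format=FLOAT_FMT)
    _sidecar(path).write_text(
        json.dumps({"housekeeping": list(tbl.housekeeping)}, indent=2) + "\n"
    )


def read_qpcr_table(path, housekeeping: list[str] | None = None) -> QpcrTable:
    df = _read_table(path, index_col=0)
    df = df.apply(pd.to_numeric, errors="raise").astype(float)
    if housekeeping is None:
        sc = _sidecar(path)
        housekeeping = json.loads(sc.read_text())["housekeeping"] if sc.exists() else []
    return QpcrTable(ct=df, housekeeping=list(housekeeping))


def write_scores(scores: pd.Series, path) -> None:
    scores.rename_axis("sample_id").rename(scores.name or "score").reset_index().to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_scores(path) -> pd.Series:
    frame = _read_table(path)
    if "sample_id" not in frame.columns or frame.shape[1] < 2:
        raise FormatError(f"{path}: scores need sample_id plus one value column")
    col = [c for c in frame.columns if c != "sample_id"][0]
    s = frame.set_index("sample_id")[col].astype(float)
    s.name = col
    return s


def write_assignment(assignment: pd.DataFrame, path) -> None:
    assignment.rename_axis("sample_id").to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )


def read_assignment(path) -> pd.DataFrame:
    frame = _read_table(path)
    if {"sample_id", "score", "group"} - set(frame.columns):
        raise FormatError(f"{path}: assignment needs sample_id, score, group")
    return frame.set_index("sample_id")
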