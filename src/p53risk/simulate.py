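"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the shape of the real study inputs without any
downloads:

* a two-class mouse arm (normal vs carcinoma) with a planted differential
  signature, the source of the centroid template;
* a human cohort arm in which a latent per-patient signature-activation
  level ``a_j`` drives both signature-gene expression and the survival
  hazard — the single bridge the risk-scoring procedure assumes;
* many-to-one probe→gene→probe platform maps with multi-probe genes and
  gene dropout on the target platform;
* qRT-PCR Ct tables linear in log2 expression with stable housekeeping
  genes and an optional corrupted-sample fraction.

One master seed per scenario; sub-generators draw from fixed named
streams so adding a generator never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import AnnotationTable, ExpressionMatrix, ProbeMap, QpcrTable

__all__ = [
    "SimulationScenario",
    "GroundTruth",
    "simulate_mouse_two_class",
    "simulate_human_cohort",
    "simulate_platform_map",
    "simulate_qpcr",
]


@dataclass
class SimulationScenario:
    """Study conditions for one simulated experiment.

    Defaults describe the conditions the pipeline is exercised under: a
    1000-probeset platform carrying a 40-probeset signature with |log2
    effect| = 3 against unit noise in the mouse arm (20 normal + 20
    carcinoma), and 200-patient human cohorts in which the latent
    activation multiplies the same effect sizes and enters the log-hazard
    with coefficient ``gamma`` = 1 over an exponential baseline of
    0.1/year, censored uniformly on 1–10 years.
    """

    n_probesets: int = 1000
    n_signature: int = 40
    n_normal: int = 20
    n_tumour: int = 20
    n_patients: int = 200
    effect_size: float = 3.0  # |d_i| in log2 units; signs random per probeset
    noise_sd: float = 1.0
    baseline_mean: float = 7.0  # mean log2 abundance
    baseline_sd: float = 1.0
    gamma: float | None = 1.0  # log-hazard per unit latent activation
    baseline_hazard: float = 0.1  # events per year at a_j = 0
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    censor_window: tuple[float, float] = (1.0, 10.0)  # years
    clinical_effects: dict = field(
        default_factory=lambda: {"age": 0.3, "gender": 0.1, "stage": 0.4}
    )  # log-hazard per SD of age, per gender code unit, per stage code unit
    clinical_activation_corr: float = 0.0  # stage–activation confounding knob
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature > self.n_probesets:
            raise ValueError("n_signature must not exceed n_probesets")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        c0, c1 = self.censor_window
        if not c0 < c1:
            raise ValueError("censor window must satisfy c_min < c_max")

    def with_seed(self, seed: int) -> "SimulationScenario":
        return replace(self, rng_seed=seed)


@dataclass
class GroundTruth:
    """Planted parameters persisted alongside every simulated dataset."""

    signature_probesets: list[str]
    effects: pd.Series  # d_i per signature probeset (signed)
    activation: pd.Series | None = None  # a_j per patient
    true_event_times: pd.Series | None = None  # pre-censoring


def _stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named RNG stream derived from the scenario seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _planted_signature(scn: SimulationScenario) -> tuple[list[str], pd.Series]:
    rng = _stream(scn.rng_seed, "signature")
    probes = [f"mp{i:05d}" for i in range(scn.n_probesets)]
    members = sorted(rng.choice(scn.n_probesets, size=scn.n_signature, replace=False))
    ids = [probes[i] for i in members]
    signs = rng.choice([-1.0, 1.0], size=scn.n_signature)
    effects = pd.Series(signs * scn.effect_size, index=ids)
    return probes, effects


def simulate_mouse_two_class(
    scn: SimulationScenario,
) -> tuple[ExpressionMatrix, AnnotationTable, GroundTruth]:
    """Normal-vs-carcinoma mouse arm: x_ij = mu_i + d_i*1[tumour] + noise."""
    if scn.n_normal < 2 or scn.n_tumour < 2:
        raise ValueError("need >=2 samples per class for a two-sample t-test")
    probes, effects = _planted_signature(scn)
    rng = _stream(scn.rng_seed, "mouse")

    mu = rng.normal(scn.baseline_mean, scn.baseline_sd, size=scn.n_probesets)
    d = pd.Series(0.0, index=probes)
    d.loc[effects.index] = effects

    n = scn.n_normal + scn.n_tumour
    tumour = np.array([0] * scn.n_normal + [1] * scn.n_tumour)
    x = (
        mu[:, None]
        + d.to_numpy()[:, None] * tumour[None, :]
        + rng.normal(0.0, scn.noise_sd, size=(scn.n_probesets, n))
    )
    samples = [f"ms{j:03d}" for j in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(x, index=probes, columns=samples), dataset_id="sim-mouse"
    )
    ann = AnnotationTable(
        pd.DataFrame(
            {"class_label": np.where(tumour == 1, "carcinoma", "normal")},
            index=pd.Index(samples, name="sample_id"),
        ),
        dataset_id="sim-mouse",
    )
    truth = GroundTruth(signature_probesets=list(effects.index), effects=effects)
    return expr, ann, truth


def _stage_probs(a: np.ndarray, corr: float, rng: np.random.Generator) -> np.ndarray:
    """Stage codes 1..3; optionally correlated with activation."""
    base = rng.choice([1, 2, 3], size=len(a), p=[0.4, 0.3, 0.3]).astype(float)
    if corr != 0.0:
        shifted = np.clip(np.round(base + corr * a), 1, 3)
        return shifted
    return base


def simulate_human_cohort(
    scn: SimulationScenario,
    homologue_map: ProbeMap,
    dataset_id: str = "sim-human",
    stream: str = "human",
) -> tuple[ExpressionMatrix, AnnotationTable, GroundTruth]:
    """Human cohort: expression driven by latent activation, which also
    drives the hazard.

    Rows of the returned matrix are the *target* probes of
    ``homologue_map``; every target probe of a gene carries the gene's
    systematic signal plus independent noise.  Event times are Weibull
    (exponential by default) with log-rate gamma*a_j plus clinical
    effects; censoring is uniform on the scenario's window.
    """
    if scn.gamma is None:
        raise ValueError("scenario gamma (hazard coefficient) must be specified")
    _, effects = _planted_signature(scn)
    missing = set(effects.index) - set(homologue_map.records["source_probe"])
    if missing:
        raise ValueError(
            f"homologue map does not cover {len(missing)} signature probesets"
        )
    rng = _stream(scn.rng_seed, stream)

    gene_of = homologue_map.gene_of()
    # gene-level effects: mean of source-probe effects mapping to the gene
    d_gene = (
        pd.Series(0.0, index=gene_of.index)
        .add(effects.reindex(gene_of.index).fillna(0.0))
        .groupby(gene_of)
        .mean()
    )

    # enumerate target probes
    rows: list[tuple[str, str]] = []  # (target_probe, gene)
    for _, rec in homologue_map.records.iterrows():
        for tp in rec["target_probes"]:
            rows.append((tp, rec["gene"]))
    if not rows:
        raise ValueError("homologue map has no target probes")
    target_probes = [r[0] for r in rows]
    genes_of_rows = [r[1] for r in rows]

    n = scn.n_patients
    a = rng.standard_normal(n)
    mu = rng.normal(scn.baseline_mean, scn.baseline_sd, size=len(rows))
    load = d_gene.loc[genes_of_rows].to_numpy()
    x = (
        mu[:, None]
        + load[:, None] * a[None, :]
        + rng.normal(0.0, scn.noise_sd, size=(len(rows), n))
    )
    samples = [f"pt{j:04d}" for j in range(n)]
    # target probes may repeat across genes in pathological maps; keep unique
    expr = ExpressionMatrix(
        pd.DataFrame(x, index=pd.Index(target_probes), columns=samples),
        dataset_id=dataset_id,
    )

    # clinical covariates
    age = rng.normal(65.0, 10.0, size=n)
    gender_code = rng.choice([-1.0, 1.0], size=n)
    stage_code = _stage_probs(a, scn.clinical_activation_corr, rng)
    eff = scn.clinical_effects
    log_rate = (
        np.log(scn.baseline_hazard)
        + scn.gamma * a
        + eff.get("age", 0.0) * (age - 65.0) / 10.0
        + eff.get("gender", 0.0) * gender_code
        + eff.get("stage", 0.0) * (stage_code - 1.0)
    )
    rate = np.exp(log_rate)
    # Weibull with shape k and scale rate^{-1/k}: k=1 reduces to exponential
    k = scn.weibull_shape
    t_true = rng.weibull(k, size=n) / rate ** (1.0 / k)
    c0, c1 = scn.censor_window
    t_cens = rng.uniform(c0, c1, size=n)
    observed = np.minimum(t_true, t_cens)
    event = (t_true <= t_cens).astype(int)

    stage_token = np.where(stage_code == 1, "IA", np.where(stage_code == 2, "IB", "II+"))
    ann = AnnotationTable(
        pd.DataFrame(
            {
                "survival_time": observed,
                "event": event,
                "age": age,
                "gender": np.where(gender_code > 0, "male", "female"),
                "stage": stage_token,
            },
            index=pd.Index(samples, name="sample_id"),
        ),
        dataset_id=dataset_id,
    )
    truth = GroundTruth(
        signature_probesets=list(effects.index),
        effects=effects,
        activation=pd.Series(a, index=samples),
        true_event_times=pd.Series(t_true, index=samples),
    )
    return expr, ann, truth


def simulate_platform_map(
    source_probes: list[str],
    probes_per_gene: tuple[int, int] = (1, 3),
    dropout: float = 0.0,
    rng_seed: int = 0,
    source_probes_per_gene: int = 1,
) -> ProbeMap:
    """Many-to-one probe→gene map for two platforms.

    Source probes are grouped into genes (``source_probes_per_gene``
    consecutive probes per gene); each gene receives between
    ``probes_per_gene[0]`` and ``probes_per_gene[1]`` target-platform
    probes, and a ``dropout`` fraction of genes gets none.
    """
    rng = _stream(rng_seed, "platform-map")
    lo, hi = probes_per_gene
    records = []
    n_genes = (len(source_probes) + source_probes_per_gene - 1) // source_probes_per_gene
    dropped = set(
        rng.choice(n_genes, size=int(round(dropout * n_genes)), replace=False)
    )
    for g in range(n_genes):
        gene = f"g{g:05d}"
        chunk = source_probes[g * source_probes_per_gene : (g + 1) * source_probes_per_gene]
        if g in dropped:
            targets: list[str] = []
        else:
            k = int(rng.integers(lo, hi + 1))
            targets = [f"hp{g:05d}_{chr(97 + t)}" for t in range(k)]
        for sp in chunk:
            records.append({"source_probe": sp, "gene": gene, "target_probes": targets})
    return ProbeMap(pd.DataFrame(records), provenance=f"simulated seed={rng_seed}")


def simulate_qpcr(
    expr: ExpressionMatrix,
    genes: list[str],
    housekeeping: list[str],
    slope: float = -1.0,
    intercept: float = 30.0,
    noise: float = 0.0,
    housekeeping_level: float = 12.0,
    housekeeping_sd: float = 0.05,
    corrupt_fraction: float = 0.0,
    rng_seed: int = 0,
) -> QpcrTable:
    """Ct values linear in log2 expression: Ct = intercept + slope * x + noise.

    Housekeeping genes get near-constant expression at
    ``housekeeping_level`` log2 units; a ``corrupt_fraction`` of samples
    has its housekeeping Cts knocked out (to exercise sample exclusion).
    """
    if slope >= 0:
        raise ValueError("slope must be negative (more transcript = lower Ct)")
    overlap = set(genes) & set(housekeeping)
    if overlap:
        raise ValueError(f"genes and housekeeping overlap: {sorted(overlap)}")
    if len(housekeeping) < 2:
        raise ValueError("need >=2 housekeeping genes")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    rng = _stream(rng_seed, "qpcr")

    x = expr.values.loc[genes]  # genes x samples
    ct_test = intercept + slope * x
    hk_x = pd.DataFrame(
        housekeeping_level
        + rng.normal(0.0, housekeeping_sd, size=(len(housekeeping), x.shape[1])),
        index=housekeeping,
        columns=x.columns,
    )
    ct_hk = intercept + slope * hk_x
    ct = pd.concat([ct_test, ct_hk]).T  # samples x genes
    if noise > 0:
        ct = ct + rng.normal(0.0, noise, size=ct.shape)

    if corrupt_fraction > 0:
        n_bad = int(round(corrupt_fraction * ct.shape[0]))
        bad = rng.choice(ct.shape[0], size=n_bad, replace=False)
        ct.iloc[bad, [ct.columns.get_loc(h) for h in housekeeping]] = np.nan
    return QpcrTable(ct=ct, housekeeping=list(housekeeping))
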