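"""Cross-platform / cross-species transfer of signatures and thresholds.

The array test is derived on one platform (probeset-level Wald weights)
and applied on another: probeset Walds are collapsed to one weight per
gene by averaging, every probe of the gene on the target platform is
multiplied by that gene weight and summed (which changes the score
scale), and score thresholds are carried over by z-standardising both
the reference and the target cohorts' scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ProbeMap, RiskThresholds, WeightedSignature, as_score_table

__all__ = [
    "collapse_walds",
    "score_on_target_platform",
    "harmonize_thresholds",
    "map_cross_species",
]

log = logging.getLogger(__name__)

LOG2_PER_LOG10 = float(np.log2(10.0))


def collapse_walds(sig: WeightedSignature, probemap: ProbeMap) -> pd.Series:
    """One weight per gene: the arithmetic mean Wald of its probesets.

    Genes whose probesets carry opposite Wald signs are kept (their mean
    shrinks toward zero) but flagged with a warning.
    """
    gene_of = probemap.gene_of()
    unmapped = [p for p in sig.probeset_ids if p not in gene_of.index]
    if unmapped:
        raise ValueError(f"signature probesets without gene mapping: {unmapped}")
    genes = gene_of.loc[sig.probeset_ids]
    collapsed = sig.walds.groupby(genes.to_numpy()).mean()
    signs = sig.walds.groupby(genes.to_numpy()).agg(lambda v: len(set(np.sign(v))) > 1)
    conflicted = list(signs.index[signs])
    if conflicted:
        log.warning("collapse_walds: sign-conflicting probesets within genes %s", conflicted)
    log.info("collapse_walds: %d probesets -> %d genes", len(sig), len(collapsed))
    collapsed.name = "wald"
    return collapsed


def score_on_target_platform(
    expr_target: ExpressionMatrix,
    gene_weights: pd.Series,
    probemap: ProbeMap,
    coverage_floor: float = 0.5,
    input_scale: str = "log2",
) -> pd.Series:
    """Risk score on another platform: per-probe summation.

    score_j = sum over genes, sum over the gene's target probes present
    in the matrix, of W_gene * x_probe,j.  Genes without any measured
    target probe are skipped with no rescaling.  ``input_scale="log10"``
    converts the matrix to log2 first (x_log2 = x_log10 / log10(2)).
    """
    if input_scale not in ("log2", "log10"):
        raise ValueError(f"unknown input scale {input_scale!r}")
    values = expr_target.values
    if input_scale == "log10":
        values = values * LOG2_PER_LOG10

    targets = probemap.targets_of_gene()
    probe_weight: dict[str, float] = {}
    covered = 0
    for gene, w in gene_weights.items():
        probes = [p for p in targets.get(gene, []) if p in values.index]
        if probes:
            covered += 1
            for p in probes:
                probe_weight[p] = probe_weight.get(p, 0.0) + float(w)
    coverage = covered / len(gene_weights) if len(gene_weights) else 0.0
    if coverage < coverage_floor:
        raise ValueError(
            f"target-platform coverage {coverage:.2f} below floor {coverage_floor}"
        )
    log.info(
        "score_on_target_platform: %d/%d genes measured via %d probes",
        covered,
        len(gene_weights),
        len(probe_weight),
    )
    w = pd.Series(probe_weight)
    sub = values.loc[w.index]
    return as_score_table(sub.mul(w, axis=0).sum(axis=0), "p53RS")


def harmonize_thresholds(
    scores_ref: pd.Series,
    thr_ref: RiskThresholds,
    scores_target: pd.Series,
) -> tuple[pd.Series, RiskThresholds]:
    """Carry raw-scale thresholds to another cohort via z-standardisation.

    Thresholds are mapped into z units using the reference cohort's mean
    and (n-1) sd; target scores are z-scored within their own cohort.
    Assignment then proceeds on the z scale, which makes the result
    invariant to any affine transform of the target platform's scale.
    """
    mu, sd = scores_ref.mean(), scores_ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("reference scores have zero standard deviation")
    z_thr = RiskThresholds(
        lower=(thr_ref.lower - mu) / sd,
        upper=(thr_ref.upper - mu) / sd,
        scale="z",
    )
    mu_t, sd_t = scores_target.mean(), scores_target.std(ddof=1)
    if not np.isfinite(sd_t) or sd_t == 0:
        raise ValueError("target scores have zero standard deviation")
    z_scores = as_score_table((scores_target - mu_t) / sd_t, scores_target.name or "score")
    return z_scores, z_thr


def map_cross_species(
    expr: ExpressionMatrix,
    probemap: ProbeMap,
    direction: str = "probe_to_gene",
) -> ExpressionMatrix:
    """Re-key expression rows across species/platforms.

    ``probe_to_gene``: source-probe rows become gene rows; several source
    probes hitting one gene are averaged (logged).  ``gene_to_probe``:
    gene rows are duplicated onto each source probe of the gene.
    """
    if direction == "probe_to_gene":
        gene_of = probemap.gene_of()
        shared = [p for p in expr.values.index if p in gene_of.index]
        if len(shared) < 3:
            raise ValueError("probe map shares <3 row identifiers with the matrix")
        sub = expr.values.loc[shared]
        genes = gene_of.loc[shared]
        collisions = genes.value_counts()
        n_multi = int((collisions > 1).sum())
        if n_multi:
            log.info("map_cross_species: averaging %d multi-probe genes", n_multi)
        out = sub.groupby(genes.to_numpy()).mean()
    elif direction == "gene_to_probe":
        gene_of = probemap.gene_of()
        keep = gene_of[gene_of.isin(expr.values.index)]
        if len(keep) < 3:
            raise ValueError("probe map shares <3 gene identifiers with the matrix")
        out = expr.values.loc[keep.to_numpy()]
        out.index = keep.index
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ExpressionMatrix(out, expr.dataset_id)
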