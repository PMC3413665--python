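"""One-call discovery/validation pipeline on simulated cohorts.

Chains every stage the way the risk tests are built on real data: derive
the tumour-vs-normal centroid in the mouse arm, map its probesets to the
human platform, screen the mapped candidates against survival in a
discovery cohort, build the Wald-group risk test with ROC selection and
sextile thresholds, then stratify and evaluate an independent validation
cohort.  Used by integration tests and by the reproduction script; also
convenient for power analyses of the design itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import clinical as clin
from . import evaluate as ev
from . import screen as scr
from . import signature as sig
from . import simulate as sim
from . import transfer as tr
from .types import RiskThresholds, RocResult, WeightedSignature


@dataclass
class ReplicateResult:
    """Everything one seeded discovery/validation run produces."""

    centroid_size: int
    selected_group: str
    selected_size: int
    discovery_roc: RocResult
    signature: WeightedSignature
    thresholds: RiskThresholds
    planted_gene_jaccard: float
    validation_logrank_p: float
    validation_logrank_chi2: float
    high_vs_low_logrank_p: float
    validation_hr: list
    grs_roc: RocResult | None = None


def _gene_of_target_probe(pmap) -> dict[str, str]:
    out: dict[str, str] = {}
    for _, rec in pmap.records.iterrows():
        for tp in rec["target_probes"]:
            out[tp] = rec["gene"]
    return out


def run_replicate(
    seed: int,
    scenario: sim.SimulationScenario | None = None,
    horizon: float = 5.0,
    sensitivity_floor: float = 1.0,
    with_clinical: bool = False,
    clinical_horizon: float = 3.0,
) -> ReplicateResult:
    """Full derive -> screen -> build -> validate run at one seed."""
    scn = (scenario or sim.SimulationScenario()).with_seed(seed)
    mouse_expr, mouse_ann, _ = sim.simulate_mouse_two_class(scn)
    pmap = sim.simulate_platform_map(
        mouse_expr.probeset_ids, probes_per_gene=(1, 3), dropout=0.05, rng_seed=seed
    )
    disc_expr, disc_ann, disc_truth = sim.simulate_human_cohort(
        scn, pmap, dataset_id="sim-discovery", stream="human-discovery"
    )
    val_expr, val_ann, _ = sim.simulate_human_cohort(
        scn, pmap, dataset_id="sim-validation", stream="human-validation"
    )

    # mouse arm: centroid template
    centroid = sig.derive_centroid(sig.standardize(mouse_expr), mouse_ann)

    # candidates: human-platform probes of the centroid's genes
    gene_of = pmap.gene_of()
    targets = pmap.targets_of_gene()
    candidate_probes = sorted(
        {tp for p in centroid.probeset_ids for tp in targets.get(gene_of[p], [])}
    )

    # discovery: screen, group, select, threshold
    cohort = scr.censor_at_horizon(disc_ann, horizon)
    fits = scr.screen_probesets(disc_expr, cohort, probesets=candidate_probes)
    groups = scr.select_wald_groups(
        fits, endpoint={"event": "simulated", "horizon_years": horizon}
    )
    best, roc = scr.choose_optimal_group(
        groups, disc_expr, cohort, horizon, sensitivity_floor
    )
    disc_scores = scr.compute_p53rs(disc_expr, best)
    thresholds = scr.derive_sextile_thresholds(disc_scores)

    # overlap with the planted signature, at gene level
    probe_gene = _gene_of_target_probe(pmap)
    selected_genes = {probe_gene[p] for p in best.probeset_ids}
    planted_genes = {gene_of[p] for p in disc_truth.signature_probesets}
    jaccard = len(selected_genes & planted_genes) / len(selected_genes | planted_genes)

    # independent validation cohort (same platform => raw thresholds apply)
    val_scores = scr.compute_p53rs(val_expr, best)
    val_cohort = scr.censor_at_horizon(val_ann, horizon)
    assignment = scr.assign_risk_groups(val_scores, thresholds)
    common = [s for s in val_cohort.index if s in assignment.index]
    chi2, _, p_all = ev.logrank_test(
        val_cohort.loc[common, "survival_time"],
        val_cohort.loc[common, "event"],
        assignment.loc[common, "group"],
    )
    hl = assignment.loc[common][assignment.loc[common, "group"].isin(["high", "low"])]
    _, _, p_hl = ev.logrank_test(
        val_cohort.loc[hl.index, "survival_time"],
        val_cohort.loc[hl.index, "event"],
        hl["group"],
    )
    hrs = ev.group_hazard_ratio(val_cohort, assignment, reference_group="low")

    grs_roc = None
    if with_clinical:
        enc = clin.encode_clinical(disc_ann)
        clin_cohort = scr.censor_at_horizon(disc_ann, clinical_horizon)
        weights = clin.fit_clinical_weights(enc, clin_cohort)
        crs = clin.compute_crs(enc, weights)
        grs = clin.combine_grs(disc_scores, crs)
        grs_roc = scr.roc_evaluate(grs, clin_cohort, clinical_horizon, sensitivity_floor)

    return ReplicateResult(
        centroid_size=len(centroid),
        selected_group=best.group_label,
        selected_size=len(best),
        discovery_roc=roc,
        signature=best,
        thresholds=thresholds,
        planted_gene_jaccard=jaccard,
        validation_logrank_p=p_all,
        validation_logrank_chi2=chi2,
        high_vs_low_logrank_p=p_hl,
        validation_hr=hrs,
        grs_roc=grs_roc,
    )
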