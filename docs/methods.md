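# Methods

## The problem and the procedure

`p53risk` implements a cross-species prognostic-signature pipeline.  A
gene-expression signature of p53 deficiency, derived in a mouse
tumour-vs-normal comparison, is transferred to human breast or lung
cancer cohorts and turned into a survival risk test.  The pipeline has
five stages:

1. **Centroid template.**  Within the mouse dataset every probeset is
   z-scored (mean 0, sd 1, denominator n−1).  A two-sample Student
   t-test (pooled variance; Welch behind a flag) compares carcinoma vs
   normal samples; probesets with Benjamini–Hochberg FDR ≤ `max_fdr`
   and |T| ≥ `t_threshold` form a T-value centroid.  Any sample — mouse
   or, after probe mapping, human — is compared to the centroid by
   Pearson correlation over the shared probesets, with a two-sided
   p-value from the t-transform t = r·√((m−2)/(1−r²)) on m−2 df, m the
   number of shared (pairwise-complete) probesets.

2. **Survival screening.**  In a discovery cohort, survival is
   administratively censored at an endpoint horizon (events after the
   horizon become censorings at the horizon; an event exactly at the
   horizon is kept).  Each candidate probeset is fit in a univariate
   Cox proportional-hazards model; the Wald statistic S_i = β_i/se_i
   carries both the strength and the direction of the association
   (S_i > 0: overexpression tracks risk).  Significant probesets
   (two-sided p < `screen_alpha`) are binned into nested groups
   |S_i| ≥ 3, ≥ 2.5, ≥ 2.

3. **Risk score and test selection.**  Each group scores patients by
   the Wald-weighted sum p53RS_j = Σ_i S_i·x_ij over the group's
   probesets (x in log2 units).  Groups are compared by ROC against
   the binary outcome "event within the horizon" (patients censored
   before the horizon are excluded — their outcome is unknowable; a
   flag treats them as non-events instead).  AUC uses the Mann–Whitney
   pair-counting identity with ties counted ½; specificity at a
   sensitivity floor is an exhaustive threshold scan with orientation
   "score ≥ t predicts event".  The winner is the group with the best
   AUC, ties broken by specificity, then by smaller size.

4. **Stratification and transfer.**  Sextile cutoffs on the discovery
   scores (type-1/inverse-CDF quantiles at 1/6 and 3/6, so cutoffs are
   observed scores) define low < lower ≤ intermediate < upper ≤ high.
   On another platform, probeset Walds collapse to one weight per gene
   (arithmetic mean; sign-conflicting genes kept with a warning), every
   measured probe of a gene contributes W_gene·x_probe (per-probe
   summation, which changes the score scale), and thresholds are
   carried over by z-standardising both the reference and the target
   cohorts' scores.  Assignment on the z scale is invariant to any
   affine transform of the target scale.

5. **Clinical branch and evaluation.**  Age (continuous years), gender
   (female = −1, male = +1) and stage (IA = 1, IB = 2, II or later = 3)
   are z-scored within the cohort and fit jointly in a proportional-
   hazards model; CRS_j = Σ_v Wald_v·z_vj, and the combined score is
   GRS_j = z(p53RS)_j + z(CRS)_j.  qRT-PCR cohorts are scored after ΔCt
   normalisation (housekeeping-mean reference, oriented so larger =
   more transcript) with failed samples excluded, and small cohorts
   merge intermediate+high into one stratum.  Evaluation uses
   Kaplan–Meier curves, the k-group log-rank test, and univariate or
   dataset-stratified multivariable Cox contrasts with Wald 95% CIs on
   the log-hazard scale.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `endpoint_horizon` | 5 | years | distant-metastasis horizon for the breast test; the lung clinical branch uses 3 years (overall survival) |
| `wald_thresholds` | 3, 2.5, 2 | — | the printed nested group definitions |
| `screen_alpha` | 0.05 | — | two-sided significance gate before grouping |
| `t_threshold`, `max_fdr` | 3, 0.05 | — | centroid selection; the original signature's exact criteria live in prior work, so these are explicit, logged knobs |
| `sensitivity_floor` | 1.0 | fraction | specificity is read at 100% sensitivity (0.8 for the lung test) |
| `coverage_floor` | 0.5 | fraction | minimum signature coverage before scoring a platform |
| `qpcr_k_mad` | 3 | MADs | housekeeping-mean outlier rule (normal-consistent MAD, so k = 3 behaves like 3σ) |

## What the generator emulates — and what it does not

The synthetic-data module is the package's test bed.  Its single
structural assumption mirrors the scoring model's: one latent per-patient
activation a_j ~ N(0,1) drives both signature-gene expression
(x_ij = μ_i + d_i·a_j + ε) and the hazard (rate λ0·exp(γ·a_j + clinical
terms)).  Default study conditions, chosen once: 1000 probesets carrying
a 40-probeset signature with |d_i| = 3 log2 units against unit noise;
mouse arm 20 normal + 20 carcinoma; human cohorts of 200 patients;
γ = 1; exponential baseline λ0 = 0.1/year (Weibull shape exposed for
robustness checks); uniform censoring on 1–10 years; clinical log-hazard
effects 0.3/SD age, 0.1 gender, 0.4 per stage code, independent of a_j
unless the confounding knob is turned.  Platform maps draw 1–3 target
probes per gene with configurable gene dropout; Ct values are linear in
log2 expression (slope −1, intercept 30) with near-constant housekeeping
genes and an optional corrupted-sample fraction.

Not emulated: probe-level array physics, batch and normalisation
artefacts, correlated gene modules beyond the single latent factor,
non-proportional hazards, informative censoring, FFPE degradation beyond
additive Ct noise.  Passing tests therefore demonstrate that the
machinery is correct and calibrated under the model's own assumptions,
not that the biological signature generalises.

## Numerical choices

* **Cox solver.**  Newton–Raphson with step-halving on the Breslow
  partial likelihood (Efron behind `ties="efron"`); covariates centred
  for conditioning; standard errors from the observed information.
  Stratified fits sum the within-stratum quantities.  |β| > 10 is
  treated as monotone likelihood (no believable finite per-log2-unit
  log-hazard exceeds that) and flagged; flagged fits never enter
  signatures.  Convergence: max |gradient| < 1e−10·max(1, |loglik|).
* **Quantiles.**  Type-1 (inverse empirical CDF), so sextile cutoffs
  are observed scores.  With the lower-closed boundary inequalities
  this puts each cutoff sample in its upper group: self-assignment
  counts are n/6, 2n/6, 3n/6 to within one boundary sample.
* **Ties.**  Kaplan–Meier processes deaths before censorings at equal
  times; the log-rank test handles tied deaths through the joint
  hypergeometric variance; AUC counts ties ½; heatmap sample order
  breaks correlation ties lexicographically by sample id.
* **Degenerate inputs.**  Zero-variance probesets are dropped with a
  warning before z-scoring (never silently zeroed); |r| = 1 reports the
  smallest positive double as its p-value; degenerate covariates,
  single-class outcomes, empty groups, zero-sd reference scores and
  all-excluded qPCR cohorts raise informative errors.
* **Serialisation.**  All on-disk reals use 12 significant digits;
  reports use fixed formatting so reruns are byte-identical.

## Design choices where the design was open

* p53RS multiplies raw log2 expression by the Wald weight, with no
  centring or rescaling; cross-platform comparability is delegated
  entirely to z harmonisation of scores and thresholds (a
  median-centred variant is a config switch).
* The ROC excludes patients censored before the horizon by default;
  counting them as non-events is available behind a flag and logged.
* The qPCR "low Ct" exclusion is implemented as a symmetric robust
  outlier rule on the housekeeping mean (k·MAD, normal-consistent)
  alongside the literal missing-housekeeping rule, because a one-sided
  reading is ambiguous (low Ct means high expression).
* The PCR risk score is the Wald-weighted sum of ΔCt-normalised values,
  keeping the array test's algebra; ΔCt is oriented so the array-derived
  weight signs carry over unchanged.
* Survival times are in years everywhere (horizons are in years;
  mixing units invites silent errors).
* Clinical z-scoring happens per combined cohort; stage tokens beyond
  IB all code to 3; missing clinical values are an error, not imputed.

## Known limitations

Single-factor expression model (no correlated modules); Breslow ties
only in the default screening path; no penalised or time-dependent Cox
variants; no competing-risk estimators; no probe-level QC beyond RLE;
evaluation exports tables, not figures.  The replication suite uses
cohorts of a few hundred patients — the scale at which the procedure's
operating characteristics (calibration, recovery rates) are measured
here — rather than the multi-thousand-patient consortium cohorts a
clinical validation would require.
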