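# Methods

This note documents the models, conventions and numerical choices behind
`lungsig`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The two-stage signature model

### Stage 1 — prognostic index

Given a gene × sample matrix of log intensities and right-censored
disease-specific survival (DSS), the prognostic pipeline is:

1. **Median centering** per platform: each gene's median across one
   platform's samples is subtracted within that platform only. Idempotent;
   missing values are excluded from medians and remain missing.
2. **Probe collapse** (when probe-level data are supplied): for each gene,
   the probe with the highest mean intensity across all samples is kept;
   ties keep the probe earliest in input order.
3. **Consensus gene selection.** Samples are split into 10 folds,
   stratified by event status. In each round, every gene is refitted on the
   nine training folds in a Cox model containing the gene *plus* age,
   gender, AJCC stage (ordinal), grade (ordinal, unknown imputed to the
   cohort median) and smoking history (categorical, "unknown" its own
   level). A gene scores a round when its Wald p < 10⁻³; genes scoring ≥ 2
   rounds are selected. Significance is evaluated on the training portion
   of each fold (the pre-validation-style reading of round-wise
   significance). The fold-consensus rule is the only multiplicity
   control — no FDR correction is layered on top, which mirrors how this
   family of signatures is built and is documented as a caveat.
4. **Percent-rank stabilization.** Only after selection, the selected
   genes' (centered) values are converted to percent-ranks. The primary
   convention is the interpolated spreadsheet convention: rank among the
   training values scaled by (n − 1), linear interpolation between order
   statistics, values outside the training range clamped to 0/1. A
   right-continuous empirical-CDF mode (k/n) is available
   (`mode="ecdf"`). Note the interpolated convention is exactly invariant
   under joint monotone transforms at the order statistics and clamps, and
   invariant up to one rank cell (< 1/(n−1)) between them.
5. **Principal-component index.** The index is the projection of the
   mean-centered percent-rank vector onto the first principal component
   (k = 1), with a deterministic loading-sign convention, multiplied by an
   orientation sign chosen so that the training-data Cox coefficient of
   the index is non-negative (higher index ⇒ higher hazard).
6. **Threshold.** The classification threshold is the 60th percentile of
   the oriented training indices, computed with the linear-interpolation
   sample quantile (numpy default, "type 7"); an index exactly at the
   threshold takes the below-threshold (low-risk) class. The convention is
   recorded in the serialized model.

### Stage 2 — ACT-response index

The response signature is selected on an all-ACT-treated cohort with
survival censored at 36 months, using the same consensus machinery with
the stage-1 **risk group** (0/1, from the frozen stage-1 model) appended
to the covariates (age, stage, gender, smoking). Genes whose outcome
association is mediated by prognosis are thereby conditioned away.

The classifier uses the top **two** principal components. How the two
component scores combine into one index was a genuinely open design
choice; this package combines them with **survival-determined signs on
the natural PCA score scale**: a Cox model of the two scores — adjusted
for the continuous stage-1 prognostic index as a nuisance covariate — 
fixes only the sign of each component's contribution. Weighting by the
Cox coefficient *magnitudes* (available via `combination="cox"`) was
implemented first and found unstable at stage-2 sample sizes: because the
genes were selected on the same cohort, outcome-associated directions
carry winner's-curse inflation, and in pilot runs the second component
(which tends to absorb residual prognostic signal through the shared gene
and any selection leak-through) received a weight several times its
out-of-sample effect, degrading responder classification badly. The sign
combination keeps the variance-dominant response component in charge
while remaining supervised in direction. The threshold is the median
(50th percentile) of the training indices; the class above threshold
(higher hazard under treatment) is labelled "ACT-non-responder", below
"ACT-responder".

### Scoring, partial coverage, and rank modes

A trained model stores its gene list, per-gene sorted training reference
values, per-gene percent-rank training means, loadings, combination
weights, orientation, threshold and conventions, and serializes to a
single JSON document.

*Partial coverage*: when a platform lacks some signature genes, the
available genes are ranked and centered as usual, the missing genes'
loadings are dropped, and each component is rescaled by
‖full loading‖/‖available loading‖, keeping the index scale comparable
across coverage levels; at full coverage this equals the full projection
exactly. Scoring requires at least 50% coverage by default.

*Rank modes*: single-sample scoring (`compute_index`) ranks against the
frozen training ECDFs — the deployment setting, where one new patient
arrives alone. Cohort-level validation (`score_cohort`,
`classify_cohort(rank_mode="within")`) ranks each gene against the
validation cohort itself. The within-cohort mode is the default for
cohort scoring because location shifts between cohorts otherwise move
the whole index distribution relative to the frozen threshold; this is
acute for bimodally expressed genes, whose per-gene median (the
centering statistic) sits in a low-density region and is therefore
unstable across cohorts. Both modes coincide on the training cohort
itself.

### Clinical comparator

The benchmark "clinical algorithm" is a Cox model on age at diagnosis and
tumor size dichotomized at 3 cm (3.0 cm inclusive in the small group),
trained on stage I patients; the risk score is the linear predictor,
thresholded at the 60th percentile of training scores to match the
genomic signature's class balance. A cohort with no size variation across
3 cm degrades to an age-only model with a warning. A Cox (not logistic)
form is used because the outcomes are censored.

## 2. Survival and agreement statistics

- **Kaplan–Meier, log-rank, multivariate Cox** are delegated to
  lifelines (Efron tie handling). Constant or linearly dependent
  covariate columns are dropped with a warning before fitting. If the
  indicator of interest shows monotone likelihood (|coef| or SE > 10 —
  e.g. a treatment arm with zero events), the model is refitted with a
  small ridge (penalizer 0.1) so that a bounded, flagged estimate is
  reported instead of a meaningless Wald statistic.
- **Per-gene Cox fits** use an in-package damped Newton–Raphson Efron
  partial-likelihood solver (numba-compiled): the selection stage
  performs ~10⁴–10⁵ fits per study, beyond what per-fit lifelines
  overhead allows. The solver accepts a log-likelihood plateau as
  convergence so that a separated *nuisance* covariate does not
  invalidate the gene term; the gene coefficient itself must be bounded
  and estimable or the gene is flagged non-convergent and excluded from
  selection. The tests verify agreement with lifelines to ~10⁻⁵ and with
  dense grid-search maximization of the partial likelihood on small
  datasets to 10⁻³.
- **Time-thresholded ROC** labels: positive = DSS death by the event
  horizon; negative = event-free with follow-up ≥ 12 months; excluded =
  alive with shorter follow-up, or (when the rule is active) death after
  the late-event exclusion time; deaths after the horizon but inside the
  exclusion window count as negatives. AUC is the tie-corrected
  Mann–Whitney statistic; its CI is Hanley–McNeil; the test against
  AUC = 0.5 uses the null-variance form. Correlated AUCs are compared
  with DeLong's method (implemented here; no installed package provides
  it).
- **Passing–Bablok regression**: slope = shifted median of all pairwise
  slopes (slopes of exactly −1 discarded; the shift K counts slopes
  below −1; x-ties contribute ±∞ when y differs), rank-based slope CI,
  intercept = median(y − b·x). Linearity: residual signs are scored
  ±√(L/l), cusum-accumulated in order of increasing x (the documented
  ordering convention), and the normalized maximum is referred to the
  Kolmogorov distribution; linear data give p = 1.
- **Censoring horizons**: 60 months for prognosis analyses, 36 months
  for treatment-response *selection*. For the ACT-vs-OBS benefit
  analysis the horizon is configurable with a 36-month default; the
  end-to-end acceptance runs evaluate benefit at 60 months, matching the
  five-year scale on which such benefits are reported.
- Wald p-values are used for Cox coefficients throughout (the mainstream
  default); subgroup analyses are reported unadjusted for multiplicity.

## 3. The cohort simulator

Each simulated patient carries two latent traits:

- **risk** ~ N(0, 1): the prognostic trait, continuous.
- **responder subtype**: a two-component Gaussian mixture,
  Z ~ 0.55·N(+1, 0.5²) + 0.45·N(−1, 0.5²) — a discrete molecular subtype
  with graded within-mode variation. The hazard uses the rectification
  resp = max(Z, 0) (an optional floor slope re-introduces a small
  gradient below zero), so treatment benefit is confined to the
  responder mode while the planted response *genes* load on the
  continuous Z and are detectable in both modes.

Expression: gene g in sample i is μ_g + λ·latent + ε with λ = 1,
ε ~ N(0, 0.4) for planted genes (unit noise for null genes) and
μ_g ~ N(8, 1) log-intensity baselines. By default 30 genes load on risk
and 37 on Z, sharing exactly one gene — mirroring the single-gene overlap
seen between real prognostic and chemo-response signatures.

Survival: Weibull hazard
h(t|i) = h₀·k·t^(k−1)·exp(β_risk·risk + Σβ_c·(z_c − z̄_c) −
β_resp·treated·resp), sampled by inverse transform, with independent
exponential censoring (rate 0.006/month) and administrative censoring at
120 months. The default shape k = 0.75 encodes the early-peaked
recurrence hazard characteristic of resected NSCLC. The baseline h₀ is
calibrated by bisection so that the *expected observed* event fraction at
a stated horizon (default 37% at 60 months, the scale of disease-specific
death in resected adenocarcinoma series; 53% for the treated training
setting; tolerance 0.001) matches the target, using the closed form for
exponential baselines and a singularity-free quadrature
(u = t^k substitution) otherwise.

Effect sizes are free parameters of the simulation, not estimates of any
real signature. The defaults — β_risk = 0.6, β_resp = 2.4 — were fixed
once by pilot power analysis at the study's sample scales (n = 332
training, n = 88 treated, n = 109 randomized): β_risk large enough for
reliable (> 80%) per-gene recovery at P < 10⁻³ with ~100 events, yet
small enough that residual prognostic signal does not swamp the stage-2
conditioning; β_resp sized so the responder-mode benefit (HR ≈ 0.1–0.2)
is detectable within a ~55-patient predicted-responder subgroup, while
avoiding the quasi-separation regime in which per-gene Wald statistics
collapse. Clinical covariates are simulated from marginal distributions
typical of resected adenocarcinoma series (age ~ N(65, 10) truncated to
[35, 90]; stage/grade/smoking categoricals; log-normal tumor size around
3 cm).

**What the simulator does not emulate** — and hence what passing tests do
*not* establish about real data: probe-level array artifacts, batch and
lab effects beyond platform gene-set differences, correlated co-expression
structure beyond the two planted programs, non-proportional hazards,
competing risks, informative censoring, and measurement differences
between fresh-frozen and FFPE material. Platform differences are reduced
to gene-set masking.

## 4. Operating characteristics and problem sizes

The acceptance suite exercises the pipeline at the study scales: null
selection on 20 cohorts of 1,000 genes × 300 samples; planted recovery on
10 default cohorts (n = 332); stage-2 decoupling and end-to-end benefit
recovery over 10 replicate treated (n = 88) + randomized (n = 109) cohort
pairs with a stage-1 model trained once; 60 replicate null trials for the
uniformity of subgroup p-values; three masked validation cohorts
(n = 264) for coverage robustness. These sizes are the package's chosen
benchmark conditions; `scripts/acceptance.py` re-runs the same study from
a single seed and reports medians over 8 stage-2 replicates because
single draws at n = 88/109 are intrinsically noisy.

Two known knife-edges, documented rather than hidden:

- The consensus selector's false-selection rate at P < 10⁻³ with ≥ 2 of
  10 overlapping rounds is ≈ 0.2% per null gene at ~100 events (identical
  in this solver and lifelines); occasionally a cohort in which the
  shared responder factor spuriously associates with outcome produces a
  *cluster* of response-gene selections at once. False positives are
  counted as selections outside both planted programs; cross-program
  pickup is tracked separately by the decoupling analysis.
- Fold-wise cross-validated risk-group tables (the training report)
  retrain the signature per fold with the gene list fixed to the
  full-data selection; the gene-selection step itself is not redone per
  fold, so these tables carry residual selection optimism.

## 5. Reproducibility

All randomness flows from explicit seeds; the CLI derives named
substreams (folds, simulation, masking) from one master seed via
`SeedSequence`. Outputs contain no timestamps; reruns with identical
inputs are byte-identical, and the test suite asserts this end to end.
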