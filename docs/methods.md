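# Methods

## The analysis model

The pipeline estimates whether a transcriptional signature of cycling
hypoxia, derived entirely in vitro, stratifies breast cancer patients by
disease-free survival. It has two statistical halves.

**Derivation.** A panel of tumour cell lines is profiled once per
oxygenation condition (normoxia, cycling hypoxia, continuous hypoxia). For
a chosen condition pair, each of `n_resamples` iterations draws a uniform
random 90/10 train/test partition of the samples, computes per-probeset
Welch two-sample *t*-tests on the training split, applies the
Benjamini–Hochberg step-up correction, and records the corrected p-values.
Probesets are ranked by the arithmetic mean of their corrected p-values
across resamplings (lower = more consistently differential); the top `k`
form the signature. Ties break by larger mean |t|, then lexicographic
probeset id. Each iteration also classifies its held-out samples with a
nearest-class-centroid rule (Euclidean distance on log2 values over that
iteration's own top-`k` probesets); the mean of these accuracies is the
reported discrimination estimate. Averaging *corrected* p-values (rather
than re-correcting averaged p-values) is deliberate: the corrected value is
the quantity that is comparable across resamplings with different
effective test multiplicities.

The *t*-test is unpaired even though cell lines are crossed with
conditions, because random resampling of samples breaks the pairing
anyway; a paired analysis over intact line pairs would require stratified
resampling, which the derivation deliberately does not do (resampling is
over samples, the simplest scheme consistent with a uniform 90% draw).

**Prognostic model.** The signature is carried to the clinical platform by
gene identifiers: every destination probeset of every mapped gene is kept
(no best-probeset collapsing), because clinical arrays routinely represent
one gene by several probesets and discarding them throws away signal.
Probesets without a gene id cannot be mapped and are dropped with a
warning.

On the training cohort, expression restricted to the mapped signature is
z-scored and fed to an elastic-net-penalized Cox proportional-hazards
model. The penalty is written λ₁‖β‖₁ + ½λ₂‖β‖₂² with independent weights;
the pair is selected from a grid by k-fold cross-validation scored by
held-out Breslow partial log-likelihood (minimizer, no one-standard-error
rule). The per-patient risk score is the linear predictor; the decision
threshold is the midpoint between consecutive observed training scores
that maximizes (sensitivity + specificity)/2 for classifying *event within
5 years* (events within the horizon are cases; patients event-free with
follow-up past the horizon are controls; patients censored earlier are
excluded — the standard strategy for dichotomizing censored follow-up).
Ties in the balanced rate break toward the higher cut (higher
specificity); a score exactly at the threshold is low risk. Follow-up is
administratively censored at 10 years before any modelling so cohorts with
different follow-up are comparable.

**Evaluation.** Per validation cohort: hazard ratio between predicted
groups (univariate Cox with Wald CI/p), Harrell's concordance index over
usable pairs (earlier time must be an event; score ties get half credit;
the standard error is the binomial-style √(c(1−c)/m) over the m usable
pairs — a simple, slightly conservative pair-decomposition estimator),
BCR/sensitivity/specificity at the 5-year horizon with a one-sample Z-test
against 0.5, the logrank test, and Kaplan–Meier curves. Cohorts pool by
fixed-effect inverse-variance weighting (log-HR pooled on the log scale);
a random-effects option is intentionally absent since cohorts are
simulated exchangeable. Two stratifications of the same patients are
compared by patient-level bootstrap of the metric difference with a
normal-approximation two-sided p — a distribution-free substitute for
closed-form correlated-estimate tests.

**Random-signature null.** Prognostic signatures must beat the "most
random signatures are prognostic" phenomenon, so the observed signature's
metric is ranked among `n_signatures` random probeset sets of the same
size, each run through the *entire* fit → threshold → classify → metric
pipeline at a fixed light penalty (λ₁ = 10⁻⁴, λ₂ = 0.1; cross-validating
per random signature would multiply cost ~50× without changing the
comparison, and the mild ridge keeps coefficients non-zero so the null
metric distribution stays continuous). The empirical p is the add-one
estimator (1+k)/(N+1), never zero, matching "P < 0.001" reporting at
N = 1000. A random signature whose pipeline degenerates (e.g. a single
predicted group) records the metric's no-signal value.

**NPI.** npi = 0.2·size_cm + grade + nodal stage (1 for 0 nodes, 2 for
1–3, 3 for ≥4); bands good ≤ 3.4 < moderate ≤ 5.4 < poor, boundaries
closed on the left band; moderate and poor merge into "high" for two-group
comparison. Constants are configurable module-level values.

## Synthetic data: what it emulates and what it does not

`gen_cell_line_experiment` plants a mean log2 shift of `effect_size`
(default 1.0) on `n_planted` probesets in the corresponding condition, on
top of probe baselines ~N(7, 1), a mild per-line array offset (sd 0.1) and
N(0, `noise_sd` = 0.5) measurement noise. It emulates the design —
balanced panel, one sample per line per condition, a coherent differential
programme — not microarray probe-level physics, batch effects, or the
marginal distributions of any real dataset.

`gen_cohort` draws a standard-normal latent activity per patient; event
times are exponential with rate `baseline_rate`·exp(log(`hr_per_sd`)·
activity) (defaults 0.08/year and 2.0, the regime of an aggressive
transcriptional programme), censoring is independent exponential with its
rate solved numerically so the expected censored fraction equals
`censor_rate` (default 0.3), plus administrative censoring at `horizon`.
Signature probesets read loading·activity + N(0, `noise_sd`); the default
noise_sd of 2.0 with loading 1.0 puts the single-probe correlation with
the activity near 0.45 — the strength typically observed between an
individual signature gene and its metagene — while a ~90-probeset average
still tracks the activity at r ≈ 0.98. This matters for the
random-signature null: with unrealistically clean per-probe readouts
(r ≈ 0.9), any random signature that happens to contain one informative
probe performs almost as well as the true signature, which is an artefact
of the one-factor design rather than a property of real expression data.
Clinical covariates are conventions sufficient for NPI and subtype
analyses (size ~ lognormal(0.7, 0.4) cm, nodes ~ Poisson(1), grade 1–3
with probabilities shifted by activity quartile when `clinical_link` is
set, ER+ 75%, HER2+ 15%, treated 50%), not calibrated to any registry.

Because the cohort model has a *single* latent factor and exchangeable
cohorts, passing tests demonstrate correct mechanics and calibrated
inference under proportional hazards — not robustness to multi-factor
biology, cross-cohort batch/platform shifts (per-cohort re-z-scoring is
the default specifically to absorb such shifts when they do occur), or
violations of proportional hazards.

## Numerical choices and edge cases

- Welch t-test with zero variance in both groups: t = 0, p = 1 when means
  agree, p = 0 otherwise; infinite |t| values are clamped for the
  tie-break statistic.
- Penalized fits run through coxnet coordinate descent (alpha = λ₁+λ₂,
  l1_ratio = λ₁/(λ₁+λ₂)); the λ₁ = 0 cases (pure ridge and unpenalized)
  run through lifelines' Newton solver, which also supplies standard
  errors for parameter-recovery checks.
- Cross-validation folds come from a seeded permutation; folds whose
  complement has no events are re-dealt with a warning.
- A monotone partial likelihood (a group without events) in the univariate
  HR is fitted with a tiny ridge, flagged with a warning, and reported
  with an infinite CI bound.
- Degenerate threshold selection (all scores equal) returns that score:
  everyone is low risk and BCR = 0.5.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator and every pipeline stage is bit-reproducible given
  (parameters, seed).

## Problem sizes used in tests and the acceptance script

Derivation checks run at the design scale (20 lines × 3 conditions, 5000
probesets, 100 planted, 200 resamplings; ~1 s per derivation). Risk-model
checks use a 344-patient training cohort — the size of the node-negative
untreated reference cohort the design targets — with validation cohorts of
300–600 patients. The random-signature comparison uses 200 random
signatures (the add-one empirical p then bottoms out at 1/201 ≈ 0.005);
null-calibration checks repeat it 100 times on no-signal cohorts of
120/150 patients with a 300-probeset universe. These sizes were chosen so
the whole statistical surface re-runs comfortably on a laptop while
keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- Gene70/Gene76/Oncotype DX scoring is not reimplemented; a plug-in
  adapter accepts any externally computed score table with a threshold.
- The expression-based ER/HER2 subtype rule is a per-cohort two-component
  Gaussian mixture per marker gene — adequate for clearly bimodal markers,
  not a substitute for clinical assays on borderline cohorts.
- The concordance-index standard error ignores pair correlation and is
  approximate; it is used for pooling weights and a z-test against 0.5,
  not for formal CIs on c itself.
- No proportional-hazards diagnostics, time-dependent effects, or
  competing risks.
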