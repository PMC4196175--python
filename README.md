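# cychyp

Tumours experience *cycling hypoxia* — repeated alternation of low-oxygen
and reoxygenation episodes — and the transcriptional programme it induces
is a candidate prognostic biomarker. `cychyp` implements, as a tested and
reusable Python pipeline, the workflow that turns a multi-condition
cell-line expression experiment into a validated prognostic gene signature
for breast cancer cohorts:

1. **Signature derivation** — over repeated random 90/10 sample splits of a
   cell-line panel profiled under normoxia, cycling hypoxia and continuous
   hypoxia, probesets are scored by a Welch *t*-test with Benjamini–Hochberg
   FDR correction on the training split; corrected p-values are averaged
   over 200 resamplings and the top 100 probesets form the signature. The
   held-out 10% estimates discrimination accuracy with a nearest-centroid
   classifier.
2. **Cross-platform transfer** — signature probesets are mapped to gene
   identifiers and carried to the clinical array platform, keeping every
   destination probeset of each mapped gene.
3. **Risk model** — an elastic-net-penalized Cox proportional-hazards model
   (penalty λ₁‖β‖₁ + ½λ₂‖β‖₂², chosen by cross-validated held-out partial
   likelihood) gives each patient a linear risk score; a decision threshold
   on the training scores maximizes balanced sensitivity/specificity for
   disease progression within 5 years. Follow-up is administratively
   censored at 10 years.
4. **Evaluation** — per validation cohort and pooled (fixed-effect inverse
   variance): hazard ratio between predicted risk groups, Harrell's
   concordance index, balanced classification rate (BCR), sensitivity,
   specificity, Kaplan–Meier curves and the logrank test; nested patient
   subsets (all → ER+/HER2− → node-negative → untreated).
5. **Random-signature null** — the whole fit/threshold/classify pipeline is
   rerun for hundreds of size-matched random probeset signatures and the
   observed signature's metric is ranked with the add-one empirical
   p-value (1+k)/(N+1).
6. **NPI reclassification** — the Nottingham Prognostic Index
   (0.2·size + grade + nodal stage; good ≤ 3.4 < moderate ≤ 5.4 < poor,
   moderate+poor merged into "high") is cross-tabulated against the
   molecular risk groups to quantify how many clinically high-risk patients
   the signature reclassifies as low risk and vice versa.

A synthetic-data module generates cell-line experiments with planted
differential probesets and survival cohorts in which a latent per-patient
activity drives both signature-gene expression and an exponential
proportional-hazards event process, so every stage is testable against
known ground truth without external downloads.

## Worked example

```python
from cychyp import (gen_cell_line_experiment, derive_signature, gen_cohort,
                    Signature, fit_penalized_cox, risk_score,
                    select_threshold, classify, cox_hr, logrank_test)

# cell-line panel: 20 lines x 3 conditions, 100 planted probesets
expr, design, truth = gen_cell_line_experiment(20, 5000, 100,
                                               effect_size=1.0,
                                               noise_sd=0.5, seed=1)
sig, summary = derive_signature(expr, design, ("normoxia", "cychyp"),
                                k=100, n_resamples=200, seed=2)
print(len(set(sig.probeset_ids) & truth.planted_cyc), summary.mean_accuracy)
# 98 1.0    -> 98/100 planted probesets recovered, held-out accuracy 100%

# survival cohorts driven by a latent activity with HR 2 per SD
probes = [f"S{i}" for i in range(87)]
train, _ = gen_cohort(344, probes, hr_per_sd=2.0, seed=1,
                      background_probes=200)
valid, _ = gen_cohort(600, probes, hr_per_sd=2.0, seed=2,
                      background_probes=200)
model = fit_penalized_cox(train, Signature(probes, "SYN_CLIN"),
                          l1_grid=[0.001, 0.01, 0.1],
                          l2_grid=[0.001, 0.01, 0.1], seed=3)
model.threshold = select_threshold(risk_score(model, train.expr),
                                   train.time, train.event, horizon=5.0)
groups = classify(risk_score(model, valid.expr), model)["group"] == "high"
print(cox_hr(groups.astype(int), valid.time, valid.event)[0])
# 2.21    -> high- vs low-risk hazard ratio on the independent cohort
print(logrank_test(groups.astype(int), valid.time, valid.event)[1])
# 1.7e-11 -> logrank p-value for the survival separation
```

Cross-validation selected (λ₁, λ₂) = (0.1, 0.001) here, leaving 13
non-zero coefficients; the validation hazard ratio of 2.2 between the
thresholded score's risk groups reflects the designed gradient of HR 2 per
SD of latent activity, attenuated by dichotomization.

The same analysis runs end-to-end from the command line:

```sh
cychyp run-all --outdir out --seed 0          # full synthetic pipeline
cychyp simulate --outdir data --seed 1        # or stage by stage:
cychyp derive --expression data/expression.tsv --design data/design.tsv \
       --out data/sig.tsv
```

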