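# radadapt

Modality-adaptive, calibrated, explainable radiomics analysis for
predicting **MGMT promoter methylation** in high-grade glioma from wide
radiomic feature tables.

MGMT methylation predicts temozolomide response but is assessed by
invasive tissue sampling. Radiomics models can estimate it pre-operatively
from MRI-derived feature tables — but multi-center cohorts differ in which
MRI sequences they acquired, raw classifier scores are poorly calibrated
for clinical use, and black-box predictions are hard to act on. This
package implements the full tabular analysis addressing those three
problems, for researchers working with radiomics feature tables (rows =
patients, columns named `<modality>_<filter>_<family>_<feature>`):

- **Modality-adaptive imputation** — features of absent MRI sequences
  (ADC/ASL/DWI) are filled with training-set medians, constant across
  affected patients, so models learn to ignore them while still exploiting
  the sequences when present.
- **Consensus feature ranking** — variance cutoff (< 10⁻⁸), greedy
  Spearman redundancy filter (|ρ| > 0.80), z-scoring, then two importance
  measures combined by rank sum: |coefficient| of an L1-penalized logistic
  fit, and permutation importance measured as the mean increase in
  validation-fold log-loss over 5 folds × 100 shuffles,

  LogLoss = −(1/N) Σᵢ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)].

- **Model builds** — {penalized logistic, gradient-boosted trees} ×
  {all features, top-K consensus, L1-front-end filtered}, tuned by a
  seeded random search maximizing mean CV AUC, with hash-guarded test-set
  isolation.
- **Platt calibration and operating point** — p = σ(a·s + b) fitted on
  pooled out-of-fold validation scores (AUC-preserving for a > 0); the
  threshold t\* minimizes FP + FN; Brier score quantifies calibration.
- **Decision curve analysis** — Net Benefit NB = TP/N − FP/N · p_t/(1−p_t)
  against treat-all/treat-none, and the Net Reduction in unnecessary
  Interventions per 100 patients, NRI₁₀₀ = (NB_model − NB_all)·(1−p_t)/p_t·100,
  plus a four-band probability interpreter (cuts 0.300 / 0.575 / 0.800).
- **Exact Shapley attribution** — f(x) = φ₀ + Σⱼ φⱼ by coalition
  enumeration (≤ 12 features; a seeded permutation-sampling estimator,
  exactly additive by telescoping, beyond that).
- **Synthetic cohort generator** — two-cohort tables (one with all seven
  modalities, one conventional-only), prevalence ≈ 0.61, planted
  informative features, latent-factor correlation blocks and pure noise,
  with ground truth recorded for every downstream test.

## Worked example

The package is a library; `examples/` holds one narrative script per
capability. For instance the decision-curve example:

```bash
python examples/05_decision_curve.py
```

prints, first, the closed-form worked values at prevalence 0.61 and
operating threshold 0.575:

```
treat-all NB at pt=0.575, prevalence 0.61: 0.0824
model NB 0.143 -> NRI_100 = 4.48 unnecessary interventions avoided per 100 patients
model NB 0.264 -> NRI_100 = 13.43
```

— a model with net benefit 0.143 at that threshold avoids about 4.5
unnecessary interventions per 100 patients compared with treating
everyone; after calibration lifts net benefit to 0.264, about 13.4 are
avoided. It then trains and calibrates a gradient-boosted model on a
synthetic cohort and tabulates its decision curve on the held-out test
set:

```
  pt    NB_model  NB_all   NRI_100   (calibrated test predictions)
 0.35   +0.5668  +0.4602   +19.80
 0.50   +0.5088  +0.2982   +21.05
 0.65   +0.4311  -0.0025   +23.35
```

NB_model above both NB_all and 0 across the window is the
decision-analytic case for using the model. Similarly,
`examples/03_rank_features.py` runs the consensus ranking on a cohort
with 14 planted informative features and reports
`top-30 consensus features recover 14/14 planted informative features`.

## Layout

```
src/radadapt/     feature grammar, synthetic cohorts, splitting, imputation,
                  ranking, model builds, calibration, DCA, attribution, pipeline
examples/         one runnable narrative script per capability
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   model assumptions, parameter choices, numerical conventions
```
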