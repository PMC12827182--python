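# Methods

This note records the statistical model behind `radadapt`, the defaults
and conventions that matter, and the design choices made where more than
one reasonable option existed.

## Problem setting

Each patient contributes a wide vector of radiomic features extracted
from pre-operative MRI, named by a four-token grammar
`<modality>_<filter>_<family>_<descriptor>` (seven modalities: ADC, ASL,
DWI, FLAIR, T1, T1CE, T2; filters: original, eight 3D wavelet sub-bands,
four Laplacian-of-Gaussian scales σ ∈ {0.5, 1.0, 2.0, 3.0} mm; seven
descriptor families). The label is binary MGMT promoter methylation
(methylated = 1, prevalence ≈ 0.61 in the emulated setting). One cohort
carries all seven modalities; a second carries only the conventional four,
so its ADC/ASL/DWI features are structurally missing. Feature extraction
itself is out of scope: the package starts from the feature table.

## Synthetic cohort generator

The generator emulates the statistical structure of such a study, not its
images:

- **Labels** are i.i.d. Bernoulli(prevalence). They are deliberately not
  forced to exact class counts, because the downstream stratified splitter
  must tolerate imperfect ratios.
- **Informative features** get a class-conditional mean shift of
  `effect_size` (δ) residual standard deviations: x ~ N(δ·σ·y, σ²). They
  occupy a prefix of the feature list whose naming layout cycles modality
  fastest and co-cycles filter and family with coprime periods, so any
  planted subset is spread round-robin across modalities, filters and
  families.
- **Correlation blocks** follow a single-factor model
  x = λ·f + √(1−λ²)·ε per block, giving expected pairwise Pearson
  correlation ≈ λ² (Spearman slightly below, ≈ (6/π)·asin(λ²/2) under
  normality) — an analytic handle for testing the redundancy filter.
  Blocks are drawn from the label-independent features so the planted
  truth set stays unambiguous.
- **Missingness** is an explicit NaN, never a sentinel value, and applies
  to exactly the advanced-modality columns of conventional-only patients.
  Imputation is a separate, auditable step.
- Defaults mirror the emulated two-cohort design: 399 + 262 patients,
  prevalence 0.61. Sub-study conditions (e.g. 600 patients × 200 features
  with 20 informative at δ = 1.0 for selection-recovery runs) are stated
  at each use site.

What the generator does *not* emulate: scanner/site batch effects,
non-Gaussian feature marginals, label noise, and correlation between
informative features. Passing tests therefore demonstrate correctness of
the procedures under a clean factor-model cohort, not performance on real
imaging data.

## Splitting

Patient-level 85/15 train-CV/test split. The test size is
round(0.15·n); the class-1 test count minimizes |test prevalence −
overall prevalence| over feasible integers; patients are then sampled per
class without replacement (seeded). Cross-validation uses stratified
5-fold partitioning of the train-CV ids (fold sizes within one of each
other, per-fold class counts within one of proportional). Patient-level
disjointness is asserted, and all later stages consume the persisted
`SplitPlan`, so every filter and rank is reproducible from the split
alone.

## Modality-adaptive imputation

Per-feature medians are computed from observed training-set values only
(even count: mean of the two middle values — pinned so tests are exact)
and fill every missing cell. The fill is constant across affected
patients, so for conventional-only patients the advanced columns carry no
discriminative signal: any deterministic model scores two such patients
with identical conventional features identically, and an imputed column
is an exact Shapley null player when the background is conventional-only.
Imputation runs *before* variance filtering and z-scoring: the pipeline
consumes one complete matrix, and in a mixed cohort the imputed columns
remain non-constant overall, so the variance cutoff does not delete them.
Z-scoring statistics are computed on the imputed training matrix,
imputed cells included.

## Consensus ranking

1. **Variance cutoff**: drop features with population variance
   (divisor N) strictly below 10⁻⁸; a variance of exactly 10⁻⁸ is kept.
2. **Spearman filter**: greedy scan in input column order; a candidate is
   dropped the first time its |ρ| with an already-kept feature exceeds
   0.80 (strict), and the (kept, dropped, |ρ|) triple is recorded. The
   surviving set provably contains no offending pair on the filtering
   matrix. Keep-first in column order was chosen for determinism and
   trace-auditability.
3. **Z-scoring** with training statistics, population SD (divisor N) —
   the convention is immaterial at study scale but is pinned for exact
   tests.
4. **Coefficient ranks** from one L1-penalized logistic regression
   (liblinear, C = 1.0 by default) fitted on the full train-CV set;
   features ranked by |coefficient| descending, ties (including all-zero
   coefficients under a strong penalty) broken by feature name so the
   rank is a total order.
5. **Permutation importance**: per fold, the same sparse-logistic model
   is fitted on the other folds; baseline AUC and log-loss are recorded
   on the validation fold; each surviving feature's validation values are
   shuffled 100 times and the importance is the mean log-loss increase
   over folds × repeats. Shuffling is confined to the validation fold —
   the marginal distribution is preserved while the link to the label is
   severed, and training rows are never contaminated. RNG streams derive
   from (seed, fold, feature), so results are reproducible and
   independent of evaluation order. Baseline AUC is reported but does not
   enter the score, which is defined through log-loss only. The model
   whose deterioration is measured is a design choice of this package
   (the same sparse logistic regressor as step 4), made so that the two
   consensus components rank the same hypothesis class.
6. **Consensus** = coefficient rank + permutation rank; top-K (default
   500) by ascending sum, ties by (permutation rank, name). K larger than
   the survivor count clamps with a warning.

Log-loss clips probabilities to [10⁻¹⁵, 1−10⁻¹⁵], since the expression is
undefined at p ∈ {0, 1}.

**Monte-Carlo error of the permutation importance.** Repeats within a
fold share one fitted model and one baseline, so the fold×repeat draws
are strongly correlated within folds; treating them as i.i.d. would
understate the standard error by roughly √(repeats). The reported SE is
therefore the per-draw standard deviation divided by √(number of folds) —
the fold is the estimator's independent sampling unit. Under this SE, a
label-independent feature's mean importance is within 3 SE of zero, as
the null analysis expects.

## Model builds and tuning

Six canonical builds: {logistic, gradient-boosted trees (LightGBM)} ×
{all features, top-K consensus, L1-front-end filtered}. The L1 front end
fits an L1-penalized logistic model (log-loss + λ·Σ|w|, the penalty that
drives small weights exactly to zero), ranks features by |coefficient|
with zeros last, and keeps ⌈(1−fraction)·p⌉ — computed as p − ⌊fraction·p⌋
to avoid float artifacts. Hyperparameters are tuned by seeded random
search (logistic: C, penalty type, tolerance; GBT: leaves, depth,
learning rate, trees, L1/L2 regularization, min child samples; L1 builds
additionally the filter fraction), objective = mean validation-fold AUC,
winner refit on the full train-CV set. The desk-scale default is 25
trials; a 400-trial search is a plain configuration change and nothing
downstream depends on the trial count. Test rows are hash-checked before
and after the search and never indexed during it. Metrics are reported
for pooled out-of-fold validation predictions and for the held-out test
set, which also resolves the ambiguity between "final fold" and "average
fold" reporting: the pooled OOF panel is labeled as such.

## Calibration and operating point

Platt scaling p = σ(a·s + b) is fitted by near-unpenalized logistic
regression (a tiny ridge only bounds the separable case) on the pooled
out-of-fold validation predictions — each train-CV patient is predicted
exactly once by a model that never saw it, avoiding optimistic bias
without sacrificing rows. For a > 0 the map is strictly monotone, so AUC
is unchanged; this is asserted on every fit. No Laplace-smoothed targets
are used. The operating threshold scans midpoints between consecutive
distinct sorted probabilities plus boundary sentinels (all-positive /
all-negative), decision rule p ≥ t, minimizing FP + FN; ties resolve
toward the larger threshold (fewer interventions), matching the clinical
preference for avoiding unnecessary treatment.

## Decision curves

NB = TP/N − FP/N·p_t/(1−p_t); treat-all is the same expression with every
patient positive (zero exactly at p_t = prevalence); treat-none is 0;
NRI₁₀₀ = (NB_model − NB_all)·(1−p_t)/p_t·100, per 100 patients with the
factor inside the formula. Positive decision at p ≥ p_t (closed at the
threshold, consistent with the probability bands being lower-closed).
Default grid 0.01–0.99 in steps of 0.005. The probability interpreter
partitions [0, 1] at 0.300 / 0.575 / 0.800, upper-closed only at 1.0.
The reference values 0.575 (operating threshold) and 0.61 (prevalence)
reproduce the worked numbers NRI₁₀₀ ≈ 4.48 at NB = 0.143 and ≈ 13.4 at
NB = 0.264; quoted rounded values of 4.5 and 13.6 are consistent with
these only up to the rounding of the printed NB and prevalence inputs,
which is why the package reports the recomputed values.

## Attribution

Interventional Shapley values: v(S) is the mean model output with
features outside S replaced by background rows (the marginal, not
conditional, expectation — it matches "expected output over the
background data" and gives the closed form φⱼ = wⱼ(xⱼ − mean background)
for linear models). Attribution is on the probability output, so
contributions sum to the predicted probability. Exact coalition
enumeration is used up to 12 features (2¹² batched model calls); beyond
that, a seeded permutation-sampling estimator whose per-permutation
marginal contributions telescope from v(∅) to f(x), making the estimate
exactly additive at any sample size. Additivity
|φ₀ + Σφ − f(x)| ≤ 10⁻⁹ (exact backend; 10⁻³ for approximate backends) is
verified for every emitted attribution. Per-class reports average φ over
all correctly classified samples of each class (a single-sample mode
exists for the most-confident-sample variant) and annotate the top-k
with modality/filter/family via the name grammar.

## Feature-anatomy tallies

Tallies count by filter class, wavelet sub-band, LoG scale, modality and
family; each map sums to the total (the sub-band and scale maps sum to
the wavelet and LoG counts respectively). The "low-pass-heavy" subtotal
counts wavelet sub-bands with ≥ 2 low-pass (L) components literally —
LLL, LLH, LHL and HLL all qualify. Groupings in the literature sometimes
list only the sub-bands beginning with L; the literal definition is used
here and documented to avoid ambiguity.

## Problem sizes

The shipped tests and the reproduction script use desk-scale cohorts
(180–730 patients, 60–210 features, 10–100 permutation repeats, 3–25
search trials), chosen so the full suite runs in well under a minute
while every statistical property being tested (filter guarantees,
null-importance calibration, planted-signal recovery at δ = 1.0,
calibration gains) is comfortably resolved at those sizes. All of them
scale up by changing configuration values only.

## Known limitations

- The generator's clean factor-model structure makes selection easier
  than on real radiomics tables with heavy-tailed marginals and
  cross-family correlation; recovery rates here are upper bounds on
  real-data behavior.
- The permutation-importance model is a linear (logistic) scorer;
  importance of features whose effect is purely interactional would be
  invisible to it. This mirrors the consensus design, which pairs the
  permutation rank with a linear coefficient rank.
- Exact Shapley is limited to 12 features by enumeration cost; the
  sampling backend is unbiased and exactly additive but its per-feature
  values carry Monte-Carlo error.
- Decision curves are reported without confidence bands.
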