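# Methods

This note documents the statistical procedures implemented in `pgdvoc`,
the synthetic cohort generator used to exercise them, and the numerical
and design choices made where the procedure leaves room.

## Problem setting

A cohort of bilateral lung-transplant recipients is sampled at the end of
surgery (< 6 h post-reperfusion, the *early* window) and again at 6–72 h
(*late*).  Each sampling yields up to two airway-fluid specimens — BALF and
BBA — whose headspace VOCs are quantified by GC×GC-TOFMS into a samples ×
features table of non-negative peak areas (absent peaks are exact zeros).
The outcome is the ISHLT PGD grade over the first 72 h, dichotomized as
grade 3 (PGD3, the positive class) versus grades 0–2.  The statistical
difficulties are the ones typical of pilot omics studies: tens of samples,
hundreds of features, and paired specimens that make samples of one patient
strongly dependent.

## Concordance and pooling

For every within-patient same-window BALF–BBA pair, and for every
unordered same-matrix pair of samples from distinct patients, the
correlation across all aligned features is computed (Pearson on values,
Spearman on average ranks).  Correlations use `log(normalized area + ε)`
with ε = the smallest nonzero normalized area in the table ÷ 10: peak
areas are log-normal-like, and without the shift the many exact zeros
would be undefined under the log.  A raw-scale option is retained
(`log_scale=False`).  The matrices are pooled for modelling iff the mean
paired correlation *strictly* exceeds both cross-individual means; ties
conservatively keep them separate.

## Model building

* **Split.** Patients are stratified by class and partitioned at a 0.5
  training fraction per class (rounded, both sides non-empty).  All of a
  patient's samples follow the patient.  The training fraction is
  configurable (`ratio`), which also accommodates the reading where the
  1:1 ratio applies to samples rather than patients.
* **Classifier.** A C-SVM with linear kernel (hinge loss + L2,
  `sklearn.svm.SVC(kernel="linear")`, C = 1.0 default) on features
  transformed by `log(x + ε)` (ε as above, computed on training data) and
  per-feature standardization fitted on training data (constant features
  are left at 0).  The log transform is the package's choice — the scale
  the original workflow fed the SVM is not documented — and can be
  disabled (`log_transform=False`).  Linear kernel only: with ~30 training
  samples any nonlinear kernel invites overfitting, and the weight vector
  is what makes feature importance meaningful.
* **Importance and selection.** Importance of feature *j* is
  `100·|w_j|/max_k|w_k|` on the standardized scale (standardization makes
  weights comparable across features).  Retained: importance ≥ 50
  (inclusive) AND detected (area > 0) in ≥ 25 % (inclusive) of the
  training samples of at least one class.  Prevalence is computed on
  training samples only, so the panel never sees held-out data.
* **Evaluation.** The classifier is refitted on the retained panel and
  scores the held-out samples.  AUROC is the Mann–Whitney concordance of
  decision scores (ties ½); its 95 % CI is a stratified percentile
  bootstrap (positives and negatives resampled separately, 2000 replicates
  by default, seed-controlled; the interval is widened to include the
  point estimate if a resampling quirk would exclude it).  Probabilities
  come from a two-parameter logistic (Platt-style) fit to the training
  decision scores; class calls use probability ≥ 0.5.  Confusion-derived
  rates (sensitivity, specificity, PPV, NPV, accuracy) follow the textbook
  identities exactly.  The no-information-rate check is a one-sided exact
  binomial test of the correct-call count against the majority-class
  fraction of the test set.
* **Late window.** Late samples are scored by the early-window model
  without refitting.  Late samples from *training* patients are excluded:
  specimens of one patient share a latent profile, and scoring them with a
  model fitted on that patient inflates performance even with no class
  signal (measured at AUROC ≈ 0.85 on effect-free data when the exclusion
  is lifted).

## Permutation validation

* **Random-feature null**: the train-and-predict step repeated on panels
  of k = 20 features drawn uniformly without replacement (200 replicates
  default), averaging test AUROC.
* **Random-label null**: the retained panel and fitted model are fixed;
  test-set labels are permuted *at the patient level* (both samples of a
  patient always share a permuted label — sample-level shuffling would
  break the very dependence structure the grouped split protects) and the
  fixed scores are re-evaluated.
* **Scheme audit**: for each of {no validation, sample-level leave-one-out
  with the panel selected on all data, grouped split}, the apparent AUROC
  is compared with the mean AUROC of the same procedure re-run end-to-end
  under patient-permuted labels.  A null mean above 0.6 flags the scheme
  as overfitting; on effect-free synthetic data the first two schemes flag
  (null means ≈ 0.98–1.0) while the grouped split does not (≈ 0.46).

## Clinical covariates

Cohort comparisons use the two-sided Wilcoxon rank-sum test for continuous
variables (exact when group sizes permit and there are no ties) and the
Pearson chi-squared test *without* continuity correction for categorical
ones — the uncorrected statistic is what reproduces the reference
contingency p-value from its printed counts (Yates' correction gives ≈ 0.09
instead of 0.03 on that table).  Output p-values are rounded to 2
significant figures with the raw value retained.

The MANOVA screen tests a categorical clinical factor against the
multivariate VOC response with Pillai's trace and its approximate F
(statsmodels).  When the response dimension p ≥ n − g the response is
projected onto its first min(p, n − g − 1) principal components (fitted on
pooled data) so the error matrix stays full rank; the projection is
logged.  With one response the test reduces exactly to one-way ANOVA (a
closed-form branch).  Stratifiers: BMI low < 18.5, normal 18.5–25
(inclusive), high > 25 kg/m²; ischemia short < 6 h, medium 6–10 h
(inclusive), long > 10 h; recipient risk is *low* iff normal BMI, COPD/CF
diagnosis and absent-or-mild pulmonary hypertension all hold (missing
fields conservatively yield *high*).  Lung-function correlations (selected
features, patient-level means, vs 3-month spirometry) are Pearson with
two-sided t-based p and Benjamini–Hochberg adjustment at 0.05 across the
feature × measure grid.

## Synthetic cohort generator

`SyntheticSpec` defaults encode the study conditions: 35 patients, 28 %
PGD3 (10 patients), 58 early samples (23 BALF/BBA pairs + 12 singles), 386
features, 20 informative features with a 2-fold PGD3 multiplier, paired /
background correlation targets 0.65 / 0.50, OCS use at 4 % / 30 % per
class, and 14 extra late-window samples (7 per class) in which the planted
log-effect is halved (`late_effect_attenuation = 0.5`).  The 58-sample
budget is spent entirely on the early window; late samples are generated
in addition, since the early set is what the concordance and
model-building stages consume.

The log-area of sample *s* of patient *i* at feature *j* is
`mu_j + p_ij + e_sj`, with variances solved analytically from the
correlation targets: `Var(mu) = ρ_b`, `Var(p) = ρ_p − ρ_b`,
`Var(e) = 1 − ρ_p`, each times the total log-variance `log_sigma²`.
Zero-inflation draws per-feature presence probabilities from a mixture
(9 % sparse features at presence 0.02–0.15 — guaranteed to fail the 25 %
prevalence filter — and Beta(14, 1) for the rest); 30 % of features have
*patient-level* absence (missing from both of a patient's specimens), the
rest drop out independently per sample.  Because zeros land far down the
log scale, this mask layer carries much of the across-feature variance;
the mixture and the patient-level fraction were calibrated once so the
achieved log-scale correlations reproduce the 0.65 / 0.50 targets at the
default cohort size (achieved 0.65 / 0.50 / 0.50, 20-seed means).  The
calibration holds at the default targets; users who move the correlation
targets far from the defaults shift the Gaussian layer correctly but keep
the fixed mask layer, so extreme targets are approximate.

`log_sigma = 0.85` (≈ 60 % within-feature CV, typical of SPME headspace
tables) was chosen because it makes the generator reproduce the reference
study's statistics jointly: 20-seed mean concordance 0.65 / 0.50 / 0.50,
median held-out AUROC ≈ 0.89 at the default 2-fold effect, and median
planted-panel recovery of 14/20.  Informative features are generated at
full presence — a discriminatory panel in this kind of study consists of
consistently detected compounds.  Clinical records draw study-population-like
marginals, with OCS linked to class; `generate_null` forces the effect
multiplier to 1 and redraws class-linked covariates independently of
class.  Everything is reproducible bit-for-bit from the spec's seed.

`make_cohort_fixture` is a *synthetic* stand-in for the study's clinical
table: group sizes and categorical cell counts (OCS 1/3, trauma 2/3, DCD
7/2, diagnosis 7-14-4 / 2-6-2, 11/8 high-risk, …) are exact; continuous
fields are drawn from the printed mean/SD only approximately, so
chi-squared results on the fixture are exactly reproducible while Wilcoxon
p-values are not.

### What passing tests do and do not show

The generator provides *structural* realism (sample sizes, pairing,
zero-inflation, dependence, effect placement), not chromatographic
realism: no retention-time drift, batch effects, heteroscedastic detector
noise, or correlated metabolite families.  Passing the planted-recovery
and null-calibration suites therefore shows the pipeline is unbiased and
sensitive under its stated assumptions — it does not certify performance
on real GC×GC data, where feature correlation structure is richer.

## Numerical choices and degenerate inputs

* ε for log transforms: smallest nonzero value ÷ 10 (computed on the
  fitting data and reused at prediction time); all-zero inputs fall back
  to 1e-12.
* Constant features standardize to 0 (scale forced to 1); constant
  vectors yield NaN correlation sentinels with a warning rather than
  errors.
* All-zero samples stay all-zero under normalization (logged).
* Abundance ratios with a zero PGD0-2 mean report `inf` with an
  `undefined` flag; 0/0 reports NaN.
* Empty retained panels raise with advice to relax the cuts; the
  validation-scheme audit (a diagnostic, not the headline path) falls back
  to the single top-importance feature instead.
* Boundary inclusivity: importance ≥ 50, prevalence ≥ 0.25, BMI 18.5 and
  25 → normal, ischemia 6 and 10 → medium.
* Randomness: one master seed per pipeline run, split per stage with
  `numpy.random.SeedSequence`; permutation draws are reproducible
  bit-for-bit given (seed, n_reps).

## Problem sizes used by the test and acceptance runs

Tests run the full default cohort (58 early samples × 386 features) for
end-to-end checks; 20-seed batteries for recovery, monotonicity and
correlation-target checks; 200 replicates for the permutation-null
calibrations; 500 replicates at n = 40, p = 5 for the MANOVA type-I
calibration; bootstrap sizes are reduced (20–200) in tests where only the
point estimate matters.

## Known limitations

* The split ratio applies at the patient level; a sample-level 1:1 split
  is only approximated by adjusting the patient-level ratio.
* Platt calibration on few, sometimes separable, training scores is
  steep; calibrated probabilities near 0/1 should be read as rankings, not
  frequencies.
* MANOVA after PCA projection tests the factor against the retained
  principal subspace, not the full response space.
* The generator's mask-layer calibration is anchored at the default
  correlation targets and cohort geometry.
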