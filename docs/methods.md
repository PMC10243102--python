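# Methods

This note describes the statistical methods implemented in `metabrisk`, the
modelling assumptions behind them, and the rationale for every default
parameter.

## 1. Profile preprocessing

Quantitative metabolite profiles are non-negative concentration tables
(samples × metabolites) with a group label per sample.

- **Contaminant exclusion.** Collection-tube contaminants (defaults:
  glycerol, propylene glycol) are dropped *before* normalisation. Order
  matters: excluding after total-area normalisation leaves row sums below
  one and distorts every remaining metabolite's share. `exclude_metabolites`
  therefore clears the `normalized` flag of its output.
- **Total-area normalisation.** Each row is divided by its sum, removing
  per-sample dilution effects. The operation is idempotent and invariant to
  positive per-sample scaling. Note the compositional consequence: a planted
  increase in one metabolite depresses the normalised share of all others,
  so univariate screens on normalised data detect closure effects alongside
  primary effects.
- **Scaling.** Column-wise centring with unit-variance (autoscaling, the
  default for all models) or Pareto (√sd) scaling, ddof = 1. Autoscaling is
  the standard choice for metabolomics because concentration ranges span
  orders of magnitude and analyte importance is not proportional to absolute
  concentration. Zero-variance columns are reported by name as errors at the
  public surface; internally, model fitting substitutes a unit scale for a
  zero sd so that constant columns (possible in small CV training splits)
  contribute nothing rather than dividing by zero.

## 2. Synthetic cohorts

The generator models the study design directly:

- **Groups and sizes.** Defaults: 30 healthy controls, 37 DM2, 15 PC I+II,
  24 PC III, 42 PC IV, 59 RODM — 207 samples, 63 metabolites (61 after the
  two contaminant dummies are excluded).
- **Signal structure.** Each metabolite has a baseline drawn log-uniformly
  over one decade. A 9-metabolite discriminant panel is multiplied by
  `effect_size` in all cancer groups; designated trend metabolites follow a
  geometric stage progression `effect_size^(k/3)` for k = 1..3 (up or down)
  across PC I+II → III → IV.
- **Noise.** Multiplicative log-normal noise with σ = √ln(1 + cv²) at
  `noise_cv = 0.25`, a typical inter-individual coefficient of variation for
  serum metabolite concentrations. Log-normal noise keeps concentrations
  positive and matches the right-skew of real metabolomics data.
- **External cohort.** A fraction `rodm_pc_fraction` (default 0.2) of RODM
  samples receive the cancer-like signal (count = ⌊f·n + 0.5⌋, 12 of 59 at
  defaults); the rest are DM2-like. Ground truth is returned as a labels
  table for recovery testing, never embedded in the profiles.
- `effect_size = 1.0` is an exact null: all groups are then exchangeable.

## 3. Multivariate models

All models are written as NIPALS algorithms over autoscaled data and follow
a model/results split: constructing the model validates the inputs, `fit()`
returns an immutable results object with `predict`, `decision_function`,
`summary` and JSON (de)serialisation.

- **PCA** by SVD of the centred matrix, with a deterministic sign convention
  (the largest-|loading| entry of each component is positive).
- **OPLS-DA** (two classes). The class labels are coded 0/1 — sorted order
  by default, or an explicit `classes=(control, case)` pair. Each orthogonal
  round computes the predictive weight w ∝ Xᵀy, its loading p, the
  orthogonal weight w₀ = p − (wᵀp)w, and deflates X by the orthogonal
  component t₀p₀ᵀ; a final one-component PLS on the deflated matrix gives
  the predictive component. With `k_ortho = 0` the model is exactly a
  one-component PLS (verified against an independent oracle to 1e-8). The
  decision function is the predicted response; the decision threshold is
  0.5, with ties assigned to the first (control) class. A fixed threshold on
  a regression response does not guarantee perfect training separation even
  on separable data — orthogonal filtering typically removes the borderline
  cases.
- **PLS-DA** (≥ 2 classes) is NIPALS PLS2 on one-hot responses with argmax
  prediction; it is used for exploratory multi-group models.
- **Component selection** uses cross-validated accuracy and a
  minimum-components-at-maximum-accuracy rule: the smallest model whose CV
  accuracy equals the maximum over the scanned range.

## 4. Validation

- **Monte-Carlo cross-validation.** Default 100 random stratified 90/10
  splits. Per-class training counts use largest-remainder allocation of
  ⌊f·n⌋ bounded to [1, n_c − 1], so both classes are always represented in
  training and test. Sensitivity/specificity are averaged with `nanmean`
  (undefined when a split's test set lacks a class).
- **Permutation testing.** The statistic is the mean MC-CV accuracy; labels
  are permuted `n_permutations` times (default 1000) and
  p = #{permuted accuracy strictly greater than observed} / n. The inner CV is
  reduced to 20 iterations for tractability — the statistic is an average,
  so fewer inner iterations add noise symmetrically under the null and the
  test stays conservative (verified by calibration in the test suite).
  P-values below 1/n are rendered as e.g. `<0.001`: zero exceedances bound,
  not measure, the P-value.

## 5. Univariate screening

- **Wilcoxon rank-sum** per metabolite: exact distribution when both groups
  have ≤ 20 samples and no ties, normal approximation with tie correction
  otherwise; `mode="exact"` refuses tied data rather than silently
  approximating.
- **Benjamini–Hochberg** step-up adjustment within each comparison.
- **Fold change** = mean(case)/mean(control) on normalised concentrations.
- **Consensus panel**: metabolites with adjusted P < 0.05 in *every* group
  comparison. All tables must share one metabolite universe; panel order
  follows the first table.
- **Stage-trend screen**: metabolites whose group means are strictly
  monotone across the three cancer stages, labelled "up" or "down".

## 6. Panel ROC

Repeated stratified train/test splits (default: two-thirds train, 20
repeats); a random forest (100 trees) or linear nearest-centroid scorer is
fit on the panel columns and AUC is computed on the held-out third. The
summary AUC is the mean across repeats with a 2.5–97.5 percentile interval;
a panel is called acceptable when AUC > 0.8, the conventional "good
discrimination" bar for clinical biomarkers.

## 7. Risk ensemble

For each cancer stage, `n_models = 20` OPLS-DA models (1 predictive + 1
orthogonal component) are trained on the full control-vs-stage data with
independent derived seeds and evaluated by MC-CV (20 iterations each).
Models with mean accuracy strictly above `min_accuracy = 80 %` qualify.
Each qualifying model classifies an independent random subsample
(`external_subsample_size = 25` of the external cohort, without
replacement), so ensemble members see different external samples. A
sample's **vote ratio** is 100 · votes/applications, reported as e.g.
`38.5% (5/13)`; samples never subsampled have an undefined ratio. A sample
is **at-risk** if any ensemble gives it a positive ratio — a deliberately
sensitive rule, appropriate when the follow-up is imaging rather than
surgery. Probable stage comes from two sources: (A) whether the
early-stage ensemble flagged the sample, and (B) a majority vote of an
early-vs-late ensemble whose votes count late calls, with ties assigned to
late (the safer error direction). The report quotes the agreement between
the two sources.

Three stage ensembles × 20 models = 60 models per full analysis; the
early-vs-late staging ensemble is reported separately.

## 8. Pipeline

`run_study` derives one seed per stage (cohort, discrimination, permutation,
ROC, risk) from a single root `SeedSequence`, so artifacts are byte-identical
across reruns of the same configuration and changing one stage's work cannot
shift another's random stream. Unknown configuration keys and unknown group
names fail before any computation.

## Default-parameter summary

| Parameter | Default | Rationale |
|---|---|---|
| `noise_cv` | 0.25 | typical inter-individual CV of serum metabolites |
| `effect_size` | 1.5 (2.0 in examples) | moderate planted effect; 1.0 = null |
| `rodm_pc_fraction` | 0.2 | plausible occult-cancer fraction; 12/59 at defaults |
| scaling | unit-variance | standard for concentration data |
| CV split | 90/10, 100 iterations | small-cohort bias/variance balance |
| permutations | 1000 (inner CV 20) | P resolution 0.001 at tractable cost |
| `n_models` | 20 per stage | vote ratios at ~5 % resolution |
| `min_accuracy` | 80 % | excludes chance-level models (~50 % null) |
| `external_subsample_size` | 25 of 59 | independent model/sample pairings |
| AUC acceptability | > 0.8 | conventional clinical-biomarker bar |
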