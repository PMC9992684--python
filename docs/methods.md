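# Methods

`regionage` implements a region-wise, multimodal brain-age analysis:
per-region machine-learning models predict chronological age from voxel
features in healthy subjects, the predictions are bias-corrected, and the
resulting brain-age *gaps* are compared between a patient and a control
group region by region. Because the cohorts such analyses are built on are
typically not shareable, the package ships a synthetic cohort generator
that reproduces the data *structure* of such a study with known ground
truth, so every stage is testable end to end.

## Data model

Each subject carries three kinds of parcellated voxel maps:

| modality | regions (default) | values |
|---|---|---|
| GM | 90 (AAL-style gray-matter parcels) | tissue intensity, a.u. |
| FC | 90 | voxel-wise average functional connectivity, Fisher-z |
| FA | 48 (JHU-style white-matter tracts) | fractional anisotropy in [0, 1] |

A map is a vector of voxel values per region; voxel order is always the
sorted linear (row-major) index of the label volume, 0-based. NIfTI
affines are ignored beyond shape checks. The FC value of a voxel is its
mean Fisher-z (arctanh) Pearson correlation with the other voxels of the
averaging scope, self-pairs excluded; correlations are clamped to
±(1 − 1e−7) before arctanh so degenerate perfect correlations stay
finite, and a constant-in-time voxel is defined to correlate at 0 (logged).

**Averaging scope.** Whether "average voxel-wise FC" should be taken over
the whole analyzed volume or within the parcel is genuinely open; the
builder itself is scope-agnostic (the caller picks the voxel set) and the
pipeline defaults to within-region averaging (`fc_scope="region"`), which
matches the per-region granularity of the models and scales as
O(V²region) rather than O(V²volume) per subject. `fc_scope="volume"`
switches to whole-volume averaging.

## Feature selection

For each region, the key-voxel selector runs a nested resampling scheme on
the healthy training cohort:

1. draw ⌊n/2⌋ subjects without replacement and compute each voxel's
   Pearson correlation with age; keep the top ⌈V/2⌉ voxels by |r|
   (ties broken deterministically by lower voxel index);
2. repeat the draw 100 times (`n_inner`) and intersect the 100 top sets —
   that intersection is one *round*'s key-voxel set;
3. repeat the whole round 100 times (`n_outer`) on independent RNG
   sub-streams; a voxel's selection count is the number of rounds whose
   set contains it, and the region's key features are the voxels with
   count **strictly greater than 10**.

Ranking uses |r| rather than signed r because gray-matter intensity and FA
decline with age — signed ranking would discard exactly the informative
voxels in those modalities (`signed_ranking=True` restores signed
ranking). Under this scheme a pure-noise voxel survives a single round
with probability ≈ 0.5^100, so noise counts are essentially zero, while a
voxel with a genuine age signal saturates at `n_outer`; the procedure is a
stability selector. If no voxel clears the threshold the region falls back
to its highest-count voxels (at least 10) so the downstream model always
has features; the fallback is flagged on the mask and logged, and the
strict-threshold set is preserved separately.

Each trial's half-sample is defined as the ⌊n/2⌋ smallest entries of one
row of a uniform (n_inner × n) matrix drawn from the round's RNG stream;
this makes a round a single vectorized computation and exactly replayable.

## Per-region age models

One Gaussian-process regressor per region, on the region's key voxels:

- **Kernel** — constant × squared-exponential + white noise, hyperparameters
  by marginal-likelihood optimization. The deployed regressor (refit on the
  full training cohort) uses 3 optimizer restarts; the five fold models,
  which exist only to produce out-of-fold predictions, run a single
  optimization from the default initialization. At 228 regions this keeps a
  full run to a few minutes without changing what the deployed model is.
- **Standardization** — features are z-scored per voxel with training-set
  statistics, stored in the model and reapplied at prediction time; the
  target is internally normalized by the regressor.
- **Cross-validation** — five folds by random permutation, no
  stratification. Out-of-fold predictions for every training subject feed
  the bias fit and the performance scores.
- **Bias correction** — ordinary least squares of predicted on
  chronological age over the pooled out-of-fold predictions gives
  (α, β); every prediction is corrected as

      corrected = raw + [chronological − (α·chronological + β)]
      gap       = corrected − chronological

  The (α, β) of a model are frozen at training time and reused for every
  test cohort; bias is never refit on test data. Fitting on the training
  CV predictions (rather than on a held-out healthy set) is a deliberate
  choice: it uses no test information and makes the training-sample mean
  gap exactly zero (an OLS residual identity).
- **Performance** — MAE and Pearson r between *corrected* out-of-fold
  predictions and age (cv_mae, cv_r).

**A caveat on corrected-age metrics.** The additive correction rewrites
the corrected age as `chronological·(1−α) + raw − β + α·chronological`,
i.e. chronological age plus model noise. When a model carries little
signal, α ≈ 0 and the corrected age tracks chronological age almost
perfectly — cv_r approaches 1 and cv_mae collapses *regardless of model
quality*. Corrected-age r therefore overstates weak models. The package
additionally records `cv_raw_r`, the correlation of the uncorrected
out-of-fold predictions with age, which is ≈ 0 for an uninformative model
(slightly negative under cross-validation, a fold-mean reversion
artifact); treat `cv_raw_r` as the honest signal diagnostic and the
corrected metrics as the conventional report.

## Group inference

- **ANCOVA** per region: OLS of gap on group plus covariates
  {chronological age, sex (0/1), MMSE, education}. The group F statistic is
  the extra-sum-of-squares test of dropping the group term
  (1, n − p − 2 df) — equivalent to Type II/III here since group is the
  only factor and there are no interactions — and the effect size is
  partial η² = SS_group / (SS_group + SS_error). Singular designs raise an
  error naming the collinear columns.
- **Multiple comparisons**: Benjamini–Hochberg step-up adjustment, applied
  within each modality family by default (90 + 90 + 48 tests separately;
  `fdr_family="joint"` corrects across all 228). Significance level 0.05
  after adjustment.
- **Clinical regressions** (patients only): one joint model per region of
  gap on {PANSS positive/negative/general, illness duration, onset age,
  nicotine use, BMI} controlling for age and sex. Continuous predictors
  and the gap are z-scored (standardized betas); binary predictors stay
  0/1. Rows with missing predictors are dropped listwise and the count
  logged. The dose model (gap ~ CPZ-equivalent dose + age + sex) first
  excludes subjects without recorded dose and requires ≥ 10 dosed
  subjects. FDR is applied per predictor across regions within a modality.

## Synthetic cohort

The generator emulates the study design, not brain anatomy:

- **Cohorts** — 230 healthy training subjects, 100 held-out controls, 194
  patients; ages uniform on [20, 84] for every cohort (the uniform choice
  maximizes identifiability of the age signal for testing). Covariates
  mimic the study's clinicodemographic table (controls: MMSE 29 ± 1,
  education ~16 y; patients: MMSE 26.8 ± 3.4, education ~12.5 y, onset
  27.7 ± 9.4 y, PANSS subscale means 10.7/10.0/21.3, CPZ-equivalent dose
  402 ± 324 mg/day recorded for ~83%) and are drawn independently of age.
  Illness duration is age − onset plus a 1.5-year reporting jitter — the
  jitter keeps {duration, onset, age} from being exactly collinear, which
  the joint clinical regression requires.
- **Maps** — 200 voxels per region (small but structurally faithful; real
  voxel counts are irrelevant to the algorithms). Within each region a
  random 20% of voxels carry a linear age signal whose slope is calibrated
  so the population voxel-age correlation is 0.6
  (r = slope·σ_age/√(slope²σ_age² + σ_noise²)); the rest are pure noise.
  Modality scaling places values on native scales (GM intensity around 10,
  FC Fisher-z around 0.5, FA in [0, 1] with clipping), with GM/FA aging
  slopes negative and FC positive.
- **Pathology** — listed regions of patient maps get their *informative*
  voxels shifted by exactly the map change of a subject `gap` years older
  (default: +5 years in ten GM regions). Acting on informative voxels only
  makes the injected gap map 1:1 onto the predicted-age shift in
  expectation, so parameter recovery is exact up to model shrinkage.
  Optionally the shift scales with illness duration relative to the cohort
  mean.
- **BOLD** — for FC-from-time-series runs, each subject's voxels share an
  age-weighted common band-limited (0.01–0.1 Hz) signal plus idiosyncratic
  band-limited noise, so average connectivity rises with age; the true
  mixing weights are returned for oracles.
- **Truth** — every dataset carries its informative-voxel indices and
  injected gaps (JSON sidecar on disk), which the tests use as oracles.

What the generator does *not* emulate: spatial structure and smoothness,
scanner/site effects, motion, covariate-age dependence, non-linear aging
trajectories, or realistic voxel counts. Passing tests therefore
demonstrate that the algorithms recover what they are designed to recover
under the stated noise model — not that the pipeline's numbers would
reproduce on real cohorts.

## Determinism

One master seed governs a run. Every stage, region and round derives a
named RNG sub-stream keyed by (seed, stage, modality, region), so stages
can be re-run in isolation and two same-seed runs are byte-identical
(tabular outputs are written with 6-decimal floats to keep reports
diffable and regenerable). Models persist as JSON metadata plus array
blobs; loading refits the regressor with the optimizer disabled at the
stored hyperparameters, which reproduces predictions exactly.

## Study conditions used by the test suite

The acceptance-level checks run at desk scale on one CPU: the structural
and model-sanity checks use the full default configuration (228 models,
200 voxels/region, n = 230 training subjects, ~3–4 min); selection
recovery uses 30 outer rounds; gap recovery uses a GM-only atlas at 60
voxels/region with 100 subjects per test group; null calibration uses 200
replicates of 40 regions × 60 subjects with gaps drawn under the null at
the inference layer. These sizes are the package's chosen study
conditions and are fixed in the tests.

## Known limitations

- Corrected-age r/MAE are inflated for weak models (see the caveat above);
  compare models on `cv_raw_r` when in doubt.
- GP shrinkage attenuates injected gaps slightly (a +5-year injection is
  recovered as ≈ 4.5 years at default scale); bias correction removes the
  age-slope bias but not this shrinkage of out-of-distribution shifts.
- The ">10 of 100 rounds" threshold is treated as out of `n_outer` rounds;
  with very small `n_outer` the strict rule can select nothing, which
  triggers the highest-count fallback.
- Group inference assumes homoscedastic Gaussian residuals (OLS); no
  permutation alternative is provided.
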