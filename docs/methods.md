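# Methods

`wmhtracts` implements a two-step strategy for locating the white-matter
hyperintensities (WMH) that matter for cognition in small-vessel-disease
cohorts, together with a synthetic cohort generator that makes every stage
testable without patient data.

## Analysis model

**Step 1A — tract-ROI screening.** A probabilistic white-matter tract
atlas is thresholded at 10% probability (inclusive boundary) and left/right
homologues are merged, yielding 11 bilateral tract ROIs. Per subject, the
normalized WMH volume (ml, template space) is computed in each ROI; a voxel
inside several overlapping tracts contributes to each of them. Per
cognitive domain z-score *y* the nested OLS sequence is

- model 1: `y ~ age + sex + education`
- model 2: model 1 + `lacunes + total WMH volume`
- models 3a–k: model 2 + one tract's regional WMH volume.

Each step is summarised by ΔR² and its partial F-test,
`F = (ΔR²/df_Δ) / ((1−R²_big)/(n−k_big−1))`. A tract is *strategic* when
its ΔR² over model 2 survives Bonferroni correction across the 13
comparisons in the table (α = 0.05/13 ≈ 0.0038) — i.e. its lesion burden
predicts cognition beyond global lesion burden. Standardized coefficients
are reported as `β = b·SD(x)/SD(y)` with 95% CIs using a normal 1.96
multiplier (the t-quantile difference is negligible at n ≈ 167).

**Step 1B — voxel-based lesion-symptom mapping (VLSM).** Domain scores are
first residualised on age, sex and education (optionally also total WMH
volume and lacune presence). At every voxel lesioned in ≥ 10 subjects (and
lesion-absent in ≥ 2), subjects are split by lesion presence and compared
with the Brunner–Munzel test of stochastic superiority
`p̂ = P(X<Y) + ½P(X=Y)`, using mid-ranks for ties. Voxels with zero pooled
rank variance (e.g. complete separation) have no finite statistic; they are
flagged, excluded from the multiple-testing family and reported in a
diagnostics count. Benjamini–Hochberg step-up control at q = 0.05 is
applied over the tested, non-degenerate voxels, separately per outcome.
Results are summarised per tract (region size, tested voxels, significant
voxels per outcome).

**Step 2 — marker comparison.** Per outcome: model 1 plus one marker each
(total WMH, forceps-minor WMH, anterior-thalamic-radiation WMH, brain
parenchymal fraction BPF = brain volume / intracranial volume); then each
WMH measure on top of the BPF model. Lacune and microbleed presence enter
single-marker models (complete-case where microbleed status is missing).
The atrophy–WMH interplay is probed by regressing BPF on each WMH measure
with age, sex, education, lacunes and microbleeds as covariates, one
marker per model. A sensitivity analysis repeats the comparison after
excluding subjects with an AD diagnosis.

## Null calibration of the voxelwise test

The classical Brunner–Munzel p-value uses a t distribution with
Satterthwaite-type degrees of freedom. That approximation is accurate near
α ≈ 0.05 but collapses in the far tail when the lesion group is small: at
n = 167 with 10 lesioned subjects, configurations whose exact permutation
probability is ~1e-4 receive t-approximation p-values down to ~1e-11
(the rank-based variance estimate in the denominator can be arbitrarily
small). A mass-univariate FDR procedure over ~2·10⁴ voxels operates
exactly in that tail, and in null simulations the t calibration produced
spurious discoveries in a large fraction of replicates.

`vlsm_map` therefore defaults to **permutation calibration**
(`p_method="permutation"`): with tie-free scores the BM statistic depends
on the data only through which pooled ranks fall in the lesion group, so
its permutation null distribution is universal given (n, n_lesioned). One
Monte-Carlo table (20 000 draws, fixed internal RNG — a numerical
calibration table, not experimental randomness) is computed lazily per
lesion count and cached, making the calibrated map barely slower than the
t version. Monte-Carlo p-values are floored at 1/(n_perm+1) ≈ 5·10⁻⁵;
under BH this is conservative at the null (the step-up threshold for few
discoveries lies below the floor) and harmless under signal (the threshold
grows with the number of discoveries). `p_method="t"` retains the
classical approximation, and the scalar `brunner_munzel` function always
reports the t-based (statistic, df, p, p̂) tuple. Scores with ties fall
back to the t calibration (a per-pattern cached voxel loop); residualised
continuous scores are tie-free in practice.

Sidedness is two-sided by default with a one-sided option
(lesion-present < lesion-absent), since rank tests of this kind are run
both ways in the lesion-mapping literature.

## Cognitive scoring

Subtest scores are standardised against the analysis cohort itself
(z = (x − cohort mean)/cohort SD, sample SD with n−1), not external norms;
timed tests (maze, colour trails 1&2) are multiplied by −1 so lower always
means worse. Domain compounds are unweighted means of the domain's subtest
z-scores (executive: 2 fluency + 2 colour-trails tests; speed: digit
cancellation, symbol-digit, maze; memory: 6 recall/recognition subtests);
a domain score is missing unless the subject completed the full domain
battery. Timed tests that hit the administration ceiling (240 s) enter at
face value — no censoring model. Cohort inclusion follows the operational
small-vessel-disease rule (Fazekas ≥ 2 or lacunes/infarcts/microbleeds; or
Fazekas = 1 with ≥ 2 of 6 vascular risk factors) and the exclusion cascade
(cortical or large subcortical lesion, then missing neuropsychology, then
failed registration).

## Synthetic cohort generator

The generator reproduces the statistical structure the analysis assumes,
with recorded ground truth (`SynthTruth`), on a 48×56×48 grid at 2 mm —
small enough that a full VLSM runs in under a second on one CPU.

- **Atlas**: 11 canonical tracts as tubular Gaussian probability fields
  around jittered centre-line paths; bilateral tracts are mirrored across
  the midline, forceps minor/major are midline singletons. All 11 merged
  ROIs are non-empty at the 10% threshold.
- **Lesions**: per subject a target volume is drawn log-normally (median
  14.7 ml, log-SD 0.95, spanning roughly 0.5–140 ml) and placed as the
  top-scoring voxels of `w · exp(3.0·coarse + 1.5·fine)`, where `w` is a
  fixed periventricular + frontal prevalence field, `fine` is blob-scale
  smoothed noise (σ = 1.5 vox) and `coarse` (σ ≈ 6 vox) gives each subject
  an individual regional emphasis. The coarse component is essential: with
  a single-scale field the 11 regional volumes are nearly collinear across
  subjects (r ≈ 0.95) and no tract-specific effect is identifiable; the
  two-scale field brings strategic-tract inter-correlations to ≈ 0.6,
  comparable to what tract-level screening implicitly assumes.
- **Covariates**: age ~ N(72.8, 9.1), 46.1% male, education ~ N(6.1, 5.0)
  truncated at 0, lacunes Bernoulli(0.287), microbleeds Bernoulli(0.569)
  with 4 subjects set missing, BPF ~ N(0.64, 0.06), 25.1% AD diagnoses.
- **Cognition**: domain score = Σ covariate effects (z-scaled; defaults
  −0.45 age, +0.35 education, +0.15 male) + Σ tract effects × standardized
  regional volume (defaults: −0.30 anterior thalamic radiation on
  executive, −0.30/−0.25 forceps minor on speed/memory) + N(0, 0.75)
  noise. These defaults put model-1 R² near 0.37 and give the tract screen
  ≈ 85% probability of ranking the true tract top by ΔR² at n = 167.
- **Focal cluster** (optional, for VLSM validation): a radius-3 voxel
  sphere (123 voxels) at the lowest-background-prevalence core of the
  anterior thalamic radiation; each subject carries the whole cluster with
  probability 0.22, and carriers' scores shift by `cluster_effect_sd`
  (typically 1.5) noise-SDs. Low background prevalence keeps the
  per-voxel lesion groups dominated by carriers; the cluster size keeps
  the BH step-up threshold above the attainable permutation p-values.

A single master seed fans out to independent per-stage streams (atlas,
lesions, covariates, noise, cluster), so stages can be regenerated
separately; a fixed (seed, config) reproduces the cohort bit-exactly.

What the generator does **not** emulate: registration error, FLAIR
intensity structure, rater variability, spatially varying noise, lesion
growth along vasculature, or correlation between lesion load and
demographics (lesions are drawn independently of age). Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the assumed model, not robustness to real-world imaging
artefacts.

## Calibration studies and problem sizes

`wmhtracts.validation` quantifies operating characteristics; replicate
counts are caller-chosen. The shipped studies use: 200 replicates with
fresh lesions/covariates/noise for tract recovery (n = 167 each); 2 200
independent score redraws on a fixed design for the per-comparison type-I
rate at 0.05/13 (the partial F-test is exact conditional on the design,
so fixing the lesion draw is legitimate); 200 score redraws on a fixed
lesion cohort for the VLSM null FDR and for the implanted-cluster
sensitivity/FDP. In the cluster study a significant voxel counts as a
false discovery only when its lesion pattern is essentially uncorrelated
with carrier status (|r| < 0.1) — voxels whose lesion status tracks the
carriers are genuinely score-associated under the generative model.

## Numerical choices and edge cases

- Binarization of "binary" lesion inputs at > 0.5 (robust to
  interpolation dust); atlas probability scale auto-detected (max ≤ 1 →
  fraction, else percent); inclusive ≥ at the ROI threshold.
- Degrees-of-freedom floor of 2 in the BM t-approximation.
- ΔR² clipped at 0 for numerically negative values of order machine
  epsilon; saturated big models (zero residual variance) report p = 0.
- Complete-case analysis per model; the n of microbleed models may differ
  from the others. Rank-deficient designs are rejected with the collinear
  columns named.
- WMH volumes enter regressions untransformed (ml, template space); no
  log-transform by default.
- Missing-value codes in subject tables ("NA", -999, 999, empty) are
  normalised to missing; labelled categoricals are recoded to 0/1 via the
  variable map.

## Known limitations

- SPSS `.sav` reading requires the optional `pyreadstat` dependency; CSV
  is the first-class table format.
- The permutation calibration assumes exchangeable residual scores; with
  strong heteroscedasticity across lesion strata it inherits the usual
  caveats of restricted permutation tests.
- Monte-Carlo p-values are floored at ~5·10⁻⁵; isolated true signals
  (fewer than ~20 associated voxels at the default grid) can fall below
  BH's step-up threshold and be missed, a deliberate trade of power for
  honest null calibration.
- Lacune/microbleed location mapping is out of scope (their prevalence
  and size do not support voxelwise testing), as are registration,
  segmentation and atlas construction.
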