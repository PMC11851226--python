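# Methods

`lesionconn` analyses resting-state fMRI functional connectivity (FC) in
cohorts where part of the brain is occupied by a focal lesion — the motivating
case is diffusely infiltrating glioma studied before and after resection.
This note documents the model, the estimators, the synthetic-data generator
used for validation, and the numerical and design choices.

## Connectivity model

All inputs of one subject (4D BOLD, integer atlas labels, binary tumor and
resection masks) must share one voxel grid; the package performs no
registration or resampling. Spatial preprocessing (realignment,
normalisation, smoothing, motion denoising) is assumed done upstream; an
optional zero-phase Butterworth high-pass (> 0.01 Hz by default) is the only
temporal filter offered.

For a parcellation with R regions (canonically the 246-region Brainnetome
atlas) and a lesion mask L:

1. **ROI exclusion.** Every atlas region intersecting L in at least
   `min_overlap_voxels` voxels (default 1 — the strictest reading of
   "covers lesion tissue") is removed from the node set.
2. **Voxel masking.** All voxels inside L are blanked (NaN sentinel) at every
   frame, so region means are taken over extralesional tissue only.
3. **Time-series extraction.** Each retained region contributes the
   arithmetic mean of its usable voxels per frame. For patients, one extra
   *tumor node* is appended: the mean series over the tumor-mask voxels of
   the **unmasked preoperative** BOLD (masking first would delete the signal
   the statistic is about). Regions left with no usable voxels or with flat
   series (variance < 1e-12) are dropped with a warning.
4. **FC matrix.** Pearson correlation of all node pairs over frames, clipped
   to |r| ≤ 1 − 1e-7, then Fisher z-transformed (z = atanh r). For a patient
   the matrix is (R − N_lesioned + 1)² including the tumor node; for a
   control it is R².

Three signed scalar summaries are taken (negative z values enter the means
as-is; no absolute value or positive thresholding is applied):

* **Tu-EL** — mean z between the tumor node and every retained region
  (preoperative only).
* **EL** — mean z over all unordered pairs of retained regions, i.e.
  N(N−1)/2 entries of the upper triangle, tumor row excluded. The phrase
  "mean z over all regions" could alternatively be read as a mean of
  per-region row means; the two differ only when node degrees differ, and
  the pair mean was chosen as the matrix's single natural scalar.
* **conEL** — the same pair mean restricted to pairs with *both* nodes in
  the hemisphere contralateral to the lesion (within-hemisphere only,
  mirroring the control construction). Controls, having no lesion side, get
  the mean of the within-left and within-right pair means as their baseline.

### Longitudinal mask contract

The **combined** mask (voxelwise union of the preoperative tumor and the
postoperative resection cavity) drives both voxel masking and ROI exclusion
at *both* timepoints. Pre- and postoperative FC of one subject are therefore
computed over an identical extralesional node set — intraindividually
constant whole-brain volumes — at the cost of discarding some healthy
preoperative tissue that is later resected. Exclusion by the
timepoint-specific mask instead would let the node set drift between
timepoints, so the combined mask is the default; the overlap threshold
remains configurable.

## Statistical battery

* **Outlier handling.** Values deviating more than 1.5 standard deviations
  from their group mean are replaced by the bound (winsorization). Bounds
  use the *sample* SD (n−1) and are computed **once** on the original data;
  applied per group, per variable, per timepoint. Winsorization is not
  idempotent in general (bounds recomputed on winsorized data shrink); data
  already within its own bounds is returned unchanged.
* **Partial correlation.** Pearson correlation of the residuals of x and y
  after least-squares regression on [1, covariates];
  t = r·√(df/(1−r²)) with df = n − 2 − k, two-sided p. Patients are
  adjusted for age and tumor volume, controls for age only.
* **Bonferroni.** Adjusted α = α/m and adjusted p = min(1, p·m). The family
  size m is configuration, not hard-coded (conventions differ on which
  correlations count as one family); the default m is the number of tests
  actually run in each family.
* **Repeated-measures ANCOVA.** Two groups × two timepoints with
  between-subject covariates. With exactly two timepoints the mixed design
  decomposes exactly: the *group* effect is an ANCOVA on the per-subject
  mean across timepoints; *time* and *group×time* are tests on the
  follow-up-minus-initial difference. Covariates are centred and the group
  factor effect-coded (±½), so each F is a Type III-style full-vs-reduced
  model comparison; error df = n − 2 − k per part. With no covariate and a
  balanced design this reproduces the classical sums-of-squares mixed ANOVA
  exactly (tested against a brute-force oracle and pingouin). Incomplete
  cases are dropped listwise and logged, matching complete-case analysis.
* **Multivariate group test.** Wilks' Λ for the two-group effect on the
  five cognitive measures jointly (subject means over timepoints), adjusted
  for age: Λ = det(E)/det(E+H) with full-vs-reduced residual SSCP matrices,
  converted to the exact F(p, n − k − p − 1) for one hypothesis df — e.g.
  F(5, 17) for 24 complete cases, five measures and one covariate.
  Cross-checked against statsmodels MANOVA.

Degenerate inputs are handled explicitly: zero residual variance raises;
perfect separation returns F = ∞ with an underflow-safe p; a zero-SD group
is returned unwinsorized with a warning.

## Synthetic cohorts

The generator produces cohorts with known ground truth; its defaults *are*
the study conditions being emulated: T = 300 frames at TR = 2.2 s, 246
regions, 18 patients + 18 controls, a contiguous unilateral lesion
overlapping k = 12 regions.

* **Signal model.** One common latent factor g per subject; extralesional
  parcel i = √b·g + √(1−b)·ε_i, giving expected pairwise correlation
  b (`base_within_corr`, default 0.3 — a typical grand-mean cortical FC
  level). The tumor series = ρ·g + √(1−ρ²)·η, so the expected
  tumor-parcel correlation is ρ√b in closed form, which the recovery tests
  use. Per-patient ρ ~ U(0.2, 0.8) so the cohort-level coupling–behavior
  correlation is estimable.
* **Noise.** Gaussian white noise by default; an AR(1) option exists because
  temporal autocorrelation inflates correlation standard errors — recovery
  tolerances are stated under the white-noise default (Fisher-z null SE
  1/√(T−3)).
* **Geometry.** The grid (default 12³ voxels at 3.1 mm) is partitioned into
  contiguous raster-order parcels, low-x half = left hemisphere. The tumor
  mask covers k consecutive lesion-side parcels; per-patient tumor extent is
  varied within the last parcel (50–100 % of its voxels) so tumor volume is
  a non-degenerate covariate while the overlapped ROI set stays fixed. The
  resection cavity is the tumor dilated by one voxel (configurable),
  restricted to the lesion hemisphere.
* **Behavior.** Five scores per timepoint with the instruments' polarities
  (higher alertness quotient / consolidation / flexibility = worse). Only
  the alertness score carries the planted coupling effect:
  alertness = intercept + slope·ρ + γ·age + noise, slope default 4 alertness
  units per unit coupling (large enough that an n = 18 cohort recovers the
  sign essentially always, as the acceptance checks quantify), attenuated by
  0.6 at follow-up to emulate a weaker postoperative association. Patients
  additionally carry ≈1-SD deficits on all measures.
* **What it does not model.** Hemodynamics, motion, physiological noise,
  spatial autocorrelation beyond the parcel structure, mass effects or
  infiltration gradients. Passing the recovery tests shows the estimators
  and their calibration are correct under the stated statistical structure,
  not that real acquisitions meet that structure.

Determinism: one integer seed drives a `numpy` SeedSequence tree; the same
config and seed reproduce every array and output CSV bit-for-bit.

## Validation scale

Desk-scale checks use 16–60 regions on 6³–8³ grids with 40–120 frames; the
calibration and recovery studies run at the full 246-region, 300-frame,
18-patient conditions with 200 replicate cohorts (null p-value uniformity by
Kolmogorov–Smirnov, RM-ANCOVA type-I error over 5000 replicates, sign
recovery and coupling monotonicity across ρ ∈ {0.3, 0.5, 0.8}). These sizes
were chosen so the full suite runs in about a minute while keeping
Monte-Carlo standard errors well below the tested tolerances.

## Known limitations

* Exactly two groups and two timepoints in the repeated-measures design.
* No partial-volume weighting or probabilistic parcellations; a region is
  in or out.
* The EL pair-mean convention (vs row-mean) is a documented choice, not a
  derived fact.
* No graph-theoretic, network-specific or sliding-window FC measures.
* The command-line interface covers simulation, extraction, FC and the full
  pipeline; statistics-only entry points are available through the library.
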