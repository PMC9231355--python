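# Methods

This document describes the model implemented by `dosestab`, its parameters
and defaults, the numerical choices, and the limits of the synthetic cohort.

## Problem

Radiotherapy delivers a prescribed dose over n fractions. Between fractions
the patient is set up anew, so the isocenter of each fraction is displaced by
a random geometric error. The dose actually accumulated over the course is
therefore a blurred version of the planned distribution. Texture ("dosiomic")
features computed on the planned dose may not survive this blurring; a
feature that changes strongly under realistic setup error is a poor candidate
for outcome modelling. `dosestab` quantifies, per feature / region of
interest / fractionation scheme, how stable each of 93 dosiomic features is
under random interfractional error.

## Error model and dose accumulation

Per-fraction isocenter shifts are independent 3-vectors with independent
axis components drawn from a Gaussian with mean 0 and standard deviation
(1.2, 1.2, 1.2) mm. Components are capped at ±3.0 mm per axis. Two
truncation modes exist:

- `clip` (default): components beyond the cap are set to the cap. This
  mirrors a clinical protocol in which detected shifts larger than the
  tolerance are corrected down to it; it puts point mass exactly at ±3 mm.
- `reject`: out-of-bound vectors are resampled, giving a smooth truncated
  Gaussian with no atoms.

Each fraction delivers 1/n of the planned dose, rigidly translated by that
fraction's shift:

    D_err = (1/n) * sum_i translate(D_ori, s_i)

Translation uses trilinear interpolation (`scipy.ndimage.shift`, order 1)
with zero fill at the boundary; the implementation warns if a translation
loses more than 1e-6 of the integral dose over the grid edge (it cannot,
for the bundled phantom — see below). Setting all SDs to 0 reproduces
D_err = D_ori exactly up to float rounding, a documented degenerate limit
used by the test suite.

The replicate protocol evaluates fraction counts n ∈ {2, 10, 20, 30} with 20
independent replicates each, i.e. 81 dose volumes per patient including the
error-free original. Replicate schedules are seeded as
`SeedSequence([base_seed, 7001, n, replicate])` and, by default, shared
across patients so each replicate applies the same error realization to
every patient's plan.

An identity used for validation: the per-voxel mean of many shifted copies
converges to the planned dose convolved with the shift-distribution kernel.
The tests splat a 100,000-sample empirical kernel onto the voxel grid with
trilinear weights and verify the replicate root-mean-square error against
`scipy.ndimage.convolve` decreases with the fraction count.

## Feature extraction

The 93-feature signature comprises 18 first-order, 24 GLCM, 16 GLRLM,
16 GLSZM, 5 NGTDM and 14 GLDM features, computed from scratch (no external
radiomics dependency). Conventions:

- **Discretization**: fixed range [0, 70] Gy in 70 levels (1 Gy bins);
  level = clip(floor((d − lo)/w) + 1, 1, 70). Doses at or above 70 Gy land
  in the top level.
- **First order** works on the raw dose values in Gy, except Entropy and
  Uniformity, which use the discretized histogram. Skewness and kurtosis are
  population (biased) moments; kurtosis is not excess-corrected (a Gaussian
  scores 3). TotalEnergy multiplies Energy by the voxel volume in mm³.
- **GLCM / GLRLM** are computed per direction over the 13 unique
  26-neighborhood directions at distance 1 (symmetric co-occurrence counts)
  and averaged over the directions that contain at least one pair/run.
- **GLSZM** zones are 26-connected components of equal gray level, found via
  sparse connected-components labelling.
- **NGTDM** statistics are accumulated over voxels with at least one in-mask
  26-neighbor.
- **GLDM** dependence of a voxel is 1 + the number of in-mask 26-neighbors
  whose level differs by at most alpha (default 0).
- Logarithms are base 2 with zero-probability terms skipped. Formulas that
  normalize by the number of gray levels (Idmn, Idn, NGTDM Contrast) use
  the count of levels actually present in the ROI.
- Degenerate conventions: constant-ROI Correlation and MCC are 1, Imc1 is
  0, NGTDM Coarseness with a zero denominator is 1e6; a single-voxel ROI
  flags the GLCM and NGTDM classes invalid (NaN) rather than raising.

Every feature was validated against an independent brute-force oracle
(explicit per-voxel loops, `tests/oracle_features.py`) at 1e-9 relative
tolerance on dozens of random images.

## Stability statistics

For each (feature, ROI, fraction group):

- **CV** = |sample SD / mean| × 100 over the 20 replicate values (SD with
  the n−1 denominator), computed per patient and then averaged over the
  cohort; undefined when a mean is exactly 0 (tallied, not silently
  dropped). Categories: <5 very small, 5–10 small, 10–20 intermediate,
  ≥20 % large.
- **ICC(A,1)**, the single-measurement absolute-agreement two-way
  random-effects intraclass correlation, over the patients × aligned
  replicates table:

      ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE)/n)

  with significance from F = MSR/MSE on (n−1) and (n−1)(k−1) degrees of
  freedom at the 0.01 level.
- **PD** = mean over replicates of (f_err − f_ori)/f_ori × 100, signed,
  averaged over patients; patients whose error-free value is exactly zero
  are excluded and counted.
- **Fraction consistency**: the same ICC computed across the four
  fraction-group means per patient, flagging features whose ranking is not
  preserved across fractionation schemes (threshold 0.95).

## Synthetic cohort

The phantom generator provides a self-contained stand-in for clinical dose
distributions. Per patient (64³ voxels at 2.5 mm, defaults):

- an ellipsoidal GTV (base radius 14 mm, jittered axis ratios) inside a PTV
  dilated by a 6 mm margin;
- dose = prescription (60 Gy) × a two-component radial logistic falloff: a
  sharp penumbra (6 mm width) at the PTV surface plus a wide low-dose bath
  (35 % amplitude, 28 mm width, offset 20 mm) emulating scatter and beam
  entrance dose, so the heart sits on the 10–30 Gy shoulder;
- correlated Gaussian noise (2 Gy amplitude, 7.5 mm correlation length)
  emulating plan heterogeneity, clipped to [0, 70] Gy;
- a smoothstep window that forces the dose to exactly zero within 10 mm of
  every grid face, so every ≤3 mm trilinear translation conserves the
  integral dose to float precision;
- a heart-like ellipsoid abutting the PTV and two large lateral lung fields
  (minus GTV and heart) as organs at risk.

Cohorts jitter tumor size, axis ratios, penumbra width, heterogeneity and
heart placement per patient from a base seed, so between-patient variance is
non-zero and ICC is meaningful.

The phantom does **not** emulate: beam arrangements or deliverability,
tissue heterogeneity corrections, DVH-realistic OAR sparing, breathing or
intrafractional motion, or anatomical deformation (shifts are rigid). Its
purpose is to give the pipeline dose-like inputs with controlled statistics,
not to replace clinical plans; cohort-level numeric results describe this
synthetic cohort only.

## Numerical choices

- All dose arrays are float64 in (x, y, z) axis order with spacing in mm.
- Texture matrices are built with vectorized `bincount`/slicing kernels and
  cached per-(shape, direction) traversal orders; a full 4-ROI, 64³
  extraction takes ~0.2 s.
- Determinism: every stochastic step derives from `numpy.random.SeedSequence`
  keys; a full study re-run with the same seed reproduces the output CSVs
  byte for byte, and an interrupted extraction resumes from the per-patient
  CSVs it already wrote.
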