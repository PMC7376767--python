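# Methods

This note documents the models, conventions, and numerical choices behind
`batquant`, and what validation on synthetic data does and does not
establish.

## Volumes and grids

All maps and masks live on an explicit voxel grid: spacing (mm), world
origin, and an orthonormal direction matrix, with 0-based indices and RAS
world coordinates. Masks are bound to the grid of the volume they index, and
every operation that combines two objects verifies grid identity (within
1e-5 on the affine) instead of resampling silently — intersections are meant
voxelwise, and an implicit resample would hide registration errors.
`resample_to_grid` is available for deliberate regridding (trilinear or
nearest, in world coordinates); nearest mode preserves the value set, which
matters for label maps. On-disk format is NIfTI-1 (float32 for scalar
volumes, complex64 for echo data, uint8 {0,1} for masks); DICOM ingestion is
out of scope.

## Dixon water–fat separation

**Two-point (dual-echo) path.** In-phase and out-of-phase magnitudes give
`W = (IP+OP)/2`, `F = (IP−OP)/2` up to the well-known magnitude ambiguity:
IP and OP are unchanged when W and F swap. The ambiguity is resolved by an
explicit `dominant` flag (default `fat`, appropriate inside an anatomically
outlined adipose depot whose FF exceeds 500‰). A consequence worth knowing:
water-dominant tissue inside the outline (e.g. muscle at the depot boundary)
reconstructs to the mirrored FF `1000 − FF` and can slip through the
400–1000‰ window. The multi-echo path does not share this failure mode, and
the sign convention makes the two paths mutually checkable: on noiseless
data, flipping the flag maps FF to 1000 − FF exactly. Negative values
arising from noise are clamped to zero.

**Multi-echo path.** Complex echoes are fitted voxelwise to

    s(TEn) = (W + F·c(TEn)) · exp(i·2π·ψ·TEn) · exp(−R2*·TEn),
    c(TE)  = Σp αp · exp(i·2π·fp·TE),

where the fat resonance offsets are `fp = 42.577478518 MHz/T · B0 ·
shift_ppm`. The default spectral model is the widely used six-peak
triglyceride spectrum (shifts −3.80, −3.40, −2.60, −1.94, −0.39, +0.60 ppm;
relative amplitudes 0.087, 0.693, 0.128, 0.004, 0.039, 0.048, renormalised
to sum to 1); a single-peak model (−3.40 ppm) is selectable for tests and
pedagogy. The fit is a variable projection: for fixed (ψ, R2*) the model is
linear in the complex amplitudes, solved in closed form from the 2×2 normal
equations in the original (decay-weighted) signal domain; the nonlinear pair
is found by a coarse grid (ψ in ±150 Hz at 4 Hz steps, R2* in 0–300 s⁻¹ at 7
points when fitted) followed by a joint shrinking-grid refinement — ψ and
R2* are refined together because the residual couples them strongly, and
coordinate-wise refinement demonstrably stalls in the diagonal valley. To
suppress isolated water–fat swaps, the field map from a first pass is
median-filtered (3×3×3) and the fit restarted from the smoothed map, keeping
the restart only where it does not worsen the residual; no region growing is
used, which is adequate at phantom scale. W and F are reported as magnitudes
after common-phase projection. A `fit_mask` restricts the fit to a region of
interest (e.g. the anatomical outline), which is both faster and avoids
reporting meaningless fits in air. Requirements: ≥ 3 echoes (≥ 4 with R2*),
complex data. Whether to fit R2* is an explicit option rather than a baked-in
choice; both variants are exercised in tests.

**Fat fraction.** `FF = 1000·F/(W+F)` on voxels whose total signal exceeds
a noise floor, by default 5% of the 99th percentile of W+F (a robust
fraction-of-maximum rule; the threshold is a parameter where a study
protocol specifies one). Degenerate voxels are excluded via the validity
mask rather than erroring. FF is clamped to [0, 1000]‰ and is invariant
under joint rescaling of W and F.

## PET quantification

SUV normalises activity concentration by injected dose per gram of body
weight — total body weight, not lean body mass, and units g/ml. The decay
reference is scan start: vendor activity maps are assumed decay-corrected
there (`decay_corrected_input=True`); otherwise the injected dose is decayed
over the uptake interval with the F-18 half-life 109.77 min,
`D(t) = D₀·2^(−t/T½)`, which is multiplicative over consecutive intervals.
ROI summaries report the mean and *population* SD over masked voxels (the
voxels are the entire population of the region); subject-level statistics
use the sample SD.

## Segmentation workflow

All threshold intervals are closed at both ends — a voxel exactly at 400‰ or
at SUV 1.5 g/ml is included — so voxel counts are bit-reproducible. The
primitives are:

- `threshold_mask(v, lo, hi)`: lo ≤ v ≤ hi.
- `intersect`: voxelwise AND, same-grid enforced.
- `shrink`: binary erosion with the 6-connected (face-adjacent) cross,
  applied once per requested voxel. Interactive margin tools erode by
  physical distance; with near-isotropic voxels one face-adjacent erosion is
  the closest integer analog, and this approximation is deliberate and
  documented rather than hidden.
- `body_mask`: threshold the in-phase volume at `quantile × (99th
  percentile)` (default 0.2) and keep the largest 6-connected component.
  A plain intensity quantile would degenerate when most of the field of view
  is air, so the threshold is anchored to the robust maximum instead.

The MR path composes them as
`shrink(anatomical ∩ FF∈[400,1000]‰ ∩ body, 1)`; the active-BAT mask is the
result intersected with SUV ≥ 1.5 g/ml. The PET/CT path replaces the FF
window with the adipose radiodensity window −190…−10 HU. The anatomical
outline is an *input* (in practice a manual delineation; the synthetic
generator provides one), not an algorithm. An empty active-BAT mask is a
reportable outcome — a BAT-negative subject — not an error; only an empty
depot after filtering raises. Both the pre-shrink ("final") and post-shrink
("optimized") masks are emitted by the CLI, since either may be the
quantification target.

**Paired spheres.** Sphere diameter is 5% of the largest in-plane world
extent of the volume (25 mm at a 500 mm field of view), mirroring the
percentage-brush convention of interactive tools; the reference length is
recorded here because the percentage alone is ambiguous. The PET-positive
sphere is centered on the maximal-SUV voxel within the depot and intersected
with the active mask. The PET-negative sphere is a deterministic surrogate
for the manual "region without discernible uptake": among depot voxels at
least one radius from the positive center whose sphere does not touch the
active mask, the center minimising the sphere-mean SUV is chosen (ties break
toward the lowest voxel index), and the sphere is intersected with the
depot. Sphere-mean SUV and active-overlap for all candidate centers are
computed by convolution with the spherical kernel.

## Cohort statistics

- `cit_percent = 100·(EE_cold − EE_warm)/EE_warm`; may be negative.
- Paired t with sample SD of differences, df = n−1, two-sided p.
- Simple OLS with intercept; slope p from t with n−2 df.
- Pooled regression: x and y are z-scaled (sample SD) *within each cohort*
  before pooling, because different Dixon protocols put FF on different
  effective scales; cross-cohort scaling is available as `scope="pooled"`.
- Multiple regression (FF, age, BMI, CIT): both predictors and response are
  z-scaled by default, so estimates are dimensionless standardized
  coefficients with |β| < 1 for non-degenerate fits; raw-scale fitting is a
  switch. Rank deficiency raises an error naming the collinear columns.
  Adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), with the pooled simple regression
  using the standard one-predictor df.
- BAT-negative subjects are excluded from FF–SUV regressions but retained in
  the data structures with `bat_positive=False`. No multiple-testing
  correction is applied anywhere; p-values are reported as-is and read
  against 0.05.
- A constant response (SStot = 0) reports R² = 0 rather than an undefined
  value.

## Synthetic data generator

`make_phantom` builds one subject on a 64×64×48 grid at 2 mm isotropic
(large enough to hold 25 mm spheres, small enough for seconds-scale tests):
an ellipsoidal body (semiaxes 56/44/42 mm), two supraclavicular depot
ellipsoids (16/13/11 mm, mirrored laterally), and per lobe two spherical BAT
blobs (radius 7 mm) placed at seeded random positions inside the depot. Fat
fraction is Normal(700, 20)‰ in white adipose tissue, Normal(600, 20)‰ in
the blobs (the core contrast: active BAT is leaner), 80‰ in muscle, 0 in
air; total MR signal is 100 inside the body. Complex echoes are synthesised
at the six cohort-2 echo times (1.09–11.59 ms, 3 T) through the same signal
model the reconstruction fits, over a smooth linear B0 gradient of ±20 Hz;
the dual-echo pair is the idealized IP = W+F, OP = |W−F|. MR noise is Rician
(complex Gaussian channel noise of SD `body_signal/mr_snr`, then modulus;
independent streams for echoes and IP/OP so either can be generated alone),
default SNR 50. PET is a Gaussian hot spot (σ = radius/1.4) per blob over a
0.4 g/ml body background, with the peak amplitude linearly linked to the
blobs' FF deficit (3.0 g/ml at the nominal 100‰ deficit) — creating the
within-depot FF–SUV anticorrelation — plus Gaussian noise of SD 0.05 on the
SUV scale; activity maps are scaled through a 75 MBq / 75 kg / 30 min
acquisition. CT is a noiseless tissue-class map (fat −100 HU, muscle +40 HU,
air −1000 HU). The anatomical outline is the depot dilated by two voxels —
deliberately "crude". Ground truth (FF, W/F, SUV, nested masks body ⊇ depot
⊇ active) is returned alongside.

`make_cohort` draws subject records from `z_suv = β·z_ff + √(1−β²)·ε` with
the designed standardized slope β (default −0.65, i.e. R² ≈ 0.42, the scale
of effect a well-powered cohort of 16 can just resolve), FF centered at
680 ± 50‰ (inside the plausible adult supraclavicular range of roughly
575–800‰), SUVmean 2.2 ± 0.7 g/ml, age uniform 18–40 y, BMI uniform
19–27 kg/m², CIT Normal(9, 3)% truncated at the 5% screening floor, and
resting energy expenditure Normal(1700, 150) kcal/day. These distribution
parameters are plausibility-anchored defaults, not fits to any dataset.
Optionally each record is paired with a phantom spec realising the drawn
summary values. All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning, so streams are independent and adding
a new consumer never perturbs existing ones; equal seeds give bit-identical
outputs.

**What the phantoms do not emulate:** partial-volume mixing at tissue
boundaries (voxels are pure-class, so the one-voxel shrink is validated
morphologically, not as a partial-volume correction), realistic anatomy
(vessels, spine), PET point-spread beyond the Gaussian kernel, attenuation
and scatter, T1 bias in FF, k-space effects, or CT noise. Passing tests
therefore demonstrate correctness of the computational chain under the
stated models, not clinical performance on real scans.

## Validation strategy and problem sizes

Unit tests check every operation against independent oracles: pure-Python
voxel loops for morphology and ROI accumulation, exact rational normal
equations plus mpmath incomplete-beta p-values for the regression layer, and
an exhaustive grid search over (FF, ψ, R2*) for the multi-echo fit. The
grid-search oracle deserves a note: the fit residual as a function of
(FF, ψ, R2*) has a long, nearly flat valley, so the oracle zooms a (ψ, R2*)
lattice with a dense FF scan at every point and finishes with a joint
pattern search evaluated in extended precision — in double precision the
valley floor sinks below evaluation noise at the sub-per-mille scale. The
acceptance script runs the same checks at fixed sizes chosen for
desk-machine turnaround: 100 voxels for the Dixon oracle comparison, 200
random instances (4–12 voxels per axis) for morphology, 50 datasets for the
statistics oracle, 500 simulated cohorts of n = 16 for parameter recovery,
and 100 phantoms for the end-to-end paired-sphere pattern.

Two arithmetic identities from the study design are also recomputed: the
cohort-1 group-mean FF difference between PET-negative and PET-positive
regions (653 − 577 = 76‰) and the size-weighted mean age of the two cohorts
(17 at 23.4 y and 16 at 24.5 y pooling to 23.9 y). Cohort-level regression
values from human imaging data are *not* reproduction targets: they depend
on data that is not deposited, and the synthetic cohorts are parameterised
at, not fitted to, that effect scale.

## Known limitations

- The magnitude two-point path mirrors water-dominant voxels into the fat
  window (see above); quantifications that must be robust to boundary
  muscle should use the multi-echo path or a tighter anatomical outline.
- Field-map unwrapping is local (median smoothing between passes); severe
  B0 inhomogeneity with spatial wraps beyond ±150 Hz would need a proper
  region-growing unwrapper.
- The negative-sphere placement is one deterministic rule among several
  defensible ones; its tie-break and exclusion radius are documented so
  counts are exactly reproducible.
- `multiple_linreg` with standardized response reports an intercept that is
  zero by construction; it is kept in the table for shape-compatibility
  with standard software output.
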