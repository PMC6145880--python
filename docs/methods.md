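# Methods

This note documents the models, estimators, numerical conventions, and
simulation conditions implemented in `plaquetrack`, and what validation on
synthetic data does and does not establish.

## Segmentation and volumetry

Plaque measurement operates on one channel of an anisotropic 3D stack
(default geometry 0.31 × 0.31 μm pixels, 2 μm axial step) restricted to an
operator-chosen ROI around a single plaque. The chain is:

1. **Iterative (isodata) threshold.** The fixed point of
   t ← (mean{v ≤ t} + mean{v > t})/2, initialized at the ROI mean,
   iterated until the partition stabilizes or |Δt| < `tol` (default 0.5
   intensity units, at most 100 iterations). The iteration is linear in
   the intensities, so rescaling the data rescales the threshold and
   leaves the mask unchanged. A constant ROI has no threshold and raises
   an error.
2. **Binarization.** Foreground is strictly `intensity > t`; ties go to
   background. This convention is asserted in tests.
3. **Defragmenting.** One synchronous pass removes every foreground voxel
   with fewer than `min_neighbors` (default 4, range 0–26) foreground
   voxels in its 26-neighbourhood, evaluated on the pre-pass mask. This
   suppresses speckle without eroding plaque cores.
4. **Component growth.** The plaque is the maximal *face-connected*
   (6-connectivity) component containing the seed voxel — the brightest
   surviving ROI voxel, ties broken by lowest linear index. Edge- or
   corner-contact does not connect.
5. **Measurement.** Volume = voxel count × dx·dy·dz exactly; maximum
   cross-sectional area is evaluated per native z-slice (count × dx·dy,
   maximum over slices) with no resampling of the anisotropic grid.

A ROI whose foreground/background class separation does not exceed
`min_separation` (default 4 pooled within-class SDs) is reported as
containing no plaque: splitting pure Gaussian noise at its isodata
threshold always produces a separation of ≈ 2.7 regardless of noise
level, so the default cleanly distinguishes "only noise" from any
realistically bright object. Components may touch the ROI border (tracked
plaques are centred by the operator); a warning is logged because the
measurement may then be clipped.

## Laser-power correction

Measured plaque size grows with excitation power. The correction model is
linear in power relative to the lowest calibrated power p_ref:
s(P)/s(p_ref) = 1 + β·(P − p_ref), fitted by no-intercept least squares
separately for volume and area. Calibration requires at least two
distinct powers (a warning is issued below three, where linearity cannot
be checked). Correction divides a measurement by the fitted factor and
flags it `corrected`; in the standard pipeline only day-0 rows are
corrected, the sessions acquired at elevated power. Powers outside the
calibrated range extrapolate with a warning; a nonpositive divisor is an
error.

## Longitudinal statistics

All statistics operate on day-0-normalized percentages (day 0 ≡ 100%).

* **Per-day summaries**: arithmetic mean and sample SD (n − 1); a day with
  one plaque reports SD 0 with n = 1.
* **Growth regression**: ordinary least squares on pooled plaque-level
  (day, value) points — individual traces share one regression line.
  Reported: slope (%/day), 95% CI from the t distribution with n − 2 df,
  and Sy.x = √(SSres/(n−2)). A day-range restriction supports fitting
  treated groups from the first post-treatment day onward.
* **Per-day tests**: one-way ANOVA across days; each later day is
  compared to day 0 with a t statistic built on the ANOVA's pooled
  residual mean square, and the per-day p-values are Holm-Šidák adjusted
  (α = 0.05; stars at 0.05/0.01/0.001/0.0001). Adjusted p-values are
  monotone in, and never smaller than, the raw ones; with a single
  comparison the adjustment is the identity.
* **Size classes**: plaques are split at the median day-0 volume (values
  equal to the median go to "smaller"); each plaque's rate of change is
  the OLS slope of its own trajectory; classes are compared with a Welch
  t-test (unequal variances are likely between size classes, so the
  pooled-variance variant is not used).

Plaques are treated as independent observations across days, matching the
one-way-ANOVA design; no repeated-measures or mixed-effects structure is
modelled. Missing imaging days are simply absent rows.

## Stereology

The fractionator estimate is N̂ = ΣQ⁻/(ssf·asf·hsf) with
asf = frame area / grid area and hsf = disector height / section
thickness. The default design uses 200 × 200 μm frames on a 500 × 500 μm
grid (asf 0.16), a 20 μm disector with 2 μm guard zones in 40 μm nominal
sections (hsf 0.5; post-processing tissue shrinkage is not corrected),
and every fourth section (ssf 1/4). Counting rules: the counting point is
the profile centroid; the frame's left and bottom edges are exclusion
lines (a point exactly on them is not counted) per the standard unbiased
counting frame; the counting point must lie inside the disector (guard
zones excluded); and the profile must be entirely contained within the
section. The section start and grid origin are systematic-uniform-random
from a seeded RNG, so the estimator is unbiased for populations whose
counting points are uniform in the sampled volume. Precision is
summarized by the Schmitz-Hof CE = 1/√ΣQ⁻.

The nucleator estimates profile area as π·mean(lᵢ²) over four rays from
the profile centre; for the circular profiles used in simulation this is
exact for any ray rotation. Plaque surface area per section is the
product of the mean fractionator count per section and the mean nucleator
area. Both the raw sampled count and the scaled estimate are reported,
since published plaque-number summaries can be on either scale.

Group statistics use the classic unpaired two-tailed t-test for
subject-level metrics (with the percent difference of means reported as
100·(CTL − FUS)/CTL), two-sided Fisher exact tests for 2×2 mortality
tables, and a two-way ANOVA (main effects of group and treatment number)
for weight fluctuations.

## MR enhancement

Relative enhancement = 100 × (mean of four 3×3-pixel target-window means)
/ (mean of a user-chosen untargeted background rectangle), on a single
post-contrast T1-weighted slice. Windows are centred on the given 0-based
(row, col) coordinate; out-of-bounds windows and windows overlapping the
background region are errors. The metric is invariant to global intensity
scaling and to target order. No pre-contrast normalization, registration,
or pharmacokinetic modelling is attempted.

## Synthetic data: what it emulates, and what it does not

Plaques are rendered as anti-aliased ellipsoids (soft ~1-voxel edge)
convolved with an anisotropic Gaussian standing in for the two-photon
PSF. The defaults, σ = 0.21 μm lateral and 0.85 μm axial, correspond to a
0.5 / 2.0 μm FWHM — representative of a high-NA water-immersion
objective. Truth masks are the pre-blur centre-in-ellipsoid
voxelizations; truth volumes are their voxel-integrated volumes. Note the
2 μm axial step makes the digitized volume of a sphere deviate from the
analytic 4/3·πr³ by a few percent (z-midpoint discretization), which is
why volumetry accuracy is assessed at percent-level, not voxel-level,
tolerances. The vessel channel renders tubes around polylines; a
configurable fraction of its above-background signal is added to the
plaque channel, emulating dye bleed-through after barrier opening. Noise
is additive Gaussian, default SD 10% of the peak-background contrast
(the source studies report only discarding poor-SNR stacks); intensities
are clipped at zero.

Longitudinal series scale plaque linear dimensions so that volume follows
v(t) = v₀(1 + g·t/100), with an optional multiplicative step shrinkage
from a treatment day onward. Power inflation magnifies each XY slice by
√(1 + β·(P − p_ref)) about the stack centre so that the segmented volume
of a calibration object scales by the full factor, monotonically in P;
the axial direction is left untouched because a 2 μm slice spacing cannot
express sub-slice boundary shifts under resampling. Section populations
are homogeneous Poisson in-plane with uniform counting-point depth and
truncated-Gaussian profile areas (default 300 ± 60 μm²); generated
profiles are always contained in their section, so containment filtering
is exercised separately with hand-built cases. T1 spots have a flat core
(so a centred 3×3 window reads the plateau exactly) and a Gaussian
shoulder.

Not emulated: microbubble/sonication physics, realistic MR sequences,
vessel-landmark plaque relocation (plaque identity is carried by explicit
IDs), tissue shrinkage, motion/breathing artifacts, and non-spherical
plaque morphology. Passing the validation suite therefore demonstrates
correctness of the estimators and the measurement chain under the stated
noise and geometry model — not robustness to every artifact of real
acquisitions.

## Validation scenarios and problem sizes

The recovery experiments (in `plaquetrack.validation`, reused by
`scripts/acceptance.py`) use study-like conditions: sphere radii 3–8 μm
at SNR 10 for volumetry; β = 0.04/mW sweeps over 8–16 mW with three
replicate stacks per power; 36 control plaques on the day grid
0, 2, 4, 7, 10, 12, 14, 21 with a true slope of 3.6%/day and 25
percentage points of per-observation noise for CI coverage (100
replicates); 18 treated plaques with a day-2 step to 0.6 of baseline and
elevated day-0 power for the full-pipeline recovery; 24 sections of
2 × 2 mm at 10 plaques/mm² with 200 systematic-random designs for
fractionator bias; and enhancement factors 1.5 (noise-free) and 1.46
(noisy) for the MR metric. Simulated stacks are tight ROIs (a few μm of
margin) around each plaque, the way an operator crops a tracked plaque —
this also keeps the whole validation suite at seconds of runtime.

## Numerical conventions and edge cases

* All randomness flows from explicit integer seeds via
  `numpy.random.default_rng` / `SeedSequence.spawn`; no global RNG state.
  Identical spec + seed reproduces outputs bit-for-bit.
* Thresholding ties go to background; frame-edge ties go uncounted
  (exclusion edges); median ties go to the "smaller" class. Each
  convention is documented at the function and pinned by a test.
* Degenerate inputs raise informative errors rather than returning
  sentinel values: constant ROIs, empty components, missing day-0 rows,
  nonpositive correction divisors, zero fractionator counts for the CE.
* Percent decreases computed from two group means carry no uncertainty;
  they are reported to one decimal and compared at printed precision.

## Known limitations

* Volumetry accuracy degrades for objects near the axial resolution
  limit; at r = 3 μm the segmented volume can run ~10–13% high. The
  acceptance tolerance (15%) reflects this.
* The fractionator's "entirely contained" rule, taken from the source
  protocol, would bias against large profiles in populations where
  profiles cross section faces; the generator does not create such
  profiles, so the implementation reproduces the protocol without
  quantifying that bias.
* The linear power-response and linear growth models are modelling
  choices exposed in configuration, not validated physics; alternative
  forms require refitting, not code changes.
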