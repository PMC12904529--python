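# Methods

This note records the models, conventions, and design choices behind
`turbimap`, and what the synthetic-data tests do and do not demonstrate
about real instrument data.

## Measurement model

**Diffuse decay.** The medium is treated as a semi-infinite turbid
half-space: the surface intensity a distance *d* from a pencil-beam
entry point decays as `I(d) = A·exp(−μ_eff·d)/d²`. Taking
`y = ln(I·d²)` linearises the model to `y = −μ_eff·d + k`, and μ_eff is
estimated as minus the slope of an unweighted ordinary least-squares
fit. The intercept *k* absorbs the source power, camera gain, exposure
normalisation and coupling losses, and is discarded — which is also why
the estimator is exactly invariant to any linear rescaling of
intensity (verified as a property test). Distances are Euclidean in
the unwrapped (arc, height) plane, an approximation to the 3-D chord
distance that is consistent with fitting along a straight horizontal
image line; all lengths are mm and μ_eff is in mm⁻¹, the only choice
of units under which the shipped calibration constants are
self-consistent with a 5–30 mm fit window.

**Fit window (5, 30) mm.** Below ~5 mm the sensor saturates around the
laser spot in every exposure (those pixels are flagged invalid by the
HDR merge and excluded); beyond ~30 mm the signal approaches the
background floor. Profiles are sampled at pixel resolution along the
row through the commanded spot position. The spot location is taken
from the scan plan mapped through the unwrap transform, because the
spot pixel itself is saturated; a brightest-blob centroid fallback
exists for data without a plan.

**Side selection and row averaging.** `extract_profile` takes a single
side of the spot (the side whose full window fits in the image — the
relevant case when a spot sits near the arc seam). `fit_spot` fits
both sides where available and combines the two estimates with
inverse-variance weights. Profile rows may be averaged over
± `row_halfwidth` neighbouring rows; the library default is a single
row, while the end-to-end pipeline uses ±2 rows (2 mm at default
pitch), which suppresses shot noise without mixing distinct heights
(the laser spacing is 5 mm).

**μ_eff from optical coefficients.** The diffusion-theory relation
`μ_eff = sqrt(3·μ_a·μ_s′)` is the default convention; a literal product
`3·μ_a·μ_s′` is selectable for compatibility with sources that quote
the product form. Both agree at the fixed point μ_a = 1/3, μ_s′ = 1.

## Calibration

Cell density is the controlled variable in a calibration experiment
(stepwise addition of counted aliquots), so the regression runs μ_eff
on density; the density-from-μ_eff map is its algebraic inversion,
`ρ = (μ_eff − intercept)/slope`. The two lowest-density points are
excluded by default: without scattering the decay model does not apply.
The shipped reference model (slope 8.23×10⁻¹² mm⁻¹ per cells/mL,
intercept 7.58×10⁻² mm⁻¹) lets users apply the published vessel
calibration without refitting. The non-zero intercept is the vessel's
own scattering (internal plastic manifold, wall imperfections); it is
fixed for a given vessel, so it cancels out of growth factors.
Densities below the floor are reported negative with a
`nonpositive-baseline` mask reason rather than clamped, so drift below
the floor remains visible. OD₆₀₀ conversion uses 8×10⁸ cells/mL per OD
unit (configurable), valid only in the linear low-concentration regime.

## Unwrapping

Each camera view is modelled as an orthographic projection of the
cylinder: a surface point at angle θ within a view of sector centre θ_c
lands at lateral position `x = R·sin(θ − θ_c)`; mirror views are
additionally reversed horizontally. Orthographic rather than
perspective is justified by the long working distance of the imaging
lens; a perspective correction is a config option, off by default.
The projection is treated as radiance-preserving — an imaging relay
reports surface radiance, which is invariant along rays — so rendering
and unwrapping resample geometry only and leave intensities unmodified
for the fit. Resampling is bilinear with a nearest-neighbour fallback
at polygon borders; overlapping views are stitched with a hard
per-column switch to the view whose sector centre is angularly closest,
with the winning view recorded per pixel in a provenance mask. Region
polygons are config-supplied for real data and generated analytically
from the geometry for synthetic data; a polygon's bounding box defines
its linear pixel ↔ (x, height) frame.

Numerically, two bilinear resamplings reproduce smooth fields to ~0.1%
RMS away from seams, but necessarily blur hard discontinuities
(sector seams, baffle-shadow edges, checkerboard cell edges); accuracy
statements therefore exclude a 2-pixel margin around discontinuities.
The residual smoothing of the (convex) decay profile biases fitted
μ_eff by about −0.5% at default pitch; the bias is common to all
timepoints of a series and largely cancels in growth factors.

## HDR merging and camera characterisation

The scattered signal spans >300× between 5 and 30 mm, beyond one
frame's dynamic range, so each acquisition is an exposure stack
(default exposure ratios of 8×). Per pixel the merge selects the
longest exposure below 0.95 of full well — a saturation margin that
stays clear of near-clipping nonlinearity — and scales it to counts
per unit exposure after black-level subtraction (floored at zero).
"Longest unsaturated" maximises per-pixel SNR while staying
radiometrically linear and trivially auditable; pixels saturated in
every frame are flagged invalid and propagate as NaN. Sensor gain and
read noise are estimated photon-transfer style from same-illumination
frame pairs: per pair, `v = var(A−B)/2` against `m = mean − black`
gives `v = gain·m + σ_read²` by OLS. The read-noise intercept is only
identifiable at low illumination where it is not swamped by shot
noise, so characterisation levels should concentrate there; pairs with
mean signal below 1 count are discarded as carrying no signal, and at
least three informative levels are required.

## Synthetic scenes and scenarios

The simulator emulates the reference instrument: a 2.5 L cylindrical
vessel (R = 65 mm) with a 140 mm scan window sampled at 0.5 mm pitch,
three view sectors covering the circumference with small overlaps,
baffle shadows and an air band above the liquid rendered as
multiplicative dark masks (attenuation 0.05 — the real levels are not
documented, so both are configurable), a 16-bit sensor (gain 2
counts/e⁻, read noise 3 counts, black level 100), Poisson shot noise,
and hard full-well clipping. The laser is scanned at 25 heights, 5 mm
apart, on the front axis. All randomness flows from a single dataset
seed; per-frame streams are spawned from (time, laser) indices so
datasets are reproducible and iteration-order independent.

Default growth scenarios: a *fermentation* scenario (uniform logistic
growth reaching 2.0× at 23 h, the outcome scale of a typical batch
culture), a *banded* scenario (final folds 2.5/1.5/2.5 above 45 mm,
between 45–80 mm, below 80 mm — a qualitative analogue of observed
height-dependent growth), and an *antibiotic* negative control
(density constant in time). The starting density, 9.71×10⁸ cells/mL,
is one third of the highest calibration density, matching how a
calibration range is chosen to cover ~3× the inoculation density.

What the synthetic data does **not** model: dead-cell optics and
sedimentation (a late-culture μ_eff decline simply reads as growth
< 1), specular glints from the vessel surface (their masking is
exercised with injected outliers instead), bubbles, impeller motion,
perspective distortion, vignetting, and fixed-pattern sensor noise.
Passing tests therefore demonstrate correctness of the algorithms
under the stated optical model, not robustness to every instrument
artefact.

## Growth maps

Each height row is normalised by its own T = 0 density (so the first
column is exactly 1), reproducing spatial-variation maps; a
global-baseline option exists for vessel-average curves. Standard
deviations are sample (n−1) throughout. Row masking is two-tier:
manual height lists (reason `specular`, the documented real-data case
at 55 and 70 mm) take precedence over automatic flagging (reason
`auto-specular`), which marks rows whose time-median growth deviates
from the cross-row median by more than a threshold (default 3.5)
robust z-scores on the 1.4826·MAD scale. Masked rows keep their values
for audit but are excluded from all summaries.

## Problem sizes and tolerances

The end-to-end validation runs the full pipeline on 25 heights × 12
timepoints (two scenarios, ~600 exposure stacks of ~0.2 Mpixel frames,
about a minute on one CPU) — 12 timepoints rather than the 138 of a
real 23 h run, since growth-map accuracy is per-cell and more
timepoints only repeat the same measurement. Headline accuracy under
default noise: median absolute relative error of the recovered growth
map < 5% (measured ~2.6%), control scenario within ±0.05 of unity at
every cell (measured max ~0.034), μ_eff exact to <10⁻⁸ relative on
noiseless profiles, calibration line recovered to 6 significant
figures from exact points. The noisy-calibration check reports the
mean slope over 100 seeds (a bias check): with σ = 2×10⁻³ mm⁻¹ on 14
points the single-seed slope standard error is ~8%, so per-seed
agreement inside 10% is not statistically guaranteed and is not
claimed.

## Known limitations

- The semi-infinite diffusion form is used as-is; no Monte-Carlo
  radiative transfer or finite-element diffusion reference, and no
  correction for vessel curvature within the fit window.
- Accuracy degrades when the fit window subtends a large angle of the
  cylinder (small vessels / coarse pitch), as the orthographic
  resampling then compresses the profile: keep the window small
  relative to R or reduce the pixel pitch.
- The calibration is vessel- and strain-specific; the shipped model is
  a convenience default, not a universal constant.
- Fluorescence channels, hardware control, and closed-loop operation
  are out of scope.
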