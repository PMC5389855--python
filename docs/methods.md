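# Methods

This note documents the models, numerical choices and limitations behind
each pipeline stage, and what the synthetic-scene generators do and do not
emulate.

## Autofluorescence unmixing

**Model.** Each lifetime-gated sensor channel records
`F_raw = F_sensor + R·F_AF (+ noise)`, where `F_AF` is the dedicated
autofluorescence channel (405ex 450–470em, gated 7–11.5 ns, no sensor
signal) and `R` is a channel-specific bleed constant. The correction is the
pixel-wise subtraction `F_sensor = F_raw − R·F_AF`.

**Fit.** `R` minimizes `Σ (F_target − R·F_AF)²` over pixels pooled across
control (non-transgenic) animals; because the correction formula has no
offset term, the default fit runs through the origin, with the closed form
`R = Σ F_target·F_AF / Σ F_AF²`. A free-intercept fit is available purely as
a diagnostic (a large fitted offset indicates a background pedestal the
model does not capture). The fit is recomputed per experimental group so
that session-to-session drifts in laser power or detector gain do not
propagate between groups. Negative closed-form estimates (possible under
noise when the true bleed is ~0) are clamped to 0, matching the physical
constraint R ≥ 0.

One caveat documented here because it is inherent to the design: Poisson
noise in the AF channel appears in the regressor, so the through-origin
estimator carries an attenuation bias of order `⟨F_AF⟩ / ⟨F_AF²⟩`. At the
count levels the generator emulates (AF ~50–150 counts over a ~20-count
baseline) this bias is a few tenths of a percent — negligible against the
2% recovery tolerance the test suite enforces — but it would grow for very
dim AF fields.

**Per-worm readout.** The quantification plane is the z-slice with the
greatest combined corrected 405+488 fluorescence inside the (2-D) head ROI,
ties toward the smallest z. The default per-worm estimator is the ratio of
sums `Σ F488 / Σ F405` over valid ROI pixels — robust to dim pixels because
each pixel enters weighted by its own intensity; mean-of-ratios is provided
alongside, since either convention is defensible and published work rarely
states which was used. Pixels with corrected 405 signal below a floor
(default: 1% of the in-ROI 99th percentile) are excluded to keep near-zero
denominators from dominating. Negative values after subtraction are clipped
to 0 (photon counts are nonnegative); the unclipped map is retained in the
stack's `extras` for diagnostics.

**INR rendering.** Intensity-normalized ratiometric images encode the ratio
as hue (clipped to a display range, mapped through a perceptually uniform
colormap) and combined intensity as brightness normalized to the in-image
maximum; invalid pixels render black. The recipe is a reimplementation
choice — published INR figures cite tooling whose exact mapping is not
specified — so the rendering is for inspection, never for quantification.

## Mitochondrial %-area morphometry

Maximum-intensity projection over a 5-slice window (the window start is a
per-cell user choice), then `percent_area = 100·|{p ∈ mask : I(p) ≥ t}| /
|mask|` within the cell boundary. The threshold is either a fixed number
applied identically to every image of an experiment, or Otsu's threshold
computed from in-mask pixels only; whichever is used is recorded in the
output. Because acquisition gain is commonly set per image, a >4-fold
spread of in-image medians within one batch triggers a logged warning — a
shared absolute threshold is dubious in that regime and the package cannot
resolve it automatically.

Richardson–Lucy deconvolution (scikit-image's implementation behind
`deconvolve_rl`) is offered as optional preprocessing and is off by
default: it is a generic substitute for whatever plugin a given lab uses,
not a replication of any of them, and thresholded %-area on projections is
only mildly sensitive to deconvolution in the regimes the phantoms cover.

## Oil Red O densitometry

Stain polarity: Oil Red O is red and absorbs green light, so stain
intensity is the inverted green channel `S = channel_max − G`; the mask is
`S ≥ t` with one numeric `t` per experiment. Integrated density is the
conventional sum of qualifying pixel intensities (area × mean) over pixels
whose integer centers fall within the 40-px-diameter circle; the circle
center is user-supplied per image (placing it "below the pharynx" requires
anatomy the software does not detect).

Pseudo flat-field correction divides each channel by its own wide Gaussian
blur (default σ = 50 px). The corrected image is re-anchored to the blur's
**maximum** rather than its mean: illumination fields peak at full
brightness where the optics are unvignetted, so the maximum anchor restores
the absolute intensity level. This matters specifically because the stain
readout is an inverted channel: a mean anchor preserves each image's own
mean brightness, so two images of the same specimen under different
vignettes come out at different global levels and their inverted-channel
densities disagree by several percent. A `rescale="mean"` option is kept
for parity with common ImageJ macros.

## Cohort statistics

* `relative_values` divides each measurement by the mean of same-experiment
  control values before pooling across experiments, so pooled values are
  dimensionless fold-changes; control rows are kept (per-experiment mean 1).
* t-tests are Welch by default (a pooled-variance option exists); ANOVA is
  one-way with Bonferroni-corrected post-hoc pairwise t-tests over the
  explicitly listed pairs. The Bonferroni factor m defaults to the number of
  requested comparisons.
* The Wilcoxon rank-sum test uses midranks. For combined n ≤ 20 the
  two-sided p is exact, by enumeration of all C(n, n_a) rank assignments.
  Above that it uses a normal approximation with a 0.5 continuity correction
  plus an Edgeworth fourth-moment term: the rank-sum null is platykurtic at
  small n, and the kurtosis term (computed from the exact finite-population
  moments of a without-replacement sample sum, which also subsumes the
  standard tie correction) reduces the worst-case error against exact
  enumeration from ~0.02 to below 0.01 on continuous data in the n = 8–20
  range. Heavily tied data at very small n remain the hard case for any
  asymptotic formula; there the exact path applies anyway.
* Survival summaries report mean, s.e.m. (sample sd / √n), median (midpoint
  convention for even n) and `S(t) = fraction with death day > t`. Rows
  flagged `excluded` (animals lost to foraging or bagging) are dropped by
  every operation; no right-censoring machinery is implemented because the
  analyses consume complete death times.
* Scored proportions (e.g. % of animals with nuclear reporter localization)
  are compared on per-experiment percentages, making the independent
  experiment the unit of replication.

## Synthetic scenes: what they emulate, and what they do not

* **Redox scenes** (default 64×64×7 voxels): autofluorescence is a sum of
  broad Gaussian blobs over a 20-count baseline — spatially smooth and
  positive, like lifetime-isolated gut autofluorescence — with blob peaks
  50–150 counts; `AFFieldSpec.mean_level` instead pins the volume-mean AF
  level when an AF:sensor amplitude ratio must be stated exactly. The
  sensor region is a disk ("head") of constant 405-channel amplitude
  (default 300 counts) with a soft z-profile, and the 488 channel is the
  prescribed true ratio field times the 405 field. Noise is Poisson on
  expected counts (gain 1) with optional additive Gaussian read noise.
  Controls are sensor-free. Not emulated: worm anatomy, sensor
  photophysics, focus drift, detector nonlinearity — so passing recovery
  tests validates the estimators under the stated forward model, not
  robustness to un-modeled optics.
* **Mitochondrial phantoms** (default 5×128×128): tubules are dilated
  random walks, blurred by a Gaussian PSF stand-in and noised; the true
  %-area is computed from the pre-blur binary mask's projection, which is
  what makes the zero-blur, zero-noise recovery test exact.
* **Stained RGB scenes** (default 256×256, 512×512 in the invariance
  tests): uniform stain disks clustered around the measurement circle (fat
  deposits cluster in the anterior intestine the circle is placed over)
  subtract from the green channel of a bright background; a multiplicative
  Gaussian-falloff vignette spanning a stated range (peak normalized to its
  upper bound) multiplies all channels. The vignette varies on the scale of
  the whole field, much more slowly than stained structures — the regime in
  which dividing by a 50-px blur is a valid flat-field estimate. Ground
  truth densities are pre-vignette.
* **Lifespan cohorts**: death times follow a Gompertz hazard a·e^{bt} with
  defaults a = 0.002/day, b = 0.25/day (mean ≈ 17 days, matching a
  wild-type cohort at 25 °C), rounded **up** to the scoring interval — a
  death is recorded at the first visit at which it is observed.

## Problem sizes and determinism

Every generator is deterministic given its seed. The validation suite and
`scripts/acceptance.py` use 8 control animals per bleed-ratio fit, 3 worms
per redox group, 4 vignette renderings per invariance check and 1000
replicate null cohorts (n = 50/group) for the type-I error of the rank-sum
test; these sizes give stable estimates (type-I error within 3–7% at
α = 0.05 across seeds) while keeping a full run in seconds.
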