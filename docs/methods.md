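# Methods

This note documents the models, parameter choices and numerical conventions
behind `tlscanopy`, and what the synthetic validation does and does not
demonstrate about field data.

## Coordinate frames and registration

Every scan starts in its instrument-local frame (`frame="scanner"`). The
season-fixed frame is defined by the sphere-target constellation; by default
the first scan of a campaign defines it, and a two-pass self-consistent
alternative (reference = per-sphere mean of first-pass transformed centers)
is available via `register_campaign(..., self_consistent=True)`. Frames are
declared on every cloud and never inferred; transforming an already-fixed
cloud is an error, so a scan can never be registered twice.

Correspondence between observed and reference spheres is by identifier
only — targets are individually placed and identifiable — never by nearest
neighbor. The rigid estimate is the closed-form least-squares solution:
center both point sets, take the SVD of the cross-covariance, and compose
the rotation as V·diag(1, 1, det(VUᵀ))·Uᵀ. The determinant correction
forces a proper rotation when the unconstrained optimum would be a
reflection (physical scans cannot reflect). No scale factor is estimated.

The QC metric is the Euclidean deviation of each transformed sphere center
from its reference position (default), or from the per-sphere mean across
scans (`mode="sphere_mean"`); campaign summaries are the mean ± sd over all
(sphere, scan) observations. For a registration noise of per-axis σ the
expected deviation is E‖ε‖ ≈ 1.6 σ, slightly shrunk by the 6 degrees of
freedom the transform absorbs; the simulator's default 1–1.2 mm
sphere-detection noise puts campaign means around 1.5–2 mm, the order of
magnitude reported for well-behaved field campaigns.

`fit_sphere` (algebraic linear fit, optional geometric refinement with
`scipy.optimize.least_squares`, fixed-radius variant for targets of known
diameter) lets the pipeline start from raw target patches when no vendor
sphere detection is available.

## Height maps

Grids use a half-open pixel convention: pixel (i, j) covers
[x₀+is, x₀+(i+1)s) × [y₀+js, y₀+(j+1)s), so every point belongs to exactly
one pixel and points on a shared edge go to the pixel on the upper side.
The default pixel size is 5 mm — small enough that a pixel rarely spans
more than one organ surface, large enough to collect several returns.

The soil map H_S takes the per-pixel *minimum* (lowest returns are most
likely true ground), fills empty pixels by nearest-neighbor interpolation
(`scipy.ndimage.distance_transform_edt`), and median-filters with a square
window of round(0.21 m / pixel) forced odd — 43 px at 5 mm — with reflect
padding. The interpolation method is deliberately parameter-free: the
median pass dominates the result and smooths fill seams, so anything more
elaborate than nearest-neighbor fill changes the output negligibly. Order
of operations is interpolate first, then median-filter. The nearest fill
extends beyond the convex hull of observed pixels; soil values outside the
observed area are extrapolations and should not be trusted, but points over
them are rare in practice because scans cover the grid.

The per-pixel minimum of n noisy returns is biased low by roughly the
expected minimum of n Gaussian draws (≈ −1.2 σ at n = 5); this bias is the
dominant term in the soil-map error budget and stays comfortably inside the
3 mm envelope measured on simulated tilted planes with 1 mm range noise at
≥ 5 points/pixel.

Height above soil is z − H_S(pixel containing x, y); points over pixels
without soil data are dropped and counted. The plant map H_P keeps, per
pixel, the maximum (or a percentile) of points *strictly* above the 10 cm
plant threshold ("higher than 10 cm"); a point at exactly 0.10 m is not a
plant point. Pixels without plant points are nodata and flagged non-plant.

Percentiles everywhere use linear interpolation between order statistics
(numpy's default rule). This is documented and fixed because different
percentile definitions differ by up to one inter-point gap, which matters
at P99 of small samples.

## Filtering approaches

- **FA_ALLPOINTS**: percentiles of the z of every point whose xy falls in
  the ROI — no plant threshold, since the approach is defined on the whole
  point population.
- **FA_MEDIANMAX / FA_MEDIANP99**: the ROI is tiled into patches anchored
  at its lower-left corner (default 10 cm × 10 cm; row crops use 15 cm
  along the row × full row width). Partial edge patches are kept — their
  smaller plant-pixel count N already down-weights them. Per patch, the
  statistic (max, or P99) of the plant-pixel heights is taken with weight
  N; the ROI value is the weighted median: the median of the list in which
  each patch statistic appears N times. The implementation walks cumulative
  weights instead of materializing the expansion and is tested against the
  brute-force expansion oracle; with an even total weight it returns the
  mean of the two middle elements, matching the common median convention.
- Percentile profiles (P90…P100) of the patchwise approaches vary the
  per-patch statistic Px, with P100 ≡ the maximum, so FA_MEDIANMAX is the
  Px = 100 endpoint of the same family as FA_MEDIANP99.

ROIs are rectangles or shapely polygons; `make_roi_grid` tiles a field
extent into plots shrunk by a border exclusion on each side (border rows
are excluded to avoid edge effects), and rejects exclusions that leave no
plot interior.

## Growth rates and the diel confound

Growth between consecutive measurements is 1000·Δh/Δt in mm h⁻¹ and may be
negative — canopies genuinely sink when leaves drop toward the evening.
Crops with strong diel leaf movement make sub-daily differencing a jumble
of reversible movement and true growth; the `same_hour` mode pairs each
measurement with the next one taken at the same time of day (±1 h default)
on a later day, which cancels the movement term exactly if the movement is
24 h-periodic. The simulator's diel canopy encodes this as
height(t) = base + ∫growth dt − A/2·(1 − cos(2π(t − t_peak)/24)): the
depression vanishes at the peak hour (leaves most horizontal) and reaches
the amplitude A at the opposite phase. With A = 5 cm and zero growth,
6-hour differencing produces an artifact of A/2 per 6 h ≈ 4.2 mm h⁻¹ while
same-hour rates stay at the noise floor (< 0.01 mm h⁻¹ in simulation);
with 1 mm h⁻¹ true growth the same-hour estimate is recovered within a few
tenths of a percent.

## Scan point height distributions

SHDs histogram plant-point heights in fixed-width bins aligned to
multiples of the bin width, with one empty guard bin at each end so that a
population at the extreme of the height range still forms a local maximum.
Shoulder detection smooths the counts with a centered 3-bin moving average
(edge-replicated padding, so flat histograms stay flat and yield no peaks)
and runs `scipy.signal.find_peaks` with a prominence threshold of 2% of
the smoothed maximum. Both parameters are exposed; the defaults resolve
layers ≥ 2 bins apart with layer populations above a few percent of the
total.

## Scanner model and simulator

Point spacing is linear in range: spacing(r) = r · (base angular step /
resolution fraction). The base step is calibrated from a printed spacing at
a reference range rather than hard-coded, because vendor angular steps are
not published; calibrating at 2 m reproduces the 10 m spacing to the
printed precision of the calibration value (the 3-decimal print rounding
propagates to 2.5×10⁻³ mm at 10 m) and vice versa.

The simulator casts rays over the angular grid covering a requested ground
window (full azimuth circle if the scanner stands inside it), extending the
zenith range so elevated sphere targets and canopy tops remain in view
across their footprints. Surfaces are opaque and first-hit only — in closed
canopies the beam does not penetrate deep, and partial transmission is out
of scope. Gaussian range noise acts along the ray (its vertical component
is σ·cos zenith); with a configurable probability a return is lifted by
U(0.5, 2) m to emulate the airborne outliers observed above real crop
canopies. Scenes are deterministic in the seed.

Soil surfaces are planes, optionally with a smooth sinusoidal undulation
(ray intersection by Newton iteration on the plane solution; convergence
relies on the undulation slope being gentle relative to the ray
inclination) and optional absorbing rectangular holes for gap-fill tests.
Canopy test shapes all have closed-form height-above-soil quantiles:

- uniform slab (all quantiles equal the height), optionally with a
  sinusoidal ripple (arcsine-law quantiles);
- hemispherical crowns of radius R (quantile R·√(p/100) over a uniformly
  sampled crown disk);
- horizontal leaf layers with per-layer interception probabilities (a
  statistical stand-in for leaf disks) producing multi-modal SHDs with one
  shoulder per layer.

`simulate_campaign` emits each scan in its own scanner-local frame
(obtained by pulling the world-frame cloud back through the scan's pose)
together with noisy sphere-center observations, so registration is
exercised exactly as in the field.

## Problem sizes and validation scope

The validation suite and the acceptance script run on 2 m × 2 m scenes at
5 mm pixels with ray budgets of 0.2–2 million rays per scan, ~10⁴–10⁵-point
ROIs, 100-replicate registration recoveries and 10³-instance
weighted-median checks — sizes at which every closed-form ground truth is
sharp and the whole suite completes in well under a minute per stage.

What passing these tests shows: the geometry, rasterization, statistics and
bookkeeping of the pipeline are correct against independent oracles, and
the percentile/weighted-median machinery has the claimed robustness
properties. What they do not show: performance on real canopies, whose
return populations include mixed soil/vegetation pixels, wind-blurred
points, multi-bounce artifacts and occlusion patterns far richer than the
opaque first-hit model; field accuracies (sphere deviations, regression R²
against manual measurements) therefore cannot be reproduced from synthetic
data, only bounded in order of magnitude.

## Known limitations

- No LAS/LAZ or vendor formats; ASCII xyz and the package's own binary
  cache only.
- Soil maps are built once per season; multi-temporal soil updating and
  terrain classification from mixed scans are out of scope.
- Row-direction-aligned patch tilings require an axis-aligned row direction
  in practice (the tiling itself is axis-aligned; `row_direction` is
  metadata for choosing the patch aspect).
- The simulator has no radiometry, no multi-return waveforms, and no wind
  jitter.
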