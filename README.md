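# tlscanopy

Terrestrial laser scanning (TLS) pipeline for measuring crop canopy height
and canopy height growth in the field.

A tripod-mounted laser scanner placed next to (or inside) a plot produces a
3D point cloud of the visible canopy surface. White spherical targets at
fixed field positions define a coordinate system that stays constant over
the whole season, so scans taken on different days — or at different hours
of the same day — can be compared directly. `tlscanopy` implements the full
processing chain from raw ASCII xyz scans to per-plot canopy heights,
growth rates in mm h⁻¹, and scan-point height distributions, plus a
ray-casting scan simulator that provides ground truth for every stage.

## Method

For each scan, observed sphere centers are matched by identifier to the
reference constellation and a proper rigid transform (R, t) minimizing
Σᵢ ‖R xᵢ + t − yᵢ‖² is estimated via SVD of the cross-covariance matrix
(Kabsch). The residual deviations of transformed sphere centers are the
quality-control metric bounding the achievable accuracy of any height
difference between scans.

Registered clouds are rasterized on a 5 mm grid. A bare-soil scan yields
the soil height map **H_S** (per-pixel minimum, gap interpolation, 21 cm
median filter); subtracting H_S(x, y) from each point's z gives height
above soil. Canopy height per region of interest (ROI) is then computed by
three filtering approaches:

- **FA_ALLPOINTS** — percentiles P90…P100 of the z of *every* point in the
  ROI;
- **FA_MEDIANMAX** — the ROI is tiled into patches (10 cm × 10 cm, or
  15 cm × row width for row crops); per patch the maximum of the plant
  height map **H_P** (pixels with points > 10 cm above soil) is weighted by
  its plant-pixel count N, and the ROI value is the weighted median;
- **FA_MEDIANP99** — the same with the per-patch 99th percentile.

P99 suppresses the sparse airborne outliers that dominate the raw maximum
while still tracking the canopy top. Growth is the height difference
between dated measurements (mm h⁻¹); for crops with strong diel leaf
movement, a same-hour pairing mode differences only measurements taken at
the same time of day, separating reversible leaf movement from true
growth. The scan-point height distribution (SHD) — a histogram of
plant-point heights — exposes organ levels (leaves, ears) as local maxima
("shoulders").

The simulator casts rays over the scanner's angular grid (point spacing
grows linearly with range: spacing = range × angular step), returns first
intersections with soil, canopy shapes with closed-form height quantiles,
and sphere targets, then adds Gaussian range noise and sparse airborne
outliers.

## Worked example

Simulate a 2 m × 2 m plot (tilted soil, 1 m canopy with 5 cm surface
ripple, four spheres) seen from two scanner poses, register the scans,
build the soil map, and measure canopy height:

```python
import numpy as np
from tlscanopy import (GridSpec, ROI, RigidTransform, ScannerSpec, SceneModel,
                       SlabCanopy, SoilPlane, build_soil_map, fa_allpoints,
                       register_campaign, simulate_campaign, simulate_scan,
                       subtract_soil)
from tlscanopy.registration import apply_transform, summarize_deviations

soil = SoilPlane(a=0.0, b=0.01)
canopy = SlabCanopy((0.1, 1.9, 0.1, 1.9), height=1.0, ripple=0.05,
                    ripple_wavelength=0.8)
scene = SceneModel(soil=soil, canopies=[canopy],
                   sphere_centers={"S1": (0.1, 0.1, 1.5), "S2": (1.9, 0.1, 1.5),
                                   "S3": (0.1, 1.9, 1.5), "S4": (1.9, 1.9, 1.6)})
spec = ScannerSpec(position=(1.0, -2.5, 3.5), resolution_fraction=1.0,
                   base_angular_step=6e-4, range_noise_sd=0.002,
                   outlier_rate=0.001)

c, s = np.cos(0.7), np.sin(0.7)
poses = {"scan_a": RigidTransform(np.eye(3), np.zeros(3)),
         "scan_b": RigidTransform(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]),
                                  np.array([3.0, -1.0, 0.2]))}
clouds, sphere_obs, _ = simulate_campaign(scene, spec, seed=1, scan_poses=poses,
                                          window=(0, 2, 0, 2),
                                          sphere_center_noise_sd=1e-3)

transforms, deviations = register_campaign(
    sphere_obs, reference=scene.reference_constellation())
mean, sd, n = summarize_deviations(deviations)
print(f"sphere deviation: {mean:.4f} +/- {sd:.4f} m over {n} positions")

fixed = apply_transform(clouds["scan_b"], transforms["scan_b"])
grid = GridSpec.from_extent(0, 2, 0, 2, pixel_size=0.005)
bare, _, _ = simulate_scan(SceneModel(soil=soil),
                           ScannerSpec(position=(1.0, -2.5, 3.5),
                                       resolution_fraction=1.0,
                                       base_angular_step=4.5e-4,
                                       range_noise_sd=1e-3),
                           seed=2, window=(0, 2, 0, 2), include_spheres=False)
soil_map = build_soil_map(bare, grid)

above, _ = subtract_soil(fixed, soil_map)
result = fa_allpoints(above, ROI("plot1", rect=(0.3, 1.7, 0.3, 1.7)))
print(f"FA_ALLPOINTS P99  = {result.height(99):.3f} m  (n = {result.n} points)")
print(f"FA_ALLPOINTS P100 = {result.height(100):.3f} m")
print(f"true surface P99  = {canopy.height_quantile(99):.3f} m")
```

Output:

```
sphere deviation: 0.0006 +/- 0.0003 m over 8 positions
FA_ALLPOINTS P99  = 1.052 m  (n = 375636 points)
FA_ALLPOINTS P100 = 3.022 m
true surface P99  = 1.050 m
```

The sphere deviations bound the registration accuracy at sub-millimeter
level here (field campaigns reach a few millimeters). The P99 canopy height
lands within 2 mm of the true surface quantile, while the raw maximum
(P100) is dragged to 3 m by a single airborne outlier — exactly the failure
mode the percentile filter exists to suppress.

The same workflow is available from the shell via the `tlscanopy` CLI
(`simulate`, `register`, `soil`, `height`, `growth`, `shd`), driven by a
YAML config; see `tlscanopy --help`.

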