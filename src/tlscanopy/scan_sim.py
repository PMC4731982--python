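"""Synthetic TLS scene generator and scanner model.

Every pipeline stage can be exercised against ground truth: the simulator
casts rays from a tripod-mounted scanner position over an angular grid,
returns first intersections with soil, canopy and sphere targets, adds
Gaussian range noise along the ray, and sprinkles sparse airborne outliers
above the canopy — the artifact population the percentile filters exist to
suppress.  Canopy test shapes (uniform slab, hemispherical crowns, layered
leaf disks) have closed-form height-above-soil quantiles so recovered canopy
heights can be checked against truth.

The module also houses the scanner point-spacing model: point spacing grows
linearly with range, spacing(r) = r * (base angular step / resolution
fraction).  At resolution 0.5 the instrument delivers ~0.61 mm spacing at
2 m range and ~3.07 mm at 10 m; at resolution 0.25, ~1.23 mm and ~6.14 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ScanPointCloud, SphereObservationSet
from .registration import ReferenceConstellation, RigidTransform

__all__ = [
    "ScannerSpec",
    "SoilPlane",
    "SlabCanopy",
    "HemisphereCanopy",
    "LayeredCanopy",
    "SceneModel",
    "point_spacing",
    "simulate_scan",
    "simulate_campaign",
    "make_diel_canopy",
    "DielCanopy",
]

SPHERE_RADIUS = 0.0725  # m: the 14.5 cm targets used for maize and soybean
SCANNER_HEIGHT = 3.5  # m: tripod-mounted scanner height


@dataclass(frozen=True)
class ScannerSpec:
    """Scanner position and angular sampling model.

    ``base_angular_step`` is the angular step (radians) at resolution
    fraction 1; the step at fraction f is ``base_angular_step / f``, so
    halving the resolution doubles the point spacing at a given range.
    """

    position: tuple[float, float, float] = (0.0, 0.0, SCANNER_HEIGHT)
    resolution_fraction: float = 0.25
    base_angular_step: float = 1.535e-4  # rad, calibrated from spacing at range
    range_noise_sd: float = 0.002
    outlier_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.resolution_fraction <= 1.0:
            raise ValueError("resolution_fraction must be in (0, 1]")
        if self.base_angular_step <= 0:
            raise ValueError("base_angular_step must be > 0")
        if self.range_noise_sd < 0:
            raise ValueError("range_noise_sd must be >= 0")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")

    @property
    def angular_step(self) -> float:
        return self.base_angular_step / self.resolution_fraction

    @classmethod
    def calibrated(cls, spacing_mm: float, at_range_m: float,
                   resolution_fraction: float, **kwargs) -> "ScannerSpec":
        """Build a spec whose spacing at ``at_range_m`` equals ``spacing_mm``."""
        base = (spacing_mm / 1000.0) / at_range_m * resolution_fraction
        return cls(resolution_fraction=resolution_fraction,
                   base_angular_step=base, **kwargs)


def point_spacing(spec: ScannerSpec, range_m: float) -> float:
    """Point spacing (mm) at a given range; linear in range."""
    if range_m <= 0:
        raise ValueError("range must be > 0")
    return range_m * spec.angular_step * 1000.0


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------

@dataclass
class SoilPlane:
    """Soil surface z = a + b x + c y, optionally with a smooth sinusoidal
    undulation A sin(kx x) sin(ky y)."""

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    amplitude: float = 0.0
    kx: float = 1.0
    ky: float = 1.0
    holes: list[tuple[float, float, float, float]] = field(default_factory=list)

    def z(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        z = self.a + self.b * x + self.c * y
        if self.amplitude:
            z = z + self.amplitude * np.sin(self.kx * x) * np.sin(self.ky * y)
        return z

    def absorbs(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Rays landing in a hole produce no return (e.g. water, tarpaulin)."""
        out = np.zeros(np.shape(x), dtype=bool)
        for x0, x1, y0, y1 in self.holes:
            out |= (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        return out

    def intersect(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Ray parameter t of the soil intersection (NaN where none).

        For the plane part the solution is closed form; the small sinusoidal
        term is handled by a few fixed-point iterations along the ray, which
        converge because the undulation slope is gentle relative to the ray
        inclination.
        """
        denom = self.b * dirs[:, 0] + self.c * dirs[:, 1] - dirs[:, 2]
        num = origin[2] - self.a - self.b * origin[0] - self.c * origin[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / denom
        t = np.where((denom != 0) & (t > 0), t, np.nan)
        if self.amplitude:
            # Newton on f(t) = z_surf - z_ray, using the plane slope denom = f'
            for _ in range(8):
                p = origin + t[:, None] * dirs
                dz = self.z(p[:, 0], p[:, 1]) - p[:, 2]
                with np.errstate(invalid="ignore"):
                    t = t - dz / denom
                t = np.where(t > 0, t, np.nan)
        return t


class _Canopy:
    """Interface: first-hit intersection and closed-form height quantiles."""

    def intersect(self, origin: np.ndarray, dirs: np.ndarray,
                  soil: SoilPlane, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def height_quantile(self, p: float) -> float:
        """True height-above-soil p-th percentile of the canopy top surface."""
        raise NotImplementedError

    @property
    def top_height(self) -> float:
        """Maximum height above soil; sizes the ray grid's zenith range."""
        raise NotImplementedError


@dataclass
class SlabCanopy(_Canopy):
    """Uniform-height canopy block over a rectangular footprint.

    The canopy top sits ``height`` above the local soil; optionally the top
    undulates sinusoidally along x with ``ripple`` amplitude (quantiles then
    follow the arcsine law of a sampled sinusoid).
    """

    footprint: tuple[float, float, float, float]
    height: float
    ripple: float = 0.0
    ripple_wavelength: float = 1.0

    def _top_z(self, x: np.ndarray, y: np.ndarray, soil: SoilPlane) -> np.ndarray:
        top = soil.z(x, y) + self.height
        if self.ripple:
            top = top + self.ripple * np.sin(2 * np.pi * x / self.ripple_wavelength)
        return top

    def intersect(self, origin, dirs, soil, rng):
        # top surface ~ soil plane shifted up by height (+ small ripple):
        # solve against the shifted plane, then fixed-point correct for ripple
        denom = soil.b * dirs[:, 0] + soil.c * dirs[:, 1] - dirs[:, 2]
        num = origin[2] - soil.a - self.height - soil.b * origin[0] - soil.c * origin[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / denom
        t = np.where((denom != 0) & (t > 0), t, np.nan)
        if self.ripple:
            for _ in range(8):
                p = origin + t[:, None] * dirs
                dz = self._top_z(p[:, 0], p[:, 1], soil) - p[:, 2]
                with np.errstate(invalid="ignore"):
                    t = t - dz / denom
                t = np.where(t > 0, t, np.nan)
        p = origin + t[:, None] * dirs
        x0, x1, y0, y1 = self.footprint
        ok = (p[:, 0] >= x0) & (p[:, 0] < x1) & (p[:, 1] >= y0) & (p[:, 1] < y1)
        return np.where(ok, t, np.nan)

    def height_quantile(self, p: float) -> float:
        if not self.ripple:
            return self.height
        # height = H + A sin(u), u uniform: quantile via the sine inverse CDF
        return self.height + self.ripple * math.sin(math.pi * (p / 100.0 - 0.5))

    @property
    def top_height(self) -> float:
        return self.height + abs(self.ripple)


@dataclass
class HemisphereCanopy(_Canopy):
    """Row of hemispherical plant crowns of radius R sitting on the soil.

    The top surface over a crown's disk is z = soil + sqrt(R^2 - r^2); over a
    uniformly sampled disk the height CDF is P(h <= t) = t^2 / R^2, so the
    p-th percentile is R * sqrt(p/100).
    """

    centers: np.ndarray  # (k, 2) crown centers in xy
    radius: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.radius <= 0:
            raise ValueError("crown radius must be > 0")

    def intersect(self, origin, dirs, soil, rng):
        best = np.full(len(dirs), np.nan)
        for cxy in self.centers:
            center = np.array([cxy[0], cxy[1], soil.z(cxy[0], cxy[1])])
            t = _ray_sphere(origin, dirs, center, self.radius)
            p = origin + t[:, None] * dirs
            upper = p[:, 2] >= center[2]  # crown is the upper hemisphere
            t = np.where(upper, t, np.nan)
            best = np.fmin(best, t)
        return best

    def height_quantile(self, p: float) -> float:
        return self.radius * math.sqrt(min(max(p / 100.0, 0.0), 1.0))

    @property
    def top_height(self) -> float:
        return self.radius


@dataclass
class LayeredCanopy(_Canopy):
    """Horizontal leaf layers with partial coverage, for SHD shoulder tests.

    Layer i sits ``layer_heights[i]`` above the soil and intercepts a passing
    ray with probability ``coverages[i]`` (a statistical stand-in for leaf
    disks); uncaught rays continue to the next layer or the soil.  This
    produces a multi-modal scan point height distribution with one shoulder
    per layer.
    """

    footprint: tuple[float, float, float, float]
    layer_heights: Sequence[float]
    coverages: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.layer_heights) != len(self.coverages):
            raise ValueError("one coverage per layer required")
        if any(not 0 < c <= 1 for c in self.coverages):
            raise ValueError("coverages must be in (0, 1]")
        order = np.argsort(self.layer_heights)[::-1]
        self.layer_heights = [float(self.layer_heights[i]) for i in order]
        self.coverages = [float(self.coverages[i]) for i in order]

    def intersect(self, origin, dirs, soil, rng):
        n = len(dirs)
        best = np.full(n, np.nan)
        undecided = np.ones(n, dtype=bool)
        x0, x1, y0, y1 = self.footprint
        for h, cov in zip(self.layer_heights, self.coverages):
            denom = soil.b * dirs[:, 0] + soil.c * dirs[:, 1] - dirs[:, 2]
            num = origin[2] - soil.a - h - soil.b * origin[0] - soil.c * origin[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = num / denom
            t = np.where((denom != 0) & (t > 0), t, np.nan)
            p = origin + t[:, None] * dirs
            ok = ((p[:, 0] >= x0) & (p[:, 0] < x1)
                  & (p[:, 1] >= y0) & (p[:, 1] < y1)
                  & undecided & np.isfinite(t))
            caught = ok & (rng.random(n) < cov)
            best[caught] = t[caught]
            undecided &= ~caught
        return best

    def height_quantile(self, p: float) -> float:
        """Quantile of the layer-height mixture seen by vertical rays."""
        probs = []
        remaining = 1.0
        for cov in self.coverages:  # heights sorted descending
            probs.append(remaining * cov)
            remaining *= 1.0 - cov
        total = sum(probs)
        acc = 0.0
        # mixture over discrete layer heights, highest first
        for h, pr in zip(self.layer_heights, probs):
            acc += pr / total
            if acc >= 1.0 - p / 100.0:
                return h
        return self.layer_heights[-1]

    @property
    def top_height(self) -> float:
        return max(self.layer_heights)


def _ray_sphere(origin: np.ndarray, dirs: np.ndarray, center: np.ndarray,
                radius: float) -> np.ndarray:
    oc = origin - center
    b = dirs @ oc
    c = oc @ oc - radius**2
    disc = b * b - c
    with np.errstate(invalid="ignore"):
        t = -b - np.sqrt(disc)
    return np.where((disc >= 0) & (t > 0), t, np.nan)


@dataclass
class SceneModel:
    """A field scene: soil surface, canopies, and sphere targets."""

    soil: SoilPlane = field(default_factory=SoilPlane)
    canopies: list[_Canopy] = field(default_factory=list)
    sphere_centers: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    sphere_radius: float = SPHERE_RADIUS

    def reference_constellation(self) -> ReferenceConstellation:
        return ReferenceConstellation(
            {k: np.asarray(v, dtype=float) for k, v in self.sphere_centers.items()})

    def true_height_quantile(self, p: float, canopy_index: int = 0) -> float:
        return self.canopies[canopy_index].height_quantile(p)


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def _direction_grid(spec: ScannerSpec, window: tuple[float, float, float, float],
                    ground_z: float, extra_zenith: float = 0.0) -> np.ndarray:
    """Unit ray directions on the angular grid covering a ground window.

    Azimuth/zenith ranges are derived from the window corners seen from the
    scanner; if the scanner stands over the window the full azimuth circle is
    scanned.  ``extra_zenith`` widens the zenith range so elevated targets
    (sphere centers above the canopy) stay in view.
    """
    ox, oy, oz = spec.position
    x0, x1, y0, y1 = window
    step = spec.angular_step
    corners = np.array([[x0, y0], [x0, y1], [x1, y0], [x1, y1]])
    dx = corners[:, 0] - ox
    dy = corners[:, 1] - oy
    dz = ground_z - oz
    if dz >= 0:
        raise ValueError("scanner must be above the scene surface")
    horiz = np.hypot(dx, dy)
    zen = np.arctan2(horiz, -dz)  # zenith angle measured from nadir
    zen_max = max(float(zen.max()), extra_zenith) + 2 * step
    zen_max = min(zen_max, 0.5 * np.pi - 1e-3)  # stay above the horizon
    inside = (x0 <= ox <= x1) and (y0 <= oy <= y1)
    if inside:
        az_lo, az_hi = 0.0, 2 * np.pi
        zen_lo = 0.0
    else:
        az = np.unwrap(np.sort(np.arctan2(dy, dx)))
        az_lo, az_hi = float(az.min()) - 2 * step, float(az.max()) + 2 * step
        zen_lo = max(float(zen.min()) - 2 * step, 0.0)
    n_az = max(int(np.ceil((az_hi - az_lo) / step)), 1)
    n_zen = max(int(np.ceil((zen_max - zen_lo) / step)), 1)
    theta = az_lo + np.arange(n_az) * step
    phi = zen_lo + np.arange(n_zen) * step
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    sin_ph = np.sin(PH)
    dirs = np.column_stack([
        (sin_ph * np.cos(TH)).ravel(),
        (sin_ph * np.sin(TH)).ravel(),
        (-np.cos(PH)).ravel(),
    ])
    return dirs


def simulate_scan(scene: SceneModel, spec: ScannerSpec, seed: int,
                  window: tuple[float, float, float, float] | None = None,
                  scan_id: str = "sim", include_spheres: bool = True,
                  ) -> tuple[ScanPointCloud, SphereObservationSet, dict]:
    """Cast rays through the scene and return the world-frame point cloud.

    Each ray keeps its first (nearest) intersection among soil, canopies and
    sphere targets.  Gaussian range noise of ``spec.range_noise_sd`` acts
    along the ray; with probability ``spec.outlier_rate`` a return is lifted
    by U(0.5, 2) m, emulating the airborne outliers seen above real crop
    canopies.  The cloud is deterministic in ``seed``.

    Returns (cloud in the fixed/world frame, true sphere-center observations,
    ground-truth record).
    """
    rng = np.random.default_rng(seed)
    if window is None:
        xs = [c[0] for c in scene.sphere_centers.values()] or [0.0]
        ys = [c[1] for c in scene.sphere_centers.values()] or [0.0]
        window = (min(xs) - 1, max(xs) + 1, min(ys) - 1, max(ys) + 1)
    origin = np.asarray(spec.position, dtype=float)
    ground_z = float(scene.soil.z(np.array([origin[0]]), np.array([origin[1]]))[0])
    extra_zen = 0.0
    if include_spheres:
        for cx, cy, cz in scene.sphere_centers.values():
            drop = origin[2] - (cz + scene.sphere_radius)
            if drop > 0:
                extra_zen = max(extra_zen, math.atan2(
                    math.hypot(cx - origin[0], cy - origin[1]), drop))
    # elevated canopy tops need steeper rays than the ground window implies
    top = max((c.top_height for c in scene.canopies), default=0.0)
    if top > 0:
        x0, x1, y0, y1 = window
        for cx, cy in ((x0, y0), (x0, y1), (x1, y0), (x1, y1)):
            drop = origin[2] - (float(scene.soil.z(np.array([cx]),
                                                   np.array([cy]))[0]) + top)
            if drop > 0:
                extra_zen = max(extra_zen, math.atan2(
                    math.hypot(cx - origin[0], cy - origin[1]), drop))
    dirs = _direction_grid(spec, window, ground_z, extra_zenith=extra_zen)

    t_best = scene.soil.intersect(origin, dirs)
    # drop soil returns inside absorbing holes
    p = origin + t_best[:, None] * dirs
    with np.errstate(invalid="ignore"):
        absorbed = scene.soil.absorbs(p[:, 0], p[:, 1])
    t_best = np.where(absorbed, np.nan, t_best)

    for canopy in scene.canopies:
        t_c = canopy.intersect(origin, dirs, scene.soil, rng)
        t_best = np.fmin(t_best, t_c)
    if include_spheres:
        for center in scene.sphere_centers.values():
            t_s = _ray_sphere(origin, dirs, np.asarray(center, dtype=float),
                              scene.sphere_radius)
            t_best = np.fmin(t_best, t_s)

    hit = np.isfinite(t_best)
    t_hit = t_best[hit]
    d_hit = dirs[hit]
    if spec.range_noise_sd > 0:
        t_hit = t_hit + rng.normal(0.0, spec.range_noise_sd, size=t_hit.shape)
    pts = origin + t_hit[:, None] * d_hit
    # clip points inside the scan window (rays at the margin can land outside)
    x0, x1, y0, y1 = window
    keep = (pts[:, 0] >= x0) & (pts[:, 0] < x1) & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
    pts = pts[keep]
    if spec.outlier_rate > 0 and len(pts):
        lift = rng.random(len(pts)) < spec.outlier_rate
        pts[lift, 2] += rng.uniform(0.5, 2.0, size=int(lift.sum()))

    cloud = ScanPointCloud(pts, scan_id=scan_id, frame="fixed")
    spheres = SphereObservationSet.from_records(
        [(sid, np.asarray(c, dtype=float), scan_id)
         for sid, c in scene.sphere_centers.items()])
    truth = {
        "soil": scene.soil,
        "sphere_centers": dict(scene.sphere_centers),
        "height_quantile": (scene.canopies[0].height_quantile
                            if scene.canopies else None),
        "n_rays": len(dirs),
    }
    return cloud, spheres, truth


def simulate_campaign(scene: SceneModel, spec: ScannerSpec, seed: int,
                      scan_poses: dict[str, RigidTransform],
                      window: tuple[float, float, float, float] | None = None,
                      sphere_center_noise_sd: float = 0.0,
                      ) -> tuple[dict[str, ScanPointCloud], SphereObservationSet, dict]:
    """Simulate several scans of one scene, each in its own scanner frame.

    ``scan_poses`` maps scan_id to the rigid motion taking that scan's local
    frame into the world frame; emitted clouds and sphere observations are
    expressed in the local (scanner) frame, ready for registration.  Optional
    Gaussian noise on the observed sphere centers emulates target-detection
    error.
    """
    rng = np.random.default_rng(seed)
    clouds: dict[str, ScanPointCloud] = {}
    rows = []
    truth: dict = {}
    for i, (scan_id, pose) in enumerate(scan_poses.items()):
        world, spheres, truth = simulate_scan(
            scene, spec, seed=int(rng.integers(2**31)), window=window,
            scan_id=scan_id)
        inv = pose.inverse()
        clouds[scan_id] = ScanPointCloud(inv.apply(world.points),
                                         scan_id=scan_id, frame="scanner")
        centers = spheres.table[["x", "y", "z"]].to_numpy(dtype=float)
        local = inv.apply(centers)
        if sphere_center_noise_sd > 0:
            local = local + rng.normal(0.0, sphere_center_noise_sd, size=local.shape)
        obs = spheres.table.copy()
        obs[["x", "y", "z"]] = local
        rows.append(obs)
    all_obs = SphereObservationSet(pd.concat(rows, ignore_index=True))
    return clouds, all_obs, truth


# ---------------------------------------------------------------------------
# diel canopy dynamics
# ---------------------------------------------------------------------------

@dataclass
class DielCanopy:
    """Time-indexed canopy: base height + integrated growth - leaf movement.

    Leaf movement is a reversible depression of the canopy top (leaves hang
    lower outside their most horizontal orientation); differencing two
    measurements therefore mixes movement and growth unless the measurements
    share a time of day.
    """

    base_height: float
    growth_rate: Callable[[float], float]  # mm/h as a function of hour
    movement: Callable[[float], float]  # m depression as a function of hour
    footprint: tuple[float, float, float, float] = (-2.0, 2.0, -2.0, 2.0)

    def true_height(self, t_hours: float) -> float:
        from scipy.integrate import quad
        grown, _ = quad(self.growth_rate, 0.0, t_hours, limit=200)
        return self.base_height + grown / 1000.0 - self.movement(t_hours)

    def scene_at(self, t_hours: float,
                 spheres: dict[str, tuple[float, float, float]] | None = None,
                 soil: SoilPlane | None = None) -> SceneModel:
        canopy = SlabCanopy(self.footprint, self.true_height(t_hours))
        return SceneModel(soil=soil or SoilPlane(), canopies=[canopy],
                          sphere_centers=spheres or {})


def make_diel_canopy(base_height: float,
                     growth_rate: float | Callable[[float], float] = 0.0,
                     movement_amplitude: float = 0.0,
                     movement_peak_hour: float = 14.0,
                     footprint: tuple[float, float, float, float] = (-2, 2, -2, 2),
                     ) -> DielCanopy:
    """Diel canopy with constant or time-varying growth and sinusoidal leaf
    movement.

    The depression term is ``A/2 * (1 - cos(2 pi (t - peak)/24))``: zero at
    ``movement_peak_hour`` (leaves most horizontal, canopy highest) and A at
    the opposite phase — the soybean pattern of rising canopy height from
    morning to afternoon and a decline toward the evening.
    """
    if callable(growth_rate):
        rate = growth_rate
    else:
        rate = lambda t, g=float(growth_rate): g

    def movement(t: float) -> float:
        return movement_amplitude / 2.0 * (
            1.0 - math.cos(2.0 * math.pi * (t - movement_peak_hour) / 24.0))

    return DielCanopy(base_height, rate, movement, footprint)
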