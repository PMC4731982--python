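"""Per-ROI canopy statistics: filtering approaches, growth rates, SHDs.

Three filtering approaches turn a height-above-soil point cloud into one
canopy height per region of interest (ROI):

* ``FA_ALLPOINTS`` — percentiles of the z-values of every point in the ROI.
* ``FA_MEDIANMAX`` — weighted median over patches of the per-patch maximum of
  the plant height map, weight = plant-pixel count N per patch.
* ``FA_MEDIANP99`` — the same with the per-patch 99th percentile.

The 99th percentile (P99) suppresses sparse airborne outliers that would
dominate the maximum while still tracking the canopy top.  Growth rates are
height differences between dated measurements in mm/h; the scan point height
distribution (SHD) is a histogram of plant-point heights whose local maxima
("shoulders") mark organ levels such as leaves and ears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from shapely.geometry import Polygon
from shapely import contains_xy

from .io_formats import ScanPointCloud
from .surface_maps import DEFAULT_PLANT_THRESHOLD, HeightMap

__all__ = [
    "ROI",
    "ROIResult",
    "SHD",
    "GrowthSeries",
    "fa_allpoints",
    "fa_patchwise",
    "weighted_median",
    "canopy_growth",
    "compute_shd",
    "detect_shd_peaks",
    "regress_reference",
    "make_roi_grid",
]

DEFAULT_PERCENTILES = tuple(range(90, 101))
DEFAULT_PATCH = (0.10, 0.10)  # m; maize variant: 0.15 m along row x row width


@dataclass
class ROI:
    """A rectangular or polygonal region of interest.

    Rectangles are given as (x_min, x_max, y_min, y_max) in meters;
    ``row_direction`` (unit 2-vector) orients row-aligned patch tilings.
    """

    roi_id: str
    rect: tuple[float, float, float, float] | None = None
    polygon: Polygon | None = None
    row_direction: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.polygon is None):
            raise ValueError("give exactly one of rect or polygon")
        if self.rect is not None:
            x0, x1, y0, y1 = self.rect
            if x1 <= x0 or y1 <= y0:
                raise ValueError(f"ROI {self.roi_id!r} has non-positive area")
        elif self.polygon.area <= 0:
            raise ValueError(f"ROI {self.roi_id!r} has non-positive area")
        if self.row_direction is not None:
            v = np.asarray(self.row_direction, dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError("row_direction must be a nonzero vector")
            self.row_direction = tuple(v / n)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max)."""
        if self.rect is not None:
            return self.rect
        x0, y0, x1, y1 = self.polygon.bounds
        return (x0, x1, y0, y1)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.rect is not None:
            x0, x1, y0, y1 = self.rect
            return ((xy[:, 0] >= x0) & (xy[:, 0] < x1)
                    & (xy[:, 1] >= y0) & (xy[:, 1] < y1))
        return contains_xy(self.polygon, xy[:, 0], xy[:, 1])


@dataclass
class ROIResult:
    """Canopy-height percentile profile of one ROI under one approach."""

    roi_id: str
    approach: str  # FA_ALLPOINTS | FA_MEDIANMAX | FA_MEDIANP99
    percentile_profile: dict[int, float]
    n: int  # points (FA_ALLPOINTS) or plant pixels (patchwise)
    timestamp: datetime | None = None

    @property
    def is_nodata(self) -> bool:
        return self.n == 0

    def height(self, percentile: int = 99) -> float:
        return self.percentile_profile.get(percentile, np.nan)

    def to_rows(self) -> list[dict]:
        return [{"roi_id": self.roi_id, "timestamp": self.timestamp,
                 "approach": self.approach, "percentile": p, "height_m": h,
                 "n": self.n}
                for p, h in sorted(self.percentile_profile.items())]


@dataclass
class SHD:
    """Scan point height distribution: histogram of plant-point heights."""

    bin_edges: np.ndarray
    counts: np.ndarray
    roi_id: str = ""
    detected_peaks: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/edges length mismatch")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "count": self.counts})


@dataclass
class GrowthSeries:
    """Dated canopy heights for one ROI and the rates between them (mm/h)."""

    roi_id: str
    timestamps: list[datetime]
    heights: list[float]
    rates_mm_per_h: list[float]
    pair_indices: list[tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), r in zip(self.pair_indices, self.rates_mm_per_h):
            rows.append({"roi_id": self.roi_id, "t_start": self.timestamps[i],
                         "t_end": self.timestamps[j], "h_start_m": self.heights[i],
                         "h_end_m": self.heights[j], "rate_mm_per_h": r})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# filtering approaches
# ---------------------------------------------------------------------------

def fa_allpoints(cloud_above_soil: ScanPointCloud, roi: ROI,
                 percentiles: Sequence[int] = DEFAULT_PERCENTILES,
                 timestamp: datetime | None = None) -> ROIResult:
    """Percentiles of ALL points in the ROI (no plant threshold)."""
    mask = roi.contains(cloud_above_soil.xy)
    z = cloud_above_soil.z[mask]
    if z.size == 0:
        profile = {int(p): np.nan for p in percentiles}
        return ROIResult(roi.roi_id, "FA_ALLPOINTS", profile, 0, timestamp)
    vals = np.percentile(z, list(percentiles))
    profile = {int(p): float(v) for p, v in zip(percentiles, vals)}
    return ROIResult(roi.roi_id, "FA_ALLPOINTS", profile, int(z.size), timestamp)


def weighted_median(values: Sequence[float], weights: Sequence[int]) -> float:
    """Median of the list in which value i is repeated weights[i] times.

    Computed by cumulative weights without materializing the expansion.  With
    an even total weight the mean of the two middle elements is returned.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights)
    if v.size == 0:
        raise ValueError("weighted_median of empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if not np.issubdtype(w.dtype, np.integer):
        if not np.all(w == np.floor(w)):
            raise ValueError("weights must be integers")
        w = w.astype(np.int64)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    total = cum[-1]
    if total % 2 == 1:
        k = (total + 1) // 2  # 1-based position of the middle element
        return float(v[np.searchsorted(cum, k)])
    lo = float(v[np.searchsorted(cum, total // 2)])
    hi = float(v[np.searchsorted(cum, total // 2 + 1)])
    return 0.5 * (lo + hi)


def _patch_tiling(roi: ROI, patch_size: tuple[float, float]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Patch edges anchored at the ROI's lower-left corner (axis-aligned)."""
    x0, x1, y0, y1 = roi.bounds
    pw, ph = patch_size
    if pw <= 0 or ph <= 0:
        raise ValueError("patch sizes must be positive")
    xs = np.arange(x0, x1, pw)
    ys = np.arange(y0, y1, ph)
    return xs, ys, np.minimum(xs + pw, x1), np.minimum(ys + ph, y1), pw, ph


def fa_patchwise(plant_map: HeightMap, roi: ROI,
                 patch_size: tuple[float, float] = DEFAULT_PATCH,
                 patch_statistic: str | float = "max",
                 timestamp: datetime | None = None,
                 percentiles: Sequence[int] = DEFAULT_PERCENTILES) -> ROIResult:
    """Weighted median over patches of a per-patch statistic of H_P.

    The ROI is tiled into patches anchored at its lower-left corner (partial
    edge patches keep their smaller weight).  Per patch, the statistic of the
    plant-pixel heights is weighted by the plant-pixel count N, so densely
    covered patches dominate the ROI's weighted median.  ``patch_statistic``
    "max" labels the result FA_MEDIANMAX, a percentile labels it
    FA_MEDIANP99-style; the profile entries vary the per-patch percentile
    (P100 being the maximum).
    """
    if plant_map.role != "plant":
        raise ValueError("fa_patchwise needs a plant-role height map")
    if isinstance(patch_statistic, str) and patch_statistic != "max":
        raise ValueError(f"unknown patch statistic {patch_statistic!r}")

    grid = plant_map.grid
    xc, yc = grid.pixel_centers()
    xx, yy = np.meshgrid(xc, yc)
    in_roi = roi.contains(np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    valid = in_roi & ~plant_map.mask
    px, py = xx[valid], yy[valid]
    pz = plant_map.values[valid]

    approach = "FA_MEDIANMAX" if patch_statistic == "max" else (
        "FA_MEDIANP99" if float(patch_statistic) == 99 else
        f"FA_MEDIANP{float(patch_statistic):g}")
    if pz.size == 0:
        profile = {int(p): np.nan for p in percentiles}
        return ROIResult(roi.roi_id, approach, profile, 0, timestamp)

    x0, _, y0, _ = roi.bounds
    pw, ph = patch_size
    ix = np.floor((px - x0) / pw).astype(np.int64)
    iy = np.floor((py - y0) / ph).astype(np.int64)
    key = ix * (iy.max() + 1) + iy
    order = np.argsort(key, kind="stable")
    key_s, z_s = key[order], pz[order]
    starts = np.flatnonzero(np.r_[True, np.diff(key_s) > 0])
    bounds = np.r_[starts, key_s.size]

    groups = [z_s[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    weights = [len(g) for g in groups]

    def _roi_value(stat) -> float:
        if stat == "max":
            vals = [g.max() for g in groups]
        else:
            vals = [float(np.percentile(g, float(stat))) for g in groups]
        return weighted_median(vals, weights)

    profile = {}
    for p in percentiles:
        profile[int(p)] = _roi_value("max" if p == 100 else p)
    # headline statistic may sit outside the profile grid (e.g. "max")
    if patch_statistic == "max":
        profile[100] = _roi_value("max")
    else:
        profile[int(float(patch_statistic))] = _roi_value(patch_statistic)
    return ROIResult(roi.roi_id, approach, profile, int(pz.size), timestamp)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def canopy_growth(timestamps: Sequence[datetime], heights: Sequence[float],
                  roi_id: str = "", mode: str = "consecutive",
                  hour_tolerance: float = 1.0) -> GrowthSeries:
    """Height growth rates (mm/h) between dated canopy heights.

    ``mode="consecutive"`` differences successive measurements (suited to
    maize, which shows only slight leaf movement).  ``mode="same_hour"``
    pairs each measurement with the next one taken at the same time of day
    (within ``hour_tolerance`` hours) on a later day — the once-per-day
    scheme needed for soybean, whose diel leaf movement otherwise confounds
    apparent height change with true growth.  Rates may be negative (leaf
    lowering); nothing is clipped.
    """
    ts = list(timestamps)
    hs = [float(h) for h in heights]
    if len(ts) != len(hs):
        raise ValueError("timestamps and heights must have equal length")
    if len(ts) < 2:
        raise ValueError("growth needs >= 2 dated heights")
    if any(t1 >= t2 for t1, t2 in zip(ts, ts[1:])):
        raise ValueError("timestamps must be strictly increasing")
    if mode == "consecutive":
        pairs = [(i, i + 1) for i in range(len(ts) - 1)]
    elif mode == "same_hour":
        pairs = []
        for i, t in enumerate(ts):
            for j in range(i + 1, len(ts)):
                dt_h = (ts[j] - t).total_seconds() / 3600.0
                if dt_h < 12.0:
                    continue
                # offset from a whole number of days, in hours
                off = abs((dt_h + 12.0) % 24.0 - 12.0)
                if off <= hour_tolerance:
                    pairs.append((i, j))
                    break
        if not pairs:
            raise ValueError("no same-hour pairs found within tolerance")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rates = []
    for i, j in pairs:
        dt_h = (ts[j] - ts[i]).total_seconds() / 3600.0
        rates.append(1000.0 * (hs[j] - hs[i]) / dt_h)
    return GrowthSeries(roi_id, ts, hs, rates, pairs)


# ---------------------------------------------------------------------------
# scan point height distribution
# ---------------------------------------------------------------------------

def compute_shd(cloud_above_soil: ScanPointCloud, roi: ROI, bin_width: float,
                plant_threshold: float = DEFAULT_PLANT_THRESHOLD) -> SHD:
    """Histogram of plant-point heights (z > threshold) within the ROI.

    Bin edges are aligned to multiples of ``bin_width`` from zero, with one
    empty guard bin at each end so that shoulders at the extremes of the
    height range register as local maxima; counts sum to the ROI's
    plant-point total.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mask = roi.contains(cloud_above_soil.xy)
    z = cloud_above_soil.z[mask]
    z = z[z > plant_threshold]
    lo = (np.floor(plant_threshold / bin_width) - 1) * bin_width
    hi = ((np.ceil(z.max() / bin_width) + 1) * bin_width if z.size
          else lo + 3 * bin_width)
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(z, bins=edges)
    return SHD(edges, counts, roi_id=roi.roi_id)


def detect_shd_peaks(shd: SHD, smoothing_window: int = 3,
                     min_prominence: float = 0.02) -> list[float]:
    """Local maxima ("shoulders") of the smoothed SHD.

    Counts are smoothed by a centered moving average of ``smoothing_window``
    bins; peaks must exceed a prominence of ``min_prominence`` times the
    smoothed maximum.  Peak heights (bin centers, meters) are returned in
    descending order; interior plateaus count once.  An empty list is a valid
    outcome (flat or empty histogram).
    """
    counts = shd.counts.astype(float)
    if counts.size == 0 or counts.max() == 0:
        return []
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        padded = np.pad(counts, pad, mode="edge")  # keeps flat input flat
        counts = np.convolve(padded, kernel, mode="valid")[:counts.size]
    prominence = min_prominence * counts.max()
    idx, _ = signal.find_peaks(counts, prominence=prominence)
    peaks = sorted((float(c) for c in shd.bin_centers[idx]), reverse=True)
    shd.detected_peaks = peaks
    return peaks


# ---------------------------------------------------------------------------
# reference regression and ROI grids
# ---------------------------------------------------------------------------

def regress_reference(tls_heights: Sequence[float], reference_heights: Sequence[float]
                      ) -> tuple[float, float, float]:
    """OLS of TLS-derived on manually measured canopy height.

    Returns (slope, intercept, r_squared); with zero variance in either
    variable the fit is undefined and all three are NaN.
    """
    y = np.asarray(tls_heights, dtype=float)
    x = np.asarray(reference_heights, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("heights must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (np.nan, np.nan, np.nan)
    fit = stats.linregress(x, y)
    return (float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2))


def make_roi_grid(extent: tuple[float, float, float, float],
                  plot_size: tuple[float, float],
                  border_exclusion: float = 0.0) -> list[ROI]:
    """Grid of plot ROIs over a field extent, shrunk to exclude border rows.

    ``extent`` is (x_min, x_max, y_min, y_max); ``plot_size`` is the plot
    footprint (width, height).  The grid holds floor(extent / plot) plots per
    axis; each ROI is the plot shrunk by ``border_exclusion`` on every side.
    """
    x0, x1, y0, y1 = extent
    pw, ph = plot_size
    if pw <= 0 or ph <= 0:
        raise ValueError("plot sizes must be positive")
    if border_exclusion < 0:
        raise ValueError("border_exclusion must be >= 0")
    if 2 * border_exclusion >= min(pw, ph):
        raise ValueError("border exclusion leaves no plot interior")
    nx = int(np.floor((x1 - x0) / pw))
    ny = int(np.floor((y1 - y0) / ph))
    rois = []
    for j in range(ny):
        for i in range(nx):
            bx0 = x0 + i * pw + border_exclusion
            by0 = y0 + j * ph + border_exclusion
            rois.append(ROI(
                roi_id=f"plot_{i:02d}_{j:02d}",
                rect=(bx0, x0 + (i + 1) * pw - border_exclusion,
                      by0, y0 + (j + 1) * ph - border_exclusion)))
    return rois
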