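from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlscanopy import (GridSpec, HeightMap, ROI, ScanPointCloud, canopy_growth,
                       compute_shd, detect_shd_peaks, fa_allpoints,
                       fa_patchwise, make_roi_grid, regress_reference,
                       weighted_median)


def cloud_at(xy, z):
    pts = np.column_stack([np.atleast_2d(xy), np.asarray(z, dtype=float)])
    return ScanPointCloud(pts, frame="fixed")


def expansion_median(values, weights):
    """Brute-force oracle: repeat each value weight times, take the median."""
    expanded = np.repeat(np.asarray(values, dtype=float), weights)
    return float(np.median(expanded))


class TestFaAllpoints:
    ROI1 = ROI("r1", rect=(0.0, 1.0, 0.0, 1.0))

    def test_constant_heights(self, rng):
        xy = rng.uniform(0, 1, size=(50, 2))
        res = fa_allpoints(cloud_at(xy, np.full(50, 0.8)), self.ROI1)
        assert res.n == 50
        assert all(v == pytest.approx(0.8) for v in res.percentile_profile.values())

    def test_matches_sort_based_oracle(self):
        z = np.arange(1, 101) / 100.0  # 0.01 .. 1.00
        xy = np.column_stack([np.linspace(0.05, 0.95, 100)] * 2)
        res = fa_allpoints(cloud_at(xy, z), self.ROI1)
        assert res.height(100) == pytest.approx(1.00)
        for p in (90, 99):
            s = np.sort(z)
            rank = p / 100 * (len(s) - 1)
            lo = int(np.floor(rank))
            oracle = s[lo] + (rank - lo) * (s[min(lo + 1, 99)] - s[lo])
            assert res.height(p) == pytest.approx(oracle, abs=1e-12)

    def test_p100_catches_outlier_but_p99_robust(self, rng):
        z = np.concatenate([rng.uniform(0.5, 1.0, size=999), [5.0]])
        xy = rng.uniform(0, 1, size=(1000, 2))
        res = fa_allpoints(cloud_at(xy, z), self.ROI1)
        assert res.height(100) == pytest.approx(5.0)
        assert res.height(99) <= 1.0

    def test_no_plant_threshold_applied(self):
        """FA_ALLPOINTS literally uses every point, including below 10 cm."""
        xy = np.full((4, 2), 0.5)
        res = fa_allpoints(cloud_at(xy, [0.01, 0.02, 0.03, 0.04]), self.ROI1,
                           percentiles=[100])
        assert res.n == 4 and res.height(100) == pytest.approx(0.04)

    def test_empty_roi_gives_nodata(self):
        res = fa_allpoints(cloud_at([[5.0, 5.0]], [1.0]), self.ROI1)
        assert res.is_nodata and np.isnan(res.height(99))

    def test_profile_nondecreasing(self, rng):
        xy = rng.uniform(0, 1, size=(2000, 2))
        res = fa_allpoints(cloud_at(xy, rng.exponential(0.3, 2000)), self.ROI1)
        profile = [res.height(p) for p in range(90, 101)]
        assert all(a <= b + 1e-12 for a, b in zip(profile, profile[1:]))


class TestWeightedMedian:
    @pytest.mark.parametrize("values,weights,expected", [
        ([5.0], [7], 5.0),
        ([1.0, 2.0, 3.0], [1, 1, 3], 3.0),
        ([1.0, 2.0], [1, 1], 1.5),
        ([3.0, 1.0, 2.0], [3, 1, 1], 3.0),  # order-independent
    ])
    def test_known_cases(self, values, weights, expected):
        assert weighted_median(values, weights) == expected
        assert expansion_median(values, weights) == expected

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.integers(1, 20)),
                    min_size=1, max_size=30))
    def test_equals_expansion_oracle(self, pairs):
        values = [v for v, _ in pairs]
        weights = [w for _, w in pairs]
        assert weighted_median(values, weights) == expansion_median(values, weights)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            weighted_median([], [])
        with pytest.raises(ValueError):
            weighted_median([1.0], [0])
        with pytest.raises(ValueError):
            weighted_median([1.0], [1.5])


def plant_map_from_pixels(pixel_values, pixel_size=0.05):
    """Build a plant HeightMap directly from a 2D array (NaN = no plants)."""
    vals = np.asarray(pixel_values, dtype=float)
    grid = GridSpec((0.0, 0.0), pixel_size, vals.shape[1], vals.shape[0])
    return HeightMap(grid, vals, role="plant")


class TestFaPatchwise:
    def test_single_patch_equals_patch_statistic(self):
        hmap = plant_map_from_pixels([[1.0, 2.0], [0.5, 3.0]])
        roi = ROI("r", rect=(0.0, 0.1, 0.0, 0.1))
        res = fa_patchwise(hmap, roi, patch_size=(0.1, 0.1), patch_statistic="max")
        assert res.approach == "FA_MEDIANMAX"
        assert res.height(100) == pytest.approx(3.0)
        assert res.n == 4

    def test_weighted_median_of_patch_maxima(self):
        # three 1-pixel-wide columns of patches with plant counts 1, 1, 3
        vals = np.full((3, 3), np.nan)
        vals[0, 0] = 1.0          # patch 0: N=1, max 1.0
        vals[0, 1] = 2.0          # patch 1: N=1, max 2.0
        vals[:, 2] = [3.0, 2.5, 2.0]  # patch 2: N=3, max 3.0
        hmap = plant_map_from_pixels(vals)
        roi = ROI("r", rect=(0.0, 0.15, 0.0, 0.15))
        res = fa_patchwise(hmap, roi, patch_size=(0.05, 0.15),
                           patch_statistic="max")
        # expansion oracle: {1, 2, 3, 3, 3} -> median 3
        assert res.height(100) == pytest.approx(3.0)

    def test_even_weight_tie_takes_mean_of_middles(self):
        vals = np.full((1, 2), np.nan)
        vals[0, 0], vals[0, 1] = 1.0, 2.0
        hmap = plant_map_from_pixels(vals)
        roi = ROI("r", rect=(0.0, 0.1, 0.0, 0.05))
        res = fa_patchwise(hmap, roi, patch_size=(0.05, 0.05),
                           patch_statistic="max")
        assert res.height(100) == pytest.approx(1.5)

    def test_medianmax_dominates_medianp99(self, rng):
        vals = rng.uniform(0.5, 2.0, size=(40, 40))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        hmap = plant_map_from_pixels(vals, pixel_size=0.005)
        roi = ROI("r", rect=(0.0, 0.2, 0.0, 0.2))
        rmax = fa_patchwise(hmap, roi, patch_statistic="max")
        rp99 = fa_patchwise(hmap, roi, patch_statistic=99.0)
        assert rmax.height(100) >= rp99.height(99) - 1e-12

    def test_zero_plant_pixels_gives_nodata(self):
        hmap = plant_map_from_pixels(np.full((4, 4), np.nan))
        roi = ROI("r", rect=(0.0, 0.2, 0.0, 0.2))
        res = fa_patchwise(hmap, roi)
        assert res.is_nodata

    def test_profile_nondecreasing(self, rng):
        vals = rng.uniform(0.5, 2.0, size=(40, 40))
        hmap = plant_map_from_pixels(vals, pixel_size=0.005)
        roi = ROI("r", rect=(0.0, 0.2, 0.0, 0.2))
        res = fa_patchwise(hmap, roi, patch_statistic=99.0)
        profile = [res.height(p) for p in range(90, 101)]
        assert all(a <= b + 1e-12 for a, b in zip(profile, profile[1:]))


class TestCanopyGrowth:
    T0 = datetime(2014, 6, 21, 6, 0)

    def test_no_change_is_zero_rate(self):
        ts = [self.T0, self.T0 + timedelta(hours=24)]
        series = canopy_growth(ts, [1.0, 1.0])
        assert series.rates_mm_per_h == [0.0]

    def test_24mm_over_24h_is_1mm_per_h(self):
        ts = [self.T0, self.T0 + timedelta(hours=24)]
        series = canopy_growth(ts, [1.000, 1.024])
        assert series.rates_mm_per_h[0] == pytest.approx(1.0)

    def test_three_scans_per_day_bookkeeping(self):
        ts = [self.T0, self.T0.replace(hour=13), self.T0.replace(hour=19)]
        series = canopy_growth(ts, [1.0, 1.007, 1.013])
        assert len(series.rates_mm_per_h) == 2
        assert series.rates_mm_per_h[0] == pytest.approx(1.0)  # 7 mm / 7 h
        assert series.rates_mm_per_h[1] == pytest.approx(1.0)  # 6 mm / 6 h

    def test_negative_growth_not_clipped(self):
        ts = [self.T0.replace(hour=15), self.T0.replace(hour=21)]
        series = canopy_growth(ts, [1.05, 1.02])
        assert series.rates_mm_per_h[0] == pytest.approx(-5.0)

    def test_same_hour_mode_pairs_across_days(self):
        hours = [8, 15, 21, 32, 39, 45]  # two days, three scans each
        ts = [self.T0 + timedelta(hours=h) for h in hours]
        heights = [1.0, 1.05, 1.02, 1.024, 1.074, 1.044]
        series = canopy_growth(ts, heights, mode="same_hour")
        assert series.pair_indices == [(0, 3), (1, 4), (2, 5)]
        assert series.rates_mm_per_h == pytest.approx([1.0, 1.0, 1.0])

    def test_non_monotonic_timestamps_raise(self):
        ts = [self.T0, self.T0]
        with pytest.raises(ValueError, match="increasing"):
            canopy_growth(ts, [1.0, 1.0])


class TestSHD:
    ROI1 = ROI("r1", rect=(0.0, 1.0, 0.0, 1.0))

    def test_single_height_single_bin(self, rng):
        xy = rng.uniform(0, 1, size=(100, 2))
        shd = compute_shd(cloud_at(xy, np.full(100, 1.00)), self.ROI1,
                          bin_width=0.05)
        assert shd.counts.sum() == 100
        assert (shd.counts > 0).sum() == 1

    def test_counts_conserve_plant_points(self, rng):
        xy = rng.uniform(0, 1, size=(500, 2))
        z = rng.uniform(0.0, 2.0, size=500)
        shd = compute_shd(cloud_at(xy, z), self.ROI1, bin_width=0.05)
        assert shd.counts.sum() == (z > 0.10).sum()

    def test_no_plant_points_gives_zero_histogram(self, rng):
        xy = rng.uniform(0, 1, size=(50, 2))
        shd = compute_shd(cloud_at(xy, np.full(50, 0.05)), self.ROI1,
                          bin_width=0.05)
        assert shd.counts.sum() == 0
        assert detect_shd_peaks(shd) == []

    def test_unimodal_histogram_one_peak(self, rng):
        xy = rng.uniform(0, 1, size=(5000, 2))
        z = rng.normal(1.2, 0.08, size=5000)
        shd = compute_shd(cloud_at(xy, z), self.ROI1, bin_width=0.05)
        peaks = detect_shd_peaks(shd)
        assert len(peaks) == 1
        assert abs(peaks[0] - 1.2) <= 0.05

    def test_flat_histogram_no_peaks(self):
        from tlscanopy.canopy_stats import SHD
        shd = SHD(np.arange(0, 1.05, 0.05), np.full(20, 37))
        assert detect_shd_peaks(shd) == []

    def test_three_layer_canopy_three_peaks(self, rng):
        """Leaf layers at 0.8, 1.3 and 1.8 m appear as three shoulders."""
        layers = [0.8, 1.3, 1.8]
        z = np.concatenate([rng.normal(h, 0.02, size=2000) for h in layers])
        xy = rng.uniform(0, 1, size=(len(z), 2))
        shd = compute_shd(cloud_at(xy, z), self.ROI1, bin_width=0.05)
        peaks = detect_shd_peaks(shd)
        assert len(peaks) == 3
        for found, true in zip(peaks, sorted(layers, reverse=True)):
            assert abs(found - true) <= 0.05


class TestRegression:
    def test_identity_line(self):
        x = [0.5, 1.0, 1.5, 2.0]
        slope, intercept, r2 = regress_reference(x, x)
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine_line(self):
        x = np.array([0.5, 1.0, 1.5, 2.0])
        slope, intercept, r2 = regress_reference(2 * x + 1, x)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_pearson_oracle(self, rng):
        ref = rng.uniform(0.5, 2.0, size=50)
        tls = 0.95 * ref + rng.normal(0, 0.05, size=50)
        _, _, r2 = regress_reference(tls, ref)
        oracle = np.corrcoef(tls, ref)[0, 1] ** 2
        assert r2 == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        slope, intercept, r2 = regress_reference([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(r2)


class TestRoiGrid:
    def test_wheat_field_grid_skeleton(self):
        """A 24 m x 24 m field tiled by 1.5 m x 1.7 m plots holds a 16 x 14
        grid before exclusions."""
        rois = make_roi_grid((0, 24, 0, 24), (1.5, 1.7))
        assert len(rois) == 16 * 14

    def test_zero_exclusion_tiles_exactly(self):
        rois = make_roi_grid((0, 3, 0, 2), (1.5, 1.0))
        assert len(rois) == 2 * 2
        x0, x1, y0, y1 = rois[0].bounds
        assert (x0, x1, y0, y1) == (0.0, 1.5, 0.0, 1.0)
        last = rois[-1].bounds
        assert last == (1.5, 3.0, 1.0, 2.0)

    def test_excessive_exclusion_raises(self):
        with pytest.raises(ValueError, match="exclusion"):
            make_roi_grid((0, 24, 0, 24), (1.5, 1.7), border_exclusion=0.75)

    def test_exclusion_shrinks_each_plot(self):
        rois = make_roi_grid((0, 3, 0, 3), (1.5, 1.5), border_exclusion=0.25)
        x0, x1, y0, y1 = rois[0].bounds
        assert (x0, x1, y0, y1) == (0.25, 1.25, 0.25, 1.25)


class TestRoiGeometry:
    def test_polygon_roi_contains(self):
        from shapely.geometry import Polygon
        roi = ROI("tri", polygon=Polygon([(0, 0), (2, 0), (0, 2)]))
        inside = roi.contains(np.array([[0.5, 0.5], [1.9, 1.9]]))
        assert inside.tolist() == [True, False]

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            ROI("bad", rect=(1.0, 1.0, 0.0, 2.0))
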