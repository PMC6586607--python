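"""Cover regression, binary classification, umbra masking, carbon budget."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from umbraflux.rasters import (
    CoverRaster,
    UmbraTrack,
    read_ascii_grid,
    read_umbra_geojson,
    write_ascii_grid,
    write_umbra_geojson,
)
from umbraflux.upscale import (
    ScalingScenario,
    carbon_budget,
    classify_sagebrush,
    leaf_area_bounds,
    mask_umbra,
    regress_cover,
)


def _raster(values, pixel=30.0):
    return CoverRaster(np.asarray(values, dtype=float), pixel, (0.0, 0.0))


def _track(centers, radius, start=datetime(2017, 8, 21, 10, 30)):
    times = [start + timedelta(minutes=i) for i in range(len(centers))]
    return UmbraTrack(times=times, centers=np.asarray(centers), radius_m=radius)


class TestRegressCover:
    def test_identity_aggregation(self):
        rng = np.random.default_rng(0)
        fine = _raster(rng.random((12, 12)) * 0.8, pixel=30.0)
        agg = fine.values.reshape(4, 3, 4, 3).transpose(0, 2, 1, 3).reshape(4, 4, 9)
        coarse = CoverRaster(agg.mean(axis=2), 90.0, (0.0, 0.0))
        reg = regress_cover(coarse, fine)
        assert reg.slope == pytest.approx(1.0, rel=1e-9)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r2 == pytest.approx(1.0)

    def test_all_nodata_block_dropped(self):
        rng = np.random.default_rng(1)
        vals = rng.random((12, 12)) * 0.8
        vals[0:3, 0:3] = np.nan  # one coarse footprint fully invalid
        fine = _raster(vals)
        coarse = _raster(rng.random((4, 4)) * 0.8, pixel=90.0)
        reg = regress_cover(coarse, fine)
        assert reg.n == 15

    def test_f_statistic_consistent_with_r2(self):
        rng = np.random.default_rng(2)
        fine = _raster(rng.random((30, 30)) * 0.9)
        agg = fine.values.reshape(10, 3, 10, 3).transpose(0, 2, 1, 3).reshape(10, 10, 9)
        coarse_vals = np.clip(
            0.8 * agg.mean(axis=2) + 0.05 + rng.normal(0, 0.05, (10, 10)), 0, 1
        )
        coarse = CoverRaster(coarse_vals, 90.0, (0.0, 0.0))
        reg = regress_cover(coarse, fine)
        expected_f = (reg.n - 2) * reg.r2 / (1 - reg.r2)
        assert reg.f_stat == pytest.approx(expected_f, rel=1e-6)

    def test_too_few_pixels_rejected(self):
        fine = _raster(np.full((3, 3), np.nan))
        coarse = _raster([[0.5]], pixel=90.0)
        with pytest.raises(ValueError, match="3"):
            regress_cover(coarse, fine)


class TestClassifySagebrush:
    def test_threshold_is_inclusive(self):
        fine = _raster([[0.5, 0.49], [0.6, np.nan]])
        out = classify_sagebrush(fine, 0.5)
        assert out.values[0, 0] == 1.0  # exactly at threshold: included
        assert out.values[0, 1] == 0.0
        assert out.values[1, 0] == 1.0
        assert np.isnan(out.values[1, 1])  # nodata preserved

    def test_checkerboard_retains_half(self):
        vals = np.indices((10, 10)).sum(axis=0) % 2 * 0.2 + 0.4  # 0.4 / 0.6
        out = classify_sagebrush(_raster(vals), 0.5)
        assert out.values.sum() == 50

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify_sagebrush(_raster([[0.5]]), 1.5)


class TestMaskUmbra:
    def test_covering_circle_counts_everything(self):
        mask = _raster(np.ones((10, 10)))
        track = _track([(150.0, 150.0)], radius=10000.0)
        per_minute, union = mask_umbra(mask, track)
        total = 100 * 30.0**2
        assert per_minute[0] == total
        assert union == total

    def test_empty_mask_yields_zero(self):
        mask = _raster(np.zeros((10, 10)))
        track = _track([(150.0, 150.0)], radius=10000.0)
        per_minute, union = mask_umbra(mask, track)
        assert np.all(per_minute == 0) and union == 0.0

    def test_center_exactly_on_circle_included(self):
        mask = _raster(np.ones((1, 1)), pixel=30.0)  # center at (15, 15)
        d = np.hypot(15.0 - 100.0, 15.0 - 100.0)
        track = _track([(100.0, 100.0)], radius=d)
        per_minute, _ = mask_umbra(mask, track)
        assert per_minute[0] == 900.0

    def test_union_bounded_by_per_minute_sum_and_reversal_invariant(self):
        rng = np.random.default_rng(3)
        mask = _raster((rng.random((20, 20)) > 0.4).astype(float))
        centers = [(100.0 + 120 * i, 300.0) for i in range(5)]
        track = _track(centers, radius=200.0)
        per_minute, union = mask_umbra(mask, track)
        assert union <= per_minute.sum() + 1e-9
        reversed_track = _track(centers[::-1], radius=200.0)
        _, union_rev = mask_umbra(mask, reversed_track)
        assert union == union_rev


class TestLeafAreaBounds:
    def test_zero_ground_area(self):
        assert leaf_area_bounds(0.0) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        _, high = leaf_area_bounds(9e4)
        assert high == pytest.approx(5.832e4)
        low, high = leaf_area_bounds(1e6)
        assert low == pytest.approx(1.224e5)
        assert high == pytest.approx(6.48e5)

    def test_invalid_scenario(self):
        with pytest.raises(ValueError):
            ScalingScenario(cover_low=0.6, cover_high=0.5)


class TestCarbonBudget:
    def _series(self, hours=4, step_s=60):
        t0 = np.datetime64("2017-08-21T09:00:00")
        n = int(hours * 3600 / step_s) + 1
        return np.arange(t0, t0 + np.timedelta64(n * step_s, "s"),
                         np.timedelta64(step_s, "s"))

    def test_no_difference_no_reduction(self):
        t = self._series()
        a = np.full(len(t), 1.5)
        b = carbon_budget(1e8, 5e8, t, a, a)
        assert b.percent_reduction == 0.0
        assert b.c_eclipse_low_gg == b.c_no_eclipse_low_gg

    def test_unit_conversion_hand_case(self):
        # constant 1 umol difference for 1e4 s integrates to 0.01 mol m-2;
        # on 1e10 m2 of leaf that is 1.2011 Gg C
        t0 = np.datetime64("2017-08-21T09:00:00")
        t = np.arange(t0, t0 + np.timedelta64(10001, "s"), np.timedelta64(1, "s"))
        b = carbon_budget(1e10, 1e10, t, np.zeros(len(t)), np.ones(len(t)))
        deficit_gg = b.c_no_eclipse_low_gg - b.c_eclipse_low_gg
        assert deficit_gg == pytest.approx(1.2011, rel=1e-9)

    def test_linear_in_leaf_area_and_antisymmetric(self):
        t = self._series()
        rng = np.random.default_rng(4)
        a_obs = rng.random(len(t))
        a_cf = a_obs + 0.5
        b1 = carbon_budget(1e8, 2e8, t, a_obs, a_cf)
        b2 = carbon_budget(2e8, 4e8, t, a_obs, a_cf)
        assert b2.c_no_eclipse_low_gg == pytest.approx(
            2 * b1.c_no_eclipse_low_gg, rel=1e-12
        )
        swapped = carbon_budget(1e8, 2e8, t, a_cf, a_obs)
        d1 = b1.c_no_eclipse_low_gg - b1.c_eclipse_low_gg
        d2 = swapped.c_no_eclipse_low_gg - swapped.c_eclipse_low_gg
        assert d2 == pytest.approx(-d1, rel=1e-12)

    def test_percent_reduction_independent_of_area(self):
        # masked-per-minute vs union areas give identical reductions when
        # the whole region shares one flux series (simultaneity assumption)
        t = self._series()
        a_obs = np.full(len(t), 1.0)
        a_cf = np.full(len(t), 1.2)
        b_small = carbon_budget(3.7e7, 3.7e7, t, a_obs, a_cf)
        b_big = carbon_budget(9.9e9, 9.9e9, t, a_obs, a_cf)
        assert b_small.percent_reduction == pytest.approx(
            b_big.percent_reduction, rel=1e-12
        )

    def test_negative_integral_warned(self):
        t = self._series(hours=1)
        a = np.full(len(t), -0.5)
        with pytest.warns(UserWarning, match="respiration"):
            carbon_budget(1e8, 1e8, t, a, a + 0.1)


class TestRasterAndTrackIO:
    def test_ascii_grid_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        vals = rng.random((6, 8))
        vals[2, 3] = np.nan
        r = CoverRaster(vals, 30.0, (1000.0, 2000.0))
        path = tmp_path / "grid.asc"
        write_ascii_grid(path, r)
        back = read_ascii_grid(path)
        assert back.pixel_size == 30.0
        assert back.origin == (1000.0, 2000.0)
        assert np.isnan(back.values[2, 3])
        ok = np.isfinite(vals)
        assert np.allclose(back.values[ok], vals[ok], atol=1e-6)

    def test_umbra_geojson_round_trip(self, tmp_path):
        track = _track([(0.0, 0.0), (500.0, 100.0), (1000.0, 200.0)], 250.0)
        path = tmp_path / "track.geojson"
        write_umbra_geojson(path, track)
        back = read_umbra_geojson(path)
        assert len(back) == 3
        assert np.allclose(back.centers, track.centers)
        assert np.allclose(back.radii, 250.0)
        assert back.times == track.times

    def test_track_requires_minute_spacing(self):
        times = [datetime(2017, 8, 21, 10, 30), datetime(2017, 8, 21, 10, 32)]
        with pytest.raises(ValueError, match="60-s"):
            UmbraTrack(times=times, centers=[(0, 0), (1, 1)], radius_m=10.0)
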