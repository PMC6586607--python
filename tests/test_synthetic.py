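"""Synthetic generators: forcing depression, leaf kinetics, water
potentials, paired landscapes."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from umbraflux.geometry import obscuration_fraction
from umbraflux.hydraulics import fit_whole_plant_conductivity
from umbraflux.landscape import LandscapeParams, block_aggregate, generate_landscape
from umbraflux.micromet import ForcingSeries, compute_vpd
from umbraflux.synthetic import (
    ForcingParams,
    LeafSimParams,
    generate_forcing,
    generate_gas_exchange,
    generate_water_potentials,
)
from umbraflux.upscale import classify_sagebrush, mask_umbra, regress_cover


class TestGenerateForcing:
    def test_ppfd_is_clear_sky_outside_eclipse(self, default_forcing, geometry):
        t = default_forcing.time.to_numpy().astype("datetime64[ns]")
        f = obscuration_fraction(t, geometry)
        outside = f == 0
        p = ForcingParams()
        sunrise_h = 12.0 - p.day_length_h / 2
        hours = (
            t - np.datetime64(datetime(2017, 8, 21))
        ).astype("timedelta64[s]").astype(float) / 3600
        x = (hours - sunrise_h) / p.day_length_h
        clear = p.ppfd_max * np.where(
            (x > 0) & (x < 1), np.sin(np.pi * np.clip(x, 0, 1)), 0.0
        )
        assert np.allclose(
            default_forcing.channel("ppfd")[outside], clear[outside], atol=1e-9
        )

    def test_vpd_depression_endpoints(self, default_forcing, geometry):
        t = default_forcing.time.to_numpy().astype("datetime64[ns]")
        vpd = default_forcing.channel("vpd")
        ecl = (t >= np.datetime64(geometry.c1_time)) & (
            t <= np.datetime64(geometry.c4_time)
        )
        assert vpd[ecl].min() == pytest.approx(1.2, abs=1e-9)
        # plateau value before first contact
        times = default_forcing.time
        pre = (times >= datetime(2017, 8, 21, 8, 46)) & (
            times < datetime(2017, 8, 21, 9, 16)
        )
        assert np.allclose(vpd[pre.to_numpy()], 2.2, atol=1e-9)

    def test_temperature_minimum_lags_totality_by_nine_minutes(
        self, default_forcing, geometry
    ):
        t = default_forcing.time.to_numpy().astype("datetime64[ns]")
        tair = default_forcing.channel("tair")
        ecl = (t >= np.datetime64(geometry.c1_time)) & (
            t <= np.datetime64(geometry.c4_time)
        )
        imin = np.argmin(tair[ecl])
        lag_s = (
            t[ecl][imin] - np.datetime64(geometry.mid_totality)
        ) / np.timedelta64(1, "s")
        assert lag_s == pytest.approx(9 * 60, abs=1e-6)
        assert tair[ecl].min() == pytest.approx(28.0 - 6.4, abs=1e-9)

    def test_net_radiation_totality_minimum(self, default_forcing, geometry):
        t = default_forcing.time.to_numpy().astype("datetime64[ns]")
        rn = default_forcing.channel("rn")
        tot = (t >= np.datetime64(geometry.c2_time)) & (
            t <= np.datetime64(geometry.c3_time)
        )
        assert np.allclose(rn[tot], -111.0, atol=1e-9)
        assert rn.min() == pytest.approx(-111.0)

    def test_rh_round_trips_to_vpd(self, default_forcing):
        vpd = compute_vpd(
            default_forcing.channel("tair"), default_forcing.channel("rh")
        )
        assert np.allclose(vpd, default_forcing.channel("vpd"), atol=1e-9)

    def test_zero_noise_is_bit_stable(self, geometry):
        a = generate_forcing(ForcingParams(), geometry, seed=1)
        b = generate_forcing(ForcingParams(), geometry, seed=2)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_timestep_must_divide_span(self, geometry):
        with pytest.raises(ValueError, match="divide"):
            generate_forcing(ForcingParams(timestep_s=7.0), geometry)

    def test_invalid_depression_rejected(self):
        with pytest.raises(ValueError, match="vpd_min"):
            ForcingParams(vpd_min=2.5)


def _constant_forcing(q: float, minutes: int = 120) -> ForcingSeries:
    t = pd.date_range(datetime(2017, 8, 21, 9, 0), periods=minutes, freq="60s")
    n = len(t)
    return ForcingSeries(
        pd.DataFrame(
            {
                "time_mst": t,
                "ppfd_umol_m2_s": np.full(n, q),
                "rn_w_m2": np.full(n, 400.0),
                "tair_c": np.full(n, 25.0),
                "rh_pct": np.full(n, 50.0),
                "vpd_kpa": np.full(n, 1.5),
                "press_kpa": np.full(n, 78.7),
            }
        )
    )


class TestGenerateGasExchange:
    def test_dark_steady_state(self, leaf_params):
        gas, fluor = generate_gas_exchange(_constant_forcing(0.0), leaf_params)
        npq = fluor.dark_fm / fluor.fm_prime - 1
        assert npq[-1] == pytest.approx(0.0, abs=1e-9)
        assert fluor.fm_prime[-1] == pytest.approx(fluor.dark_fm, abs=1e-9)
        fvfm_dark = (fluor.dark_fm - fluor.dark_fo) / fluor.dark_fm
        fvfm_prime = (fluor.fm_prime[-1] - fluor.fo_prime[-1]) / fluor.fm_prime[-1]
        assert fvfm_prime == pytest.approx(fvfm_dark, abs=1e-9)
        assert gas.gs_mol_m2_s[-1] == pytest.approx(leaf_params.g_min, abs=1e-9)

    def test_conductance_bounded_and_light_efficiency_below_dark(
        self, default_leaf, leaf_params
    ):
        gas, fluor = default_leaf
        assert np.all(gas.gs_mol_m2_s >= leaf_params.g_min - 1e-12)
        assert np.all(gas.gs_mol_m2_s <= leaf_params.g_max + 1e-12)
        npq = fluor.dark_fm / fluor.fm_prime - 1
        assert np.all(npq >= -1e-12)
        fvfm_dark = (fluor.dark_fm - fluor.dark_fo) / fluor.dark_fm
        fvfm_prime = (fluor.fm_prime - fluor.fo_prime) / fluor.fm_prime
        assert np.all(fvfm_prime <= fvfm_dark + 1e-12)

    def test_calibrated_stomatal_endpoints(self, default_leaf, geometry):
        gas, _ = default_leaf
        t = gas.time.to_numpy().astype("datetime64[ns]")
        pre = t < np.datetime64(geometry.c1_time)
        ecl = (t >= np.datetime64(geometry.c1_time)) & (
            t <= np.datetime64(geometry.c4_time)
        )
        assert gas.gs_mol_m2_s[pre][-1] == pytest.approx(0.012, abs=5e-4)
        assert round(float(gas.gs_mol_m2_s[ecl].min()), 3) == 0.002

    def test_npq_step_kinetics_match_exponential_relaxation(self, leaf_params):
        # step up 0 -> 1200: induction ~ 3 tau; step down needs ~3 tau_relax
        up = _constant_forcing(1200.0, minutes=60)
        gas_up, fluor_up = generate_gas_exchange(up, leaf_params)
        npq_up = fluor_up.dark_fm / fluor_up.fm_prime - 1
        ss = leaf_params.npq_max * 1200 / (1200 + leaf_params.k_npq)
        t95 = 3.0 * leaf_params.tau_npq_induction
        idx = int(t95 // 30)
        assert npq_up[idx] >= 0.93 * ss
        assert 3.0 * leaf_params.tau_npq_relaxation > 138.0

    def test_30s_cadence_and_determinism(self, default_leaf):
        gas, _ = default_leaf
        dt = np.diff(gas.time.to_numpy()).astype("timedelta64[s]").astype(float)
        assert np.all(dt == 30.0)

    def test_nonfinite_forcing_rejected(self, leaf_params):
        bad = _constant_forcing(500.0)
        bad.frame.loc[3, "ppfd_umol_m2_s"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            generate_gas_exchange(bad, leaf_params)


class TestGenerateWaterPotentials:
    def test_zero_flux_gives_soil_potential(self, leaf_params):
        gas, _ = generate_gas_exchange(_constant_forcing(0.0), leaf_params)
        gas.e_mmol_m2_s[:] = 0.0
        wp = generate_water_potentials(
            gas, leaf_params, sample_times=[gas.time.iloc[10]], labels=["x"]
        )
        assert wp[0].psi_mean == pytest.approx(leaf_params.psi_soil)

    def test_hand_arithmetic_drawdown(self, leaf_params):
        gas, _ = generate_gas_exchange(_constant_forcing(0.0), leaf_params)
        gas.e_mmol_m2_s[:] = 0.1
        gas.e_mmol_m2_s[100:] = 0.2
        wp = generate_water_potentials(
            gas, leaf_params,
            sample_times=[gas.time.iloc[50], gas.time.iloc[150]],
            labels=["a", "b"],
        )
        # 0.1 / 0.256 = 0.390625 MPa of extra drawdown
        assert wp[1].psi_mean - wp[0].psi_mean == pytest.approx(-0.3906, abs=1e-4)

    def test_regression_recovers_k_plant_exactly_at_zero_noise(
        self, default_water, default_leaf, leaf_params
    ):
        gas, _ = default_leaf
        t = gas.time.to_numpy().astype("datetime64[ns]")
        sec = (t - t[0]).astype("timedelta64[ns]").astype(float) / 1e9
        e_at = [
            float(
                np.interp(
                    (np.datetime64(s.time) - t[0]).astype("timedelta64[ns]").astype(float) / 1e9,
                    sec,
                    gas.e_mmol_m2_s,
                )
            )
            for s in default_water
        ]
        fit = fit_whole_plant_conductivity(default_water, e_at)
        assert fit.k_l == pytest.approx(leaf_params.k_plant, rel=1e-9)
        assert fit.psi_soil_implied == pytest.approx(leaf_params.psi_soil, rel=1e-9)

    def test_replicate_noise_shrinks_se(self, default_leaf, leaf_params):
        gas, _ = default_leaf
        wp = generate_water_potentials(
            gas, leaf_params, noise_sd=0.1, n_replicates=6, seed=7
        )
        assert all(s.psi_se > 0 for s in wp)
        assert all(s.n == 6 for s in wp)

    def test_nonpositive_conductance_rejected(self, default_leaf):
        gas, _ = default_leaf
        with pytest.raises(ValueError, match="k_plant"):
            generate_water_potentials(gas, LeafSimParams(k_plant=-1.0))


class TestGenerateLandscape:
    def test_identity_aggregation_when_noise_free(self):
        p = LandscapeParams(
            extent_m=(2700.0, 2700.0), coarse_fine_slope=1.0,
            coarse_fine_intercept=0.0, coarse_fine_r2_target=1.0, seed=3,
        )
        coarse, fine, _ = generate_landscape(p)
        agg = block_aggregate(fine.values, 3)
        assert np.allclose(coarse.values, agg, atol=1e-12)

    def test_track_outside_extent_masks_nothing(self):
        p = LandscapeParams(
            extent_m=(2700.0, 2700.0),
            umbra_radius_m=100.0,
            track_start=(-50000.0, -50000.0),
            track_end=(-40000.0, -50000.0),
            seed=3,
        )
        _, fine, track = generate_landscape(p)
        binary = classify_sagebrush(fine, 0.3)
        per_minute, union = mask_umbra(binary, track)
        assert np.all(per_minute == 0)
        assert union == 0.0

    def test_regression_recovers_configured_slope_within_2_se(self):
        p = LandscapeParams(extent_m=(9000.0, 9000.0), coarse_fine_slope=0.8,
                            coarse_fine_intercept=0.05, seed=11)
        coarse, fine, _ = generate_landscape(p)
        reg = regress_cover(coarse, fine)
        assert abs(reg.slope - 0.8) <= 2.0 * reg.slope_se

    def test_cover_values_bounded(self):
        coarse, fine, _ = generate_landscape(
            LandscapeParams(extent_m=(2700.0, 2700.0), seed=5)
        )
        for r in (coarse, fine):
            assert np.nanmin(r.values) >= 0.0
            assert np.nanmax(r.values) <= 1.0

    def test_extent_smaller_than_coarse_pixel_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            LandscapeParams(extent_m=(50.0, 50.0))

    def test_same_seed_reproduces_fields(self):
        a = generate_landscape(LandscapeParams(extent_m=(2700.0, 2700.0), seed=9))
        b = generate_landscape(LandscapeParams(extent_m=(2700.0, 2700.0), seed=9))
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)
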