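"""Pipeline orchestration: simulate → analyze → upscale → report.

A :class:`RunConfig` (TOML-loadable) carries stage toggles, file paths,
seeds and the per-module parameter blocks.  One global seed expands
deterministically into per-stage seeds through ``numpy``'s
``SeedSequence`` spawn mechanism, so stages can be rerun independently
yet reproducibly.  Every run writes a manifest echoing the resolved
configuration and seed set; identical config + seed gives a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .fluorescence import bin_hysteresis, npq, psii_max_efficiency, welch_t_summary
from .geometry import EclipseGeometry
from .hydraulics import (
    fit_whole_plant_conductivity,
    hysteresis_loop_area,
    psi_e_correlation,
)
from .landscape import LandscapeParams, generate_landscape
from .leaf_series import read_leaf_csv, write_leaf_csv
from .light_response import assimilation_deficit, counterfactual_ppfd, fit_light_response
from .micromet import ForcingSeries, depression_metrics
from .rasters import (
    read_ascii_grid,
    read_umbra_geojson,
    write_ascii_grid,
    write_umbra_geojson,
)
from .synthetic import (
    ForcingParams,
    LeafSimParams,
    generate_forcing,
    generate_gas_exchange,
    generate_water_potentials,
    read_water_potential_csv,
    write_water_potential_csv,
)
from .upscale import (
    ScalingScenario,
    carbon_budget,
    classify_sagebrush,
    leaf_area_bounds,
    mask_umbra,
    regress_cover,
)

__all__ = ["RunConfig", "Report", "run_pipeline", "write_report", "read_report"]

log = logging.getLogger("umbraflux")

_STAGE_NAMES = ("forcing", "leaf", "water", "landscape", "bins")


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Expand one global seed into named per-stage seeds (< 2³¹).

    Children are spawned from ``SeedSequence(global_seed)`` in a fixed
    stage order, so any stage's seed is reproducible in isolation.
    """
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


@dataclass
class RunConfig:
    """Resolved pipeline configuration (all defaults are paper-calibrated)."""

    outdir: str = "umbraflux_run"
    seed: int = 0
    simulate: bool = True
    analyze: bool = True
    upscale: bool = True
    forcing_csv: str | None = None
    leaf_csv: str | None = None
    water_csv: str | None = None
    coarse_grid: str | None = None
    fine_grid: str | None = None
    track_geojson: str | None = None
    baseline_window_min: float = 30.0
    counterfactual_method: str = "diel_fit"
    fit_theta: float | None = None  # None: fit curvature; else fixed
    bin_levels: tuple = (0.0, 400.0, 800.0, 1200.0)
    bin_n: int = 4
    water_noise_sd: float = 0.0
    geometry: EclipseGeometry = field(default_factory=EclipseGeometry)
    forcing_params: ForcingParams = field(default_factory=ForcingParams)
    leaf_params: LeafSimParams = field(default_factory=LeafSimParams)
    landscape_params: LandscapeParams = field(default_factory=LandscapeParams)
    scenario: ScalingScenario = field(default_factory=ScalingScenario)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        top = {k: v for k, v in raw.items() if not isinstance(v, dict)}
        for key, val in top.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        for section, factory in [
            ("forcing", ForcingParams),
            ("leaf", LeafSimParams),
            ("landscape", LandscapeParams),
            ("scenario", ScalingScenario),
            ("geometry", EclipseGeometry),
        ]:
            if section in raw:
                block = dict(raw[section])
                for key, val in block.items():
                    if isinstance(val, str) and key.endswith(("_time", "noon", "start", "end")):
                        try:
                            block[key] = datetime.fromisoformat(val)
                        except ValueError:
                            pass
                attr = {
                    "forcing": "forcing_params",
                    "leaf": "leaf_params",
                    "landscape": "landscape_params",
                    "scenario": "scenario",
                    "geometry": "geometry",
                }[section]
                setattr(cfg, attr, dataclasses.replace(factory(), **block))
        return cfg

    def to_manifest(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, datetime):
                return obj.isoformat()
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        from . import __version__  # deferred: avoids import cycle

        manifest = {k: enc(v) for k, v in dataclasses.asdict(self).items()}
        manifest["seeds"] = derive_seeds(self.seed)
        manifest["version"] = __version__
        return manifest


@dataclass
class Report:
    """Assembled analysis results; every numeric block carries units."""

    depression: dict = field(default_factory=dict)
    psi_summary: dict = field(default_factory=dict)
    hydraulics: dict = field(default_factory=dict)
    fluorescence: dict = field(default_factory=dict)
    light_response: dict = field(default_factory=dict)
    deficit: dict = field(default_factory=dict)
    carbon: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Report":
        return cls(**{f.name: data.get(f.name, {}) for f in dataclasses.fields(cls)})


def write_report(report: Report, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True, allow_nan=False)


def read_report(path) -> Report:
    with open(path) as fh:
        return Report.from_dict(json.load(fh))


def _setup_logging(outdir: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        log.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(outdir / "umbraflux.log")
    log.addHandler(fh)


def run_pipeline(config: RunConfig) -> Report:
    """Execute enabled stages in dependency order and assemble the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    seeds = derive_seeds(config.seed)
    report = Report(manifest=config.to_manifest())
    geom = config.geometry

    try:
        forcing, gas, fluor, wp, coarse, fine, track = _stage_simulate(config, seeds, outdir)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    if config.analyze:
        try:
            _stage_analyze(config, geom, forcing, gas, fluor, wp, seeds, report)
        except Exception as exc:
            raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc

    if config.upscale:
        try:
            _stage_upscale(config, geom, gas, coarse, fine, track, report)
        except Exception as exc:
            raise RuntimeError(f"stage 'upscale' failed: {exc}") from exc

    write_report(report, outdir / "report.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=1, sort_keys=True)
    log.info(
        "design defaults used: baseline_window=%s min, theta=%s, "
        "counterfactual=%s, umbra containment=pixel-center inclusive",
        config.baseline_window_min,
        "fitted" if config.fit_theta is None else config.fit_theta,
        config.counterfactual_method,
    )
    return report


def _stage_simulate(config: RunConfig, seeds: dict, outdir: Path):
    if config.simulate:
        log.info("simulate: generating synthetic inputs (seed %s)", config.seed)
        forcing = generate_forcing(config.forcing_params, config.geometry,
                                   seed=seeds["forcing"])
        gas, fluor = generate_gas_exchange(forcing, config.leaf_params,
                                           seed=seeds["leaf"])
        wp = generate_water_potentials(
            gas, config.leaf_params, noise_sd=config.water_noise_sd,
            seed=seeds["water"],
        )
        lp = dataclasses.replace(config.landscape_params, seed=seeds["landscape"])
        coarse, fine, track = generate_landscape(lp)
        forcing.to_csv(outdir / "forcing.csv")
        write_leaf_csv(outdir / "leaf.csv", gas, fluor)
        write_water_potential_csv(outdir / "water_potential.csv", wp)
        write_ascii_grid(outdir / "cover_coarse.asc", coarse)
        write_ascii_grid(outdir / "cover_fine.asc", fine)
        write_umbra_geojson(outdir / "umbra_track.geojson", track)
        return forcing, gas, fluor, wp, coarse, fine, track

    def need(path, what):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing {what} input: {path}")
        return path

    lp = config.leaf_params
    forcing = ForcingSeries.from_csv(need(config.forcing_csv, "forcing CSV"),
                                     geometry=config.geometry)
    gas, fluor = read_leaf_csv(
        need(config.leaf_csv, "leaf CSV"), dark_fm=lp.fm_dark, dark_fo=lp.fo_dark,
        vpd_leaf_kpa=lp.chamber_vpd_kpa, pressure_kpa=config.forcing_params.pressure_kpa,
    )
    wp = read_water_potential_csv(need(config.water_csv, "water-potential CSV"))
    coarse = fine = track = None
    if config.upscale:
        coarse = read_ascii_grid(need(config.coarse_grid, "coarse raster"))
        fine = read_ascii_grid(need(config.fine_grid, "fine raster"))
        track = read_umbra_geojson(need(config.track_geojson, "umbra track"))
    return forcing, gas, fluor, wp, coarse, fine, track


def _metrics_dict(m) -> dict:
    return {
        "baseline": m.baseline,
        "minimum": m.minimum,
        "drop": m.drop,
        "drop_fraction_pct": m.drop_fraction,
        "lag_minutes": m.lag_minutes,
    }


def _stage_analyze(config, geom, forcing, gas, fluor, wp, seeds, report) -> None:
    log.info("analyze: depression metrics, hydraulics, fluorescence, light response")
    units = {"vpd": "kPa", "tair": "degC", "rn": "W m-2", "ppfd": "umol m-2 s-1"}
    report.depression = {
        ch: {**_metrics_dict(
            depression_metrics(forcing, ch, geom, config.baseline_window_min)
        ), "units": units[ch]}
        for ch in ("vpd", "tair", "rn", "ppfd")
    }

    rows = []
    for s in wp:
        rows.append(
            {"time": s.time.isoformat(), "label": s.label, "psi_mean_mpa": s.psi_mean,
             "psi_se_mpa": s.psi_se, "n": s.n}
        )
    comparisons = []
    predawn = [s for s in wp if s.label == "predawn"]
    if predawn:
        ref = predawn[0]
        for s in wp:
            if s is ref:
                continue
            if ref.psi_se > 0 and s.psi_se > 0:
                t, df, p = welch_t_summary(
                    ref.psi_mean, ref.psi_se, ref.n, s.psi_mean, s.psi_se, s.n
                )
                comparisons.append(
                    {"against": s.label, "t": t, "df": df, "p": p}
                )
            else:
                comparisons.append(
                    {"against": s.label, "t": None, "df": None, "p": None,
                     "note": "zero SE: test undefined"}
                )
    report.psi_summary = {"samples": rows, "welch_vs_predawn": comparisons,
                          "units": "MPa"}

    tg = gas.time.to_numpy().astype("datetime64[ns]")
    sec = (tg - tg[0]).astype("timedelta64[ns]").astype(float) / 1e9
    e_at = [
        float(np.interp(
            (np.datetime64(s.time) - tg[0]).astype("timedelta64[ns]").astype(float) / 1e9,
            sec, gas.e_mmol_m2_s,
        ))
        for s in wp
    ]
    fit = fit_whole_plant_conductivity(wp, e_at)
    loop = hysteresis_loop_area(
        [(s.psi_mean, e) for s, e in zip(wp, e_at) if s.label != "predawn"]
    )
    r2, p = psi_e_correlation([s.psi_mean for s in wp], e_at)
    report.hydraulics = {
        "k_l": fit.k_l, "intercept": fit.intercept, "r2": fit.r2,
        "p_value": fit.p_value, "n_points": fit.n_points,
        "predawn_excluded": fit.predawn_excluded,
        "psi_soil_implied_mpa": fit.psi_soil_implied,
        "hysteresis_loop_area": loop,
        "psi_e_r2_all_points": r2, "psi_e_p_all_points": p,
        "units": {"k_l": "mmol H2O m-2 s-1 MPa-1",
                  "loop_area": "MPa mmol m-2 s-1"},
    }

    fv_fm = psii_max_efficiency(fluor.dark_fm, fluor.dark_fo)
    npq_series = npq(fluor.dark_fm, fluor.fm_prime)
    in_tot = (tg >= np.datetime64(geom.c2_time)) & (tg <= np.datetime64(geom.c3_time))
    pre_c1 = tg < np.datetime64(geom.c1_time)
    bins = bin_hysteresis(
        fluor, geom, levels=config.bin_levels, n=config.bin_n, seed=seeds["bins"]
    )
    report.fluorescence = {
        "fv_fm_dark": fv_fm,
        "npq_pre_eclipse": float(npq_series[pre_c1][-1]) if pre_c1.any() else None,
        "npq_totality_min": float(npq_series[in_tot].min()) if in_tot.any() else None,
        "npq_negative_flagged": bool((npq_series < 0).any()),
        "bins": [
            {"level": b.level, "t": b.t_stat, "df": b.df, "p": b.p_value,
             "flagged": b.flagged, "note": b.note}
            for b in bins
        ],
        "units": {"npq": "dimensionless", "levels": "umol m-2 s-1"},
    }

    lr = fit_light_response(gas.q_umol_m2_s, gas.a_umol_m2_s, theta=config.fit_theta)
    q_cf = counterfactual_ppfd(tg, gas.q_umol_m2_s, geom,
                               method=config.counterfactual_method)
    from .light_response import nrh_assimilation

    a_cf = nrh_assimilation(q_cf, lr)
    window = (geom.c1_time, geom.c4_time)
    deficit = assimilation_deficit(tg, gas.a_umol_m2_s, a_cf, window)
    report.light_response = {
        "phi": lr.phi, "a_max": lr.a_max, "theta": lr.theta, "r_d": lr.r_d,
        "r2": lr.r2_fit, "counterfactual": config.counterfactual_method,
        "units": {"phi": "mol CO2 mol-1 photons", "a_max": "umol CO2 m-2 s-1",
                  "r_d": "umol CO2 m-2 s-1"},
    }
    report.deficit = {
        "cumulative_mol_m2": deficit.cumulative_deficit_mol_m2,
        "mean_rate_umol_m2_s": deficit.mean_rate_difference_umol_m2_s,
        "window": [window[0].isoformat(), window[1].isoformat()],
        "timestep_s": deficit.timestep_s,
        "units": deficit.units,
    }
    report.manifest["_a_cf_cache"] = [float(v) for v in a_cf]


def _stage_upscale(config, geom, gas, coarse, fine, track, report) -> None:
    log.info("upscale: cover regression, umbra masking, carbon budget")
    reg = regress_cover(coarse, fine)
    binary = classify_sagebrush(fine, config.scenario.classification_threshold)
    per_minute, union_area = mask_umbra(binary, track)
    low, high = leaf_area_bounds(union_area, config.scenario)

    tg = gas.time.to_numpy().astype("datetime64[ns]")
    a_cf = report.manifest.pop("_a_cf_cache", None)
    if a_cf is None:
        a_cf = list(gas.a_umol_m2_s)
    budget = carbon_budget(low, high, tg, gas.a_umol_m2_s, np.asarray(a_cf))
    report.carbon = {
        "cover_regression": {
            "slope": reg.slope, "intercept": reg.intercept, "r2": reg.r2,
            "f_stat": reg.f_stat, "p_value": reg.p_value, "n": reg.n,
        },
        "per_minute_masked_area_m2": [float(v) for v in per_minute],
        "union_area_m2": union_area,
        "leaf_area_low_m2": budget.leaf_area_low_m2,
        "leaf_area_high_m2": budget.leaf_area_high_m2,
        "c_no_eclipse_gg": [budget.c_no_eclipse_low_gg, budget.c_no_eclipse_high_gg],
        "c_eclipse_gg": [budget.c_eclipse_low_gg, budget.c_eclipse_high_gg],
        "percent_reduction": budget.percent_reduction,
        "units": {"areas": "m2", "carbon": "Gg C", "percent_reduction": "%"},
    }
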