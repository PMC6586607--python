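"""Micrometeorological forcing series and eclipse-depression metrics.

A :class:`ForcingSeries` is a uniform-timestep record of photosynthetic
photon flux density (PPFD), net radiation, air temperature, relative
humidity, pressure and derived vapor pressure deficit (VPD), optionally
carrying the eclipse contact-time geometry.  Depression metrics quantify
how far a channel dropped below its pre-eclipse baseline and how long the
minimum lagged mid-totality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .geometry import EclipseGeometry

__all__ = [
    "ForcingSeries",
    "DepressionMetrics",
    "saturation_vapor_pressure",
    "compute_vpd",
    "relative_humidity_from_vpd",
    "depression_metrics",
]

FORCING_COLUMNS = [
    "time_mst",
    "ppfd_umol_m2_s",
    "rn_w_m2",
    "tair_c",
    "rh_pct",
    "vpd_kpa",
    "press_kpa",
]

# Tetens saturation vapor pressure constants (kPa over liquid water).
# The standard micromet parameterization; alternates can be swapped here.
_TETENS_A = 0.61078
_TETENS_B = 17.27
_TETENS_C = 237.3


def saturation_vapor_pressure(t_air):
    """Saturation vapor pressure (kPa) at air temperature ``t_air`` (°C).

    Tetens form: es = 0.61078 · exp(17.27·T / (T + 237.3)).  Valid for
    −40 °C ≤ T ≤ 60 °C; values outside are rejected.
    """
    t = np.asarray(t_air, dtype=float)
    if np.any(t < -40) or np.any(t > 60):
        raise ValueError("air temperature outside supported range [-40, 60] degC")
    es = _TETENS_A * np.exp(_TETENS_B * t / (t + _TETENS_C))
    return float(es) if np.ndim(t_air) == 0 else es


def compute_vpd(t_air, rh):
    """Vapor pressure deficit (kPa) from temperature (°C) and RH (%)."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0) or np.any(rh_arr > 100):
        raise ValueError("relative humidity must lie in [0, 100] %")
    vpd = saturation_vapor_pressure(t_air) * (1.0 - rh_arr / 100.0)
    return float(vpd) if np.ndim(rh) == 0 and np.ndim(t_air) == 0 else vpd


def relative_humidity_from_vpd(t_air, vpd):
    """RH (%) consistent with ``compute_vpd`` (exact round-trip)."""
    es = saturation_vapor_pressure(t_air)
    rh = 100.0 * (1.0 - np.asarray(vpd, dtype=float) / es)
    return float(rh) if np.ndim(vpd) == 0 and np.ndim(t_air) == 0 else rh


@dataclass
class ForcingSeries:
    """Uniform-timestep micromet record with optional eclipse geometry."""

    frame: pd.DataFrame
    geometry: EclipseGeometry | None = None

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in FORCING_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"forcing frame missing columns: {missing}")
        t = pd.to_datetime(df["time_mst"])
        dt = np.diff(t.to_numpy().astype("datetime64[ns]").astype(np.int64)) / 1e9
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("timestamps must be strictly increasing and uniform")
        for col, lo in [("ppfd_umol_m2_s", 0.0), ("vpd_kpa", 0.0)]:
            if np.any(df[col].to_numpy() < -1e-9):
                raise ValueError(f"{col} must be nonnegative")
        rh = df["rh_pct"].to_numpy()
        if np.any(rh < 0) or np.any(rh > 100):
            raise ValueError("rh_pct must lie in [0, 100]")
        if df[FORCING_COLUMNS[1:]].isna().any().any():
            raise ValueError("forcing contains non-finite values")

    @property
    def time(self) -> pd.Series:
        return pd.to_datetime(self.frame["time_mst"])

    @property
    def timestep_s(self) -> float:
        t = self.time.to_numpy()
        return float((t[1] - t[0]) / np.timedelta64(1, "s"))

    def channel(self, name: str) -> np.ndarray:
        alias = {
            "ppfd": "ppfd_umol_m2_s",
            "rn": "rn_w_m2",
            "tair": "tair_c",
            "rh": "rh_pct",
            "vpd": "vpd_kpa",
            "pressure": "press_kpa",
        }
        return self.frame[alias.get(name, name)].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["time_mst"] = self.time.dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, geometry: EclipseGeometry | None = None) -> "ForcingSeries":
        df = pd.read_csv(path)
        df["time_mst"] = pd.to_datetime(df["time_mst"])
        return cls(df, geometry=geometry)


@dataclass(frozen=True)
class DepressionMetrics:
    """Eclipse depression of one forcing channel relative to baseline."""

    baseline: float
    minimum: float
    drop: float
    drop_fraction: float  # percent of baseline
    lag_minutes: float | None  # None when the minimum is not an interior one
    channel: str = ""
    units: str = ""


def depression_metrics(
    series: ForcingSeries,
    channel: str,
    geometry: EclipseGeometry | None = None,
    baseline_window_min: float = 30.0,
) -> DepressionMetrics:
    """Baseline, minimum, drop and lag of one channel over the eclipse.

    Baseline is the mean over the ``baseline_window_min`` minutes before C1;
    the minimum is taken over [C1, C4]; the lag is the time of the minimum
    minus mid-totality, in minutes.  A minimum attained at the window
    boundary has no defined lag and is reported as ``None`` rather than a
    number.  Ties in the minimum break to the earliest time.
    """
    geom = geometry or series.geometry
    if geom is None:
        raise ValueError("eclipse geometry required (none attached to series)")
    t = series.time.to_numpy().astype("datetime64[ns]")
    y = series.channel(channel)
    c1 = np.datetime64(geom.c1_time)
    c4 = np.datetime64(geom.c4_time)
    w0 = np.datetime64(geom.c1_time - timedelta(minutes=baseline_window_min))
    if t[0] > w0 or t[-1] < c4:
        raise ValueError(
            "series must cover [c1 - baseline_window, c4] for depression metrics"
        )
    base_mask = (t >= w0) & (t < c1)
    win_mask = (t >= c1) & (t <= c4)
    if not base_mask.any() or not win_mask.any():
        raise ValueError("empty baseline or eclipse window")
    baseline = float(np.mean(y[base_mask]))
    yw = y[win_mask]
    tw = t[win_mask]
    imin = int(np.argmin(yw))  # argmin returns the first minimum: earliest time
    minimum = float(yw[imin])
    drop = baseline - minimum
    drop_fraction = 100.0 * drop / baseline if baseline != 0 else math.nan
    lag: float | None
    if imin == 0 or imin == len(yw) - 1:
        lag = None  # boundary minimum: lag undefined, never silently reported
    else:
        mid = np.datetime64(geom.mid_totality)
        lag = float((tw[imin] - mid) / np.timedelta64(1, "s")) / 60.0
    return DepressionMetrics(
        baseline=baseline,
        minimum=minimum,
        drop=drop,
        drop_fraction=drop_fraction,
        lag_minutes=lag,
        channel=channel,
    )
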