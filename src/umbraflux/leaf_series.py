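"""Containers for 30-s leaf gas-exchange and chlorophyll-fluorescence series.

Both ride on the same instrument cadence and share one CSV schema
(``time_mst, a_umol_m2_s, e_mmol_m2_s, gs_mol_m2_s, f, fm_prime,
q_umol_m2_s``), mirroring a chamber system logging gas exchange and pulse
fluorometry together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GasExchangeSeries", "FluorescenceSeries", "write_leaf_csv", "read_leaf_csv"]

LEAF_COLUMNS = [
    "time_mst",
    "a_umol_m2_s",
    "e_mmol_m2_s",
    "gs_mol_m2_s",
    "f",
    "fm_prime",
    "q_umol_m2_s",
]


@dataclass
class GasExchangeSeries:
    """Leaf CO₂ assimilation A, transpiration E, conductance g_s vs time."""

    time: pd.Series
    a_umol_m2_s: np.ndarray
    e_mmol_m2_s: np.ndarray
    gs_mol_m2_s: np.ndarray
    q_umol_m2_s: np.ndarray
    vpd_leaf_kpa: float = float("nan")
    pressure_kpa: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("a_umol_m2_s", "e_mmol_m2_s", "gs_mol_m2_s", "q_umol_m2_s"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        if np.any(self.e_mmol_m2_s < -1e-12) or np.any(self.gs_mol_m2_s < -1e-12):
            raise ValueError("E and g_s must be nonnegative")


@dataclass
class FluorescenceSeries:
    """Steady-state F, saturating-pulse Fm', and dark references Fm, Fo."""

    time: pd.Series
    f_steady: np.ndarray
    fm_prime: np.ndarray
    q_umol_m2_s: np.ndarray
    dark_fm: float
    dark_fo: float
    fo_prime: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.dark_fo < self.dark_fm):
            raise ValueError("need 0 < dark Fo < dark Fm")
        self.f_steady = np.asarray(self.f_steady, dtype=float)
        self.fm_prime = np.asarray(self.fm_prime, dtype=float)
        self.q_umol_m2_s = np.asarray(self.q_umol_m2_s, dtype=float)
        if np.any(self.fm_prime <= 0):
            raise ValueError("fm_prime must be positive")
        if np.any(self.q_umol_m2_s < 0):
            raise ValueError("PPFD must be nonnegative")


def write_leaf_csv(path, gas: GasExchangeSeries, fluor: FluorescenceSeries) -> None:
    df = pd.DataFrame(
        {
            "time_mst": pd.Series(pd.to_datetime(gas.time)).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "a_umol_m2_s": gas.a_umol_m2_s,
            "e_mmol_m2_s": gas.e_mmol_m2_s,
            "gs_mol_m2_s": gas.gs_mol_m2_s,
            "f": fluor.f_steady,
            "fm_prime": fluor.fm_prime,
            "q_umol_m2_s": gas.q_umol_m2_s,
        }
    )
    df.to_csv(path, index=False)


def read_leaf_csv(
    path,
    dark_fm: float,
    dark_fo: float,
    vpd_leaf_kpa: float = float("nan"),
    pressure_kpa: float = float("nan"),
) -> tuple[GasExchangeSeries, FluorescenceSeries]:
    df = pd.read_csv(path)
    missing = [c for c in LEAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"leaf CSV missing columns: {missing}")
    t = pd.to_datetime(df["time_mst"])
    gas = GasExchangeSeries(
        time=t,
        a_umol_m2_s=df["a_umol_m2_s"].to_numpy(),
        e_mmol_m2_s=df["e_mmol_m2_s"].to_numpy(),
        gs_mol_m2_s=df["gs_mol_m2_s"].to_numpy(),
        q_umol_m2_s=df["q_umol_m2_s"].to_numpy(),
        vpd_leaf_kpa=vpd_leaf_kpa,
        pressure_kpa=pressure_kpa,
    )
    fluor = FluorescenceSeries(
        time=t,
        f_steady=df["f"].to_numpy(),
        fm_prime=df["fm_prime"].to_numpy(),
        q_umol_m2_s=df["q_umol_m2_s"].to_numpy(),
        dark_fm=dark_fm,
        dark_fo=dark_fo,
    )
    return gas, fluor
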