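"""Photosystem II efficiency, quenching metrics, and the PPFD-binned
pre/post-totality hysteresis comparison.

Conventions: PSII efficiency uses (Fm − Fo)/Fm in both dark- and
light-adapted forms; NPQ = Fm/Fm' − 1 against the predawn dark reference;
Fo' is estimated with the Oxborough–Baker relation when not measured
(standard fluorometer-firmware practice); t-tests are Welch (unequal
variance).  The pre/post phase boundary is the midpoint of totality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import EclipseGeometry
from .leaf_series import FluorescenceSeries

__all__ = [
    "BinComparison",
    "psii_max_efficiency",
    "npq",
    "estimate_fo_prime",
    "recovery_ratio",
    "percent_difference",
    "bin_hysteresis",
    "welch_t_summary",
]


def psii_max_efficiency(fm, fo):
    """(Fm − Fo)/Fm.  Serves Fv/Fm (dark) and Fv'/Fm' (light-adapted)."""
    fm_arr = np.asarray(fm, dtype=float)
    fo_arr = np.asarray(fo, dtype=float)
    if np.any(fo_arr <= 0) or np.any(fo_arr >= fm_arr):
        raise ValueError("need 0 < Fo < Fm")
    out = (fm_arr - fo_arr) / fm_arr
    return float(out) if np.ndim(fm) == 0 and np.ndim(fo) == 0 else out


def npq(fm_dark, fm_prime):
    """Non-photochemical quenching Fm/Fm' − 1.

    Negative values (Fm' above the dark reference) are permitted so the
    caller can flag them, never silently clipped.
    """
    fmp = np.asarray(fm_prime, dtype=float)
    if np.any(fmp <= 0):
        raise ValueError("fm_prime must be positive")
    out = np.asarray(fm_dark, dtype=float) / fmp - 1.0
    return float(out) if np.ndim(fm_prime) == 0 else out


def estimate_fo_prime(fo_dark, fm_dark, fm_prime):
    """Oxborough–Baker: Fo' = Fo / (Fv/Fm + Fo/Fm')."""
    if fo_dark <= 0 or fm_dark <= 0 or fo_dark >= fm_dark:
        raise ValueError("need 0 < fo_dark < fm_dark")
    fmp = np.asarray(fm_prime, dtype=float)
    if np.any(fmp <= 0):
        raise ValueError("fm_prime must be positive")
    denom = (fm_dark - fo_dark) / fm_dark + fo_dark / fmp
    if np.any(denom <= 0):
        raise ValueError("nonpositive denominator in Oxborough-Baker relation")
    out = fo_dark / denom
    return float(out) if np.ndim(fm_prime) == 0 else out


def recovery_ratio(light_value: float, dark_value: float) -> int:
    """Integer-percent recovery floor(100·light/dark).

    Floor, not round: 100·0.71/0.81 = 87.65 is reported as 87, matching
    the field convention of not overstating recovery.
    """
    if dark_value <= 0:
        raise ValueError("dark_value must be positive")
    return math.floor(100.0 * light_value / dark_value)


def percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference 100·|a − b| / mean(a, b)."""
    mean = (a + b) / 2.0
    if mean == 0:
        raise ValueError("degenerate mean; percent difference undefined")
    return 100.0 * abs(a - b) / mean


def welch_t_summary(mean1, se1, n1, mean2, se2, n2) -> tuple[float, float, float]:
    """Welch two-sample t-test from summary statistics (mean, SE, n).

    t = (m1 − m2)/sqrt(se1² + se2²) with Welch–Satterthwaite degrees of
    freedom; two-sided p.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = se1**2, se2**2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


@dataclass(frozen=True)
class BinComparison:
    """Welch comparison of pre- vs post-totality values at one PPFD level."""

    level: float  # umol m-2 s-1
    half_window: float
    pre_samples: tuple
    post_samples: tuple
    t_stat: float | None
    df: float | None
    p_value: float | None
    flagged: bool = False  # insufficient observations in one phase
    note: str = ""


def bin_hysteresis(
    series: FluorescenceSeries,
    geometry: EclipseGeometry,
    values: np.ndarray | None = None,
    levels=(0.0, 400.0, 800.0, 1200.0),
    half_window: float = 25.0,
    n: int = 4,
    seed: int | None = None,
) -> list[BinComparison]:
    """Pre/post-totality Welch comparisons in ±``half_window`` PPFD bins.

    For each level, ``n`` observations are drawn without replacement from
    the pre-phase (before mid-totality) and post-phase windows and
    compared with a Welch t-test.  ``values`` defaults to light-adapted
    PSII efficiency Fv'/Fm' computed from the series.  Bins with too few
    observations are flagged, never fabricated.  Sampling is over
    timestamp-sorted rows, so input row order does not affect the draw.
    Note: the four levels imply four simultaneous tests; no multiplicity
    correction is applied.
    """
    t = np.asarray(series.time, dtype="datetime64[ns]")
    order = np.argsort(t, kind="stable")
    t = t[order]
    q = series.q_umol_m2_s[order]
    if values is None:
        fo_p = (
            series.fo_prime[order]
            if series.fo_prime is not None
            else estimate_fo_prime(series.dark_fo, series.dark_fm, series.fm_prime[order])
        )
        values = (series.fm_prime[order] - fo_p) / series.fm_prime[order]
    else:
        values = np.asarray(values, dtype=float)[order]
    mid = np.datetime64(geometry.mid_totality)
    pre = t < mid
    rng = np.random.default_rng(seed)
    out: list[BinComparison] = []
    for level in levels:
        in_bin = np.abs(q - level) <= half_window
        pre_idx = np.nonzero(in_bin & pre)[0]
        post_idx = np.nonzero(in_bin & ~pre)[0]
        if len(pre_idx) < n or len(post_idx) < n:
            out.append(
                BinComparison(
                    level=level, half_window=half_window,
                    pre_samples=(), post_samples=(),
                    t_stat=None, df=None, p_value=None, flagged=True,
                    note=f"insufficient observations (pre={len(pre_idx)}, "
                         f"post={len(post_idx)}, need {n})",
                )
            )
            continue
        pre_draw = values[np.sort(rng.choice(pre_idx, size=n, replace=False))]
        post_draw = values[np.sort(rng.choice(post_idx, size=n, replace=False))]
        if np.allclose(pre_draw, post_draw):
            t_stat, df, p = 0.0, float(2 * n - 2), 1.0
        else:
            res = stats.ttest_ind(pre_draw, post_draw, equal_var=False)
            t_stat, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        out.append(
            BinComparison(
                level=level, half_window=half_window,
                pre_samples=tuple(pre_draw), post_samples=tuple(post_draw),
                t_stat=t_stat, df=df, p_value=p,
                note="4 simultaneous tests, no multiplicity correction",
            )
        )
    return out
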