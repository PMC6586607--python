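"""Non-rectangular hyperbola light response, counterfactual PPFD, and the
eclipse assimilation deficit.

The light-response model is the non-rectangular hyperbola of Marshall &
Biscoe: net assimilation

    A(Q) = [φQ + Amax − sqrt((φQ + Amax)² − 4θφQ·Amax)] / (2θ) − Rd

with apparent quantum yield φ (mol CO₂ mol⁻¹ photons), light-saturated
gross rate Amax (µmol m⁻² s⁻¹), curvature θ ∈ (0, 1], and dark respiration
Rd (µmol m⁻² s⁻¹).  As θ → 0 the expression degenerates 0/0; below
``THETA_EPS`` the rectangular-hyperbola limit φQ·Amax/(φQ + Amax) − Rd is
used instead.

The counterfactual reconstructs the PPFD a leaf would have seen on the
same day without the eclipse, either by fitting a clear-sky diel curve to
observations outside the eclipse window ("diel_fit") or by dividing the
observed PPFD by the unobscured disk fraction ("transmission").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from scipy.optimize import curve_fit

from .geometry import EclipseGeometry, obscuration_fraction

__all__ = [
    "LightResponseParams",
    "DeficitSummary",
    "nrh_assimilation",
    "fit_light_response",
    "counterfactual_ppfd",
    "assimilation_deficit",
]

THETA_EPS = 1e-6


@dataclass(frozen=True)
class LightResponseParams:
    phi: float  # mol CO2 / mol photons
    a_max: float  # umol CO2 m-2 s-1 (gross, light-saturated)
    theta: float  # curvature, (0, 1]
    r_d: float  # umol CO2 m-2 s-1, dark respiration >= 0
    r2_fit: float | None = None

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        if not (0 < self.theta <= 1):
            raise ValueError("theta must lie in (0, 1]")
        if self.r_d < 0:
            raise ValueError("r_d must be nonnegative")


def nrh_assimilation(q, params: LightResponseParams):
    """Net CO₂ assimilation (µmol m⁻² s⁻¹) at PPFD ``q`` (µmol m⁻² s⁻¹)."""
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0):
        raise ValueError("PPFD must be nonnegative")
    a = _nrh_gross(q_arr, params.phi, params.a_max, params.theta) - params.r_d
    return float(a) if np.ndim(q) == 0 else a


def _nrh_gross(q, phi, a_max, theta):
    s = phi * q + a_max
    if theta < THETA_EPS:
        # series-safe rectangular-hyperbola limit
        return phi * q * a_max / s
    disc = s * s - 4.0 * theta * phi * q * a_max
    return (s - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * theta)


def _nrh_net(q, phi, a_max, theta, r_d):
    return _nrh_gross(q, phi, a_max, theta) - r_d


def fit_light_response(
    q_series,
    a_series,
    theta: float | None = None,
) -> LightResponseParams:
    """Nonlinear least-squares fit of the non-rectangular hyperbola.

    Parameters are initialized from the data: φ from the OLS slope over the
    lowest-quartile PPFD points, Amax from the 95th-percentile assimilation
    plus the Rd guess, θ = 0.7, Rd from |min(A)|.  Pass ``theta`` to fit
    with fixed curvature.  Non-convergence raises, never returns silently.
    """
    q = np.asarray(q_series, dtype=float)
    a = np.asarray(a_series, dtype=float)
    if q.shape != a.shape or q.ndim != 1:
        raise ValueError("q_series and a_series must be matching 1-D arrays")
    if len(q) < 8:
        raise ValueError("need at least 8 points spanning low and high PPFD")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(a))):
        raise ValueError("non-finite values in light-response data")
    if np.ptp(q) == 0:
        raise ValueError("all PPFD values identical; light response undefined")

    r_d0 = max(abs(float(np.min(a))), 0.01)
    q25 = np.quantile(q, 0.25)
    low = q <= q25
    if low.sum() >= 2 and np.ptp(q[low]) > 0:
        phi0 = float(np.polyfit(q[low], a[low], 1)[0])
    else:
        phi0 = 0.03
    phi0 = min(max(phi0, 1e-4), 0.12)
    a_max0 = max(float(np.quantile(a, 0.95)) + r_d0, 0.05)

    if theta is None:
        p0 = [phi0, a_max0, 0.7, r_d0]
        bounds = ([1e-6, 1e-3, 1e-4, 0.0], [0.5, 1e3, 1.0, 1e2])
        model = _nrh_net
    else:
        if not (0 < theta <= 1):
            raise ValueError("fixed theta must lie in (0, 1]")
        p0 = [phi0, a_max0, r_d0]
        bounds = ([1e-6, 1e-3, 0.0], [0.5, 1e3, 1e2])

        def model(qq, phi, a_max, r_d):  # type: ignore[misc]
            return _nrh_net(qq, phi, a_max, theta, r_d)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, q, a, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - rare
        raise RuntimeError(
            f"light-response fit did not converge (start {p0}): {exc}"
        ) from exc

    pred = model(q, *popt)
    ss_res = float(np.sum((a - pred) ** 2))
    ss_tot = float(np.sum((a - np.mean(a)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if theta is None:
        phi, a_max, th, r_d = popt
    else:
        phi, a_max, r_d = popt
        th = theta
    return LightResponseParams(
        phi=float(phi), a_max=float(a_max), theta=float(th), r_d=float(r_d),
        r2_fit=r2,
    )


def _diel_curve(t_hours, q_max, k, sunrise, day_length):
    x = np.clip((t_hours - sunrise) / day_length, 0.0, 1.0)
    return q_max * np.sin(np.pi * x) ** k


def counterfactual_ppfd(
    time,
    q_obs,
    geometry: EclipseGeometry,
    method: str = "diel_fit",
    clamp_fraction: float = 0.99,
) -> np.ndarray:
    """No-eclipse PPFD series on the same timestamps.

    ``diel_fit`` fits q(t) = qmax·sin^k(π(t−sunrise)/daylength) to points
    outside [C1, C4] and evaluates it inside; ``transmission`` divides the
    observed PPFD by (1−f) and bridges near-total obscuration (f >
    ``clamp_fraction``) by linear interpolation.  Points where the
    counterfactual falls below the observation inside the window are lifted
    to the observation (and counted as flagged violations).
    """
    t = np.asarray(time, dtype="datetime64[ns]")
    q = np.asarray(q_obs, dtype=float)
    inside = (t >= np.datetime64(geometry.c1_time)) & (
        t <= np.datetime64(geometry.c4_time)
    )
    hours = (
        t - t[0].astype("datetime64[D]").astype("datetime64[ns]")
    ).astype("timedelta64[s]").astype(float) / 3600.0

    if method == "diel_fit":
        if (~inside).sum() < 8:
            raise ValueError("insufficient out-of-window data for diel_fit")
        q_out = q[~inside]
        h_out = hours[~inside]
        q_max0 = float(np.max(q_out))
        p0 = [q_max0, 1.2, 5.5, 13.5]
        bounds = ([q_max0 * 0.3, 0.3, 0.0, 6.0], [q_max0 * 3.0, 5.0, 12.0, 20.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _diel_curve, h_out, q_out, p0=p0, bounds=bounds, maxfev=20000
            )
        q_cf = q.copy()
        q_cf[inside] = _diel_curve(hours[inside], *popt)
    elif method == "transmission":
        f = obscuration_fraction(t, geometry)
        q_cf = q.copy()
        ok = inside & (f <= clamp_fraction)
        q_cf[ok] = q[ok] / (1.0 - f[ok])
        gap = inside & (f > clamp_fraction)
        if gap.any():
            idx = np.arange(len(q))
            q_cf[gap] = np.interp(idx[gap], idx[~gap], q_cf[~gap])
    else:
        raise ValueError(f"unknown counterfactual method: {method!r}")

    q_cf[inside] = np.maximum(q_cf[inside], q[inside])
    return q_cf


@dataclass(frozen=True)
class DeficitSummary:
    """Time-integrated assimilation shortfall over the eclipse window."""

    cumulative_deficit_mol_m2: float
    mean_rate_difference_umol_m2_s: float
    window: tuple[datetime, datetime]
    timestep_s: float
    n_points: int = 0
    units: dict = field(
        default_factory=lambda: {
            "cumulative_deficit": "mol CO2 m-2 leaf",
            "mean_rate_difference": "umol CO2 m-2 s-1",
        }
    )


def assimilation_deficit(
    time, a_obs, a_cf, window: tuple[datetime, datetime], dt_s: float | None = None
) -> DeficitSummary:
    """Trapezoidal integral of (A_cf − A_obs) over ``window``, in mol m⁻²."""
    t = np.asarray(time, dtype="datetime64[ns]")
    a_o = np.asarray(a_obs, dtype=float)
    a_c = np.asarray(a_cf, dtype=float)
    if not (len(t) == len(a_o) == len(a_c)):
        raise ValueError("misaligned series: time, a_obs, a_cf lengths differ")
    mask = (t >= np.datetime64(window[0])) & (t <= np.datetime64(window[1]))
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    tt = t[mask]
    sec = (tt - tt[0]).astype("timedelta64[ns]").astype(float) / 1e9
    diff = a_c[mask] - a_o[mask]
    cumulative = float(np.trapezoid(diff, sec)) * 1e-6  # umol -> mol
    mean_rate = float(np.mean(diff))
    step = dt_s if dt_s is not None else float(sec[1] - sec[0])
    return DeficitSummary(
        cumulative_deficit_mol_m2=cumulative,
        mean_rate_difference_umol_m2_s=mean_rate,
        window=window,
        timestep_s=step,
        n_points=int(mask.sum()),
    )
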