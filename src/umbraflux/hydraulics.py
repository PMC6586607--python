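"""Leaf hydraulics: stomatal conductance from transpiration, whole-plant
conductivity by a Darcy-law regression, and Ψ–E hysteresis.

The supply model is Darcy-like: E = K_L·(Ψ_soil − Ψ_L), with leaf
transpiration E in mmol H₂O m⁻² s⁻¹, water potentials in MPa, and
whole-plant conductivity K_L in mmol m⁻² s⁻¹ MPa⁻¹.  K_L is therefore the
negative OLS slope of E on Ψ_L over the diel trajectory; the soil water
potential emerges from the fitted intercept (−intercept/slope) rather than
being assumed.  Predawn points are excluded by default because elevated
nighttime VPD keeps predawn Ψ_L out of equilibrium with the soil.
Capacitance is taken as zero: no lag term in the supply model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np
from scipy import stats

__all__ = [
    "WaterPotentialSample",
    "HydraulicFit",
    "stomatal_conductance",
    "fit_whole_plant_conductivity",
    "hysteresis_loop_area",
    "psi_e_correlation",
]


@dataclass(frozen=True)
class WaterPotentialSample:
    """Mean ± SE leaf water potential at one sampling occasion."""

    time: datetime
    psi_mean: float  # MPa, <= 0
    psi_se: float
    n: int
    label: str = ""  # predawn / pre-totality / end-totality / post-totality / post-partial

    def __post_init__(self) -> None:
        if self.psi_mean > 0:
            raise ValueError("leaf water potential must be <= 0 MPa")
        if self.psi_se < 0 or self.n < 1:
            raise ValueError("need se >= 0 and n >= 1")


@dataclass(frozen=True)
class HydraulicFit:
    """Whole-plant conductivity from the Ψ–E regression."""

    k_l: float  # mmol H2O m-2 s-1 MPa-1 (= -slope)
    intercept: float  # mmol m-2 s-1
    r2: float
    p_value: float
    n_points: int
    predawn_excluded: bool
    psi_soil_implied: float  # MPa, from E = 0 intercept

    @property
    def units(self) -> dict:
        return {"k_l": "mmol H2O m-2 s-1 MPa-1", "intercept": "mmol m-2 s-1"}


def stomatal_conductance(e_l, vpd_leaf: float, pressure: float):
    """g_s (mol H₂O m⁻² s⁻¹) from E (mmol m⁻² s⁻¹) by the diffusion
    approximation g_s = (E/1000)·P/VPD; boundary layer ignored."""
    if np.any(np.asarray(vpd_leaf) <= 0):
        raise ValueError("vpd_leaf must be positive")
    if np.any(np.asarray(pressure) <= 0):
        raise ValueError("pressure must be positive")
    g = (np.asarray(e_l, dtype=float) / 1000.0) * pressure / vpd_leaf
    return float(g) if np.ndim(e_l) == 0 else g


def transpiration_from_conductance(gs, vpd_leaf: float, pressure: float):
    """Inverse of :func:`stomatal_conductance`: E (mmol) = 1000·g·VPD/P."""
    return np.asarray(gs, dtype=float) * 1000.0 * vpd_leaf / pressure


def fit_whole_plant_conductivity(
    samples,
    e_l,
    exclude_labels: set[str] = frozenset({"predawn"}),
) -> HydraulicFit:
    """OLS of E on Ψ over retained sampling occasions; K_L = −slope.

    ``samples`` is a sequence of :class:`WaterPotentialSample` (or bare
    (psi, label) tuples); ``e_l`` the matching transpiration rates in mmol
    m⁻² s⁻¹.  Occasions whose label is in ``exclude_labels`` are dropped
    (predawn by default).  A negative conductivity estimate is returned
    as-is with a warning, never clipped.
    """
    psi, labels = [], []
    for s in samples:
        if isinstance(s, WaterPotentialSample):
            psi.append(s.psi_mean)
            labels.append(s.label)
        else:
            psi.append(float(s[0]))
            labels.append(s[1] if len(s) > 1 else "")
    psi = np.asarray(psi, dtype=float)
    e = np.asarray(e_l, dtype=float)
    if len(psi) != len(e):
        raise ValueError("samples and e_l length mismatch")
    keep = np.array([lab not in exclude_labels for lab in labels])
    psi, e = psi[keep], e[keep]
    if len(psi) < 3:
        raise ValueError("need at least 3 retained (psi, E) pairs")
    if np.ptp(psi) == 0:
        raise ValueError("zero variance in water potential; slope undefined")
    if np.ptp(e) == 0:
        # flat transpiration: zero conductivity, no explained variance
        return HydraulicFit(
            k_l=0.0, intercept=float(e[0]), r2=0.0, p_value=1.0,
            n_points=len(psi), predawn_excluded="predawn" in exclude_labels,
            psi_soil_implied=math.nan,
        )
    res = stats.linregress(psi, e)
    k_l = -float(res.slope)
    if k_l < 0:
        warnings.warn(
            "negative whole-plant conductivity estimate; data are not "
            "physically consistent with the Darcy supply model",
            stacklevel=2,
        )
    psi_soil = (
        -float(res.intercept) / float(res.slope) if res.slope != 0 else math.nan
    )
    return HydraulicFit(
        k_l=k_l,
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n_points=len(psi),
        predawn_excluded="predawn" in exclude_labels,
        psi_soil_implied=psi_soil,
    )


def hysteresis_loop_area(path_points) -> float:
    """Absolute shoelace area of an ordered (Ψ, E) loop (closed polygon).

    Collinear or degenerate paths give 0 (with a warning when all points
    coincide).  MPa·mmol m⁻² s⁻¹.
    """
    pts = np.asarray(path_points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a loop")
    if np.allclose(pts, pts[0]):
        warnings.warn("degenerate loop: all points identical", stacklevel=2)
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(
        float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    )
    return area


def psi_e_correlation(psi, e_l) -> tuple[float, float]:
    """Squared Pearson correlation of Ψ and E with two-sided p-value."""
    psi = np.asarray(psi, dtype=float)
    e = np.asarray(e_l, dtype=float)
    if len(psi) != len(e) or len(psi) < 3:
        raise ValueError("need >= 3 aligned pairs")
    if np.ptp(psi) == 0 or np.ptp(e) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(psi, e)
    return float(r) ** 2, float(p)
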