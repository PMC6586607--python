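"""Regional leaf-area estimation and the eclipse carbon budget.

Workflow: regress coarse (90 m) sagebrush cover on block-aggregated fine
(30 m) shrub cover; threshold the fine map into a binary sagebrush mask
(cover ≥ 50%); intersect the mask with the moving umbra at 1-minute
steps (pixel-center containment, boundary inclusive); convert ground area
to a low/high leaf-area envelope from stand-age cover fractions and LAI;
and scale the leaf-level with/without-eclipse assimilation series to
regional carbon totals under big-leaf linearity (every m² of leaf behaves
as the measured leaf, and the whole region experiences the eclipse
simultaneously).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np
from scipy import stats

from .landscape import block_aggregate
from .rasters import CoverRaster, UmbraTrack

__all__ = [
    "ScalingScenario",
    "CarbonBudget",
    "CoverRegression",
    "regress_cover",
    "classify_sagebrush",
    "mask_umbra",
    "leaf_area_bounds",
    "carbon_budget",
]

CARBON_MOLAR_MASS = 12.011  # g mol-1, carbon in CO2


@dataclass(frozen=True)
class ScalingScenario:
    """Allometric bounds: ground cover of 20- vs 45-yr stands and LAI."""

    cover_low: float = 0.24
    cover_high: float = 0.54
    lai_low: float = 0.51  # m2 leaf m-2 ground
    lai_high: float = 1.2
    classification_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.cover_low > self.cover_high or self.lai_low > self.lai_high:
            raise ValueError("low bounds must not exceed high bounds")
        if not (0 < self.classification_threshold < 1):
            raise ValueError("classification threshold must lie in (0, 1)")


@dataclass(frozen=True)
class CoverRegression:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    p_value: float
    slope_se: float
    n: int


def regress_cover(coarse: CoverRaster, fine: CoverRaster) -> CoverRegression:
    """OLS of coarse cover on block-aggregated fine cover.

    Fine pixels are averaged over each coarse footprint (NaN-aware); coarse
    pixels whose footprint holds no valid fine pixel are dropped.
    """
    ratio = coarse.pixel_size / fine.pixel_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("fine pixel must divide coarse pixel")
    factor = int(round(ratio))
    agg = block_aggregate(fine.values, factor)
    nr = min(agg.shape[0], coarse.values.shape[0])
    nc = min(agg.shape[1], coarse.values.shape[1])
    if nr == 0 or nc == 0:
        raise ValueError("no overlapping extent between rasters")
    x = agg[:nr, :nc].ravel()
    y = coarse.values[:nr, :nc].ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 overlapping valid coarse pixels")
    res = stats.linregress(x[ok], y[ok])
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return CoverRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        f_stat=float(t**2),
        p_value=float(res.pvalue),
        slope_se=float(res.stderr),
        n=int(ok.sum()),
    )


def classify_sagebrush(fine: CoverRaster, threshold: float = 0.5) -> CoverRaster:
    """Binary map: 1 where cover ≥ threshold (inclusive), nodata preserved."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    vals = np.where(
        np.isfinite(fine.values),
        (fine.values >= threshold).astype(float),
        np.nan,
    )
    return CoverRaster(vals, fine.pixel_size, fine.origin, fine.crs_tag)


def mask_umbra(
    mask: CoverRaster, track: UmbraTrack
) -> tuple[np.ndarray, float]:
    """Umbra-covered sagebrush area per minute and over the track union.

    A pixel counts when its center lies within the shadow circle
    (boundary inclusive) and the mask value is 1.  A track entirely
    outside the extent yields zeros, which is valid, not an error.
    """
    xs, ys = mask.pixel_centers()
    on = np.isfinite(mask.values) & (mask.values >= 0.5)
    per_minute = np.zeros(len(track))
    union = np.zeros(mask.values.shape, dtype=bool)
    for i, ((cx, cy), r) in enumerate(zip(track.centers, track.radii)):
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2
        hit = inside & on
        per_minute[i] = hit.sum() * mask.pixel_area_m2
        union |= hit
    return per_minute, float(union.sum() * mask.pixel_area_m2)


def leaf_area_bounds(
    ground_area_m2: float, scenario: ScalingScenario = ScalingScenario()
) -> tuple[float, float]:
    """Low/high leaf area (m²): ground area × cover fraction × LAI.

    Cover and LAI uncertainty combine multiplicatively into one envelope.
    """
    if ground_area_m2 < 0:
        raise ValueError("ground area must be nonnegative")
    return (
        ground_area_m2 * scenario.cover_low * scenario.lai_low,
        ground_area_m2 * scenario.cover_high * scenario.lai_high,
    )


@dataclass(frozen=True)
class CarbonBudget:
    """Regional with/without-eclipse carbon totals (Gg C) with bounds."""

    leaf_area_low_m2: float
    leaf_area_high_m2: float
    c_no_eclipse_low_gg: float
    c_no_eclipse_high_gg: float
    c_eclipse_low_gg: float
    c_eclipse_high_gg: float
    percent_reduction: float
    window: tuple[datetime, datetime] | None = None

    @property
    def units(self) -> dict:
        return {"leaf_area": "m2", "carbon_totals": "Gg C", "percent_reduction": "%"}


def _integrate(time_s: np.ndarray, a: np.ndarray) -> float:
    """Trapezoidal integral of a rate in µmol m⁻² s⁻¹ → mol m⁻²."""
    return float(np.trapezoid(a, time_s)) * 1e-6


def carbon_budget(
    leaf_area_low_m2: float,
    leaf_area_high_m2: float,
    time,
    a_obs,
    a_cf,
    window: tuple[datetime, datetime] | None = None,
) -> CarbonBudget:
    """Scale leaf assimilation to regional Gg-carbon totals per bound.

    Total C (Gg) = leaf area (m²) · ∫A dt (mol m⁻²) · 12.011 g mol⁻¹ /
    10⁹.  The percent reduction uses the deficit over the no-eclipse
    total and is identical for both bounds (linearity in leaf area).
    """
    if leaf_area_low_m2 < 0 or leaf_area_high_m2 < 0:
        raise ValueError("leaf-area bounds must be nonnegative")
    t = np.asarray(time, dtype="datetime64[ns]")
    a_o = np.asarray(a_obs, dtype=float)
    a_c = np.asarray(a_cf, dtype=float)
    if not (len(t) == len(a_o) == len(a_c)):
        raise ValueError("misaligned series")
    if window is not None:
        m = (t >= np.datetime64(window[0])) & (t <= np.datetime64(window[1]))
        t, a_o, a_c = t[m], a_o[m], a_c[m]
    sec = (t - t[0]).astype("timedelta64[ns]").astype(float) / 1e9
    mol_obs = _integrate(sec, a_o)
    mol_cf = _integrate(sec, a_c)
    if mol_obs < 0 or mol_cf < 0:
        warnings.warn(
            "negative integrated assimilation: respiration-dominated day",
            stacklevel=2,
        )
    to_gg = CARBON_MOLAR_MASS / 1e9
    c_no_low = leaf_area_low_m2 * mol_cf * to_gg
    c_no_high = leaf_area_high_m2 * mol_cf * to_gg
    c_ec_low = leaf_area_low_m2 * mol_obs * to_gg
    c_ec_high = leaf_area_high_m2 * mol_obs * to_gg
    reduction = 100.0 * (1.0 - mol_obs / mol_cf) if mol_cf != 0 else np.nan
    return CarbonBudget(
        leaf_area_low_m2=leaf_area_low_m2,
        leaf_area_high_m2=leaf_area_high_m2,
        c_no_eclipse_low_gg=c_no_low,
        c_no_eclipse_high_gg=c_no_high,
        c_eclipse_low_gg=c_ec_low,
        c_eclipse_high_gg=c_ec_high,
        percent_reduction=reduction,
        window=window,
    )
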