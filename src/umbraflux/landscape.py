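"""Synthetic paired cover rasters and a moving-umbra track.

The fine (30 m) raster is a spatially correlated shrub-cover field; the
coarse (90 m) raster is the block mean of the fine field pushed through a
configured linear relation plus Gaussian noise scaled so the coarse–fine
regression lands near a target R².  The umbra track is a straight line of
1-minute timestamped shadow centers with a fixed radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy.ndimage import gaussian_filter

from .rasters import CoverRaster, UmbraTrack

__all__ = ["LandscapeParams", "generate_landscape", "block_aggregate"]


@dataclass(frozen=True)
class LandscapeParams:
    extent_m: tuple[float, float] = (20000.0, 20000.0)
    coarse_pixel_m: float = 90.0
    fine_pixel_m: float = 30.0
    cover_mean: float = 0.45
    cover_sd: float = 0.15
    corr_length_m: float = 150.0
    coarse_fine_slope: float = 1.0
    coarse_fine_intercept: float = 0.0
    coarse_fine_r2_target: float = 0.67
    umbra_radius_m: float = 57500.0  # ~115 km wide path of totality
    track_start: tuple[float, float] = (-70000.0, 10000.0)
    track_end: tuple[float, float] = (90000.0, 10000.0)
    track_speed_m_s: float = 900.0
    track_start_time: datetime = field(
        default_factory=lambda: datetime(2017, 8, 21, 10, 37)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        ratio = self.coarse_pixel_m / self.fine_pixel_m
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fine_pixel must divide coarse_pixel")
        if not (0 <= self.cover_mean <= 1):
            raise ValueError("cover_mean must lie in [0, 1]")
        if self.umbra_radius_m <= 0:
            raise ValueError("umbra_radius must be positive")
        if min(self.extent_m) < self.coarse_pixel_m:
            raise ValueError("extent smaller than one coarse pixel")


def block_aggregate(values: np.ndarray, factor: int) -> np.ndarray:
    """Mean of ``factor``×``factor`` blocks, ignoring NaN; all-NaN → NaN."""
    nrow, ncol = values.shape
    nr, nc = nrow // factor, ncol // factor
    v = values[: nr * factor, : nc * factor].reshape(nr, factor, nc, factor)
    v = v.transpose(0, 2, 1, 3).reshape(nr, nc, factor * factor)
    with warnings.catch_warnings():
        # all-NaN blocks legitimately aggregate to NaN (nodata footprint)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(v, axis=2)


def generate_landscape(
    params: LandscapeParams = LandscapeParams(),
) -> tuple[CoverRaster, CoverRaster, UmbraTrack]:
    rng = np.random.default_rng(params.seed)
    factor = int(round(params.coarse_pixel_m / params.fine_pixel_m))
    ncol = int(params.extent_m[0] // params.fine_pixel_m)
    nrow = int(params.extent_m[1] // params.fine_pixel_m)
    # trim to whole coarse pixels so the grids align exactly
    ncol -= ncol % factor
    nrow -= nrow % factor

    white = rng.standard_normal((nrow, ncol))
    sigma_px = params.corr_length_m / params.fine_pixel_m
    fieldv = gaussian_filter(white, sigma=sigma_px, mode="wrap")
    sd = fieldv.std()
    if sd > 0 and params.cover_sd > 0:
        fieldv = fieldv / sd * params.cover_sd
    fine_vals = np.clip(params.cover_mean + fieldv, 0.0, 1.0)
    fine = CoverRaster(fine_vals, params.fine_pixel_m, (0.0, 0.0))

    agg = block_aggregate(fine_vals, factor)
    signal = params.coarse_fine_slope * agg + params.coarse_fine_intercept
    r2 = params.coarse_fine_r2_target
    if 0 < r2 < 1:
        noise_sd = float(np.std(signal)) * np.sqrt((1.0 - r2) / r2)
    else:
        noise_sd = 0.0
    coarse_vals = signal + (
        rng.normal(0.0, noise_sd, signal.shape) if noise_sd > 0 else 0.0
    )
    coarse = CoverRaster(
        np.clip(coarse_vals, 0.0, 1.0), params.coarse_pixel_m, (0.0, 0.0)
    )

    start = np.asarray(params.track_start, dtype=float)
    end = np.asarray(params.track_end, dtype=float)
    dist = float(np.hypot(*(end - start)))
    step_m = params.track_speed_m_s * 60.0
    n_steps = max(int(dist // step_m), 1)
    fracs = np.arange(n_steps + 1) * step_m / dist
    fracs = fracs[fracs <= 1.0 + 1e-12]
    centers = start[None, :] + fracs[:, None] * (end - start)[None, :]
    times = [
        params.track_start_time + timedelta(minutes=int(i))
        for i in range(len(centers))
    ]
    track = UmbraTrack(times=times, centers=centers, radius_m=params.umbra_radius_m)
    return coarse, fine, track
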