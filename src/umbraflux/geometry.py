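"""Eclipse contact-time geometry and solar-disk obscuration.

The moon's and sun's apparent disks are treated as circles of equal radius
(``apparent_radius_ratio`` defaults to 1) whose center separation shrinks
linearly from tangency at first contact (C1) to zero at the start of
totality (C2), stays zero through totality, and grows back to tangency at
last contact (C4).  The obscured fraction of the solar disk is the
two-disk lens-overlap area divided by the solar disk area.  Real ephemeris
computation is out of scope: the four contact times are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

__all__ = ["EclipseGeometry", "obscuration_fraction"]

# Default contact times for the 2017-08-21 event at the Wyoming site (MST).
# Totality lasts 138 s; the partial+total phase lasts 2 h 45 min 36 s.
# Mid-totality is placed on a whole minute so 60-s logger grids sample it.
_MID = datetime(2017, 8, 21, 10, 39, 0)
_TOTALITY = timedelta(seconds=138)
_FULL = timedelta(seconds=9936)


def _default(dt: datetime) -> "field":
    return field(default_factory=lambda: dt)


@dataclass(frozen=True)
class EclipseGeometry:
    """Contact times C1–C4 (local standard time) and apparent radius ratio."""

    c1_time: datetime = _default(_MID - _FULL / 2)
    c2_time: datetime = _default(_MID - _TOTALITY / 2)
    c3_time: datetime = _default(_MID + _TOTALITY / 2)
    c4_time: datetime = _default(_MID + _FULL / 2)
    apparent_radius_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (self.c1_time < self.c2_time <= self.c3_time < self.c4_time):
            raise ValueError(
                "invalid eclipse geometry: contact times must satisfy "
                "c1 < c2 <= c3 < c4"
            )
        if self.apparent_radius_ratio <= 0:
            raise ValueError("apparent_radius_ratio must be positive")

    @property
    def mid_totality(self) -> datetime:
        return self.c2_time + (self.c3_time - self.c2_time) / 2

    @property
    def totality_duration_s(self) -> float:
        return (self.c3_time - self.c2_time).total_seconds()

    @property
    def full_duration_s(self) -> float:
        return (self.c4_time - self.c1_time).total_seconds()

    def separation(self, t) -> np.ndarray:
        """Center separation in units of the solar radius (tangency = 2)."""
        t = np.asarray(t, dtype="datetime64[ns]")
        sec = (t - np.datetime64(self.c1_time)).astype("timedelta64[ns]").astype(
            float
        ) / 1e9
        t_c2 = (self.c2_time - self.c1_time).total_seconds()
        t_c3 = (self.c3_time - self.c1_time).total_seconds()
        t_c4 = (self.c4_time - self.c1_time).total_seconds()
        d = np.empty_like(sec)
        ingress = sec <= t_c2
        egress = sec >= t_c3
        d[ingress] = 2.0 * (1.0 - sec[ingress] / t_c2)
        d[egress] = 2.0 * (sec[egress] - t_c3) / (t_c4 - t_c3)
        d[~ingress & ~egress] = 0.0
        # outside [c1, c4] the linear ramps exceed tangency; clip handles it
        return np.clip(d, 0.0, None)


def _lens_fraction(d: np.ndarray) -> np.ndarray:
    """Overlap fraction of two unit-radius disks at center separation ``d``.

    f = [2 acos(d/2) − (d/2)·sqrt(4 − d²)] / π for d in [0, 2], else 0.
    """
    d = np.asarray(d, dtype=float)
    x = np.clip(d / 2.0, 0.0, 1.0)
    area = 2.0 * np.arccos(x) - d * np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    return np.clip(area / np.pi, 0.0, 1.0)


def obscuration_fraction(t, geometry: EclipseGeometry) -> np.ndarray | float:
    """Fraction of the solar disk obscured at time(s) ``t``.

    Returns 0 outside [C1, C4] and exactly 1 throughout totality [C2, C3].
    Scalar in, scalar out.
    """
    scalar = np.ndim(t) == 0 and not isinstance(t, (list, tuple, np.ndarray))
    ts = np.atleast_1d(np.asarray(t, dtype="datetime64[ns]"))
    f = _lens_fraction(geometry.separation(ts))
    outside = (ts < np.datetime64(geometry.c1_time)) | (
        ts > np.datetime64(geometry.c4_time)
    )
    f[outside] = 0.0
    total = (ts >= np.datetime64(geometry.c2_time)) & (
        ts <= np.datetime64(geometry.c3_time)
    )
    f[total] = 1.0
    return float(f[0]) if scalar else f


def obscuration_from_separation(d) -> np.ndarray | float:
    """Obscured fraction directly from a separation in solar radii.

    Exposed for geometry checks (e.g. against a Monte-Carlo disk-sampling
    estimate) without constructing contact times.
    """
    out = _lens_fraction(d)
    return float(out) if np.ndim(d) == 0 else out
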