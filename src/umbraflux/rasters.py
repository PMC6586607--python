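"""Cover-fraction rasters and umbra shadow tracks.

Rasters are single-band grids of shrub cover fraction in [0, 1] on a
planar equal-area coordinate system (meters), stored as ESRI ASCII grids
(nodata −9999).  Row 0 is the top row, origin is the lower-left corner,
matching the ASCII-grid convention.  Umbra tracks are GeoJSON
FeatureCollections of Point features with ``time_mst`` and ``radius_m``
properties at strict 1-minute spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

__all__ = ["CoverRaster", "UmbraTrack", "read_ascii_grid", "write_ascii_grid"]

NODATA = -9999.0


@dataclass
class CoverRaster:
    """Grid of cover fraction with pixel size and lower-left origin (m)."""

    values: np.ndarray  # 2-D, row 0 = top; np.nan marks nodata
    pixel_size: float
    origin: tuple[float, float]  # (x, y) of the lower-left corner
    crs_tag: str = "planar-equal-area-m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        valid = self.values[np.isfinite(self.values)]
        if valid.size and (valid.min() < -1e-9 or valid.max() > 1.0 + 1e-9):
            raise ValueError("cover fractions must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size**2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of every pixel center (2-D arrays)."""
        nrow, ncol = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.pixel_size
        # row 0 is the TOP row
        ys = y0 + (nrow - np.arange(nrow) - 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def write_ascii_grid(path, raster: CoverRaster) -> None:
    nrow, ncol = raster.values.shape
    vals = np.where(np.isfinite(raster.values), raster.values, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.pixel_size:.6f}\n")
        fh.write(f"nodata_value {NODATA:.1f}\n")
        np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path) -> CoverRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header field {key!r}")
    values = np.loadtxt(lines[n_header:], ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared nrows/ncols")
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return CoverRaster(
        values=values,
        pixel_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )


@dataclass
class UmbraTrack:
    """Timestamped umbra-center points with a fixed shadow radius."""

    times: list  # datetimes at strict 60-s spacing
    centers: np.ndarray  # (n, 2) planar coordinates, m
    radius_m: float = 0.0
    radii: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if len(self.times) != len(self.centers):
            raise ValueError("times and centers length mismatch")
        if len(self.times) == 0:
            raise ValueError("umbra track must be nonempty")
        ts = pd.to_datetime(pd.Series(list(self.times)))
        gaps = ts.diff().dropna().dt.total_seconds().to_numpy()
        if len(gaps) and not np.allclose(gaps, 60.0):
            raise ValueError("umbra track requires strictly increasing 60-s spacing")
        if self.radii is None:
            self.radii = np.full(len(self.times), float(self.radius_m))
        else:
            self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("umbra radius must be positive")
        self.times = list(ts)

    def __len__(self) -> int:
        return len(self.times)


def write_umbra_geojson(path, track: UmbraTrack) -> None:
    features = []
    for t, (x, y), r in zip(track.times, track.centers, track.radii):
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                "properties": {
                    "time_mst": pd.Timestamp(t).strftime("%Y-%m-%dT%H:%M:%S"),
                    "radius_m": float(r),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_umbra_geojson(path) -> UmbraTrack:
    with open(path) as fh:
        data = json.load(fh)
    times: list[datetime] = []
    centers = []
    radii = []
    for feat in data["features"]:
        times.append(pd.Timestamp(feat["properties"]["time_mst"]).to_pydatetime())
        centers.append(feat["geometry"]["coordinates"])
        radii.append(feat["properties"]["radius_m"])
    return UmbraTrack(times=times, centers=np.asarray(centers), radii=np.asarray(radii))
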