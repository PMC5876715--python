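"""Affine grid geometry and raster I/O.

Rasters are stored as plain TIFF (via :mod:`tifffile`) with a JSON sidecar
(`<name>.tif` + `<name>.json`) carrying the affine geotransform, nodata value
and, for categorical rasters, the class legend.  Pixel indexing is 0-based
(row, col) with pixel-center semantics; the origin is the outer corner of
pixel (0, 0) and rows increase southward (y decreases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["GridGeometry", "write_raster", "read_raster"]


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned affine grid: top-left corner, square pixels, no rotation."""

    nrows: int
    ncols: int
    pixel_size: float = 2.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.nrows}x{self.ncols}")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size**2

    @property
    def transform(self) -> tuple[float, float, float, float, float, float]:
        """GDAL-style geotransform (x0, dx, 0, y0, 0, -dy)."""
        return (self.x0, self.pixel_size, 0.0, self.y0, 0.0, -self.pixel_size)

    def xy(self, row, col):
        """Map coordinates of pixel centers."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.y0 - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def rowcol(self, x, y):
        """Pixel indices of the cells containing map points (x, y)."""
        col = np.floor((np.asarray(x) - self.x0) / self.pixel_size).astype(int)
        row = np.floor((self.y0 - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    def contains(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_raster(
    path,
    data: np.ndarray,
    geometry: GridGeometry,
    *,
    nodata=None,
    band_names=None,
    legend=None,
) -> Path:
    """Write a 2-D (rows, cols) or 3-D (bands, rows, cols) raster + sidecar.

    ``legend`` may be any JSON-serialisable object (e.g. ``{class_id: name}``).
    """
    path = Path(path)
    data = np.asarray(data)
    if data.ndim == 2:
        shape = data.shape
    elif data.ndim == 3:
        shape = data.shape[1:]
    else:
        raise ValueError("raster must be 2-D or 3-D (bands first)")
    if shape != geometry.shape:
        raise ValueError(f"raster shape {shape} does not match geometry {geometry.shape}")
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "transform": geometry.transform,
        "pixel_size": geometry.pixel_size,
        "nrows": geometry.nrows,
        "ncols": geometry.ncols,
        "nodata": nodata,
        "band_names": list(band_names) if band_names is not None else None,
        "legend": legend,
        "dtype": str(data.dtype),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_raster(path) -> tuple[np.ndarray, GridGeometry, dict]:
    """Read a raster written by :func:`write_raster`; returns (data, geometry, meta)."""
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    t = meta["transform"]
    geom = GridGeometry(
        nrows=meta["nrows"], ncols=meta["ncols"], pixel_size=meta["pixel_size"], x0=t[0], y0=t[3]
    )
    if meta.get("legend") is not None and isinstance(meta["legend"], dict):
        meta["legend"] = {int(k): v for k, v in meta["legend"].items()}
    return data, geom, meta
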