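"""Per-pixel feature stacks for single-season and bi-seasonal classification.

A single-season set comprises, per band, the reflectance value and three
local texture statistics (mean, range, sample standard deviation over a
square moving window, 3x3 by default), plus NDVI and the terrain model:
8 + 8 + 8 + 8 + 1 + 1 = 34 features.  The bi-seasonal set is the union of the
wet and dry sets with a single terrain feature: 67.

Border pixels use the truncated in-grid neighborhood (no padding).
Cloud-masked pixels propagate as NaN through every feature of that season
only; the terrain feature is never masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .grid import GridGeometry
from .simulate import BAND_NAMES, SeasonalScene, TerrainModel

__all__ = [
    "FeatureSetSpec",
    "FeatureStack",
    "local_texture",
    "ndvi",
    "resample_terrain",
    "assemble",
    "extract",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which seasons enter the feature set; ``name`` one of wet|dry|biseasonal."""

    name: str
    include_dtm: bool = True

    _SEASONS = {"wet": ("wet",), "dry": ("dry",), "biseasonal": ("wet", "dry")}

    def __post_init__(self) -> None:
        if self.name not in self._SEASONS:
            raise ValueError(f"feature set name must be one of {sorted(self._SEASONS)}")

    @property
    def seasons(self) -> tuple[str, ...]:
        return self._SEASONS[self.name]

    @property
    def n_features(self) -> int:
        return 33 * len(self.seasons) + (1 if self.include_dtm else 0)


@dataclass(frozen=True)
class FeatureStack:
    """Named feature rasters sharing one grid geometry."""

    data: np.ndarray  # (n_features, rows, cols)
    descriptors: tuple[str, ...]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != len(self.descriptors):
            raise ValueError("data must be (n_features, rows, cols) matching descriptors")
        if self.data.shape[1:] != self.geometry.shape:
            raise ValueError("feature rasters do not match geometry")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError("feature descriptors must be unique")

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def feature(self, descriptor: str) -> np.ndarray:
        return self.data[self.descriptors.index(descriptor)]


def local_texture(band: np.ndarray, kernel_size: int = 3):
    """Moving-window mean, range and sample standard deviation.

    Statistics are computed over the valid (finite) pixels of the truncated
    in-grid ``kernel_size`` x ``kernel_size`` neighborhood.  Output is NaN
    where the center pixel is NaN; the standard deviation is 0 where fewer
    than two valid neighbors exist.
    """
    band = np.asarray(band, dtype=float)
    if band.size == 0:
        raise ValueError("empty raster")
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    h = kernel_size // 2
    padded = np.pad(band, h, mode="constant", constant_values=np.nan)
    win = sliding_window_view(padded, (kernel_size, kernel_size))
    valid = np.isfinite(win)
    cnt = valid.sum(axis=(2, 3))
    vals = np.where(valid, win, 0.0)
    s1 = vals.sum(axis=(2, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        big = np.where(valid, win, -np.inf).max(axis=(2, 3))
        small = np.where(valid, win, np.inf).min(axis=(2, 3))
        rng_ = big - small
        dev2 = np.where(valid, (win - mean[..., None, None]) ** 2, 0.0).sum(axis=(2, 3))
        sd = np.sqrt(dev2 / (cnt - 1))
    sd = np.where(cnt > 1, sd, 0.0)
    center_nan = ~np.isfinite(band)
    for arr in (mean, rng_, sd):
        arr[center_nan] = np.nan
    return mean, rng_, sd


def ndvi(scene: SeasonalScene, nir_band: str = "nir1") -> np.ndarray:
    """(NIR - red) / (NIR + red); a zero denominator yields 0.  NaN propagates."""
    nir = scene.band(nir_band)
    red = scene.band("red")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, 0.0)
    out[~np.isfinite(nir) | ~np.isfinite(red)] = np.nan
    return out


def resample_terrain(dtm: TerrainModel, target: GridGeometry) -> np.ndarray:
    """Nearest-neighbor resampling of the terrain raster onto ``target``.

    Each target pixel takes the value of the source cell containing its
    center (for square axis-aligned grids this is the nearest source center).
    Raises if any target center falls outside the source extent.
    """
    src = dtm.geometry
    jj = np.arange(target.ncols)
    ii = np.arange(target.nrows)
    xc = target.x0 + (jj + 0.5) * target.pixel_size
    yc = target.y0 - (ii + 0.5) * target.pixel_size
    col = np.floor((xc - src.x0) / src.pixel_size).astype(int)
    row = np.floor((src.y0 - yc) / src.pixel_size).astype(int)
    if (
        col.min() < 0
        or col.max() >= src.ncols
        or row.min() < 0
        or row.max() >= src.nrows
    ):
        raise ValueError("target extent is not covered by the terrain raster")
    return dtm.elevation[np.ix_(row, col)]


def _season_features(scene: SeasonalScene) -> tuple[list[np.ndarray], list[str]]:
    tag = scene.season
    masked = scene.bands.astype(float).copy()
    masked[:, scene.cloud_mask] = np.nan
    rasters: list[np.ndarray] = []
    names: list[str] = []
    for b, bname in enumerate(BAND_NAMES):  # reflectance block
        rasters.append(masked[b])
        names.append(f"{tag}_{bname}")
    stats: dict[str, list[np.ndarray]] = {"mean": [], "range": [], "sd": []}
    for b in range(len(BAND_NAMES)):
        m, r, s = local_texture(masked[b], kernel_size=3)
        stats["mean"].append(m)
        stats["range"].append(r)
        stats["sd"].append(s)
    for stat in ("mean", "range", "sd"):  # texture blocks, band order within each
        for b, bname in enumerate(BAND_NAMES):
            rasters.append(stats[stat][b])
            names.append(f"{tag}_{bname}_{stat}")
    nd = ndvi(scene)
    nd = nd.copy()
    nd[scene.cloud_mask] = np.nan
    rasters.append(nd)
    names.append(f"{tag}_ndvi")
    return rasters, names


def assemble(
    spec: FeatureSetSpec,
    scenes: dict[str, SeasonalScene],
    terrain: np.ndarray | None = None,
) -> FeatureStack:
    """Assemble the feature stack for ``spec`` from rendered scenes + terrain.

    ``terrain`` is a raster already on the scene grid (see
    :func:`resample_terrain`).  Feature order is stable: per season the
    reflectance block, then mean/range/sd texture blocks, then NDVI; the
    terrain feature comes last.
    """
    rasters: list[np.ndarray] = []
    names: list[str] = []
    geom: GridGeometry | None = None
    for season in spec.seasons:
        if season not in scenes:
            raise KeyError(f"feature set {spec.name!r} requires the {season} scene")
        scene = scenes[season]
        if geom is None:
            geom = scene.geometry
        elif scene.geometry != geom:
            raise ValueError("scenes do not share one grid geometry")
        r, n = _season_features(scene)
        rasters.extend(r)
        names.extend(n)
    assert geom is not None
    if spec.include_dtm:
        if terrain is None:
            raise ValueError("spec includes the terrain feature but no terrain was given")
        terrain = np.asarray(terrain, dtype=float)
        if terrain.shape != geom.shape:
            raise ValueError("terrain raster does not match scene geometry")
        rasters.append(terrain)
        names.append("dtm")
    stack = FeatureStack(
        data=np.stack(rasters).astype(float), descriptors=tuple(names), geometry=geom
    )
    assert stack.n_features == spec.n_features
    return stack


def extract(stack: FeatureStack, points: pd.DataFrame) -> pd.DataFrame:
    """Feature table at training points: one row per point, columns = descriptors.

    Points falling on NaN (cloud/nodata) pixels in any feature are excluded
    with a logged count.  Returns columns (row, col, class_id, *descriptors).
    """
    cols = ["row", "col", "class_id", *stack.descriptors]
    if len(points) == 0:
        return pd.DataFrame(columns=cols)
    rr = points["row"].to_numpy(int)
    cc = points["col"].to_numpy(int)
    if not np.all(stack.geometry.contains(rr, cc)):
        raise ValueError("training points fall outside the grid")
    values = stack.data[:, rr, cc].T  # (n_points, n_features)
    table = pd.DataFrame(values, columns=list(stack.descriptors))
    table.insert(0, "class_id", points["class_id"].to_numpy())
    table.insert(0, "col", cc)
    table.insert(0, "row", rr)
    bad = table[list(stack.descriptors)].isna().any(axis=1)
    if bad.any():
        log.info("excluded %d of %d points on nodata/cloud pixels", int(bad.sum()), len(table))
        table = table[~bad].reset_index(drop=True)
    return table
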