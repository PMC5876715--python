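"""Synthetic bi-seasonal scene generator.

Emulates the statistical structure a bi-seasonal supervised classification of
coastal plant communities relies on, without any real imagery:

* a terrain model with a contiguous high-elevation embankment ridge rising
  from a gentle seaward-to-landward ramp, plus spatially correlated noise;
* a community map driven by elevation zonation (hammock highest, then the two
  buttonwood forests, halophyte prairie, mangroves and open water lowest),
  with patch processes overlaying classes such as the invasive shrubs that
  occur irrespective of elevation;
* 8-band reflectance scenes for a wet and a dry season, with class- and
  season-specific mean signatures, independent within-class Gaussian noise,
  and seasonal contrast concentrated in the near-infrared bands for
  designated confusable class pairs;
* contiguous cloud/shadow blobs covering a configured fraction of each scene;
* training points constrained to patch interiors (edge buffer and minimum
  patch diameter), mirroring field protocols that keep samples away from
  community boundaries.

All signatures are synthetic fixtures: they encode plausible relative
structure (vegetation vs. water vs. bare soil, seasonal NIR phenology), not
measured spectra.  Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridGeometry
from .legend import (
    BLACK_MANGROVE,
    BUTTONWOOD_GLYCOPHYTE,
    BUTTONWOOD_HALOPHYTE,
    COLUBRINA,
    HALOPHYTE_PRAIRIE,
    HARDWOOD_HAMMOCK,
    MUD_FLAT,
    RED_MANGROVE,
    SCHINUS,
    UNASSIGNED,
    WATER,
    WHITE_MANGROVE,
    ClassLegend,
    default_legend,
)

__all__ = [
    "BAND_NAMES",
    "SEASONS",
    "SimulationConfig",
    "TerrainModel",
    "ClassMap",
    "SeasonalScene",
    "default_signatures",
    "seasonal_contrast_config",
    "generate_terrain",
    "generate_class_map",
    "render_scene",
    "sample_training_points",
]

#: the eight multispectral band names, in wavelength order
BAND_NAMES = ("coastal", "blue", "green", "yellow", "red", "red_edge", "nir1", "nir2")
SEASONS = ("wet", "dry")

# stream tags so each operation draws from an independent, seed-derived stream
_STREAM = {"terrain": 11, "classmap": 13, "scene_wet": 17, "scene_dry": 19, "points": 23}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[stream]]))


@dataclass(frozen=True)
class TerrainModel:
    """Bare-earth elevation raster, cm above datum."""

    elevation: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if self.elevation.shape != self.geometry.shape:
            raise ValueError("terrain shape does not match geometry")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("terrain elevation must be finite")


@dataclass(frozen=True)
class ClassMap:
    """Categorical raster over a legend; 0 marks unassigned pixels."""

    classes: np.ndarray
    geometry: GridGeometry
    legend: ClassLegend

    def __post_init__(self) -> None:
        if self.classes.shape != self.geometry.shape:
            raise ValueError("class raster shape does not match geometry")
        present = set(np.unique(self.classes)) - {UNASSIGNED}
        unknown = present - set(self.legend.class_ids)
        if unknown:
            raise ValueError(f"class ids not in legend: {sorted(unknown)}")

    def area_ha(self, class_id: int) -> float:
        n = int(np.count_nonzero(self.classes == class_id))
        return n * self.geometry.pixel_area_m2 / 10_000.0

    def mapped_areas_ha(self) -> dict[int, float]:
        return {cid: self.area_ha(cid) for cid in self.legend.class_ids}


@dataclass(frozen=True)
class SeasonalScene:
    """One season's 8-band reflectance scene plus cloud/shadow mask."""

    season: str
    bands: np.ndarray  # (8, rows, cols), reflectance in [0, 1]
    cloud_mask: np.ndarray  # bool, True where clouded
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}")
        if self.bands.shape != (len(BAND_NAMES), *self.geometry.shape):
            raise ValueError("scene bands must be (8, rows, cols) matching geometry")
        if self.cloud_mask.shape != self.geometry.shape:
            raise ValueError("cloud mask shape does not match geometry")
        if not np.all(np.isfinite(self.bands)):
            raise ValueError("reflectance must be finite")

    def band(self, name: str) -> np.ndarray:
        return self.bands[BAND_NAMES.index(name)]


def default_signatures(nir_contrast: float = 0.08) -> dict[tuple[int, str], np.ndarray]:
    """Synthetic per-class, per-season mean reflectance (8 bands, unitless).

    The two buttonwood forests share one signature except for a wet-season NIR
    offset of ``nir_contrast``; the two invasive shrubs share one signature
    except for a dry-season NIR offset.  This concentrates the discriminating
    signal for each confusable pair in a single season, the regime in which
    bi-seasonal data should outperform either season alone.
    """
    # base wet-season signatures: (coastal, blue, green, yellow, red, red_edge, nir1, nir2)
    wet = {
        BLACK_MANGROVE: [0.04, 0.04, 0.07, 0.06, 0.05, 0.22, 0.42, 0.40],
        RED_MANGROVE: [0.04, 0.04, 0.08, 0.06, 0.04, 0.25, 0.48, 0.46],
        WHITE_MANGROVE: [0.05, 0.05, 0.09, 0.07, 0.06, 0.24, 0.44, 0.41],
        BUTTONWOOD_HALOPHYTE: [0.05, 0.06, 0.10, 0.09, 0.08, 0.23, 0.38, 0.36],
        BUTTONWOOD_GLYCOPHYTE: [0.05, 0.06, 0.10, 0.09, 0.08, 0.23, 0.38, 0.36],
        HALOPHYTE_PRAIRIE: [0.07, 0.08, 0.13, 0.13, 0.13, 0.22, 0.33, 0.31],
        HARDWOOD_HAMMOCK: [0.04, 0.04, 0.08, 0.06, 0.05, 0.28, 0.52, 0.50],
        SCHINUS: [0.04, 0.05, 0.09, 0.07, 0.06, 0.26, 0.46, 0.44],
        COLUBRINA: [0.04, 0.05, 0.09, 0.07, 0.06, 0.26, 0.46, 0.44],
        MUD_FLAT: [0.10, 0.12, 0.16, 0.18, 0.20, 0.23, 0.26, 0.27],
        WATER: [0.06, 0.05, 0.04, 0.03, 0.02, 0.015, 0.01, 0.008],
    }
    sig: dict[tuple[int, str], np.ndarray] = {}
    for cid, s in wet.items():
        s = np.asarray(s, dtype=float)
        sig[(cid, "wet")] = s.copy()
        dry = s.copy()
        if cid != WATER:
            # dry-season stress: greenness drops, visible brightens slightly
            dry[5:] *= 0.85
            dry[:5] *= 1.10
        sig[(cid, "dry")] = dry
    # seasonal NIR contrast for the confusable pairs
    sig[(BUTTONWOOD_GLYCOPHYTE, "wet")][6:] += nir_contrast
    sig[(SCHINUS, "dry")][6:] += nir_contrast
    for v in sig.values():
        np.clip(v, 0.0, 1.0, out=v)
    return sig


def seasonal_contrast_config(
    seed: int = 0,
    nir_contrast: float = 0.08,
    nrows: int = 140,
    ncols: int = 140,
) -> "SimulationConfig":
    """Study conditions for the bi-seasonal vs single-season comparison.

    Two confusable class pairs carry their discriminating signal in one
    season only: the buttonwood/glycophyte forest differs from the
    buttonwood/halophyte forest solely in wet-season NIR, and the two
    invasive shrubs differ solely in dry-season NIR.  To keep the terrain
    model uninformative about the pairs, the glycophyte forest occurs as
    patches inside the halophyte-buttonwood elevation band and the invasives
    as patches across all vegetated elevations.  Either single season then
    leaves one pair spectrally identical, while the bi-seasonal feature set
    sees both.
    """
    bands = _default_elevation_bands()
    bands[BUTTONWOOD_HALOPHYTE] = (21.0, 33.0)
    del bands[BUTTONWOOD_GLYCOPHYTE]
    return SimulationConfig(
        nrows=nrows,
        ncols=ncols,
        seed=seed,
        elevation_bands=bands,
        patch_processes={
            BUTTONWOOD_GLYCOPHYTE: (300.0, 12.0),
            SCHINUS: (60.0, 12.0),
            COLUBRINA: (60.0, 12.0),
        },
        patch_hosts={BUTTONWOOD_GLYCOPHYTE: (BUTTONWOOD_HALOPHYTE,)},
        signatures=default_signatures(nir_contrast=nir_contrast),
        cloud_fraction={"wet": 0.0, "dry": 0.0},
    )


def _default_elevation_bands() -> dict[int, tuple[float, float]]:
    """Elevation band (cm) per zonal class, low to high; ends open to ±inf."""
    return {
        WATER: (-np.inf, -9.0),
        MUD_FLAT: (-9.0, -3.0),
        RED_MANGROVE: (-3.0, 3.0),
        BLACK_MANGROVE: (3.0, 9.0),
        WHITE_MANGROVE: (9.0, 15.0),
        HALOPHYTE_PRAIRIE: (15.0, 21.0),
        BUTTONWOOD_HALOPHYTE: (21.0, 27.0),
        BUTTONWOOD_GLYCOPHYTE: (27.0, 33.0),
        HARDWOOD_HAMMOCK: (33.0, np.inf),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study area.

    Elevation is in cm above datum, distances in metres, reflectance unitless
    in [0, 1].  Defaults emulate a coastal embankment: a ridge of about 45 cm
    rising from a ramp that runs from shallow open water up to the backshore.
    """

    nrows: int = 200
    ncols: int = 200
    pixel_size: float = 2.0
    seed: int = 0
    # terrain: a seaward-to-landward ramp plus an embankment ridge; the crest
    # reaches about 45 cm absolute elevation (ramp + relief) at the defaults
    ridge_row_frac: float = 0.90  # ridge crest position as a fraction of nrows
    ridge_height_cm: float = 8.0  # ridge relief above the local ramp
    ridge_sigma_m: float = 24.0  # Gaussian ridge half-width
    base_low_cm: float = -15.0  # seaward end of the background ramp
    base_high_cm: float = 38.0  # landward end
    noise_sd_cm: float = 2.5
    noise_corr_m: float = 12.0  # correlation length of the smoothed noise
    # community model
    elevation_bands: dict[int, tuple[float, float]] = field(
        default_factory=_default_elevation_bands
    )
    # class id -> (patches per km^2, patch radius m); patches overlay the zonal map
    patch_processes: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {SCHINUS: (40.0, 14.0), COLUBRINA: (40.0, 14.0)}
    )
    # patch class id -> zonal host classes its centers may fall on; a class
    # absent here may seed anywhere except open water
    patch_hosts: dict[int, tuple[int, ...]] = field(default_factory=dict)
    # spectra
    signatures: dict[tuple[int, str], np.ndarray] = field(default_factory=default_signatures)
    within_class_sd: float = 0.02
    cloud_fraction: dict[str, float] = field(
        default_factory=lambda: {"wet": 0.006, "dry": 0.009}
    )
    cloud_blob_radius_m: float = 24.0

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.nrows}x{self.ncols}")
        if self.within_class_sd < 0 or self.noise_sd_cm < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for (cid, season), s in self.signatures.items():
            s = np.asarray(s)
            if s.shape != (len(BAND_NAMES),):
                raise ValueError(f"signature for class {cid} season {season} must have 8 bands")
            if np.any(s < 0) or np.any(s > 1):
                raise ValueError(f"reflectance means must lie in [0, 1] (class {cid}, {season})")
        for season, f in self.cloud_fraction.items():
            if not 0 <= f < 1:
                raise ValueError(f"cloud fraction for {season} must be in [0, 1)")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(nrows=self.nrows, ncols=self.ncols, pixel_size=self.pixel_size)


def generate_terrain(config: SimulationConfig) -> TerrainModel:
    """Ridge + ramp + spatially correlated noise terrain; deterministic per seed."""
    geom = config.geometry
    rows = np.arange(config.nrows, dtype=float)[:, None]
    ridge_row = config.ridge_row_frac * (config.nrows - 1)
    sigma_px = max(config.ridge_sigma_m / config.pixel_size, 1e-9)
    ridge = config.ridge_height_cm * np.exp(-0.5 * ((rows - ridge_row) / sigma_px) ** 2)
    frac = rows / max(config.nrows - 1, 1)
    ramp = config.base_low_cm + (config.base_high_cm - config.base_low_cm) * frac
    elev = np.broadcast_to(ridge + ramp, geom.shape).astype(float).copy()
    if config.noise_sd_cm > 0:
        rng = _rng(config.seed, "terrain")
        white = rng.normal(size=geom.shape)
        smooth = ndimage.gaussian_filter(white, sigma=config.noise_corr_m / config.pixel_size)
        sd = smooth.std()
        if sd > 0:
            elev += smooth * (config.noise_sd_cm / sd)
    return TerrainModel(elevation=elev, geometry=geom)


def generate_class_map(
    terrain: TerrainModel,
    config: SimulationConfig,
    legend: ClassLegend | None = None,
) -> ClassMap:
    """Assign zonal classes by elevation band, then overlay patch-process classes.

    The elevation bands must cover every elevation the terrain realises;
    pixels falling in a gap raise ``ValueError``.  Patch classes (e.g. the
    invasive shrubs) are stamped as random disks on non-water pixels and may
    locally violate the zonation.
    """
    legend = legend or default_legend()
    if terrain.geometry != config.geometry:
        raise ValueError("terrain geometry does not match config")
    elev = terrain.elevation
    classes = np.full(elev.shape, UNASSIGNED, dtype=np.uint8)
    # ordered low->high by band lower edge; interval [low, high)
    for cid, (low, high) in sorted(config.elevation_bands.items(), key=lambda kv: kv[1][0]):
        sel = (elev >= low) & (elev < high)
        classes[sel] = cid
    if np.any(classes == UNASSIGNED):
        n = int(np.count_nonzero(classes == UNASSIGNED))
        raise ValueError(f"elevation bands leave {n} pixels unassignable")

    if config.patch_processes:
        rng = _rng(config.seed, "classmap")
        zonal = classes.copy()
        area_km2 = config.nrows * config.ncols * config.pixel_size**2 / 1e6
        default_host = zonal != WATER if WATER in legend.names else np.ones_like(zonal, bool)
        ii, jj = np.indices(classes.shape)
        for cid, (density, radius_m) in sorted(config.patch_processes.items()):
            if cid in config.patch_hosts:
                host = np.isin(zonal, config.patch_hosts[cid])
            else:
                host = default_host
            hr, hc = np.nonzero(host)
            n_patches = rng.poisson(density * area_km2)
            if n_patches == 0 or hr.size == 0:
                continue
            centers = rng.choice(hr.size, size=n_patches, replace=True)
            r_px = radius_m / config.pixel_size
            for k in centers:
                disk = (ii - hr[k]) ** 2 + (jj - hc[k]) ** 2 <= r_px**2
                classes[disk & host] = cid
    return ClassMap(classes=classes, geometry=config.geometry, legend=legend)


def _cloud_mask(config: SimulationConfig, season: str, rng: np.random.Generator) -> np.ndarray:
    """Contiguous blobs covering approximately the configured scene fraction."""
    geom = config.geometry
    mask = np.zeros(geom.shape, dtype=bool)
    target = config.cloud_fraction.get(season, 0.0)
    if target <= 0:
        return mask
    npix = geom.nrows * geom.ncols
    r_px = max(config.cloud_blob_radius_m / config.pixel_size, 1.0)
    # keep a single blob well below the target so small fractions are reachable
    r_px = min(r_px, max(1.0, np.sqrt(target * npix / (2 * np.pi))))
    ii, jj = np.indices(geom.shape)
    # add disks (jittered radius) until the target fraction is reached
    for _ in range(1000):
        if mask.sum() >= target * npix:
            break
        cr = rng.integers(0, geom.nrows)
        cc = rng.integers(0, geom.ncols)
        r = r_px * rng.uniform(0.6, 1.4)
        mask |= (ii - cr) ** 2 + (jj - cc) ** 2 <= r**2
    return mask


def render_scene(class_map: ClassMap, season: str, config: SimulationConfig) -> SeasonalScene:
    """Render one season: class mean + Gaussian noise per band, clipped to [0, 1]."""
    if season not in SEASONS:
        raise ValueError(f"season must be one of {SEASONS}")
    present = set(np.unique(class_map.classes)) - {UNASSIGNED}
    missing = [c for c in present if (c, season) not in config.signatures]
    if missing:
        raise KeyError(f"no {season}-season signature for classes {sorted(missing)}")
    rng = _rng(config.seed, f"scene_{season}")
    geom = class_map.geometry
    bands = np.zeros((len(BAND_NAMES), *geom.shape), dtype=float)
    for cid in sorted(present):
        sel = class_map.classes == cid
        mu = np.asarray(config.signatures[(cid, season)], dtype=float)
        n = int(sel.sum())
        vals = mu[:, None] + (
            rng.normal(0.0, config.within_class_sd, size=(len(BAND_NAMES), n))
            if config.within_class_sd > 0
            else 0.0
        )
        bands[:, sel] = vals
    np.clip(bands, 0.0, 1.0, out=bands)
    mask = _cloud_mask(config, season, rng)
    return SeasonalScene(season=season, bands=bands, cloud_mask=mask, geometry=geom)


def edge_distance_m(class_map: ClassMap) -> np.ndarray:
    """Distance (m) from each pixel center to the nearest boundary with a
    different class: Euclidean distance transform to the nearest foreign-pixel
    center, minus half a pixel."""
    px = class_map.geometry.pixel_size
    out = np.zeros(class_map.geometry.shape, dtype=float)
    for cid in np.unique(class_map.classes):
        sel = class_map.classes == cid
        d = ndimage.distance_transform_edt(sel, sampling=px)
        out[sel] = d[sel] - 0.5 * px
    return out


def sample_training_points(
    true_map: ClassMap,
    n_per_class: dict[int, int],
    min_patch_diameter_m: float = 14.0,
    edge_buffer_m: float = 7.0,
    seed: int = 0,
    source: str = "digitized",
) -> pd.DataFrame:
    """Sample labeled training pixels from patch interiors.

    A pixel is eligible for its class when (a) its center lies strictly more
    than ``edge_buffer_m`` from the community boundary and (b) its connected
    patch (8-connectivity) has a maximum inscribed-circle diameter greater
    than ``min_patch_diameter_m``.  Sampling is uniform without replacement
    within each class; infeasible requests raise with the offending classes.

    Returns a DataFrame with columns (row, col, x, y, class_id, source).
    """
    geom = true_map.geometry
    px = geom.pixel_size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM["points"]]))
    frames = []
    infeasible: dict[int, int] = {}
    struct = np.ones((3, 3), bool)  # 8-connectivity
    for cid, n_req in sorted(n_per_class.items()):
        sel = true_map.classes == cid
        if not sel.any():
            infeasible[cid] = 0
            continue
        dist = ndimage.distance_transform_edt(sel, sampling=px)
        interior = sel & (dist - 0.5 * px > edge_buffer_m)
        labels, n_comp = ndimage.label(sel, structure=struct)
        if min_patch_diameter_m > 0 and n_comp:
            diam = 2.0 * ndimage.maximum(dist, labels, index=np.arange(1, n_comp + 1))
            ok_comp = np.zeros(n_comp + 1, dtype=bool)
            ok_comp[1:] = np.asarray(diam) > min_patch_diameter_m
            interior &= ok_comp[labels]
        rr, cc = np.nonzero(interior)
        if rr.size < n_req:
            infeasible[cid] = int(rr.size)
            continue
        pick = rng.choice(rr.size, size=n_req, replace=False)
        x, y = geom.xy(rr[pick], cc[pick])
        frames.append(
            pd.DataFrame(
                {
                    "row": rr[pick],
                    "col": cc[pick],
                    "x": x,
                    "y": y,
                    "class_id": cid,
                    "source": source,
                }
            )
        )
    if infeasible:
        detail = ", ".join(
            f"class {c}: {n_per_class[c]} requested, {avail} eligible"
            for c, avail in infeasible.items()
        )
        raise ValueError(f"training sample infeasible ({detail})")
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["row", "col", "x", "y", "class_id", "source"]
    )
    dup = out.duplicated(subset=["row", "col"])
    if dup.any():
        out = out[~dup].reset_index(drop=True)
    return out
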