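"""End-to-end pipeline driver.

Chains the stages: scene input (synthetic simulation or files on disk),
feature-stack assembly, paired random-forest feature-set comparison,
final-map prediction with cloud fallback, minimum-mapping-unit filtering,
stratified reference sampling, and error-adjusted area/accuracy estimation.
Every stochastic stage derives its stream from the single configured seed;
a manifest records seeds, sizes and content hashes so a fixed-seed run is
reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from .accuracy import (
    SamplingDesign,
    adjusted_estimates,
    build_error_matrix,
    label_with_truth,
    stratified_sample,
)
from .classify import TuningPlan, compare_feature_sets, predict_map
from .grid import read_raster, write_raster
from .legend import default_legend
from .postprocess import mmu_filter
from .simulate import (
    BAND_NAMES,
    ClassMap,
    SeasonalScene,
    SimulationConfig,
    TerrainModel,
    generate_class_map,
    generate_terrain,
    render_scene,
    sample_training_points,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


def _default_training_counts() -> dict[int, int]:
    # unequal allocation: zonal communities get more points than the rarer
    # patch-process classes, mirroring field campaigns where rare classes
    # yield fewer samples
    from . import legend as L

    return {
        L.BLACK_MANGROVE: 120,
        L.RED_MANGROVE: 120,
        L.WHITE_MANGROVE: 100,
        L.BUTTONWOOD_GLYCOPHYTE: 60,
        L.BUTTONWOOD_HALOPHYTE: 80,
        L.HALOPHYTE_PRAIRIE: 100,
        L.HARDWOOD_HAMMOCK: 80,
        L.SCHINUS: 30,
        L.COLUBRINA: 30,
        L.MUD_FLAT: 100,
        L.WATER: 120,
    }


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    In simulation mode (default) the scenes, terrain and training points come
    from :mod:`coastmap.simulate`.  In file mode, ``wet_scene_path``,
    ``dry_scene_path``, ``dtm_path`` and ``points_path`` must name rasters /
    tables written by this package; accuracy assessment then also needs a
    labeled reference sample (``reference_path``).
    """

    out_dir: str | Path = "coastmap_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    # file mode
    wet_scene_path: str | None = None
    dry_scene_path: str | None = None
    dtm_path: str | None = None
    points_path: str | None = None
    reference_path: str | None = None
    # stage parameters
    plan: TuningPlan | None = None
    training_counts: dict[int, int] = field(default_factory=_default_training_counts)
    edge_buffer_m: float = 7.0
    min_patch_diameter_m: float = 14.0
    mmu_min_area_m2: float = 20.0
    mmu_connectivity: int = 8
    design: SamplingDesign | None = None
    write_stacks: bool = False

    def validate(self) -> None:
        if self.simulation is None:
            required = ("wet_scene_path", "dry_scene_path", "dtm_path", "points_path")
            for fname in required:
                if getattr(self, fname) is None:
                    raise ValueError(f"configuration error: {fname} is required in file mode")
            for fname in required:
                val = getattr(self, fname)
                if not Path(val).exists():
                    raise ValueError(f"configuration error: {fname}={val!r} does not exist")


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _load_scene(path: str, season: str) -> SeasonalScene:
    data, geom, meta = read_raster(path)
    mask_path = Path(path).with_name(Path(path).stem + "_cloud.tif")
    if mask_path.exists():
        mask, _, _ = read_raster(mask_path)
        mask = mask.astype(bool)
    else:
        mask = np.zeros(geom.shape, dtype=bool)
    return SeasonalScene(season=season, bands=data, cloud_mask=mask, geometry=geom)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    legend = default_legend()
    legend_json = {int(k): v for k, v in legend.names.items()}

    stage = "inputs"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            terrain = generate_terrain(sim)
            truth = generate_class_map(terrain, sim, legend)
            scenes = {s: render_scene(truth, s, sim) for s in ("wet", "dry")}
            points = sample_training_points(
                truth,
                config.training_counts,
                min_patch_diameter_m=config.min_patch_diameter_m,
                edge_buffer_m=config.edge_buffer_m,
                seed=config.seed,
            )
            dtm = terrain.elevation
            geom = truth.geometry
            write_raster(out / "dtm.tif", dtm, geom, band_names=["elevation_cm"])
            write_raster(out / "class_truth.tif", truth.classes, geom, nodata=0,
                         legend=legend_json)
            for s, scene in scenes.items():
                write_raster(out / f"scene_{s}.tif", scene.bands, geom,
                             band_names=list(BAND_NAMES))
                write_raster(out / f"scene_{s}_cloud.tif",
                             scene.cloud_mask.astype(np.uint8), geom)
            points.to_csv(out / "training_points.csv", index=False)
            _write_geojson(out / "training_points.geojson", points)
        else:
            truth = None
            scenes = {
                "wet": _load_scene(config.wet_scene_path, "wet"),
                "dry": _load_scene(config.dry_scene_path, "dry"),
            }
            geom = scenes["wet"].geometry
            dtm_data, dtm_geom, _ = read_raster(config.dtm_path)
            dtm = ft.resample_terrain(TerrainModel(dtm_data.astype(float), dtm_geom), geom)
            points = pd.read_csv(config.points_path)
        manifest["stages"][stage] = {
            "n_training_points": int(len(points)),
            "cloud_pct": {
                s: round(100.0 * float(sc.cloud_mask.mean()), 3) for s, sc in scenes.items()
            },
        }

        stage = "features"
        stacks = {}
        for name in ("wet", "dry", "biseasonal"):
            spec = ft.FeatureSetSpec(name)
            stacks[name] = ft.assemble(spec, scenes, dtm)
            if config.write_stacks:
                write_raster(out / f"stack_{name}.tif", stacks[name].data.astype(np.float32),
                             geom, band_names=list(stacks[name].descriptors))
        tables = {name: ft.extract(stacks[name], points) for name in stacks}
        # keep only points valid in every feature set so the comparison is paired
        keys = None
        for t in tables.values():
            k = set(zip(t["row"], t["col"]))
            keys = k if keys is None else keys & k
        for name in tables:
            t = tables[name]
            sel = [(r, c) in keys for r, c in zip(t["row"], t["col"])]
            tables[name] = t[sel].sort_values(["row", "col"]).reset_index(drop=True)
            tables[name].to_csv(out / f"table_{name}.csv", index=False)
        manifest["stages"][stage] = {
            "n_features": {n: stacks[n].n_features for n in stacks},
            "n_paired_samples": len(next(iter(tables.values()))),
        }

        stage = "classification"
        plan = config.plan or TuningPlan(seed=config.seed)
        plan = dataclasses.replace(plan, seed=config.seed)
        comparison = compare_feature_sets(tables, plan)
        comparison.table.to_csv(out / "comparison.csv")
        for name, rep in comparison.reports.items():
            rep.importance.to_csv(out / f"importance_{name}.csv", index=False)
            (out / f"model_{name}.json").write_text(json.dumps({
                "feature_set": name,
                "selected_mtry": rep.selected_mtry,
                "cv_accuracy_pct": rep.cv_accuracy_pct,
                "cv_accuracy_sd_pct": rep.cv_accuracy_sd_pct,
                "oob_accuracy_pct": rep.oob_accuracy_pct,
                "omission_error_pct": rep.omission_error_pct,
            }, indent=1))
        best = max(comparison.reports, key=lambda n: comparison.reports[n].cv_accuracy_pct)
        manifest["stages"][stage] = {
            "overall_accuracy_pct": comparison.overall_accuracy_pct,
            "selected_feature_set": best,
        }

        stage = "prediction"
        raw_map = predict_map(
            comparison.reports[best].model,
            stacks,
            {s: scenes[s].cloud_mask for s in ("wet", "dry")},
            {s: comparison.reports[s].model for s in ("wet", "dry")},
            legend,
        )
        write_raster(out / "map_raw.tif", raw_map.classes, geom, nodata=0, legend=legend_json)

        stage = "postprocess"
        clean_map = mmu_filter(raw_map, config.mmu_min_area_m2, config.mmu_connectivity)
        write_raster(out / "map_mmu.tif", clean_map.classes, geom, nodata=0, legend=legend_json)
        manifest["stages"][stage] = {
            "reclassified_pixels": int(np.count_nonzero(clean_map.classes != raw_map.classes))
        }

        stage = "accuracy"
        design = config.design or SamplingDesign(seed=config.seed)
        design = dataclasses.replace(design, seed=config.seed)
        sample = stratified_sample(clean_map, design)
        if truth is not None:
            sample = label_with_truth(sample, truth, legend)
        elif config.reference_path is not None:
            ref = pd.read_csv(config.reference_path)
            sample = sample.merge(ref[["row", "col", "ref_class"]], on=["row", "col"])
        else:
            sample.to_csv(out / "reference_sample_unlabeled.csv", index=False)
            manifest["stages"][stage] = {"note": "no reference labels; assessment skipped"}
            sample = None
        if sample is not None:
            sample.to_csv(out / "reference_sample.csv", index=False)
            areas = {
                ac: sum(clean_map.area_ha(m) for m in legend.members(ac))
                for ac in legend.assessment_classes
            }
            matrix = build_error_matrix(sample, areas)
            matrix.to_frame().to_csv(out / "error_matrix.csv")
            (out / "mapped_areas.json").write_text(json.dumps(areas, indent=1))
            report = adjusted_estimates(matrix, design.confidence)
            report.per_class.to_csv(out / "area_accuracy_report.csv")
            (out / "area_accuracy_report.json").write_text(json.dumps({
                "overall_accuracy": report.overall_accuracy,
                "overall_accuracy_se": report.overall_accuracy_se,
                "overall_accuracy_ci": report.overall_accuracy_ci,
                "naive_accuracy": report.naive_accuracy,
                "naive_accuracy_ci": report.naive_accuracy_ci,
            }, indent=1))
            manifest["stages"][stage] = {
                "overall_accuracy": report.overall_accuracy,
                "naive_accuracy": report.naive_accuracy,
            }
    except Exception as err:
        log.error("pipeline stage %r failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["hashes"] = {
        "map_raw": _sha(raw_map.classes),
        "map_mmu": _sha(clean_map.classes),
        "training_points": _sha(points[["row", "col", "class_id"]].to_numpy()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_geojson(path: Path, points: pd.DataFrame) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(r.x), float(r.y)]},
            "properties": {"row": int(r.row), "col": int(r.col),
                           "class_id": int(r.class_id), "source": str(r.source)},
        }
        for r in points.itertuples()
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
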