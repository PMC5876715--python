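"""Synthetic scene generator: terrain, zonation, rendering, training points."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coastmap import (
    ClassMap,
    GridGeometry,
    SimulationConfig,
    default_legend,
    default_signatures,
    generate_class_map,
    generate_terrain,
    render_scene,
    sample_training_points,
)
from coastmap.legend import (
    BLACK_MANGROVE,
    BUTTONWOOD_GLYCOPHYTE,
    BUTTONWOOD_HALOPHYTE,
    HALOPHYTE_PRAIRIE,
    HARDWOOD_HAMMOCK,
    RED_MANGROVE,
    WATER,
)
from coastmap.simulate import BAND_NAMES


def flat_config(**kw):
    """Flat base (no ramp), ridge only; convenient for terrain arithmetic."""
    defaults = dict(nrows=60, ncols=60, base_low_cm=0.0, base_high_cm=0.0,
                    ridge_row_frac=0.5, ridge_height_cm=45.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestTerrain:
    def test_zero_noise_constant_off_ridge(self):
        cfg = flat_config(noise_sd_cm=0.0, ridge_sigma_m=4.0)
        t = generate_terrain(cfg)
        # far from the ridge the Gaussian term vanishes -> flat base
        assert np.allclose(t.elevation[0], 0.0, atol=1e-6)
        assert np.allclose(t.elevation[-1], 0.0, atol=1e-6)

    def test_same_seed_bit_identical(self):
        cfg = flat_config(seed=5)
        a = generate_terrain(cfg)
        b = generate_terrain(cfg)
        assert np.array_equal(a.elevation, b.elevation)

    def test_different_seed_differs(self):
        a = generate_terrain(flat_config(seed=1))
        b = generate_terrain(flat_config(seed=2))
        assert not np.array_equal(a.elevation, b.elevation)

    def test_ridge_crest_mean_matches_configured_height(self):
        # over 10 seeds, mean elevation at the crest row ~ ridge height (45 cm)
        crest_means = []
        for seed in range(10):
            cfg = flat_config(seed=seed)
            t = generate_terrain(cfg)
            crest_row = round(cfg.ridge_row_frac * (cfg.nrows - 1))
            crest_means.append(t.elevation[crest_row].mean())
        assert np.mean(crest_means) == pytest.approx(45.0, abs=1.5)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            SimulationConfig(nrows=0, ncols=10)


class TestClassMap:
    def test_monotone_ramp_gives_elevation_ordered_stripes(self, legend):
        cfg = SimulationConfig(nrows=120, ncols=30, noise_sd_cm=0.0,
                               ridge_height_cm=0.0, patch_processes={})
        cm = generate_class_map(generate_terrain(cfg), cfg, legend)
        # rows are constant-elevation -> each row is a single class, and the
        # class sequence down the ramp is ordered by band
        for r in range(cfg.nrows):
            assert len(np.unique(cm.classes[r])) == 1
        seq = [cm.classes[r, 0] for r in range(cfg.nrows)]
        band_low = {cid: lo for cid, (lo, hi) in cfg.elevation_bands.items()}
        lows = [band_low[c] for c in seq]
        assert lows == sorted(lows)

    def test_no_patches_pure_function_of_elevation(self, legend):
        cfg = SimulationConfig(nrows=50, ncols=50, seed=3, patch_processes={})
        t = generate_terrain(cfg)
        cm = generate_class_map(t, cfg, legend)
        for cid, (lo, hi) in cfg.elevation_bands.items():
            sel = (t.elevation >= lo) & (t.elevation < hi)
            assert np.all(cm.classes[sel] == cid)

    def test_uncovered_elevation_raises(self, legend):
        cfg = SimulationConfig(nrows=30, ncols=30, seed=0,
                               elevation_bands={WATER: (-5.0, 5.0),
                                                BLACK_MANGROVE: (5.0, 10.0)},
                               patch_processes={})
        with pytest.raises(ValueError, match="unassignable"):
            generate_class_map(generate_terrain(cfg), cfg, legend)

    def test_zonation_rank_correlation_over_seeds(self, legend):
        # per-class mean elevation follows the configured band order exactly
        zonal = [RED_MANGROVE, BLACK_MANGROVE, HALOPHYTE_PRAIRIE,
                 BUTTONWOOD_HALOPHYTE, BUTTONWOOD_GLYCOPHYTE, HARDWOOD_HAMMOCK]
        for seed in range(5):
            cfg = SimulationConfig(seed=seed)
            t = generate_terrain(cfg)
            cm = generate_class_map(t, cfg, legend)
            mids = [np.mean(np.clip(cfg.elevation_bands[c], -30, 50)) for c in zonal]
            realized = [t.elevation[cm.classes == c].mean() for c in zonal]
            rho = stats.spearmanr(mids, realized).statistic
            assert rho == 1.0


class TestRenderScene:
    def test_zero_noise_equals_class_mean(self, legend):
        cfg = SimulationConfig(nrows=40, ncols=40, seed=1, within_class_sd=0.0,
                               cloud_fraction={"wet": 0.0, "dry": 0.0})
        cm = generate_class_map(generate_terrain(cfg), cfg, legend)
        scene = render_scene(cm, "wet", cfg)
        for cid in np.unique(cm.classes):
            sel = cm.classes == cid
            expected = cfg.signatures[(cid, "wet")]
            assert np.allclose(scene.bands[:, sel], expected[:, None])

    def test_cloud_fraction_zero_no_mask(self, legend):
        cfg = SimulationConfig(nrows=40, ncols=40, seed=1,
                               cloud_fraction={"wet": 0.0, "dry": 0.0})
        cm = generate_class_map(generate_terrain(cfg), cfg, legend)
        assert not render_scene(cm, "wet", cfg).cloud_mask.any()

    def test_cloud_fraction_approximate_and_contiguous(self, legend):
        cfg = SimulationConfig(seed=4, cloud_fraction={"wet": 0.05, "dry": 0.0})
        cm = generate_class_map(generate_terrain(cfg), cfg, legend)
        mask = render_scene(cm, "wet", cfg).cloud_mask
        frac = mask.mean()
        assert 0.05 <= frac < 0.12  # reaches target, blob granularity overshoots a bit

    def test_missing_signature_raises(self, legend):
        cfg = SimulationConfig(nrows=30, ncols=30, seed=1)
        cm = generate_class_map(generate_terrain(cfg), cfg, legend)
        sigs = {k: v for k, v in cfg.signatures.items() if k != (WATER, "wet")}
        broken = dataclasses.replace(cfg, signatures=sigs)
        with pytest.raises(KeyError, match="signature"):
            render_scene(cm, "wet", broken)

    def test_configured_nir_contrast_is_realized(self, legend):
        # +0.10 wet-vs-dry NIR1 offset for one class only -> realized
        # within-class mean difference ~ 0.10 +/- 3*sd/sqrt(n)
        delta = 0.10
        sigs = default_signatures(nir_contrast=0.0)
        base = sigs[(BUTTONWOOD_GLYCOPHYTE, "dry")].copy()
        sigs[(BUTTONWOOD_GLYCOPHYTE, "wet")] = base.copy()
        sigs[(BUTTONWOOD_GLYCOPHYTE, "dry")] = base.copy()
        sigs[(BUTTONWOOD_GLYCOPHYTE, "wet")][6] += delta
        cfg = SimulationConfig(seed=9, signatures=sigs,
                               cloud_fraction={"wet": 0.0, "dry": 0.0})
        cm = generate_class_map(generate_terrain(cfg), cfg, legend)
        wet = render_scene(cm, "wet", cfg)
        dry = render_scene(cm, "dry", cfg)
        sel = cm.classes == BUTTONWOOD_GLYCOPHYTE
        n = sel.sum()
        diff = (wet.band("nir1")[sel] - dry.band("nir1")[sel]).mean()
        tol = 3 * np.sqrt(2) * cfg.within_class_sd / np.sqrt(n)
        assert abs(diff - delta) < tol

    def test_scene_determinism(self, small_config, legend):
        cm = generate_class_map(generate_terrain(small_config), small_config, legend)
        a = render_scene(cm, "dry", small_config)
        b = render_scene(cm, "dry", small_config)
        assert np.array_equal(a.bands, b.bands)
        assert np.array_equal(a.cloud_mask, b.cloud_mask)


def checkerboard_map(legend, block=10, nblocks=4, pixel_size=2.0):
    n = block * nblocks
    ii, jj = np.indices((n, n))
    classes = np.where(((ii // block + jj // block) % 2) == 0,
                       BLACK_MANGROVE, RED_MANGROVE).astype(np.uint8)
    geom = GridGeometry(nrows=n, ncols=n, pixel_size=pixel_size)
    return ClassMap(classes=classes, geometry=geom, legend=legend)


def brute_force_eligible(cm, buffer_m):
    """Nested-loop oracle: center-to-nearest-foreign-center distance minus
    half a pixel must strictly exceed the buffer."""
    px = cm.geometry.pixel_size
    classes = cm.classes
    n, m = classes.shape
    ii, jj = np.indices((n, m))
    out = np.zeros((n, m), bool)
    for r in range(n):
        for c in range(m):
            foreign = classes != classes[r, c]
            d = np.sqrt((ii[foreign] - r) ** 2 + (jj[foreign] - c) ** 2).min() * px
            out[r, c] = d - 0.5 * px > buffer_m
    return out


class TestTrainingPoints:
    def test_zero_buffer_zero_diameter_samples_any_class_pixel(self, legend):
        cm = checkerboard_map(legend, block=5, nblocks=2)
        n_black = int((cm.classes == BLACK_MANGROVE).sum())
        pts = sample_training_points(cm, {BLACK_MANGROVE: n_black},
                                     min_patch_diameter_m=0, edge_buffer_m=0, seed=0)
        assert len(pts) == n_black
        assert (cm.classes[pts["row"], pts["col"]] == BLACK_MANGROVE).all()

    def test_single_pixel_island_infeasible(self, legend):
        classes = np.full((20, 20), BLACK_MANGROVE, dtype=np.uint8)
        classes[10, 10] = RED_MANGROVE
        cm = ClassMap(classes=classes, geometry=GridGeometry(20, 20, 2.0), legend=legend)
        with pytest.raises(ValueError, match=f"class {RED_MANGROVE}"):
            sample_training_points(cm, {RED_MANGROVE: 1},
                                   min_patch_diameter_m=0, edge_buffer_m=7.0, seed=0)

    def test_checkerboard_eligibility_matches_brute_force(self, legend):
        # 10x10-pixel blocks (20 m) with a 7 m buffer: a block surrounded on
        # all four sides by the other class keeps only its interior 2x2
        # (centers > 3.5 px from the community edge)
        cm = checkerboard_map(legend, block=10, nblocks=4)
        oracle = brute_force_eligible(cm, 7.0)
        per_block = oracle[10:20, 10:20].sum()
        assert per_block == 4
        n_eligible = int((oracle & (cm.classes == BLACK_MANGROVE)).sum())
        pts = sample_training_points(cm, {BLACK_MANGROVE: n_eligible},
                                     min_patch_diameter_m=14.0, edge_buffer_m=7.0, seed=1)
        got = set(zip(pts["row"], pts["col"]))
        want = set(zip(*np.nonzero(oracle & (cm.classes == BLACK_MANGROVE))))
        assert got == want
        with pytest.raises(ValueError, match="infeasible"):
            sample_training_points(cm, {BLACK_MANGROVE: n_eligible + 1},
                                   min_patch_diameter_m=14.0, edge_buffer_m=7.0, seed=1)

    def test_min_patch_diameter_excludes_narrow_patches(self, legend):
        # a 6-pixel-wide bar (12 m) fails a 14 m minimum inscribed diameter
        classes = np.full((30, 30), BLACK_MANGROVE, dtype=np.uint8)
        classes[12:18, :] = RED_MANGROVE
        cm = ClassMap(classes=classes, geometry=GridGeometry(30, 30, 2.0), legend=legend)
        with pytest.raises(ValueError, match="infeasible"):
            sample_training_points(cm, {RED_MANGROVE: 1},
                                   min_patch_diameter_m=14.0, edge_buffer_m=0.0, seed=0)

    def test_points_deterministic_and_unique(self, small_config, legend):
        cm = generate_class_map(generate_terrain(small_config), small_config, legend)
        counts = {BLACK_MANGROVE: 20, RED_MANGROVE: 20}
        a = sample_training_points(cm, counts, 0, 0, seed=3)
        b = sample_training_points(cm, counts, 0, 0, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert not a.duplicated(subset=["row", "col"]).any()


def test_full_generation_determinism(small_config, legend):
    """Identical seed + config give identical terrain, map, scenes and points."""
    outs = []
    for _ in range(2):
        t = generate_terrain(small_config)
        cm = generate_class_map(t, small_config, legend)
        sc = render_scene(cm, "wet", small_config)
        pts = sample_training_points(cm, {WATER: 10}, 0, 0, seed=small_config.seed)
        outs.append((t.elevation, cm.classes, sc.bands, pts))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.array_equal(outs[0][1], outs[1][1])
    assert np.array_equal(outs[0][2], outs[1][2])
    pd.testing.assert_frame_equal(outs[0][3], outs[1][3])


def test_signal_exceeds_within_class_noise():
    """Separability precondition: between-class mean spectral distance beats
    the within-class noise sd for every class pair, in at least one season."""
    cfg = SimulationConfig()
    ids = sorted({cid for cid, _ in cfg.signatures})
    for a in ids:
        for b in ids:
            if a >= b:
                continue
            dist = max(
                np.linalg.norm(cfg.signatures[(a, s)] - cfg.signatures[(b, s)])
                for s in ("wet", "dry")
            )
            assert dist > cfg.within_class_sd
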