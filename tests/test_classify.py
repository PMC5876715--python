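"""Random-forest evaluation: tuning, oob metrics, paired comparison, routing."""

import numpy as np
import pandas as pd
import pytest

from coastmap import (
    FeatureSetSpec,
    TuningPlan,
    assemble,
    compare_feature_sets,
    default_legend,
    extract,
    generate_class_map,
    generate_terrain,
    model_metrics,
    predict_map,
    render_scene,
    sample_training_points,
    tune_and_train,
)
from coastmap.legend import UNASSIGNED
from coastmap.simulate import SimulationConfig


def make_table(X, y):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "class_id", y)
    df.insert(0, "col", np.arange(len(y)))
    df.insert(0, "row", 0)
    return df


FAST = TuningPlan(n_trees=60, candidates=(1,), cv_folds=5, seed=0)


class TestTuneAndTrain:
    def test_perfectly_separated_classes(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.1, 60), rng.normal(10, 0.1, 60)])
        y = np.repeat([1, 2], 60)
        rep = tune_and_train(make_table(x[:, None], y), FAST)
        assert rep.cv_accuracy_pct == 100.0
        assert all(v == 0.0 for v in rep.omission_error_pct.values())

    def test_permuted_labels_near_chance(self):
        # a single permuted dataset can carry exploitable chance structure,
        # so the null is evaluated as the mean over independent dataset seeds
        accs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 5))
            y = rng.permutation(np.repeat([1, 2], 100))
            plan = TuningPlan(n_trees=40, candidates=(2,), cv_folds=5, seed=seed)
            accs.append(tune_and_train(make_table(X, y), plan).cv_accuracy_pct)
        assert 40.0 <= float(np.mean(accs)) <= 60.0

    @pytest.mark.parametrize("seed", range(5))
    def test_decisive_feature_ranks_first_in_importance(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 150
        y = np.repeat([1, 2], n // 2)
        X = rng.normal(size=(n, 6))
        X[:, 3] = y + rng.normal(0, 0.1, n)  # the decisive feature
        plan = TuningPlan(n_trees=100, candidates=(2,), cv_folds=5, seed=seed)
        rep = tune_and_train(make_table(X, y), plan)
        assert rep.importance.iloc[0]["feature"] == "f3"

    def test_tie_breaks_to_smallest_candidate(self):
        # a perfectly separable problem ties all candidates at 100%
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.1, 60), rng.normal(10, 0.1, 60)])
        X = np.column_stack([x, x + rng.normal(0, 0.01, 120)])
        y = np.repeat([1, 2], 60)
        plan = TuningPlan(n_trees=40, candidates=(1, 2), cv_folds=5, seed=0)
        rep = tune_and_train(make_table(X, y), plan)
        assert rep.selected_mtry == 1

    def test_class_smaller_than_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(25, 2))
        y = np.array([1] * 22 + [2] * 3)
        with pytest.raises(ValueError, match="fewer samples"):
            tune_and_train(make_table(X, y), TuningPlan(cv_folds=5, candidates=(1,)))

    def test_constant_features_flagged_but_retained(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.2, 40), rng.normal(5, 0.2, 40)])
        X = np.column_stack([x, np.full(80, 7.0)])
        rep = tune_and_train(make_table(X, np.repeat([1, 2], 40)), FAST)
        assert rep.constant_features == ("f1",)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 4))
        y = (X[:, 0] + rng.normal(0, 0.5, 100) > 0).astype(int) + 1
        reps = [tune_and_train(make_table(X, y), FAST) for _ in range(2)]
        assert reps[0].cv_accuracy_pct == reps[1].cv_accuracy_pct
        assert reps[0].selected_mtry == reps[1].selected_mtry
        assert reps[0].omission_error_pct == reps[1].omission_error_pct


class TestModelMetrics:
    def test_omission_confusion_identity(self):
        # sum over classes of (1 - omission/100) * n_c equals total oob-correct
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 3))
        y = (X[:, 0] > 0).astype(int) + (X[:, 1] > 0.5).astype(int) + 1
        table = make_table(X, y)
        rep = tune_and_train(table, TuningPlan(n_trees=200, candidates=(2,),
                                               cv_folds=3, seed=0))
        overall, omission = model_metrics(rep.model, table)
        n_c = pd.Series(y).value_counts()
        correct = sum((1 - omission[c] / 100) * n_c[c] for c in omission)
        assert correct == pytest.approx(overall / 100 * len(y), abs=1e-9)

    def test_confusable_pair_has_largest_omission(self):
        rng = np.random.default_rng(5)
        n = 90
        mu = {1: 0.0, 2: 0.4, 3: 5.0}  # classes 1 and 2 overlap, 3 is far
        X = np.concatenate([rng.normal(mu[c], 0.5, n) for c in (1, 2, 3)])[:, None]
        y = np.repeat([1, 2, 3], n)
        rep = tune_and_train(make_table(X, y), TuningPlan(n_trees=200, candidates=(1,),
                                                          cv_folds=5, seed=0))
        _, om = model_metrics(rep.model, make_table(X, y))
        assert sorted(om, key=om.get, reverse=True)[:2] == [1, 2] or \
               sorted(om, key=om.get, reverse=True)[:2] == [2, 1]
        assert om[3] < min(om[1], om[2])


class TestCompareFeatureSets:
    def test_identical_tables_zero_differences(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(120, 4))
        y = (X[:, 0] > 0).astype(int) + 1
        t = make_table(X, y)
        rep = compare_feature_sets({"wet": t, "dry": t.copy(), "biseasonal": t.copy()},
                                   TuningPlan(n_trees=60, candidates=(2,), cv_folds=5, seed=0))
        assert np.allclose(rep.table["wet-dry"], 0.0)
        assert np.allclose(rep.table["bi-wet"], 0.0)

    def test_difference_columns_are_exact_subtractions(self):
        rng = np.random.default_rng(7)
        y = (rng.normal(size=150) > 0).astype(int) + 1
        tables = {}
        for name in ("wet", "dry", "biseasonal"):
            X = rng.normal(size=(150, 3))
            X[:, 0] += y * (1.0 if name != "dry" else 0.2)
            tables[name] = make_table(X, y)
        rep = compare_feature_sets(tables, TuningPlan(n_trees=60, candidates=(2,),
                                                      cv_folds=5, seed=1))
        t = rep.table
        assert np.array_equal(t["wet-dry"].to_numpy(), (t["wet"] - t["dry"]).to_numpy())
        assert np.array_equal(t["bi-dry"].to_numpy(),
                              (t["biseasonal"] - t["dry"]).to_numpy())

    def test_row_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2))
        y = np.repeat([1, 2], 30)
        a = make_table(X, y)
        b = a.copy()
        b.loc[0, "row"] = 5
        with pytest.raises(ValueError, match="different samples"):
            compare_feature_sets({"wet": a, "dry": b}, FAST)


@pytest.fixture(scope="module")
def routing_setup():
    """Small cloud-free scenes + trained models for prediction routing tests."""
    import dataclasses

    legend = default_legend()
    cfg = SimulationConfig(nrows=60, ncols=60, seed=21,
                           cloud_fraction={"wet": 0.0, "dry": 0.0})
    terrain = generate_terrain(cfg)
    cm = generate_class_map(terrain, cfg, legend)
    scenes = {s: render_scene(cm, s, cfg) for s in ("wet", "dry")}
    stacks = {n: assemble(FeatureSetSpec(n), scenes, terrain.elevation)
              for n in ("wet", "dry", "biseasonal")}
    present = [c for c in np.unique(cm.classes) if c != UNASSIGNED]
    pts = sample_training_points(cm, {c: 25 for c in present}, 0, 0, seed=21)
    plan = TuningPlan(n_trees=50, candidates=(4,), cv_folds=3, seed=0)
    models = {n: tune_and_train(extract(stacks[n], pts), plan, feature_set=n).model
              for n in stacks}
    return legend, cm, stacks, models


class TestPredictMap:
    def test_no_clouds_equals_primary_prediction(self, routing_setup):
        legend, cm, stacks, models = routing_setup
        shape = cm.geometry.shape
        clear = {s: np.zeros(shape, bool) for s in ("wet", "dry")}
        out = predict_map(models["biseasonal"], stacks, clear,
                          {"wet": models["wet"], "dry": models["dry"]}, legend)
        assert (out.classes != UNASSIGNED).all()
        # identical to predicting every pixel with the bi-seasonal model
        again = predict_map(models["biseasonal"], stacks, clear,
                            {"wet": models["wet"], "dry": models["dry"]}, legend)
        assert np.array_equal(out.classes, again.classes)

    def test_cloud_block_routed_to_other_season(self, routing_setup):
        legend, cm, stacks, models = routing_setup
        shape = cm.geometry.shape
        wet_cloud = np.zeros(shape, bool)
        wet_cloud[10:20, 10:20] = True
        masks = {"wet": wet_cloud, "dry": np.zeros(shape, bool)}
        out = predict_map(models["biseasonal"], stacks, masks,
                          {"wet": models["wet"], "dry": models["dry"]}, legend)
        # the wet-clouded block must equal the dry+terrain model's prediction
        from coastmap.classify import _predict_pixels

        want = _predict_pixels(models["dry"], stacks["dry"], wet_cloud)
        assert np.array_equal(out.classes[wet_cloud], want)

    def test_overlapping_clouds_left_unassigned(self, routing_setup):
        legend, cm, stacks, models = routing_setup
        shape = cm.geometry.shape
        wet_cloud = np.zeros(shape, bool)
        dry_cloud = np.zeros(shape, bool)
        wet_cloud[0:8, 0:8] = True
        dry_cloud[4:12, 4:12] = True
        out = predict_map(models["biseasonal"], stacks,
                          {"wet": wet_cloud, "dry": dry_cloud},
                          {"wet": models["wet"], "dry": models["dry"]}, legend)
        overlap = wet_cloud & dry_cloud
        assert (out.classes[overlap] == UNASSIGNED).all()
        assert (out.classes[~overlap] != UNASSIGNED).all()

    def test_missing_fallback_raises(self, routing_setup):
        legend, cm, stacks, models = routing_setup
        shape = cm.geometry.shape
        wet_cloud = np.zeros(shape, bool)
        wet_cloud[0, 0] = True
        with pytest.raises(ValueError, match="fallback"):
            predict_map(models["biseasonal"], stacks,
                        {"wet": wet_cloud, "dry": np.zeros(shape, bool)},
                        {"wet": models["wet"]}, legend)
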