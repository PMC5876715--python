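"""Random-forest feature-set evaluation and class-map prediction.

The classifier itself is scikit-learn's ``RandomForestClassifier``; this
module contributes the evaluation design around it: seeded tuning of the
features-per-split parameter by stratified k-fold cross-validation, paired
comparison of wet / dry / bi-seasonal feature sets on identical fold
assignments, out-of-bag class omission errors, permutation feature importance
expressed as mean decrease in accuracy, and cloud-mask fallback routing when
predicting the final map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .grid import GridGeometry
from .legend import UNASSIGNED, ClassLegend
from .simulate import ClassMap

__all__ = ["TuningPlan", "ModelReport", "ComparisonReport", "tune_and_train",
           "model_metrics", "compare_feature_sets", "predict_map"]

log = logging.getLogger(__name__)

_META_COLS = ("row", "col", "class_id")


@dataclass(frozen=True)
class TuningPlan:
    """How to tune and fit one forest.

    ``candidates`` are the features-per-split (mtry) values tried; ``None``
    means every integer from 2 to p when p <= 40, else 20 log-spaced integers
    including 2 and p.  Selection maximizes mean CV accuracy; ties go to the
    smallest candidate.
    """

    n_trees: int = 1000
    candidates: tuple[int, ...] | None = None
    cv_folds: int = 10
    seed: int = 0
    n_jobs: int = 1
    importance_repeats: int = 5

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def grid(self, p: int) -> tuple[int, ...]:
        if self.candidates is not None:
            bad = [c for c in self.candidates if not 1 <= c <= p]
            if bad:
                raise ValueError(f"candidates {bad} outside [1, {p}]")
            return tuple(sorted(set(self.candidates)))
        if p <= 2:
            return (p,)
        if p <= 40:
            return tuple(range(2, p + 1))
        g = np.unique(np.round(np.geomspace(2, p, 20)).astype(int))
        return tuple(int(v) for v in g)


@dataclass
class ModelReport:
    """Result of tuning + fitting one feature set."""

    feature_set: str
    selected_mtry: int
    cv_accuracy_pct: float  # mean over folds
    cv_accuracy_sd_pct: float  # sd over folds
    oob_accuracy_pct: float
    omission_error_pct: dict[int, float]  # per class, out-of-bag
    importance: pd.DataFrame  # columns: feature, mean_decrease_accuracy_pct
    constant_features: tuple[str, ...]
    model: RandomForestClassifier
    fold_accuracy_pct: tuple[float, ...] = ()
    cv_omission_error_pct: dict[int, float] = field(default_factory=dict)


@dataclass
class ComparisonReport:
    """Paired wet / dry / bi-seasonal comparison on identical fold assignments."""

    reports: dict[str, ModelReport]
    table: pd.DataFrame  # per-class omission errors and pairwise differences

    @property
    def overall_accuracy_pct(self) -> dict[str, float]:
        return {name: r.cv_accuracy_pct for name, r in self.reports.items()}


def _split_table(table: pd.DataFrame):
    feats = [c for c in table.columns if c not in _META_COLS]
    X = table[feats]
    y = table["class_id"].to_numpy()
    return X, y, feats


def _forest(plan: TuningPlan, mtry: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=plan.n_trees,
        max_features=mtry,
        random_state=plan.seed,
        n_jobs=plan.n_jobs,
        oob_score=True,
    )


def _cv_eval(X, y, folds, plan: TuningPlan, mtry: int):
    """Fold accuracies and pooled out-of-fold predictions for one mtry."""
    acc = []
    pooled = np.empty_like(y)
    for tr, te in folds:
        rf = _forest(plan, mtry)
        rf.oob_score = False
        rf.fit(X.iloc[tr], y[tr])
        pred = rf.predict(X.iloc[te])
        pooled[te] = pred
        acc.append(float(np.mean(pred == y[te])))
    return np.asarray(acc), pooled


def _omission_from_predictions(y, pred) -> dict[int, float]:
    out = {}
    for cid in np.unique(y):
        sel = y == cid
        out[int(cid)] = 100.0 * float(np.mean(pred[sel] != cid))
    return out


def tune_and_train(
    table: pd.DataFrame, plan: TuningPlan, *, feature_set: str = "features", folds=None
) -> ModelReport:
    """Tune mtry by stratified CV, refit on all rows, report accuracies and importance.

    Deterministic given ``plan.seed``: fold assignment, every forest and the
    permutation importance all derive from it.
    """
    X, y, feats = _split_table(table)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    small = classes[counts < plan.cv_folds]
    if small.size:
        raise ValueError(
            f"classes {small.tolist()} have fewer samples than cv_folds={plan.cv_folds}"
        )
    constant = tuple(f for f in feats if X[f].nunique(dropna=False) <= 1)
    if constant:
        log.warning("%s: constant feature columns retained: %s", feature_set, constant)

    if folds is None:
        skf = StratifiedKFold(n_splits=plan.cv_folds, shuffle=True, random_state=plan.seed)
        folds = list(skf.split(X, y))
    best_mtry, best_acc, best_folds, best_pooled = None, -1.0, None, None
    for mtry in plan.grid(len(feats)):
        acc, pooled = _cv_eval(X, y, folds, plan, mtry)
        if acc.mean() > best_acc + 1e-12:  # tie -> smallest candidate (grid is sorted)
            best_mtry, best_acc, best_folds, best_pooled = mtry, acc.mean(), acc, pooled

    model = _forest(plan, best_mtry)
    model.fit(X, y)
    oob_acc, oob_omission = model_metrics(model, table)
    imp = permutation_importance(
        model, X, y, n_repeats=plan.importance_repeats,
        random_state=plan.seed, scoring="accuracy", n_jobs=plan.n_jobs,
    )
    importance = (
        pd.DataFrame(
            {"feature": feats, "mean_decrease_accuracy_pct": 100.0 * imp.importances_mean}
        )
        .sort_values("mean_decrease_accuracy_pct", ascending=False)
        .reset_index(drop=True)
    )
    return ModelReport(
        feature_set=feature_set,
        selected_mtry=int(best_mtry),
        cv_accuracy_pct=100.0 * float(best_folds.mean()),
        cv_accuracy_sd_pct=100.0 * float(best_folds.std(ddof=1)),
        oob_accuracy_pct=oob_acc,
        omission_error_pct=oob_omission,
        importance=importance,
        constant_features=constant,
        model=model,
        fold_accuracy_pct=tuple(100.0 * best_folds),
        cv_omission_error_pct=_omission_from_predictions(y, best_pooled),
    )


def model_metrics(model: RandomForestClassifier, table: pd.DataFrame):
    """Overall accuracy and per-class omission error from out-of-bag votes.

    The model must have been fit with ``oob_score=True`` on exactly the rows
    of ``table``.  Omission error for class c is the percentage of reference-c
    samples whose out-of-bag majority vote is not c.
    """
    X, y, _ = _split_table(table)
    if not hasattr(model, "oob_decision_function_"):
        raise ValueError("model was not fit with oob_score=True")
    votes = model.oob_decision_function_
    if votes.shape[0] != len(y):
        raise ValueError("table does not match the model's training data")
    never_oob = ~np.isfinite(votes).all(axis=1)
    if never_oob.any():
        log.warning("%d samples never out-of-bag; excluded from oob metrics",
                    int(never_oob.sum()))
    pred = model.classes_[np.nanargmax(np.where(np.isfinite(votes), votes, -1), axis=1)]
    ok = ~never_oob
    overall = 100.0 * float(np.mean(pred[ok] == y[ok]))
    omission = {}
    for cid in np.unique(y):
        sel = (y == cid) & ok
        if not sel.any():
            raise ValueError(f"class {cid} absent from usable oob samples")
        omission[int(cid)] = 100.0 * float(np.mean(pred[sel] != cid))
    return overall, omission


def compare_feature_sets(
    tables: dict[str, pd.DataFrame], plan: TuningPlan
) -> ComparisonReport:
    """Train one model per feature set on identical samples and fold assignments.

    ``tables`` maps feature-set name (wet, dry, biseasonal) to its feature
    table; the (row, col, class_id) triples must coincide across tables so
    the comparison is paired.  The output table carries per-class CV omission
    errors, the pairwise difference columns (wet-dry, bi-wet, bi-dry), and
    overall accuracies.
    """
    names = list(tables)
    first = tables[names[0]][list(_META_COLS)].reset_index(drop=True)
    for name in names[1:]:
        other = tables[name][list(_META_COLS)].reset_index(drop=True)
        if len(other) != len(first) or not first.equals(other):
            raise ValueError(f"feature table {name!r} has different samples than {names[0]!r}")
    y = first["class_id"].to_numpy()
    skf = StratifiedKFold(n_splits=plan.cv_folds, shuffle=True, random_state=plan.seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    reports = {
        name: tune_and_train(tables[name], plan, feature_set=name, folds=folds)
        for name in names
    }
    rows = {}
    for cid in np.unique(y):
        rows[int(cid)] = {n: reports[n].cv_omission_error_pct[int(cid)] for n in names}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "class_id"
    if {"wet", "dry", "biseasonal"} <= set(names):
        table["wet-dry"] = table["wet"] - table["dry"]
        table["bi-wet"] = table["biseasonal"] - table["wet"]
        table["bi-dry"] = table["biseasonal"] - table["dry"]
    return ComparisonReport(reports=reports, table=table)


def _predict_pixels(model: RandomForestClassifier, stack, sel: np.ndarray) -> np.ndarray:
    feats = list(model.feature_names_in_)
    idx = [stack.descriptors.index(f) for f in feats]
    X = pd.DataFrame(stack.data[idx][:, sel].T, columns=feats)
    return model.predict(X)


def predict_map(
    primary_model: RandomForestClassifier,
    stacks: dict,
    cloud_masks: dict[str, np.ndarray],
    fallback_models: dict[str, RandomForestClassifier],
    legend: ClassLegend,
) -> ClassMap:
    """Predict the class map with cloud-mask fallback routing.

    Pixels clear in both seasons use the primary (bi-seasonal) model on the
    ``biseasonal`` stack; pixels clouded in exactly one season use the other
    season's single-season model on that season's stack; pixels clouded in
    both seasons are left unassigned (sentinel 0) for post-processing to fill.
    """
    geom: GridGeometry = stacks["biseasonal"].geometry
    wet_cloud = cloud_masks["wet"]
    dry_cloud = cloud_masks["dry"]
    out = np.full(geom.shape, UNASSIGNED, dtype=np.uint8)
    clear = ~wet_cloud & ~dry_cloud
    if clear.any():
        out[clear] = _predict_pixels(primary_model, stacks["biseasonal"], clear)
    for season, clouded_other in (("wet", dry_cloud & ~wet_cloud), ("dry", wet_cloud & ~dry_cloud)):
        if clouded_other.any():
            if season not in fallback_models:
                raise ValueError(f"no fallback model for the {season} season")
            out[clouded_other] = _predict_pixels(
                fallback_models[season], stacks[season], clouded_other
            )
    both = wet_cloud & dry_cloud
    if both.any():
        log.info("%d pixels clouded in both seasons left unassigned", int(both.sum()))
    return ClassMap(classes=out, geometry=geom, legend=legend)
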