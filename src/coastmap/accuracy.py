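"""Design-based map validation: stratified sampling and error-adjusted
area / accuracy estimation.

The map's classes (after merging assessment groups) are the strata.  A simple
random sample without replacement of reference pixels is drawn within each
stratum, cross-tabulated against reference labels into an error matrix with
mapped-area weights, and fed to the standard stratified estimators for
error-adjusted class areas, user's / producer's / overall accuracies, their
standard errors and normal-approximation confidence intervals
(Olofsson et al. / Stehman good-practice estimators).  The naive overall
accuracy additionally gets an exact Clopper-Pearson binomial interval.

Notation: for map class i and reference class j, n_ij are sample counts,
n_i. row totals, A_i mapped areas, W_i = A_i / sum(A) area weights, and
p_ij = W_i * n_ij / n_i. the estimated area proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .legend import UNASSIGNED, ClassLegend
from .simulate import ClassMap

__all__ = [
    "SamplingDesign",
    "ErrorMatrix",
    "AreaAccuracyReport",
    "multinomial_sample_size",
    "stratified_sample",
    "label_with_truth",
    "build_error_matrix",
    "adjusted_estimates",
    "naive_overall_accuracy",
]


def multinomial_sample_size(
    k: int, target_accuracy: float = 0.85, confidence: float = 0.95, half_width: float = 0.1
) -> tuple[int, int]:
    """Worst-case multinomial sample size (Tortora), split evenly over strata.

    n = B * Pi * (1 - Pi) / b^2 with B the chi-square(1 df) quantile at
    1 - (1 - confidence)/k, Pi the target accuracy and b the half-width.
    Returns (total n, per-stratum n), both rounded up.
    """
    if k < 2:
        raise ValueError("need at least two classes")
    if not (0 < target_accuracy < 1 and 0 < confidence < 1 and half_width > 0):
        raise ValueError("degenerate design parameters")
    B = stats.chi2.ppf(1.0 - (1.0 - confidence) / k, df=1)
    n = B * target_accuracy * (1.0 - target_accuracy) / half_width**2
    n_total = math.ceil(n)
    return n_total, math.ceil(n_total / k)


@dataclass(frozen=True)
class SamplingDesign:
    """Stratified random design: strata are assessment classes of the map.

    ``n_per_stratum`` is an int, a {assessment class: n} mapping, or the
    string ``"census"`` (every pixel of every stratum).
    """

    n_per_stratum: int | dict[str, int] | str = 53
    target_accuracy: float = 0.85
    confidence: float = 0.95
    seed: int = 0

    def n_for(self, stratum: str, stratum_size: int) -> int:
        if self.n_per_stratum == "census":
            return stratum_size
        if isinstance(self.n_per_stratum, dict):
            n = int(self.n_per_stratum[stratum])
        else:
            n = int(self.n_per_stratum)
        if n < 2:
            raise ValueError(f"stratum {stratum!r}: need n >= 2, got {n}")
        return n


def stratified_sample(class_map: ClassMap, design: SamplingDesign) -> pd.DataFrame:
    """Simple random sample without replacement within each assessment stratum.

    Merge-group strata are sampled from the union of their member classes.
    Returns a DataFrame (row, col, map_class, source); reference labels are
    attached afterwards (e.g. :func:`label_with_truth` or photo
    interpretation).  Raises if a stratum is smaller than its target n.
    """
    rng = np.random.default_rng(design.seed)
    legend = class_map.legend
    frames = []
    for stratum in legend.assessment_classes:
        members = legend.members(stratum)
        sel = np.isin(class_map.classes, members)
        rr, cc = np.nonzero(sel)
        if rr.size == 0:  # strata are the classes the map realizes
            continue
        n = design.n_for(stratum, rr.size)
        if rr.size < n:
            raise ValueError(f"stratum {stratum!r} has {rr.size} pixels < n={n}")
        pick = rng.choice(rr.size, size=n, replace=False)
        frames.append(
            pd.DataFrame(
                {"row": rr[pick], "col": cc[pick], "map_class": stratum, "source": "stratified"}
            )
        )
    return pd.concat(frames, ignore_index=True)


def label_with_truth(
    sample: pd.DataFrame, truth: ClassMap, legend: ClassLegend | None = None
) -> pd.DataFrame:
    """Attach reference labels by looking the sample up in a truth map
    (assessment legend)."""
    legend = legend or truth.legend
    out = sample.copy()
    cids = truth.classes[out["row"].to_numpy(int), out["col"].to_numpy(int)]
    out["ref_class"] = [legend.assessment_label(int(c)) for c in cids]
    return out


@dataclass(frozen=True)
class ErrorMatrix:
    """Cross-tabulated counts (rows = map label, cols = reference label) plus
    mapped areas (ha) per map class."""

    classes: tuple[str, ...]
    counts: np.ndarray  # (k, k) non-negative integers
    areas_ha: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.areas_ha.shape != (k,) or np.any(self.areas_ha < 0):
            raise ValueError("areas must be k non-negative values")
        sampled_empty = (self.counts.sum(axis=1) > 0) & (self.areas_ha == 0)
        if sampled_empty.any():
            bad = [self.classes[i] for i in np.nonzero(sampled_empty)[0]]
            raise ValueError(f"classes with sampled pixels but zero mapped area: {bad}")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total_area_ha(self) -> float:
        return float(self.areas_ha.sum())

    @property
    def weights(self) -> np.ndarray:
        """W_i = A_i / total area."""
        return self.areas_ha / self.total_area_ha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def build_error_matrix(sample: pd.DataFrame, mapped_areas_ha: dict[str, float]) -> ErrorMatrix:
    """Cross-tabulate a labeled reference sample; class order follows
    ``mapped_areas_ha``. Record order is irrelevant."""
    classes = tuple(mapped_areas_ha)
    idx = {c: i for i, c in enumerate(classes)}
    unknown = set(sample["map_class"]) | set(sample["ref_class"])
    unknown -= set(classes)
    if unknown:
        raise ValueError(f"sample labels not in the area table: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for m, r in zip(sample["map_class"], sample["ref_class"]):
        counts[idx[m], idx[r]] += 1
    areas = np.array([mapped_areas_ha[c] for c in classes], dtype=float)
    return ErrorMatrix(classes=classes, counts=counts, areas_ha=areas)


@dataclass(frozen=True)
class AreaAccuracyReport:
    """Error-adjusted areas and accuracies with SEs and confidence intervals."""

    classes: tuple[str, ...]
    proportions: np.ndarray  # p_ij, sums to 1
    per_class: pd.DataFrame  # adjusted areas / UA / PA with SEs and CIs
    overall_accuracy: float
    overall_accuracy_se: float
    overall_accuracy_ci: tuple[float, float]
    naive_accuracy: float
    naive_accuracy_ci: tuple[float, float]
    confidence: float

    @property
    def adjusted_areas_ha(self) -> pd.Series:
        return self.per_class["adjusted_area_ha"]


def naive_overall_accuracy(
    matrix: ErrorMatrix, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Diagonal fraction of the raw counts with an exact Clopper-Pearson CI."""
    n = int(matrix.counts.sum())
    if n < 1:
        raise ValueError("empty error matrix")
    x = int(np.trace(matrix.counts))
    alpha = 1.0 - confidence
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return x / n, (lo, hi)


def adjusted_estimates(matrix: ErrorMatrix, confidence: float = 0.95) -> AreaAccuracyReport:
    """Stratified error-adjusted estimators.

    p_ij = W_i n_ij / n_i.;  adjusted area A^_j = A_tot * p_.j with
    SE(p_.j) = sqrt( sum_i W_i^2 (n_ij/n_i.)(1 - n_ij/n_i.)/(n_i. - 1) );
    user's accuracy U_i = p_ii / W_i with the within-stratum binomial SE;
    producer's accuracy P_j = p_jj / p_.j with the stratified variance;
    overall accuracy OA = sum_j p_jj = sum_i W_i U_i with
    SE = sqrt( sum_i W_i^2 U_i (1-U_i)/(n_i. - 1) ).
    Confidence intervals are estimate +/- z * SE.
    """
    k = len(matrix.classes)
    n_i = matrix.row_totals.astype(float)
    if np.any(n_i < 2):
        bad = [matrix.classes[i] for i in np.nonzero(n_i < 2)[0]]
        raise ValueError(f"strata with fewer than 2 samples (SE undefined): {bad}")
    W = matrix.weights
    A_tot = matrix.total_area_ha
    phat = matrix.counts / n_i[:, None]  # row-conditional proportions n_ij/n_i.
    p = W[:, None] * phat  # p_ij
    z = stats.norm.ppf(0.5 + confidence / 2.0)

    p_dot_j = p.sum(axis=0)
    var_p_dot_j = ((W[:, None] ** 2) * phat * (1 - phat) / (n_i[:, None] - 1)).sum(axis=0)
    se_p_dot_j = np.sqrt(var_p_dot_j)
    adj_area = A_tot * p_dot_j
    se_area = A_tot * se_p_dot_j

    UA = np.diag(phat).copy()
    se_UA = np.sqrt(UA * (1 - UA) / (n_i - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        PA = np.where(p_dot_j > 0, np.diag(p) / p_dot_j, np.nan)
    # stratified producer's-accuracy variance (area-weighted analogue of the
    # pixel-count formula; mapped areas play the role of stratum sizes)
    N_i = matrix.areas_ha
    N_hat_j = (N_i[:, None] * phat).sum(axis=0)
    se_PA = np.full(k, np.nan)
    for j in range(k):
        if p_dot_j[j] <= 0:
            continue
        t1 = N_i[j] ** 2 * (1 - PA[j]) ** 2 * UA[j] * (1 - UA[j]) / (n_i[j] - 1)
        t2 = 0.0
        for i in range(k):
            if i == j:
                continue
            t2 += N_i[i] ** 2 * phat[i, j] * (1 - phat[i, j]) / (n_i[i] - 1)
        se_PA[j] = np.sqrt((t1 + PA[j] ** 2 * t2) / N_hat_j[j] ** 2)

    OA = float(np.trace(p))
    se_OA = float(np.sqrt((W**2 * UA * (1 - UA) / (n_i - 1)).sum()))
    naive, naive_ci = naive_overall_accuracy(matrix, confidence)

    per_class = pd.DataFrame(
        {
            "mapped_area_ha": matrix.areas_ha,
            "adjusted_area_ha": adj_area,
            "adjusted_area_se_ha": se_area,
            "adjusted_area_lo_ha": adj_area - z * se_area,
            "adjusted_area_hi_ha": adj_area + z * se_area,
            "adjusted_pct_cover": 100.0 * p_dot_j,
            "users_accuracy": UA,
            "users_accuracy_se": se_UA,
            "users_accuracy_lo": UA - z * se_UA,
            "users_accuracy_hi": UA + z * se_UA,
            "producers_accuracy": PA,
            "producers_accuracy_se": se_PA,
            "producers_accuracy_lo": PA - z * se_PA,
            "producers_accuracy_hi": PA + z * se_PA,
        },
        index=list(matrix.classes),
    )
    return AreaAccuracyReport(
        classes=matrix.classes,
        proportions=p,
        per_class=per_class,
        overall_accuracy=OA,
        overall_accuracy_se=se_OA,
        overall_accuracy_ci=(OA - z * se_OA, OA + z * se_OA),
        naive_accuracy=naive,
        naive_accuracy_ci=naive_ci,
        confidence=confidence,
    )
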