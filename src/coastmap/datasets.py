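"""Packaged worked-example data.

The worked example is the published accuracy assessment of an Everglades
coastal plant-community map: a 10-class stratified reference sample (53
pixels per stratum, 530 total) cross-tabulated against photo-interpreted
reference labels, published as two-decimal row proportions, together with
the mapped class areas (7063.5 ha total) and per-class adjusted user's
accuracies.  Integer counts are reconstructed from the proportions by
multiplying by the stratum size and rounding half away from zero, which
restores every row total to exactly 53.

Note the published matrix's diagonal and the published per-class user's
accuracies disagree for some classes (their row orders appear inconsistent
at the source); the area/user's-accuracy table is treated as authoritative
for area-weighted quantities, the matrix for the raw sample counts.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .accuracy import ErrorMatrix

__all__ = ["load_assessment_matrix", "load_assessment_area_table", "SAMPLES_PER_STRATUM"]

SAMPLES_PER_STRATUM = 53


def _data(name: str):
    return resources.files("coastmap.data").joinpath(name)


def counts_from_proportions(proportions: np.ndarray, row_total: int) -> np.ndarray:
    """Reconstruct integer counts from printed row proportions: multiply by the
    row total and round half away from zero."""
    return np.floor(np.asarray(proportions, dtype=float) * row_total + 0.5).astype(np.int64)


def load_assessment_area_table() -> pd.DataFrame:
    """Mapped areas (ha) and adjusted user's accuracies per assessment class."""
    with resources.as_file(_data("assessment_area_table.csv")) as path:
        return pd.read_csv(path, index_col="class")


def load_assessment_matrix() -> ErrorMatrix:
    """The worked-example error matrix with reconstructed integer counts and
    mapped-area weights."""
    with resources.as_file(_data("assessment_matrix_proportions.csv")) as path:
        props = pd.read_csv(path, index_col="map_class")
    areas = load_assessment_area_table()["area_ha"]
    classes = tuple(props.index)
    counts = counts_from_proportions(props.to_numpy(), SAMPLES_PER_STRATUM)
    assert (counts.sum(axis=1) == SAMPLES_PER_STRATUM).all()
    return ErrorMatrix(
        classes=classes,
        counts=counts,
        areas_ha=areas.loc[list(classes)].to_numpy(float),
    )
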