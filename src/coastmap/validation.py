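"""Estimator-validation scenarios with known truth.

Builds a fixed synthetic landscape together with a "mapped" version carrying
seeded, per-pixel classification confusion, so that the design-based
estimators can be checked against exactly known targets: the true class
areas, the true overall accuracy, and — under full-census sampling — the
exact confusion proportions.  Confusion leaks each assessment class to its
three cyclic neighbors in legend order, which keeps every error-matrix cell
away from the degenerate 0/1 proportions where the variance estimators
vanish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .legend import ClassLegend
from .simulate import ClassMap, SimulationConfig, generate_class_map, generate_terrain

__all__ = ["ConfusionScenario", "confusion_scenario"]


@dataclass(frozen=True)
class ConfusionScenario:
    """A mapped/truth pair with known design-based targets."""

    map: ClassMap  # the "classified" map defining the strata
    truth: ClassMap  # the reference truth, assessment-level
    mapped_areas_ha: dict[str, float]
    true_areas_ha: dict[str, float]
    true_overall_accuracy: float

    @property
    def legend(self) -> ClassLegend:
        return self.map.legend


def confusion_scenario(
    terrain_seed: int = 2026,
    confusion_seed: int = 123,
    retain: float = 0.82,
    n_leak: int = 3,
    config: SimulationConfig | None = None,
) -> ConfusionScenario:
    """Fixed synthetic map with seeded confusion against its own truth.

    ``retain`` is the per-pixel probability a pixel keeps its true class; the
    remainder is split evenly over the next ``n_leak`` assessment classes in
    cyclic legend order.  Classes are represented at assessment level (merge
    groups collapsed onto their first member id).
    """
    if not 0 < retain <= 1:
        raise ValueError("retain must be in (0, 1]")
    cfg = config or SimulationConfig(seed=terrain_seed)
    truth_full = generate_class_map(generate_terrain(cfg), cfg)
    legend = truth_full.legend
    acl = legend.assessment_classes
    rep_id = {ac: legend.members(ac)[0] for ac in acl}

    t_ids = truth_full.classes.copy()
    for ac in acl:
        for m in legend.members(ac):
            t_ids[truth_full.classes == m] = rep_id[ac]

    rng = np.random.default_rng(confusion_seed)
    order = [rep_id[ac] for ac in acl]
    u = rng.random(t_ids.shape)
    m_ids = t_ids.copy()
    leak_each = (1.0 - retain) / n_leak
    for k, cid in enumerate(order):
        sel = t_ids == cid
        for s in range(1, n_leak + 1):
            lo = retain + (s - 1) * leak_each
            hi = retain + s * leak_each
            m_ids[sel & (u >= lo) & (u < hi)] = order[(k + s) % len(order)]

    map_cm = ClassMap(classes=m_ids, geometry=truth_full.geometry, legend=legend)
    truth_cm = ClassMap(classes=t_ids, geometry=truth_full.geometry, legend=legend)
    areas = {ac: sum(map_cm.area_ha(m) for m in legend.members(ac)) for ac in acl}
    true_areas = {ac: sum(truth_cm.area_ha(m) for m in legend.members(ac)) for ac in acl}
    return ConfusionScenario(
        map=map_cm,
        truth=truth_cm,
        mapped_areas_ha=areas,
        true_areas_ha=true_areas,
        true_overall_accuracy=float(np.mean(m_ids == t_ids)),
    )
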