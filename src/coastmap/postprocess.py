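"""Minimum-mapping-unit enforcement on predicted class maps.

Clumps (connected components of same-class pixels) below the minimum mapping
unit are dissolved: their pixels are voided and then refilled iteratively
from the outside in, each pass assigning every void pixel with at least one
labeled 3x3 neighbor the majority label among its labeled neighbors.  Passes
use simultaneous updates (all fills in a pass read the previous pass's
labels), which makes the result deterministic and independent of scan order.

Tie-breaking is fixed: a tied neighbor vote goes to whichever tied class is
most frequent in the map at the start of the fill, and a residual tie to the
lowest class id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .legend import UNASSIGNED
from .simulate import ClassMap

__all__ = ["ClumpSet", "label_clumps", "mmu_filter"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClumpSet:
    """Per-class connected components: clump-id raster + per-clump records."""

    labels: np.ndarray  # int32, 0 where unassigned
    clumps: pd.DataFrame  # columns: clump_id, class_id, n_pixels, area_m2


def label_clumps(class_map: ClassMap, connectivity: int = 8) -> ClumpSet:
    """Connected components per class; unassigned pixels are excluded.

    ``connectivity`` is 4 (edge-adjacent) or 8 (the 3x3 neighborhood).
    Clump ids are 1-based and partition the labeled pixels.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    classes = class_map.classes
    out = np.zeros(classes.shape, dtype=np.int32)
    records = []
    next_id = 1
    pixel_area = class_map.geometry.pixel_area_m2
    for cid in sorted(set(np.unique(classes)) - {UNASSIGNED}):
        sel = classes == cid
        lab, n = cc_label(sel, connectivity=conn, return_num=True)
        if n == 0:
            continue
        out[sel] = lab[sel] + next_id - 1
        sizes = np.bincount(lab[sel])[1:]
        for k, size in enumerate(sizes, start=next_id):
            records.append(
                {"clump_id": k, "class_id": int(cid), "n_pixels": int(size),
                 "area_m2": float(size * pixel_area)}
            )
        next_id += n
    clumps = pd.DataFrame(records, columns=["clump_id", "class_id", "n_pixels", "area_m2"])
    return ClumpSet(labels=out, clumps=clumps)


def _majority_fill(classes: np.ndarray, class_ids: np.ndarray) -> tuple[np.ndarray, int]:
    """Iterative outside-in gap fill; returns (filled map, number of passes)."""
    work = classes.copy()
    if not (work != UNASSIGNED).any():
        raise ValueError("map entirely void: nothing to fill from")
    # global-frequency tie-break priority, fixed at fill start: rank by
    # (-frequency, class id); lower rank wins among tied neighbor counts
    freq = {cid: int(np.count_nonzero(work == cid)) for cid in class_ids}
    order = sorted(class_ids, key=lambda c: (-freq[c], c))
    rank = {cid: r for r, cid in enumerate(order)}
    rank_arr = np.array([rank[c] for c in class_ids])

    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    n_pass = 0
    while (work == UNASSIGNED).any():
        n_pass += 1
        counts = np.zeros((len(class_ids), *work.shape), dtype=np.int16)
        for di, dj in shifts:
            shifted = np.full_like(work, UNASSIGNED)
            src = work[
                max(0, -di): work.shape[0] - max(0, di),
                max(0, -dj): work.shape[1] - max(0, dj),
            ]
            shifted[
                max(0, di): work.shape[0] - max(0, -di),
                max(0, dj): work.shape[1] - max(0, -dj),
            ] = src
            for k, cid in enumerate(class_ids):
                counts[k] += shifted == cid
        void = work == UNASSIGNED
        best = counts.max(axis=0)
        fillable = void & (best > 0)
        if not fillable.any():  # cannot happen with >=1 labeled pixel on a connected grid
            raise RuntimeError("fill stalled with void pixels remaining")
        tied = counts == best  # (k, rows, cols)
        cand_rank = np.where(tied, rank_arr[:, None, None], np.iinfo(np.int32).max)
        winner = class_ids[cand_rank.argmin(axis=0)]
        work[fillable] = winner[fillable]
    return work, n_pass


def mmu_filter(
    class_map: ClassMap, min_area_m2: float = 20.0, connectivity: int = 8
) -> ClassMap:
    """Remove clumps strictly below ``min_area_m2`` and fill the gaps.

    Pixels of surviving clumps are bit-identical in the output.  After
    filling, any newly formed sub-threshold clump consisting purely of filled
    pixels is re-voided and refilled, up to 3 bounded re-passes; residual
    violations are logged, not raised (outside-in filling can create slivers).
    """
    classes = class_map.classes
    class_ids = np.array(sorted(set(np.unique(classes)) - {UNASSIGNED}))
    if class_ids.size == 0:
        raise ValueError("map entirely void")
    pixel_area = class_map.geometry.pixel_area_m2

    cs = label_clumps(class_map, connectivity=connectivity)
    small = cs.clumps.loc[cs.clumps["area_m2"] < min_area_m2, "clump_id"].to_numpy()
    work = classes.copy()
    work[np.isin(cs.labels, small)] = UNASSIGNED
    protected = work != UNASSIGNED  # surviving-clump pixels, must not change
    n_voided = int((work == UNASSIGNED).sum())

    work, n_pass = _majority_fill(work, class_ids)
    log.info("mmu filter: voided %d pixels, filled in %d passes", n_voided, n_pass)

    for repass in range(3):
        cs2 = label_clumps(
            ClassMap(classes=work, geometry=class_map.geometry, legend=class_map.legend),
            connectivity=connectivity,
        )
        small2 = cs2.clumps.loc[cs2.clumps["area_m2"] < min_area_m2, "clump_id"].to_numpy()
        bad = np.isin(cs2.labels, small2) & ~protected
        # clumps touching protected pixels are original survivors; leave them
        bad_ids = np.unique(cs2.labels[bad])
        keep = np.unique(cs2.labels[np.isin(cs2.labels, bad_ids) & protected])
        bad &= ~np.isin(cs2.labels, keep)
        if not bad.any():
            break
        log.info("mmu filter re-pass %d: re-voiding %d filled pixels", repass + 1, int(bad.sum()))
        work[bad] = UNASSIGNED
        work, _ = _majority_fill(work, class_ids)
    else:
        log.warning("mmu filter: sub-threshold filled slivers remain after 3 re-passes")

    assert np.array_equal(work[protected], classes[protected])
    return ClassMap(classes=work, geometry=class_map.geometry, legend=class_map.legend)
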