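"""Basal / midventricular / apical slice classification and position tables.

Short-axis stacks are classified relative to a reference reader: the smallest
slice index that the reference segmented, and every index above it (towards
the base), is basal; the largest segmented index and everything below is
apical; strictly in-between slices are midventricular. Classification is done
per contour type, since LV and RV extents may differ, and per phase. A stack
the reference segmented on a single slice classifies that slice as basal.

The position table aggregates comparison metrics by position x contour type
with two Dice inclusion rules: ``dice_all`` averages over every slice
annotated by at least one reader, scoring one-sided slices 0, while
``dice_both`` averages only over slices annotated by both readers. Hausdorff
distances are averaged over both-annotated slices; absolute per-slice
millilitre differences over slices annotated by at least one reader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import CaseAnnotation, pair_cases
from .metrics import COMPARED_CTYPES, compare_slice, slice_ctype_geometry

__all__ = ["ClassificationError", "PositionMap", "classify_slices", "position_table", "position_table_wide"]

POSITIONS = ("basal", "mid", "apical")


class ClassificationError(ValueError):
    """The reference reader segmented nothing, so positions are undefined."""


@dataclass(frozen=True)
class PositionMap:
    """Slice-position rule derived from a reference reader's segmented extent."""

    ctype: str
    first_segmented: int
    last_segmented: int

    def position(self, slice_index: int) -> str:
        if slice_index <= self.first_segmented:
            return "basal"
        if slice_index >= self.last_segmented:
            return "apical"
        return "mid"


def _segments_ctype(slc, ctype: str, geom) -> bool:
    g = slice_ctype_geometry(slc, ctype, geom)
    return g is not None and g.area > 0


def classify_slices(
    reference: CaseAnnotation, ctype: str, phase: str
) -> PositionMap:
    """Position rule for ``ctype`` at ``phase`` from the reference reader."""
    segmented = [
        s.slice_index
        for s in reference.phase_slices(phase)
        if _segments_ctype(s, ctype, reference.geometry)
    ]
    if not segmented:
        raise ClassificationError(
            f"reference reader segments no {ctype!r} at phase {phase!r}"
        )
    return PositionMap(ctype, min(segmented), max(segmented))


def position_table(
    case_pairs: list[tuple[CaseAnnotation, CaseAnnotation]],
    policy: str = "reader1",
    ctypes: tuple[str, ...] = COMPARED_CTYPES,
) -> pd.DataFrame:
    """Aggregate metrics by cardiac position and contour type over a study.

    ES and ED slice pairs are pooled. Returns a tidy frame indexed by
    (position, ctype) with columns dice_all_pct, dice_both_pct, hd_mm,
    abs_ml_per_slice and the underlying slice counts; cells with no
    qualifying slices are NaN.
    """
    if policy not in ("reader1", "reader2"):
        raise ValueError(f"unknown policy {policy!r}")
    acc: dict[tuple[str, str], dict[str, list]] = {
        (pos, ct): {"dice_all": [], "dice_both": [], "hd": [], "ml": []}
        for pos in POSITIONS
        for ct in ctypes
    }
    for r1, r2 in case_pairs:
        reference = r1 if policy == "reader1" else r2
        pairs = pair_cases(r1, r2)
        phases = sorted({p.phase for p in pairs})
        for ctype in ctypes:
            pos_maps = {}
            for phase in phases:
                try:
                    pos_maps[phase] = classify_slices(reference, ctype, phase)
                except ClassificationError:
                    continue
            for pair in pairs:
                if pair.phase not in pos_maps:
                    continue
                m = compare_slice(pair.s1, pair.s2, ctype, r1.geometry)
                if m.dice is None:  # neither reader annotated this ctype
                    continue
                cell = acc[(pos_maps[pair.phase].position(pair.slice_index), ctype)]
                cell["dice_all"].append(m.dice)
                cell["ml"].append(m.abs_ml_diff)
                if m.hd is not None:  # both readers annotated
                    cell["dice_both"].append(m.dice)
                    cell["hd"].append(m.hd)
    rows = []
    for (pos, ct), cell in acc.items():
        rows.append(
            {
                "position": pos,
                "ctype": ct,
                "dice_all_pct": 100 * np.mean(cell["dice_all"]) if cell["dice_all"] else np.nan,
                "dice_both_pct": 100 * np.mean(cell["dice_both"]) if cell["dice_both"] else np.nan,
                "hd_mm": np.mean(cell["hd"]) if cell["hd"] else np.nan,
                "abs_ml_per_slice": np.mean(cell["ml"]) if cell["ml"] else np.nan,
                "n_slices_any": len(cell["dice_all"]),
                "n_slices_both": len(cell["dice_both"]),
            }
        )
    return pd.DataFrame(rows).set_index(["position", "ctype"]).sort_index()


def position_table_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot to the report layout: rows position x metric, columns contour types."""
    metrics = ["dice_all_pct", "dice_both_pct", "hd_mm", "abs_ml_per_slice"]
    wide = (
        table[metrics]
        .stack()
        .unstack("ctype")
        .rename_axis(index=["position", "metric"], columns=None)
    )
    order = [(p, m) for p in POSITIONS for m in metrics]
    return wide.reindex([ix for ix in order if ix in wide.index])
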