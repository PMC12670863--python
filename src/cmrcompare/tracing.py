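"""Error tracing: decompose a clinical-parameter difference into per-slice
contour-difference contributions.

For slice-additive parameters (volumes and masses under Simpson slice
summation) the decomposition is exact: each slice contributes
``(A1 - A2) * D / 1000`` (times 1.05 g/ml for masses), and the contributions
sum to the total reader difference. Stroke volumes combine the ED trace and
the negated ES trace. Ratio parameters (EF, scar fraction) are traced through
a first-order decomposition into their ingredient traces plus an explicitly
reported nonlinearity residual, which keeps the conservation property
auditable. Mapping parameters are decomposed per slice through the
voxel-count weighting of the global mean.

Entries are ranked by absolute contribution, so the first entry names the
slice (and contour type) most responsible for the difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import CaseAnnotation, pair_cases
from .metrics import (
    compare_slice,
    contour_union,
    metrics_table,
    polygon_area,
    slice_ctype_geometry,
)
from .params import MYO_DENSITY_G_PER_ML, _ring_area, compute_parameters
from .position import ClassificationError, classify_slices

__all__ = ["TraceError", "TraceEntry", "trace_parameter", "case_table"]


class TraceError(ValueError):
    """The parameter cannot be traced (not computable for both readers)."""


@dataclass(frozen=True)
class TraceEntry:
    """One slice-level (or residual) contribution to a parameter difference.

    ``contribution`` is signed, oriented reader1 - reader2, in the parameter's
    unit per-ingredient scale (ml, g, ms, cm^2, or % for ratio traces). The
    residual entry of a ratio trace has ``slice_index is None`` and
    ``ctype="residual"``.
    """

    slice_index: int | None
    phase: str | None
    ctype: str
    contribution: float
    dice: float | None = None
    hd: float | None = None


def _slice_region_area(slc, ctype: str, geom) -> float:
    """Area (mm^2) of the traced region on one slice; 0 when absent.

    Uses the same area definitions as the clinical-parameter computations so
    that trace contributions sum exactly to the parameter difference: the
    myocardial ring is the clamped difference of epi and endo areas, scar is
    clipped to the ring.
    """
    if slc is None:
        return 0.0
    if ctype == "myo":
        return _ring_area(slc, geom)
    if ctype == "scar":
        scar = contour_union(slc.polygons("scar"), geom)
        if scar is None:
            return 0.0
        ring = slice_ctype_geometry(slc, "myo", geom)
        return scar.intersection(ring).area if ring is not None else 0.0
    return polygon_area(slc.polygons(ctype), geom)


def _additive_trace(
    r1: CaseAnnotation,
    r2: CaseAnnotation,
    ctype: str,
    phase: str,
    scale: float,
    sign: float = 1.0,
) -> list[TraceEntry]:
    geom = r1.geometry
    d = geom.slice_distance
    entries = []
    for pair in pair_cases(r1, r2):
        if pair.phase != phase:
            continue
        a1 = _slice_region_area(pair.s1, ctype, geom)
        a2 = _slice_region_area(pair.s2, ctype, geom)
        if a1 == 0.0 and a2 == 0.0:
            continue
        m = compare_slice(pair.s1, pair.s2, "myo" if ctype == "scar" else ctype, geom)
        entries.append(
            TraceEntry(
                slice_index=pair.slice_index,
                phase=phase,
                ctype=ctype,
                contribution=sign * (a1 - a2) * d / 1000.0 * scale,
                dice=m.dice,
                hd=m.hd,
            )
        )
    return entries


def _scaled(entries: list[TraceEntry], factor: float) -> list[TraceEntry]:
    return [
        TraceEntry(e.slice_index, e.phase, e.ctype, e.contribution * factor, e.dice, e.hd)
        for e in entries
    ]


def _mapping_trace(r1: CaseAnnotation, r2: CaseAnnotation) -> list[TraceEntry]:
    from .params import _ring_voxel_mask  # voxel-in-ring membership

    geom = r1.geometry
    per_slice: dict[int, list] = {}
    totals = []
    for case in (r1, r2):
        sums, counts = {}, {}
        for slc in case.phase_slices("single"):
            if slc.value_map is None:
                continue
            mask = _ring_voxel_mask(slc, geom)
            sums[slc.slice_index] = float(slc.value_map[mask].sum())
            counts[slc.slice_index] = int(mask.sum())
        total = sum(counts.values())
        if total == 0:
            raise TraceError(f"reader {case.reader_id}: no ring voxels to trace")
        totals.append((sums, counts, total))
    (s1, c1, t1), (s2, c2, t2) = totals
    entries = []
    for idx in sorted(set(s1) | set(s2)):
        contrib = s1.get(idx, 0.0) / t1 - s2.get(idx, 0.0) / t2
        pair = [p for p in pair_cases(r1, r2) if p.slice_index == idx and p.phase == "single"]
        m = compare_slice(pair[0].s1, pair[0].s2, "myo", geom) if pair else None
        entries.append(
            TraceEntry(idx, "single", "myo", contrib,
                       dice=m.dice if m else None, hd=m.hd if m else None)
        )
    return entries


_VOLUME_TRACES = {
    "LVESV": ("lv_endo", "ES", 1.0),
    "LVEDV": ("lv_endo", "ED", 1.0),
    "RVESV": ("rv_endo", "ES", 1.0),
    "RVEDV": ("rv_endo", "ED", 1.0),
    "LVV": ("lv_endo", "single", 1.0),
    "LVM": ("myo", "ED", MYO_DENSITY_G_PER_ML),
    "PAPMU_ES": ("papmu", "ES", MYO_DENSITY_G_PER_ML),
    "PAPMU_ED": ("papmu", "ED", MYO_DENSITY_G_PER_ML),
    "SCARM": ("scar", "single", MYO_DENSITY_G_PER_ML),
}


def trace_parameter(
    r1: CaseAnnotation, r2: CaseAnnotation, parameter: str
) -> list[TraceEntry]:
    """Per-slice contributions to ``parameter``'s reader1 - reader2 difference,
    sorted by absolute contribution (largest first)."""
    p1 = compute_parameters(r1)
    p2 = compute_parameters(r2)
    for reader, p in ((r1, p1), (r2, p2)):
        if parameter not in p and parameter not in ("SCARM", "SCARF"):
            raise TraceError(
                f"parameter {parameter!r} not computable for reader {reader.reader_id!r}"
            )

    if parameter in _VOLUME_TRACES:
        ctype, phase, scale = _VOLUME_TRACES[parameter]
        if parameter == "LVM" and r1.sequence == "sax_lge":
            phase = "single"
        entries = _additive_trace(r1, r2, ctype, phase, scale)
    elif parameter in ("LVSV", "RVSV"):
        ct = "lv_endo" if parameter == "LVSV" else "rv_endo"
        entries = _additive_trace(r1, r2, ct, "ED", 1.0) + _additive_trace(
            r1, r2, ct, "ES", 1.0, sign=-1.0
        )
    elif parameter in ("LVEF", "RVEF"):
        pre = parameter[:2]
        ct = "lv_endo" if pre == "LV" else "rv_endo"
        edv2, esv2 = p2[f"{pre}EDV"].value, p2[f"{pre}ESV"].value
        if edv2 == 0:
            raise TraceError(f"{pre}EDV of reader2 is 0; EF trace undefined")
        d_edv = _additive_trace(r1, r2, ct, "ED", 1.0)
        d_esv = _additive_trace(r1, r2, ct, "ES", 1.0)
        entries = _scaled(d_edv, 100.0 * esv2 / edv2**2) + _scaled(d_esv, -100.0 / edv2)
        total = p1[parameter].value - p2[parameter].value
        residual = total - sum(e.contribution for e in entries)
        entries.append(TraceEntry(None, None, "residual", residual))
    elif parameter == "SCARF":
        scarm2, lvm2 = p2.get("SCARM"), p2.get("LVM")
        if scarm2 is None or lvm2 is None or "SCARF" not in p1 or "SCARF" not in p2:
            raise TraceError("scar fraction not computable for both readers")
        d_scar = _additive_trace(r1, r2, "scar", "single", MYO_DENSITY_G_PER_ML)
        d_lvm = _additive_trace(r1, r2, "myo", "single", MYO_DENSITY_G_PER_ML)
        entries = _scaled(d_scar, 100.0 / lvm2.value) + _scaled(
            d_lvm, -100.0 * scarm2.value / lvm2.value**2
        )
        total = p1["SCARF"].value - p2["SCARF"].value
        residual = total - sum(e.contribution for e in entries)
        entries.append(TraceEntry(None, None, "residual", residual))
    elif parameter in ("GLOBAL_T1", "GLOBAL_T2"):
        entries = _mapping_trace(r1, r2)
    elif parameter.endswith("_Area"):
        ct, phase = parameter[:2].lower(), parameter[2:4]
        geom = r1.geometry
        entries = []
        for pair in pair_cases(r1, r2):
            if pair.phase != phase:
                continue
            a1 = _slice_region_area(pair.s1, ct, geom)
            a2 = _slice_region_area(pair.s2, ct, geom)
            if a1 == a2 == 0.0:
                continue
            m = compare_slice(pair.s1, pair.s2, ct, geom)
            entries.append(
                TraceEntry(pair.slice_index, phase, ct, (a1 - a2) / 100.0, m.dice, m.hd)
            )
    elif parameter.endswith("V") and parameter[:2] in ("LA", "RA"):
        # ellipsoid volume: single-slice parameter, one entry carries the difference
        diff = p1[parameter].value - p2[parameter].value
        ct, phase = parameter[:2].lower(), parameter[2:4]
        m = None
        for pair in pair_cases(r1, r2):
            if pair.phase == phase:
                m = compare_slice(pair.s1, pair.s2, ct, r1.geometry)
                entries = [TraceEntry(pair.slice_index, phase, ct, diff,
                                      m.dice, m.hd)]
                break
        else:
            raise TraceError(f"no {phase} slice to trace {parameter}")
    else:
        raise TraceError(f"no trace rule for parameter {parameter!r}")
    return sorted(entries, key=lambda e: abs(e.contribution), reverse=True)


def case_table(r1: CaseAnnotation, r2: CaseAnnotation) -> pd.DataFrame:
    """Per-case metric table: one row per (slice, phase, ctype) with Dice,
    Hausdorff distance, areas, ml impact and cardiac position."""
    pairs = pair_cases(r1, r2)
    table = metrics_table(r1.case_id, pairs, r1.geometry)
    positions = []
    for _, row in table.iterrows():
        try:
            pm = classify_slices(r1, row["ctype"], row["phase"])
            positions.append(pm.position(row["slice_index"]))
        except ClassificationError:
            positions.append(None)
    table["position"] = positions
    return table
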