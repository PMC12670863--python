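"""Clinical parameters computed from one reader's case annotation.

Ventricular volumes follow SCMR-standard short-axis slice summation
(Simpson's method): the contoured area of every slice is multiplied by the
inter-slice distance ``D = slice_thickness + slice_gap`` and summed; there is
no inter-slice interpolation. Masses convert myocardial volume to grams with
the conventional tissue density of 1.05 g/ml. Atrial volumes use the
monoplane area-length ellipsoid model ``V = 8 A^2 / (3 pi L)``. Mapping
parameters average the parametric voxel values whose centres fall inside the
myocardial ring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .annotation import CaseAnnotation, ImageGeometry, SliceAnnotation
from .metrics import contour_union, polygon_area, slice_ctype_geometry

__all__ = [
    "MYO_DENSITY_G_PER_ML",
    "ParameterError",
    "ClinicalParameter",
    "SegmentValue",
    "chamber_volume",
    "myocardial_mass",
    "papillary_mass",
    "sv_ef",
    "scar_mass_fraction",
    "atrial_area",
    "max_caliper_mm",
    "atrial_volume",
    "global_mapping_value",
    "aha_segments",
    "refpoint_distance",
    "compute_parameters",
    "parameters_table",
]

MYO_DENSITY_G_PER_ML = 1.05

PARAMETER_UNITS = {
    "LVESV": "ml", "LVEDV": "ml", "LVSV": "ml", "LVEF": "%",
    "RVESV": "ml", "RVEDV": "ml", "RVSV": "ml", "RVEF": "%",
    "LVM": "g", "PAPMU_ES": "g", "PAPMU_ED": "g",
    "LVV": "ml", "SCARM": "g", "SCARF": "%",
    "GLOBAL_T1": "ms", "GLOBAL_T2": "ms",
    "LAES_Area": "cm2", "LAED_Area": "cm2",
    "RAES_Area": "cm2", "RAED_Area": "cm2",
    "LAESV": "ml", "LAEDV": "ml", "RAESV": "ml", "RAEDV": "ml",
}


class ParameterError(ValueError):
    """A clinical parameter cannot be computed from the given annotation."""


@dataclass(frozen=True)
class ClinicalParameter:
    name: str
    value: float
    unit: str


@dataclass(frozen=True)
class SegmentValue:
    """Per-angular-segment mapping statistics (segment model of a short-axis ring)."""

    segment_index: int  # 1-based
    mean: float
    sd: float
    voxel_count: int


# ---------------------------------------------------------------------------
# volumes and masses

def chamber_volume(
    case: CaseAnnotation,
    ctype: str,
    phase: str,
    papillary_in_cavity: bool = True,
) -> float:
    """Slice-summation chamber volume (ml) of ``ctype`` at ``phase``.

    Slices without the contour type contribute 0. With
    ``papillary_in_cavity=False`` the papillary-muscle area inside the cavity
    is subtracted slice by slice.
    """
    slices = case.phase_slices(phase)
    if not slices:
        raise ParameterError(f"case {case.case_id}: no slices at phase {phase!r}")
    d = case.geometry.slice_distance
    total = 0.0
    for slc in slices:
        area = polygon_area(slc.polygons(ctype), case.geometry)
        if not papillary_in_cavity and area > 0:
            cavity = contour_union(slc.polygons(ctype), case.geometry)
            pap = contour_union(slc.polygons("papmu"), case.geometry)
            if pap is not None:
                area -= cavity.intersection(pap).area
        total += area * d
    return total / 1000.0


def _ring_area(slc: SliceAnnotation, geom: ImageGeometry) -> float:
    """Myocardial ring area (mm^2): epi minus endo areas, clamped at 0."""
    epi = polygon_area(slc.polygons("lv_epi"), geom)
    if epi == 0.0:
        return 0.0
    endo = polygon_area(slc.polygons("lv_endo"), geom)
    return max(epi - endo, 0.0)


def myocardial_mass(case: CaseAnnotation, phase: str) -> float:
    """LV myocardial mass (g): ring volume by slice summation x 1.05 g/ml."""
    slices = case.phase_slices(phase)
    if not any(slc.polygons("lv_epi") for slc in slices):
        raise ParameterError(
            f"case {case.case_id}: no lv_epi contour at phase {phase!r}"
        )
    d = case.geometry.slice_distance
    vol_ml = sum(_ring_area(s, case.geometry) * d for s in slices) / 1000.0
    return vol_ml * MYO_DENSITY_G_PER_ML


def papillary_mass(case: CaseAnnotation, phase: str) -> float:
    """Papillary muscle mass (g) from dedicated papmu contours."""
    d = case.geometry.slice_distance
    vol_ml = (
        sum(
            polygon_area(s.polygons("papmu"), case.geometry) * d
            for s in case.phase_slices(phase)
        )
        / 1000.0
    )
    return vol_ml * MYO_DENSITY_G_PER_ML


def sv_ef(edv: float, esv: float) -> tuple[float, float | None]:
    """Stroke volume SV = EDV - ESV (ml) and ejection fraction EF = 100 SV/EDV (%).

    EF is ``None`` when EDV is 0. A negative SV (ESV > EDV) is returned as is.
    """
    sv = edv - esv
    ef = None if edv == 0 else 100.0 * sv / edv
    return sv, ef


def scar_mass_fraction(case: CaseAnnotation, phase: str = "single") -> tuple[float, float]:
    """Scar mass SCARM (g) and scar fraction SCARF (% of LVM) on an LGE stack.

    Scar polygons are clipped to the myocardial ring before summation, so
    scar reaching into the cavity or beyond the epicardium does not count.
    Returns (0, 0) when no scar is contoured.
    """
    d = case.geometry.slice_distance
    scar_vol = 0.0
    any_scar = False
    for slc in case.phase_slices(phase):
        scar = contour_union(slc.polygons("scar"), case.geometry)
        if scar is None:
            continue
        any_scar = True
        ring = slice_ctype_geometry(slc, "myo", case.geometry)
        if ring is None:
            raise ParameterError(
                f"case {case.case_id} slice {slc.slice_index}: scar contour "
                "without myocardial (lv_epi) contour"
            )
        scar_vol += scar.intersection(ring).area * d
    if not any_scar:
        return 0.0, 0.0
    scarm = scar_vol / 1000.0 * MYO_DENSITY_G_PER_ML
    lvm = myocardial_mass(case, phase)
    if lvm == 0.0:
        raise ParameterError(
            f"case {case.case_id}: scar present but myocardial mass is 0; "
            "scar fraction undefined"
        )
    return scarm, 100.0 * scarm / lvm


# ---------------------------------------------------------------------------
# atria

def atrial_area(case: CaseAnnotation, ctype: str, phase: str) -> float | None:
    """Atrial area (cm^2) on the single long-axis slice of ``phase``.

    Returns ``None`` when no contour is present (missing, as opposed to 0).
    """
    slices = case.phase_slices(phase)
    if not slices:
        return None
    contours = [c for s in slices for c in s.polygons(ctype)]
    if not contours:
        return None
    return polygon_area(contours, case.geometry) / 100.0


def max_caliper_mm(contours, geom: ImageGeometry) -> float:
    """Maximum caliper diameter (mm): largest pairwise vertex distance."""
    pts = np.vstack(
        [c.points * np.array([geom.spacing_col, geom.spacing_row]) for c in contours]
    )
    # max pairwise distance is attained on the convex hull; vertex set is small
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def atrial_volume(area_cm2: float, length_cm: float) -> float:
    """Monoplane area-length ellipsoid volume V = 8 A^2 / (3 pi L) in ml."""
    if area_cm2 < 0:
        raise ParameterError("negative atrial area")
    if length_cm <= 0:
        raise ParameterError("atrial long-axis length must be > 0")
    return 8.0 * area_cm2**2 / (3.0 * np.pi * length_cm)


def atrial_volume_from_case(
    case: CaseAnnotation, ctype: str, phase: str
) -> float | None:
    """Ellipsoid atrial volume with L = the contour's maximum caliper diameter."""
    area = atrial_area(case, ctype, phase)
    if area is None:
        return None
    if area == 0.0:
        return 0.0
    contours = [c for s in case.phase_slices(phase) for c in s.polygons(ctype)]
    length_cm = max_caliper_mm(contours, case.geometry) / 10.0
    return atrial_volume(area, length_cm)


# ---------------------------------------------------------------------------
# parametric mapping

def _ring_voxel_mask(slc: SliceAnnotation, geom: ImageGeometry) -> np.ndarray:
    """Boolean mask of value_map voxels whose centres lie in the myocardial ring."""
    if slc.value_map is None:
        raise ParameterError("slice has no value_map")
    ring = slice_ctype_geometry(slc, "myo", geom)
    if ring is None:
        raise ParameterError("slice has no lv_epi contour")
    nrow, ncol = slc.value_map.shape
    jj, ii = np.meshgrid(np.arange(ncol), np.arange(nrow))
    x = jj.ravel() * geom.spacing_col
    y = ii.ravel() * geom.spacing_row
    return shapely.contains_xy(ring, x, y).reshape(nrow, ncol)


def global_mapping_value(slc: SliceAnnotation, geom: ImageGeometry) -> float:
    """Mean voxel value (ms) within the myocardial ring of a mapping slice."""
    mask = _ring_voxel_mask(slc, geom)
    if not mask.any():
        raise ParameterError("no voxel centre inside the myocardial ring")
    return float(slc.value_map[mask].mean())


def aha_segments(
    slc: SliceAnnotation, geom: ImageGeometry, n_segments: int = 6
) -> list[SegmentValue]:
    """Partition ring voxels into equal angular segments about the LV centroid.

    Segment 1 starts at the ray through the reference point and segments
    proceed counterclockwise as seen on the image (screen y points down).
    The segments partition the ring voxels exactly, so the voxel-count
    weighted mean of segment means equals the global mapping value.
    """
    rp = slc.refpoint
    if rp is None:
        raise ParameterError("aha_segments requires a refpoint contour")
    endo = contour_union(slc.polygons("lv_endo"), geom)
    centre_src = endo if endo is not None else slice_ctype_geometry(slc, "myo", geom)
    cx, cy = centre_src.centroid.x, centre_src.centroid.y
    mask = _ring_voxel_mask(slc, geom)
    ii, jj = np.nonzero(mask)
    x = jj * geom.spacing_col - cx
    y = ii * geom.spacing_row - cy
    # flip y so "counterclockwise on screen" is increasing angle
    theta = np.arctan2(-y, x)
    rx = rp[0] * geom.spacing_col - cx
    ry = rp[1] * geom.spacing_row - cy
    theta0 = np.arctan2(-ry, rx)
    rel = np.mod(theta - theta0, 2 * np.pi)
    seg = np.minimum((rel / (2 * np.pi / n_segments)).astype(int), n_segments - 1)
    values = slc.value_map[ii, jj]
    out = []
    for k in range(n_segments):
        v = values[seg == k]
        out.append(
            SegmentValue(
                segment_index=k + 1,
                mean=float(v.mean()) if v.size else float("nan"),
                sd=float(v.std(ddof=0)) if v.size else float("nan"),
                voxel_count=int(v.size),
            )
        )
    return out


def refpoint_distance(
    s1: SliceAnnotation, s2: SliceAnnotation, geom: ImageGeometry
) -> float | None:
    """Euclidean distance (mm) between two readers' reference points."""
    p1, p2 = s1.refpoint, s2.refpoint
    if p1 is None or p2 is None:
        return None
    dx = (p1[0] - p2[0]) * geom.spacing_col
    dy = (p1[1] - p2[1]) * geom.spacing_row
    return float(np.hypot(dx, dy))


# ---------------------------------------------------------------------------
# per-sequence parameter sets

def _cine_parameters(case: CaseAnnotation) -> dict[str, float]:
    out: dict[str, float] = {}
    phases = [ph for ph in ("ES", "ED") if case.phase_slices(ph)]
    for prefix, ctype in (("LV", "lv_endo"), ("RV", "rv_endo")):
        for ph in phases:
            out[f"{prefix}{ph}V"] = chamber_volume(case, ctype, ph)
        if len(phases) == 2:
            sv, ef = sv_ef(out[f"{prefix}EDV"], out[f"{prefix}ESV"])
            out[f"{prefix}SV"] = sv
            if ef is not None:
                out[f"{prefix}EF"] = ef
    if "ED" in phases:
        try:
            out["LVM"] = myocardial_mass(case, "ED")
        except ParameterError:
            pass
    for ph in phases:
        out[f"PAPMU_{ph}"] = papillary_mass(case, ph)
    return out


def _lge_parameters(case: CaseAnnotation) -> dict[str, float]:
    out = {"LVV": chamber_volume(case, "lv_endo", "single")}
    try:
        out["LVM"] = myocardial_mass(case, "single")
    except ParameterError:
        return out
    scarm, scarf = scar_mass_fraction(case)
    out["SCARM"] = scarm
    out["SCARF"] = scarf
    return out


def _mapping_parameters(case: CaseAnnotation, name: str) -> dict[str, float]:
    vals, counts = [], []
    for slc in case.phase_slices("single"):
        if slc.value_map is None:
            continue
        mask = _ring_voxel_mask(slc, case.geometry)
        if mask.any():
            vals.append(float(slc.value_map[mask].sum()))
            counts.append(int(mask.sum()))
    if not counts:
        raise ParameterError(f"case {case.case_id}: no ring voxels for {name}")
    return {name: sum(vals) / sum(counts)}


def _atrial_parameters(case: CaseAnnotation) -> dict[str, float]:
    out: dict[str, float] = {}
    chambers = ("la",) if case.sequence == "lax_2cv" else ("la", "ra")
    for ctype in chambers:
        p = ctype.upper()
        for ph in ("ES", "ED"):
            area = atrial_area(case, ctype, ph)
            if area is None:
                continue
            out[f"{p}{ph}_Area"] = area
            vol = atrial_volume_from_case(case, ctype, ph)
            if vol is not None:
                out[f"{p}{ph}V"] = vol
    return out


def compute_parameters(case: CaseAnnotation) -> dict[str, ClinicalParameter]:
    """All clinical parameters defined for the case's sequence.

    Parameters that cannot be computed because a contour is missing are
    omitted (missing is distinguished from a value of 0).
    """
    if case.sequence == "sax_cine":
        values = _cine_parameters(case)
    elif case.sequence == "sax_lge":
        values = _lge_parameters(case)
    elif case.sequence == "sax_t1":
        values = _mapping_parameters(case, "GLOBAL_T1")
    elif case.sequence == "sax_t2":
        values = _mapping_parameters(case, "GLOBAL_T2")
    else:
        values = _atrial_parameters(case)
    return {
        name: ClinicalParameter(name, val, PARAMETER_UNITS[name])
        for name, val in values.items()
    }


def parameters_table(cases: list[CaseAnnotation]) -> pd.DataFrame:
    """Long-format parameter table: case_id, reader_id, parameter, value, unit."""
    rows = [
        {
            "case_id": c.case_id,
            "reader_id": c.reader_id,
            "parameter": p.name,
            "value": p.value,
            "unit": p.unit,
        }
        for c in cases
        for p in compute_parameters(c).values()
    ]
    return pd.DataFrame(rows, columns=["case_id", "reader_id", "parameter", "value", "unit"])
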