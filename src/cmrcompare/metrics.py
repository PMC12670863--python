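"""Contour-comparison metrics: polygon areas, Dice, Hausdorff distance, ml impact.

All metrics operate in physical millimetre coordinates obtained by scaling
pixel coordinates with the anisotropic pixel spacing. Dice is computed on
exact polygon-intersection areas (resolution independent); the Hausdorff
distance is computed between contour boundary polylines densified to a small
segment length, which bounds the discretization error by that length.

The myocardium ("myo") is treated as a virtual contour type: the set
difference between the epicardial and endocardial polygons, so that ring is
compared against ring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .annotation import Contour, GeometryError, ImageGeometry, SliceAnnotation, SlicePair

__all__ = [
    "SliceMetric",
    "polygon_area",
    "contour_union",
    "slice_ctype_geometry",
    "dice",
    "hausdorff",
    "ml_impact",
    "compare_slice",
    "metrics_table",
]

#: maximum boundary segment length (mm) used when densifying for Hausdorff
HD_DENSIFY_MM = 0.05

#: contour types compared in position tables: LV endocard, myocardial ring, RV
COMPARED_CTYPES = ("lv_endo", "myo", "rv_endo")


def _scale(points: np.ndarray, geom: ImageGeometry) -> np.ndarray:
    """Pixel (col, row) -> physical (x, y) mm."""
    return points * np.array([geom.spacing_col, geom.spacing_row])


def _polygon_mm(contour: Contour, geom: ImageGeometry) -> Polygon:
    poly = Polygon(_scale(contour.points, geom))
    if not poly.is_valid:
        raise GeometryError(f"{contour.ctype}: self-intersecting polygon")
    return poly


def polygon_area(contours: list[Contour], geom: ImageGeometry) -> float:
    """Total physical area (mm^2) of a list of polygons.

    Fragmented segmentations (several polygons for one contour type) add up:
    the total is the sum of the individual absolute shoelace areas scaled by
    the pixel spacing. An empty list has area 0.
    """
    return float(sum(_polygon_mm(c, geom).area for c in contours))


def contour_union(contours: list[Contour] | None, geom: ImageGeometry):
    """Shapely union (mm coordinates) of a contour list; ``None`` if absent/empty."""
    if not contours:
        return None
    return unary_union([_polygon_mm(c, geom) for c in contours])


def slice_ctype_geometry(slc: SliceAnnotation | None, ctype: str, geom: ImageGeometry):
    """Region of ``ctype`` on a slice as shapely geometry in mm, or ``None``.

    ``ctype="myo"`` yields the myocardial ring (lv_epi minus lv_endo); it is
    present whenever lv_epi is annotated.
    """
    if slc is None:
        return None
    if ctype == "myo":
        epi = contour_union(slc.polygons("lv_epi"), geom)
        if epi is None:
            return None
        endo = contour_union(slc.polygons("lv_endo"), geom)
        return epi if endo is None else epi.difference(endo)
    return contour_union(slc.polygons(ctype), geom)


def _as_geom(c, geom: ImageGeometry | None):
    if c is None:
        return None
    if isinstance(c, (list, tuple)):
        if geom is None:
            raise ValueError("geometry required to interpret contour lists")
        return contour_union(list(c), geom)
    return c  # already a shapely geometry


def dice(c1, c2, geom: ImageGeometry | None = None) -> float | None:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) on polygon areas.

    Accepts contour lists (with ``geom``) or shapely geometries. If one side
    is absent or empty the score is 0; if both are absent it is undefined
    (``None``) and excluded from averages.
    """
    g1, g2 = _as_geom(c1, geom), _as_geom(c2, geom)
    a1 = 0.0 if g1 is None else g1.area
    a2 = 0.0 if g2 is None else g2.area
    if a1 == 0.0 and a2 == 0.0:
        return None
    if g1 is None or g2 is None or a1 == 0.0 or a2 == 0.0:
        return 0.0
    return 2.0 * g1.intersection(g2).area / (a1 + a2)


def _boundary_points(g) -> np.ndarray:
    boundary = shapely.segmentize(g.boundary, HD_DENSIFY_MM)
    return shapely.get_coordinates(boundary)


def hausdorff(c1, c2, geom: ImageGeometry | None = None) -> float | None:
    """Symmetric Hausdorff distance (mm) between two contour boundaries.

    Computed as the maximum over both directed sup-inf distances between the
    densified boundary polylines; undefined (``None``) if either side is
    absent or empty.
    """
    g1, g2 = _as_geom(c1, geom), _as_geom(c2, geom)
    if g1 is None or g2 is None or g1.is_empty or g2.is_empty:
        return None
    p1, p2 = _boundary_points(g1), _boundary_points(g2)
    d12 = cKDTree(p2).query(p1, k=1)[0].max()
    d21 = cKDTree(p1).query(p2, k=1)[0].max()
    return float(max(d12, d21))


def ml_impact(c1, c2, geom: ImageGeometry) -> float:
    """Absolute per-slice volumetric impact |A1 - A2| * D / 1000 in ml.

    An absent side counts as area 0; D is the inter-slice distance
    (slice thickness + gap).
    """
    g1, g2 = _as_geom(c1, geom), _as_geom(c2, geom)
    a1 = 0.0 if g1 is None else g1.area
    a2 = 0.0 if g2 is None else g2.area
    return abs(a1 - a2) * geom.slice_distance / 1000.0


@dataclass(frozen=True)
class SliceMetric:
    """Per-slice, per-contour-type comparison result."""

    dice: float | None
    hd: float | None
    area_r1: float
    area_r2: float
    abs_ml_diff: float


def compare_slice(
    s1: SliceAnnotation | None,
    s2: SliceAnnotation | None,
    ctype: str,
    geom: ImageGeometry,
) -> SliceMetric:
    """All comparison metrics for one contour type on one aligned slice pair."""
    g1 = slice_ctype_geometry(s1, ctype, geom)
    g2 = slice_ctype_geometry(s2, ctype, geom)
    return SliceMetric(
        dice=dice(g1, g2),
        hd=hausdorff(g1, g2),
        area_r1=0.0 if g1 is None else g1.area,
        area_r2=0.0 if g2 is None else g2.area,
        abs_ml_diff=ml_impact(g1, g2, geom),
    )


def metrics_table(
    case_id: str,
    pairs: list[SlicePair],
    geom: ImageGeometry,
    ctypes: tuple[str, ...] = COMPARED_CTYPES,
) -> pd.DataFrame:
    """Long-format metric table over aligned slice pairs.

    One row per (slice, phase, ctype) where at least one reader annotated the
    contour type; columns match the CSV export: case_id, slice_index, phase,
    ctype, dice, hd_mm, area_r1_mm2, area_r2_mm2, abs_ml_diff.
    """
    rows = []
    for pair in pairs:
        for ctype in ctypes:
            m = compare_slice(pair.s1, pair.s2, ctype, geom)
            if m.dice is None and m.area_r1 == 0.0 and m.area_r2 == 0.0:
                continue  # neither reader annotated this ctype here
            rows.append(
                {
                    "case_id": case_id,
                    "slice_index": pair.slice_index,
                    "phase": pair.phase,
                    "ctype": ctype,
                    "dice": m.dice,
                    "hd_mm": m.hd,
                    "area_r1_mm2": m.area_r1,
                    "area_r2_mm2": m.area_r2,
                    "abs_ml_diff": m.abs_ml_diff,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "slice_index",
            "phase",
            "ctype",
            "dice",
            "hd_mm",
            "area_r1_mm2",
            "area_r2_mm2",
            "abs_ml_diff",
        ],
    )
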