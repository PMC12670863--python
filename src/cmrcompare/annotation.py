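"""Annotation data model and JSON interchange format.

One file per case per reader. Contours are closed polygons drawn on image
slices; coordinates are continuous 0-based pixel coordinates ``(col, row)``
and physical sizes come from the per-case :class:`ImageGeometry`. A contour
type may carry several polygons on one slice, which represents fragmented
segmentations (a frequent failure mode of automatic contouring).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "CTYPES",
    "POLYGON_CTYPES",
    "PHASES",
    "SEQUENCES",
    "ValidationError",
    "GeometryError",
    "PairingError",
    "Contour",
    "ImageGeometry",
    "SliceAnnotation",
    "CaseAnnotation",
    "SlicePair",
    "load_case",
    "save_case",
    "pair_cases",
]

CTYPES = ("lv_endo", "lv_epi", "rv_endo", "la", "ra", "scar", "papmu", "refpoint")
POLYGON_CTYPES = tuple(c for c in CTYPES if c != "refpoint")
PHASES = ("ES", "ED", "single")
SEQUENCES = ("sax_cine", "sax_t1", "sax_t2", "sax_lge", "lax_2cv", "lax_4cv")


class ValidationError(ValueError):
    """The file or object violates the interchange schema."""


class GeometryError(ValueError):
    """A contour is geometrically invalid (too few points, self-intersecting)."""


class PairingError(ValueError):
    """Two cases cannot be paired (different case, sequence or geometry)."""


@dataclass(frozen=True)
class Contour:
    """A single contour: a closed polygon or a reference point.

    Parameters
    ----------
    ctype
        One of :data:`CTYPES`. ``refpoint`` marks the anterior RV-insertion
        landmark used to anchor angular segment models on mapping slices.
    points
        ``(n, 2)`` array of ``(col, row)`` pixel coordinates. Polygons are
        implicitly closed (last vertex connects back to the first).
    """

    ctype: str
    points: np.ndarray

    def __post_init__(self):
        if self.ctype not in CTYPES:
            raise ValidationError(f"unknown contour type {self.ctype!r}")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"{self.ctype}: points must be an (n, 2) array")
        if not np.isfinite(pts).all():
            raise ValidationError(f"{self.ctype}: non-finite coordinates")
        object.__setattr__(self, "points", pts)
        if self.ctype == "refpoint":
            if len(pts) != 1:
                raise GeometryError("refpoint must have exactly 1 point")
        else:
            if len(pts) < 3:
                raise GeometryError(
                    f"{self.ctype}: polygon needs >= 3 points, got {len(pts)}"
                )
            if not Polygon(pts).is_valid:
                raise GeometryError(f"{self.ctype}: self-intersecting polygon")

    def __eq__(self, other):
        return (
            isinstance(other, Contour)
            and self.ctype == other.ctype
            and self.points.shape == other.points.shape
            and np.array_equal(self.points, other.points)
        )


@dataclass(frozen=True)
class ImageGeometry:
    """Pixel spacing and slice geometry, all in millimetres.

    The inter-slice distance used by slice-summation volumetry is
    ``slice_thickness + slice_gap``.
    """

    spacing_row: float
    spacing_col: float
    slice_thickness: float
    slice_gap: float = 0.0

    def __post_init__(self):
        for name in ("spacing_row", "spacing_col", "slice_thickness"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"geometry.{name} must be > 0")
        if self.slice_gap < 0:
            raise ValidationError("geometry.slice_gap must be >= 0")

    @property
    def slice_distance(self) -> float:
        """Inter-slice distance D = thickness + gap (mm)."""
        return self.slice_thickness + self.slice_gap

    @property
    def pixel_area(self) -> float:
        """Physical area of one pixel (mm^2)."""
        return self.spacing_row * self.spacing_col


@dataclass
class SliceAnnotation:
    """All contours of one reader on one slice at one cardiac phase.

    ``slice_index`` 0 is the most basal slice; indices ascend towards the
    apex. ``value_map`` optionally carries a parametric map (T1/T2 relaxation
    times in ms), stored row-major with voxel ``(i, j)`` centred at
    ``(row=i, col=j)``.
    """

    slice_index: int
    phase: str
    contours: dict[str, list[Contour]] = field(default_factory=dict)
    value_map: np.ndarray | None = None

    def __post_init__(self):
        if self.slice_index < 0:
            raise ValidationError("slice_index must be >= 0")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        for ctype, clist in self.contours.items():
            if ctype not in CTYPES:
                raise ValidationError(f"unknown contour type {ctype!r}")
            for c in clist:
                if c.ctype != ctype:
                    raise ValidationError(
                        f"contour of type {c.ctype!r} filed under {ctype!r}"
                    )
        if len(self.contours.get("refpoint", [])) > 1:
            raise ValidationError("at most one refpoint contour per slice")
        if self.value_map is not None:
            vm = np.asarray(self.value_map, dtype=float)
            if vm.ndim != 2:
                raise ValidationError("value_map must be 2-D")
            self.value_map = vm

    @property
    def key(self) -> tuple[int, str]:
        return (self.slice_index, self.phase)

    def polygons(self, ctype: str) -> list[Contour]:
        return self.contours.get(ctype, [])

    @property
    def refpoint(self) -> np.ndarray | None:
        rp = self.contours.get("refpoint")
        return rp[0].points[0] if rp else None


@dataclass
class CaseAnnotation:
    """One reader's annotations for one case of one sequence."""

    case_id: str
    reader_id: str
    sequence: str
    geometry: ImageGeometry
    slices: list[SliceAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if self.sequence not in SEQUENCES:
            raise ValidationError(f"unknown sequence {self.sequence!r}")
        keys = [s.key for s in self.slices]
        if len(keys) != len(set(keys)):
            raise ValidationError("(slice_index, phase) pairs must be unique")
        self.slices = sorted(self.slices, key=lambda s: s.key)  # canonical order

    def slice_at(self, slice_index: int, phase: str) -> SliceAnnotation | None:
        for s in self.slices:
            if s.key == (slice_index, phase):
                return s
        return None

    def phase_slices(self, phase: str) -> list[SliceAnnotation]:
        return sorted(
            (s for s in self.slices if s.phase == phase), key=lambda s: s.slice_index
        )

    def phases(self) -> list[str]:
        return sorted({s.phase for s in self.slices})


@dataclass
class SlicePair:
    """One aligned (slice_index, phase) position of two paired readers.

    Either side may be ``None`` when that reader did not annotate the slice.
    """

    slice_index: int
    phase: str
    s1: SliceAnnotation | None
    s2: SliceAnnotation | None


# ---------------------------------------------------------------------------
# JSON interchange

def _case_to_dict(case: CaseAnnotation) -> dict:
    slices = []
    for s in sorted(case.slices, key=lambda s: (s.slice_index, s.phase)):
        d: dict = {
            "slice_index": s.slice_index,
            "phase": s.phase,
            "contours": {
                ctype: [c.points.tolist() for c in clist]
                for ctype, clist in sorted(s.contours.items())
                if clist
            },
        }
        if s.value_map is not None:
            d["value_map"] = {
                "shape": list(s.value_map.shape),
                "values": s.value_map.ravel().tolist(),
            }
        slices.append(d)
    g = case.geometry
    return {
        "case_id": case.case_id,
        "reader_id": case.reader_id,
        "sequence": case.sequence,
        "geometry": {
            "spacing_row": g.spacing_row,
            "spacing_col": g.spacing_col,
            "slice_thickness": g.slice_thickness,
            "slice_gap": g.slice_gap,
        },
        "slices": slices,
    }


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ValidationError(f"{where}: missing required field {key!r}")
    return d[key]


def case_from_dict(data: dict) -> CaseAnnotation:
    """Build a validated :class:`CaseAnnotation` from a parsed JSON dict."""
    if not isinstance(data, dict):
        raise ValidationError("top level must be a JSON object")
    gd = _require(data, "geometry", "case")
    geom = ImageGeometry(
        spacing_row=_require(gd, "spacing_row", "geometry"),
        spacing_col=_require(gd, "spacing_col", "geometry"),
        slice_thickness=_require(gd, "slice_thickness", "geometry"),
        slice_gap=gd.get("slice_gap", 0.0),
    )
    slices = []
    for i, sd in enumerate(_require(data, "slices", "case")):
        where = f"slices[{i}]"
        contours: dict[str, list[Contour]] = {}
        for ctype, polys in sd.get("contours", {}).items():
            try:
                contours[ctype] = [Contour(ctype, np.asarray(p, float)) for p in polys]
            except GeometryError as e:
                raise GeometryError(f"{where}: {e}") from e
        vm = None
        if "value_map" in sd and sd["value_map"] is not None:
            vmd = sd["value_map"]
            shape = tuple(_require(vmd, "shape", f"{where}.value_map"))
            values = np.asarray(_require(vmd, "values", f"{where}.value_map"), float)
            if values.size != int(np.prod(shape)):
                raise ValidationError(f"{where}.value_map: shape/values mismatch")
            vm = values.reshape(shape)
        slices.append(
            SliceAnnotation(
                slice_index=_require(sd, "slice_index", where),
                phase=_require(sd, "phase", where),
                contours=contours,
                value_map=vm,
            )
        )
    return CaseAnnotation(
        case_id=str(_require(data, "case_id", "case")),
        reader_id=str(_require(data, "reader_id", "case")),
        sequence=_require(data, "sequence", "case"),
        geometry=geom,
        slices=slices,
    )


def load_case(path) -> CaseAnnotation:
    """Read and validate a case annotation file (JSON interchange format)."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValidationError(f"{path}: not valid JSON ({e})") from e
    return case_from_dict(data)


def save_case(case: CaseAnnotation, path) -> None:
    """Write a case to the JSON interchange format (full float precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_case_to_dict(case), fh, indent=1)
        fh.write("\n")


def pair_cases(r1: CaseAnnotation, r2: CaseAnnotation) -> list[SlicePair]:
    """Align two readers' slices on (slice_index, phase).

    Returns one :class:`SlicePair` per key present in either reader, sorted
    by (slice_index, phase); a reader missing the key gets ``None``.
    """
    if r1.case_id != r2.case_id:
        raise PairingError(f"case_id mismatch: {r1.case_id!r} vs {r2.case_id!r}")
    if r1.sequence != r2.sequence:
        raise PairingError(f"sequence mismatch: {r1.sequence!r} vs {r2.sequence!r}")
    if r1.geometry != r2.geometry:
        raise PairingError("image geometry mismatch between readers")
    keys = sorted({s.key for s in r1.slices} | {s.key for s in r2.slices})
    return [
        SlicePair(idx, ph, r1.slice_at(idx, ph), r2.slice_at(idx, ph))
        for idx, ph in keys
    ]
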