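"""Synthetic two-reader phantom cohorts with analytic ground truth.

The phantom emulates the annotated structures of a CMR study without any
image data: short-axis cine stacks (LV endo/epi circles tapering base to
apex, an RV crescent sharing the septal wall, papillary-muscle contours, ES
and ED phases), single-slice T1/T2 maps (myocardial ring over a synthetic
parametric value map with a reference point), LGE stacks with transmural scar
wedges, and long-axis atrial ellipses. All contours are dense polygons
(180-gon circles by default), so polygon-exact parameter values can be
compared against closed-form values of the continuous phantom.

A second reader is derived from the first by a parameterized perturbation
model covering the documented failure modes of automatic and novice readers:
per-vertex radial noise, systematic dilation per contour type, omission or
addition of a basal slice, fragmentation of a contour into disconnected
pieces, and reference-point shift. Radial noise is independent per vertex;
because the shoelace area is bilinear in adjacent vertex radii, independent
mean-zero radial noise leaves the expected polygon area unchanged, so noise
alone induces no volume bias.

Contoured slices start at stack index 1, leaving index 0 free so that an
"extra basal slice" perturbation remains representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .annotation import (
    CaseAnnotation,
    Contour,
    GeometryError,
    ImageGeometry,
    SliceAnnotation,
    save_case,
)
from .params import MYO_DENSITY_G_PER_ML, compute_parameters

__all__ = [
    "PhantomParams",
    "Perturbation",
    "PhantomTruth",
    "PhantomPair",
    "generate_case",
    "perturb_reader",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and tissue parameters of the continuous phantom.

    Defaults describe a plausible adult heart on a standard short-axis
    protocol: ~25 mm basal endocardial radius tapering 35% towards the apex,
    8 mm wall, 8 mm slices with 2 mm gap, end-systolic radii at 65% of
    end-diastolic ones (EF ~= 58%).
    """

    sequence: str = "sax_cine"
    n_slices: int = 8
    base_radius: float = 25.0  # basal LV endocardial radius, mm (ED)
    apex_taper: float = 0.35  # fractional radius reduction at the apex
    wall_thickness: float = 8.0  # myocardial wall, mm
    rv_scale: float = 1.1  # RV disk radius relative to LV epicardial radius
    rv_offset_frac: float = 1.15  # RV disk centre offset / LV epicardial radius
    slice_thickness: float = 8.0  # mm
    slice_gap: float = 2.0  # mm
    spacing: float = 1.0  # isotropic pixel spacing, mm
    es_scale: float = 0.65  # ES radii relative to ED
    n_vertices: int = 180
    centre: tuple[float, float] = (64.0, 64.0)  # (col, row), pixels
    papmu_radius: float = 4.0  # mm
    papmu_slices: tuple[int, ...] = (2, 3)  # stack indices carrying papillaries
    # parametric mapping (single slice)
    map_shape: tuple[int, int] = (128, 128)
    myo_value: float = 1000.0  # ms (native T1 at 1.5T scale)
    myo_noise_sd: float = 30.0  # ms
    blood_value: float = 1600.0  # ms
    fat_value: float = 300.0  # ms
    # LGE scar wedge
    scar_angle: float = np.pi / 3  # transmural wedge, rad
    scar_slices: tuple[int, ...] = (1, 2, 3)
    # long-axis atria (ellipse semi-axes, mm, at ventricular end-systole)
    la_axes: tuple[float, float] = (30.0, 20.0)
    ra_axes: tuple[float, float] = (28.0, 19.0)
    atrial_ed_scale: float = 0.75  # atria are smallest at ventricular ED

    def __post_init__(self):
        if self.base_radius <= 0 or not (0 <= self.apex_taper < 1):
            raise ValueError("base_radius > 0 and apex_taper in [0, 1) required")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be > 0")


@dataclass(frozen=True)
class Perturbation:
    """Second-reader perturbation model (all lengths in mm)."""

    radial_sigma: float = 0.0
    dilation_mm: dict = field(default_factory=dict)  # ctype -> signed mm
    p_miss_basal: float = 0.0
    p_extra_basal: float = 0.0
    p_fragment: float = 0.0
    fragment_ctypes: tuple[str, ...] = ("rv_endo",)
    refpoint_shift: float = 0.0
    reader_id: str = "reader2"
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_miss_basal, self.p_extra_basal, self.p_fragment):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth parameter values of a generated case.

    ``exact`` holds values computed from the emitted polygons (authoritative);
    ``analytic`` holds closed-form values of the continuous phantom, which
    differ from ``exact`` only by polygon discretization.
    """

    exact: dict
    analytic: dict


@dataclass(frozen=True)
class PhantomPair:
    case_id: str
    reader1: CaseAnnotation
    reader2: CaseAnnotation
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# contour construction (continuous coordinates, in pixels; spacing is isotropic)

def _circle(centre, radius_mm, spacing, n) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = radius_mm / spacing
    return np.column_stack(
        [centre[0] + r * np.cos(theta), centre[1] + r * np.sin(theta)]
    )


def _ellipse(centre, a_mm, b_mm, spacing, n) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [
            centre[0] + a_mm / spacing * np.cos(theta),
            centre[1] + b_mm / spacing * np.sin(theta),
        ]
    )


def _annular_sector(centre, r_in, r_out, theta0, theta1, spacing, n=60) -> np.ndarray:
    th = np.linspace(theta0, theta1, n)
    outer = np.column_stack(
        [centre[0] + r_out / spacing * np.cos(th), centre[1] + r_out / spacing * np.sin(th)]
    )
    inner = np.column_stack(
        [centre[0] + r_in / spacing * np.cos(th[::-1]), centre[1] + r_in / spacing * np.sin(th[::-1])]
    )
    return np.vstack([outer, inner])


def _lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two disks with radii r1, r2 at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    k = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return float(a1 + a2 - k)


def _crescent(centre, r_epi, rv_radius, offset, spacing, n) -> np.ndarray | None:
    """RV crescent: RV disk minus the LV epicardial disk (septal wall shared)."""
    rv_centre = (centre[0] - offset / spacing, centre[1])
    rv = Polygon(_circle(rv_centre, rv_radius, spacing, n))
    epi = Polygon(_circle(centre, r_epi, spacing, n))
    crescent = rv.difference(epi)
    if crescent.is_empty:
        return None
    if crescent.geom_type == "MultiPolygon":
        crescent = max(crescent.geoms, key=lambda g: g.area)
    return np.asarray(crescent.exterior.coords)[:-1]


def _endo_radii(p: PhantomParams) -> np.ndarray:
    """ED endocardial radius per contoured slice (most basal first)."""
    i = np.arange(p.n_slices)
    frac = i / max(p.n_slices - 1, 1)
    return p.base_radius * (1.0 - p.apex_taper * frac)


# ---------------------------------------------------------------------------
# case generation

def _cine_slices(p: PhantomParams, rng) -> list[SliceAnnotation]:
    radii = _endo_radii(p)
    slices = []
    for i, r_ed in enumerate(radii):
        idx = i + 1  # index 0 reserved for extra-basal perturbations
        for phase, scale in (("ES", p.es_scale), ("ED", 1.0)):
            r_endo = r_ed * scale
            r_epi = r_endo + p.wall_thickness
            if r_endo <= 0:
                raise ValueError("infeasible geometry: endocardial radius <= 0")
            contours = {
                "lv_endo": [Contour("lv_endo", _circle(p.centre, r_endo, p.spacing, p.n_vertices))],
                "lv_epi": [Contour("lv_epi", _circle(p.centre, r_epi, p.spacing, p.n_vertices))],
            }
            cres = _crescent(
                p.centre, r_epi, p.rv_scale * r_epi, p.rv_offset_frac * r_epi,
                p.spacing, p.n_vertices,
            )
            if cres is not None:
                contours["rv_endo"] = [Contour("rv_endo", cres)]
            if idx in p.papmu_slices:
                d = 0.4 * r_endo
                pap = []
                for sign in (-1, 1):
                    c = (p.centre[0] + sign * d / p.spacing, p.centre[1])
                    pap.append(Contour("papmu", _circle(c, p.papmu_radius, p.spacing, 90)))
                contours["papmu"] = pap
            slices.append(SliceAnnotation(idx, phase, contours))
    return slices


def _lge_slices(p: PhantomParams, rng) -> list[SliceAnnotation]:
    radii = _endo_radii(p)
    slices = []
    for i, r_endo in enumerate(radii):
        idx = i + 1
        r_epi = r_endo + p.wall_thickness
        contours = {
            "lv_endo": [Contour("lv_endo", _circle(p.centre, r_endo, p.spacing, p.n_vertices))],
            "lv_epi": [Contour("lv_epi", _circle(p.centre, r_epi, p.spacing, p.n_vertices))],
        }
        if idx in p.scar_slices and p.scar_angle > 0:
            wedge = _annular_sector(p.centre, r_endo, r_epi, 0.0, p.scar_angle, p.spacing)
            contours["scar"] = [Contour("scar", wedge)]
        slices.append(SliceAnnotation(idx, "single", contours))
    return slices


def _mapping_slice(p: PhantomParams, rng) -> SliceAnnotation:
    r_endo = p.base_radius * (1.0 - 0.5 * p.apex_taper)  # a midventricular slice
    r_epi = r_endo + p.wall_thickness
    nrow, ncol = p.map_shape
    jj, ii = np.meshgrid(np.arange(ncol), np.arange(nrow))
    dist = np.hypot(jj - p.centre[0], ii - p.centre[1]) * p.spacing
    vm = np.full(p.map_shape, p.fat_value, dtype=float)
    vm[dist <= r_epi] = p.myo_value
    vm[dist <= r_endo] = p.blood_value
    ring = (dist <= r_epi) & (dist > r_endo)
    vm[ring] += rng.normal(0.0, p.myo_noise_sd, size=int(ring.sum()))
    refpoint = np.array([[p.centre[0] - (r_epi + 2.0) / p.spacing, p.centre[1]]])
    contours = {
        "lv_endo": [Contour("lv_endo", _circle(p.centre, r_endo, p.spacing, p.n_vertices))],
        "lv_epi": [Contour("lv_epi", _circle(p.centre, r_epi, p.spacing, p.n_vertices))],
        "refpoint": [Contour("refpoint", refpoint)],
    }
    return SliceAnnotation(1, "single", contours, value_map=vm)


def _lax_slices(p: PhantomParams, rng) -> list[SliceAnnotation]:
    slices = []
    chambers = [("la", p.la_axes, p.centre)]
    if p.sequence == "lax_4cv":
        ra_centre = (p.centre[0] + (p.la_axes[0] + p.ra_axes[0] + 10.0) / p.spacing, p.centre[1])
        chambers.append(("ra", p.ra_axes, ra_centre))
    for phase, scale in (("ES", 1.0), ("ED", p.atrial_ed_scale)):
        contours = {
            ct: [Contour(ct, _ellipse(c, a * scale, b * scale, p.spacing, p.n_vertices))]
            for ct, (a, b), c in chambers
        }
        slices.append(SliceAnnotation(1, phase, contours))
    return slices


def _analytic_truth(p: PhantomParams) -> dict:
    d = p.slice_thickness + p.slice_gap
    out: dict[str, float] = {}
    if p.sequence in ("sax_cine", "sax_lge"):
        radii = _endo_radii(p)
        if p.sequence == "sax_cine":
            for prefix, scale in (("ED", 1.0), ("ES", p.es_scale)):
                r = radii * scale
                out[f"LV{prefix}V"] = float(np.pi * (r**2).sum() * d / 1000.0)
                r_epi = r + p.wall_thickness
                rv = sum(
                    np.pi * (p.rv_scale * re) ** 2
                    - _lens_area(p.rv_scale * re, re, p.rv_offset_frac * re)
                    for re in r_epi
                )
                out[f"RV{prefix}V"] = float(rv * d / 1000.0)
            for pre in ("LV", "RV"):
                out[f"{pre}SV"] = out[f"{pre}EDV"] - out[f"{pre}ESV"]
                out[f"{pre}EF"] = 100.0 * out[f"{pre}SV"] / out[f"{pre}EDV"]
            ring = np.pi * ((radii + p.wall_thickness) ** 2 - radii**2).sum()
            out["LVM"] = float(ring * d / 1000.0 * MYO_DENSITY_G_PER_ML)
            pap = 2 * np.pi * p.papmu_radius**2 * len(p.papmu_slices)
            out["PAPMU_ES"] = out["PAPMU_ED"] = float(pap * d / 1000.0 * MYO_DENSITY_G_PER_ML)
        else:
            out["LVV"] = float(np.pi * (radii**2).sum() * d / 1000.0)
            ring_each = np.pi * ((radii + p.wall_thickness) ** 2 - radii**2)
            out["LVM"] = float(ring_each.sum() * d / 1000.0 * MYO_DENSITY_G_PER_ML)
            scar = sum(
                ring_each[i - 1] * p.scar_angle / (2 * np.pi)
                for i in p.scar_slices
                if 1 <= i <= p.n_slices
            )
            out["SCARM"] = float(scar * d / 1000.0 * MYO_DENSITY_G_PER_ML)
            out["SCARF"] = 100.0 * out["SCARM"] / out["LVM"]
    elif p.sequence in ("sax_t1", "sax_t2"):
        out["GLOBAL_T1" if p.sequence == "sax_t1" else "GLOBAL_T2"] = p.myo_value
    else:
        chambers = [("LA", p.la_axes)]
        if p.sequence == "lax_4cv":
            chambers.append(("RA", p.ra_axes))
        for name, (a, b) in chambers:
            for phase, scale in (("ES", 1.0), ("ED", p.atrial_ed_scale)):
                area = np.pi * (a * scale) * (b * scale) / 100.0  # cm^2
                length = 2 * a * scale / 10.0  # cm
                out[f"{name}{phase}_Area"] = float(area)
                out[f"{name}{phase}V"] = float(8 * area**2 / (3 * np.pi * length))
    return out


def generate_case(
    params: PhantomParams, seed: int, case_id: str = "phantom", reader_id: str = "reader1"
) -> tuple[CaseAnnotation, PhantomTruth]:
    """Deterministically generate one reader-1 case plus its ground truth."""
    rng = np.random.default_rng(seed)
    p = params
    if p.sequence == "sax_cine":
        slices = _cine_slices(p, rng)
    elif p.sequence == "sax_lge":
        slices = _lge_slices(p, rng)
    elif p.sequence in ("sax_t1", "sax_t2"):
        slices = [_mapping_slice(p, rng)]
    elif p.sequence in ("lax_2cv", "lax_4cv"):
        slices = _lax_slices(p, rng)
    else:
        raise ValueError(f"unknown sequence {p.sequence!r}")
    geom = ImageGeometry(
        spacing_row=p.spacing,
        spacing_col=p.spacing,
        slice_thickness=p.slice_thickness,
        slice_gap=p.slice_gap,
    )
    case = CaseAnnotation(case_id, reader_id, p.sequence, geom, slices)
    exact = {name: cp.value for name, cp in compute_parameters(case).items()}
    return case, PhantomTruth(exact=exact, analytic=_analytic_truth(p))


# ---------------------------------------------------------------------------
# reader-2 perturbation

def _perturb_polygon(points_px, geom, rng, sigma, dilation):
    """Dilate (mm) then add independent per-vertex radial noise (mm)."""
    scale = np.array([geom.spacing_col, geom.spacing_row])
    pts = points_px * scale
    if dilation:
        poly = Polygon(pts).buffer(dilation, quad_segs=32)
        if poly.is_empty:
            return None
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        pts = np.asarray(poly.exterior.coords)[:-1]
    if sigma > 0:
        centre = pts.mean(axis=0)
        rel = pts - centre
        radii = np.linalg.norm(rel, axis=1)
        radii[radii == 0] = 1e-9
        unit = rel / radii[:, None]
        for _ in range(20):  # redraw if noise created a self-intersection
            eps = rng.normal(0.0, sigma, size=len(pts))
            cand = centre + (radii + np.clip(eps, -0.9 * radii, None))[:, None] * unit
            if Polygon(cand).is_valid:
                pts = cand
                break
        else:
            pass  # keep the unperturbed polygon on persistent failure
    return pts / scale


def _split_polygon(points_px, geom, rng, gap_mm=1.0):
    """Fragment a polygon into pieces by removing a thin strip through it."""
    scale = np.array([geom.spacing_col, geom.spacing_row])
    poly = Polygon(points_px * scale)
    cx, cy = poly.centroid.x, poly.centroid.y
    angle = rng.uniform(0, np.pi)
    length = 4 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1])
    strip = shapely_rotate(
        box(cx - length, cy - gap_mm / 2, cx + length, cy + gap_mm / 2), angle, (cx, cy)
    )
    pieces = poly.difference(strip)
    geoms = list(pieces.geoms) if pieces.geom_type == "MultiPolygon" else [pieces]
    out = []
    for g in geoms:
        if g.is_empty or g.area < 1.0 or len(g.exterior.coords) < 4:
            continue
        out.append(np.asarray(g.exterior.coords)[:-1] / scale)
    return out or [points_px]


def shapely_rotate(geometry, angle_rad, origin):
    from shapely import affinity

    return affinity.rotate(geometry, angle_rad, origin=origin, use_radians=True)


def perturb_reader(case: CaseAnnotation, pert: Perturbation) -> CaseAnnotation:
    """Derive a second reader's case from reader 1 under the perturbation model.

    Deterministic given ``pert.seed``. A zero perturbation returns an exact
    copy (apart from the reader id).
    """
    rng = np.random.default_rng(pert.seed)
    geom = case.geometry
    new_slices: list[SliceAnnotation] = []
    by_phase: dict[str, list[SliceAnnotation]] = {}
    for s in case.slices:
        by_phase.setdefault(s.phase, []).append(s)

    for phase, slices in sorted(by_phase.items()):
        slices = sorted(slices, key=lambda s: s.slice_index)
        contoured = [s for s in slices if any(s.contours.values())]
        miss_idx = extra_from = None
        if contoured:
            if pert.p_miss_basal > 0 and rng.random() < pert.p_miss_basal:
                miss_idx = contoured[0].slice_index
            if pert.p_extra_basal > 0 and rng.random() < pert.p_extra_basal:
                extra_from = contoured[0]
        for s in slices:
            if s.slice_index == miss_idx:
                continue  # basal slice omitted entirely
            new_slices.append(_perturb_slice(s, s.slice_index, geom, pert, rng))
        if extra_from is not None and extra_from.slice_index >= 1:
            new_slices.append(
                _perturb_slice(extra_from, extra_from.slice_index - 1, geom, pert, rng)
            )
    return CaseAnnotation(
        case_id=case.case_id,
        reader_id=pert.reader_id,
        sequence=case.sequence,
        geometry=geom,
        slices=new_slices,
    )


def _perturb_slice(s: SliceAnnotation, new_index, geom, pert, rng) -> SliceAnnotation:
    contours: dict[str, list[Contour]] = {}
    for ctype, clist in sorted(s.contours.items()):
        if ctype == "refpoint":
            pt = clist[0].points[0].copy()
            if pert.refpoint_shift > 0:
                ang = rng.uniform(0, 2 * np.pi)
                pt = pt + np.array(
                    [
                        pert.refpoint_shift * np.cos(ang) / geom.spacing_col,
                        pert.refpoint_shift * np.sin(ang) / geom.spacing_row,
                    ]
                )
            contours["refpoint"] = [Contour("refpoint", pt[None, :])]
            continue
        new_list: list[Contour] = []
        for c in clist:
            pts = _perturb_polygon(
                c.points, geom, rng, pert.radial_sigma, pert.dilation_mm.get(ctype, 0.0)
            )
            if pts is None:
                continue
            pieces = [pts]
            if ctype in pert.fragment_ctypes and rng.random() < pert.p_fragment:
                pieces = _split_polygon(pts, geom, rng)
            for piece in pieces:
                try:
                    new_list.append(Contour(ctype, piece))
                except GeometryError:
                    new_list.append(Contour(ctype, c.points.copy()))
        if new_list:
            contours[ctype] = new_list
    vm = None if s.value_map is None else s.value_map.copy()
    return SliceAnnotation(new_index, s.phase, contours, value_map=vm)


# ---------------------------------------------------------------------------
# cohorts

def _case_seeds(master_seed: int, index: int) -> tuple[int, int]:
    """Per-case (generation, perturbation) seeds: SeedSequence(master, (index, k))."""
    gen = np.random.SeedSequence(master_seed, spawn_key=(index, 0))
    per = np.random.SeedSequence(master_seed, spawn_key=(index, 1))
    return (
        int(gen.generate_state(1)[0] % (2**31)),
        int(per.generate_state(1)[0] % (2**31)),
    )


def generate_cohort(
    n_cases: int,
    params: PhantomParams,
    pert: Perturbation,
    seed: int,
    radius_jitter_frac: float = 0.08,
) -> list[PhantomPair]:
    """n independent paired phantom cases with per-case ground truth.

    Per-case seeds derive from the master seed through a fixed splitting rule
    (:func:`_case_seeds`), so the cohort is reproducible from ``seed`` alone.
    Anatomical variability between cases is modelled as Gaussian jitter of
    the basal radius (SD ``radius_jitter_frac`` of the default, truncated).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**16,)))
    pairs = []
    for i in range(n_cases):
        gen_seed, pert_seed = _case_seeds(seed, i)
        jitter = float(np.clip(rng.normal(0.0, radius_jitter_frac), -0.2, 0.2))
        case_params = replace(params, base_radius=params.base_radius * (1 + jitter))
        case_id = f"phantom_{i:03d}"
        r1, truth = generate_case(case_params, gen_seed, case_id=case_id)
        r2 = perturb_reader(r1, replace(pert, seed=pert_seed))
        pairs.append(PhantomPair(case_id, r1, r2, truth))
    return pairs


def write_cohort(pairs: list[PhantomPair], outdir) -> pd.DataFrame:
    """Write interchange JSON per reader per case plus a truth table CSV.

    Returns the truth table (case_id, parameter, exact, analytic).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for pair in pairs:
        save_case(pair.reader1, os.path.join(outdir, f"{pair.case_id}_reader1.json"))
        save_case(pair.reader2, os.path.join(outdir, f"{pair.case_id}_reader2.json"))
        for name in sorted(set(pair.truth.exact) | set(pair.truth.analytic)):
            rows.append(
                {
                    "case_id": pair.case_id,
                    "parameter": name,
                    "exact": pair.truth.exact.get(name),
                    "analytic": pair.truth.analytic.get(name),
                }
            )
    truth = pd.DataFrame(rows, columns=["case_id", "parameter", "exact", "analytic"])
    truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    return truth
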