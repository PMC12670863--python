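# Methods

This note documents the models, conventions and numerical choices behind
`cmrcompare`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Annotation model and conventions

Contours are closed polygons in continuous, 0-based pixel coordinates
`(col, row)`; physical size enters only through the per-case pixel spacing
(mm/pixel, possibly anisotropic) and the slice geometry. Slice index 0 is the
most basal slice and indices ascend towards the apex; "above the base" means
smaller indices. A contour type may carry several polygons on one slice — a
fragmented segmentation — and its total area is the sum of the polygon areas.
Only annotated cardiac phases are stored (`ES`, `ED`, or `single` for
mapping/LGE); phases are taken from the stored labels, there is no
argmin/argmax phase search. Parametric maps are row-major grids of voxel
values (ms) with voxel `(i, j)` centred at `(row=i, col=j)`.

The interchange format is one JSON file per case per reader
(`schema/case.schema.json`). Loading validates all structural invariants
(polygon ctypes need ≥ 3 vertices and must be simple; a reference point is
exactly one point; `(slice_index, phase)` keys are unique; spacings are
positive) and raises errors naming the offending field or slice.

## Segmentation metrics

All metrics are computed in millimetre coordinates after scaling by the
anisotropic spacing.

- **Dice** is computed on exact polygon-intersection areas rather than
  rasterized masks: it is resolution independent and testable against closed
  forms (concentric disks of radii r < R give exactly 2r²/(r²+R²)). A
  rasterized-mask oracle is kept in the test suite and agrees within 0.005 on
  random convex shapes at a 0.1 mm grid. A slice annotated by only one reader
  scores 0; a slice annotated by neither is undefined and excluded from
  averages (inclusion rules below).
- **Hausdorff distance** is the symmetric max-min distance between boundary
  polylines (not filled regions), densified to ≤ 0.05 mm segment length; the
  discretization error is bounded by that length. It is undefined when either
  side is absent.
- **Millilitre impact** per slice is |A₁−A₂|·D/1000 with D = slice thickness
  + gap; an absent side counts area 0.
- **Myocardium** is compared ring against ring: the set difference of the
  epicardial and endocardial polygons.

Empty-vs-empty slices are excluded from averages rather than scored 1, so
metric tables cover exactly the slices at least one reader annotated.

## Clinical parameters

- **Volumes** use short-axis slice summation (Simpson's method): Σ area·D,
  no inter-slice interpolation. This is the standard volumetry for SAX stacks
  and the only method consistent with a per-slice millilitre decomposition.
- **Masses** convert ring (epi − endo areas, clamped at 0 per slice) or
  papillary volumes with the conventional myocardial density 1.05 g/ml.
  Papillary muscles are reported as separate PAPMU masses; the cavity volume
  includes the papillary region by default (`papillary_in_cavity=False`
  subtracts it).
- **SV/EF**: SV = EDV − ESV; EF = 100·SV/EDV, undefined when EDV = 0. A
  negative SV is returned as computed.
- **Scar**: scar polygons are clipped to the myocardial ring before
  summation; SCARF = 100·SCARM/LVM, undefined when scar exists with zero
  LVM. The package does not *detect* scar — readers supply scar contours.
- **Atria**: single long-axis slice areas (cm²) and monoplane area–length
  ellipsoid volumes V = 8A²/(3πL). The long-axis length L is the contour's
  maximum caliper diameter (largest pairwise vertex distance). The length
  definition is a genuine design choice — annulus-based lengths would need
  extra landmarks; the maximum caliper is reproducible from the contour alone
  and reproduces the sphere volume (4/3)πr³ for a circular contour. A missing
  atrial contour yields a *missing* parameter, distinguished from 0.
- **Mapping**: global T1/T2 is the mean of voxels whose centres fall inside
  the myocardial ring (voxel-centre-in-polygon membership, no erosion
  margin). The 6-segment model partitions ring voxels into equal angular
  sectors about the LV centroid, sector 1 starting at the ray through the
  reference point and proceeding counterclockwise as seen on the image; the
  sectors partition the ring exactly, so the voxel-count-weighted mean of
  segment means equals the global value. The 17-segment polar map is out of
  scope.

## Position classification and inclusion rules

Positions are defined relative to a reference reader (configurable,
default reader 1), per contour type and per phase, because LV and RV extents
differ: the smallest slice index the reference segmented and everything above
it is *basal*, the largest and everything below *apical*, strictly between is
*midventricular*. A reference extent of a single slice classifies that slice
as basal (deterministic tie-break for a degenerate case). Position tables
pool ES and ED slice pairs and report per cell: Dice over all slices
annotated by ≥ 1 reader (one-sided slices scored 0), Dice over both-annotated
slices only, mean Hausdorff distance (both-annotated only) and mean absolute
millilitre difference per slice (≥ 1 reader). By construction the
both-annotated Dice can never be lower than the all-slices Dice in a cell.

## Tolerance ranges, bias and outliers

Differences are oriented reader 1 − reader 2 throughout. The bias CI is
mean ± 1.96·SD/√n with the *normal* critical value: the published interval
bounds for the summary statistics this package reproduces are consistent with
z = 1.96 and not with Student-t at n = 144. Tolerance ranges are symmetric
about zero, ±1.96 × sample SD of an expert's intrareader differences
(method tag `z95`, default); a normal tolerance interval with Howe's
k-factor for 95 % coverage at 95 % confidence (`ki-factor`) is available for
small intrareader samples and is wider for small n. Fewer than 30 intrareader
cases triggers a warning. A bias is acceptable iff its CI lies inside
[−hw, +hw]; an outlier is a case with |difference| > hw. Acceptability is
monotone in hw and the outlier count non-increasing — both are property
tested. No hypothesis tests beyond this framework and no multiple-testing
correction are applied.

## Error tracing

Volume and mass parameters are slice-additive, so their reader difference
decomposes exactly into per-slice contributions (A₁−A₂)·D/1000 (× 1.05 g/ml
for masses), computed with the *same* area definitions as the parameters
themselves (clamped ring areas, ring-clipped scar). Stroke volumes combine
the ED trace with the negated ES trace. EF and scar fraction are not
slice-additive; they are traced by first-order decomposition into their
ingredient traces (partials evaluated at reader 2's values) plus a
nonlinearity residual reported as its own entry, so the contributions still
sum exactly to the parameter difference. Mapping values decompose per slice
through the voxel-count weighting of the global mean. Entries are ranked by
absolute contribution; conservation is asserted to float precision over
random phantom cohorts in the test suite.

## Synthetic phantoms

The phantom emulates annotated *geometry*, not image intensities:

- **SAX cine**: LV endocardium as circles of radius r(i) decreasing linearly
  base → apex (default 25 mm basal radius, 35 % apical taper — linear taper
  keeps every closed form integrable and produces realistic basal/mid/apical
  contrast); epicardium at +8 mm wall; RV as the crescent of an offset disk
  minus the epicardial disk (circular-segment geometry with an exact lens
  formula as the analytic oracle); two papillary disks on mid slices; ES
  radii at 65 % of ED (EF ≈ 58 %). 8 slices of 8 mm with 2 mm gap, 180-gon
  contours, isotropic 1 mm spacing. Contoured slices start at stack index 1
  so an extra-basal perturbation stays representable.
- **LGE**: the same stack single-phase with a transmural 60° scar wedge on
  three basal slices.
- **T1/T2 maps**: one midventricular slice over a 128×128 value map —
  myocardium 1000 ms (T2: set `myo_value`) with 30 ms Gaussian voxel noise,
  blood 1600 ms, fat 300 ms — plus a reference point near the septal
  epicardium.
- **LAX atria**: ellipses (LA 30×20 mm semi-axes at ventricular end-systole,
  ED scaled to 75 %).

Ground truth is recorded twice per case: *exact* values computed from the
emitted polygons (authoritative) and *analytic* values of the continuous
phantom; they differ only by polygon discretization (< 0.1 % at 180 vertices).

The second reader derives from the first by: independent per-vertex radial
Gaussian noise (the shoelace area is bilinear in adjacent vertex radii, so
independent mean-zero radial noise leaves the expected area unchanged — noise
alone induces no volume bias); uniform dilation per contour type via buffer
(a dilated circle is exactly concentric, giving closed-form Dice and
Hausdorff oracles); basal-slice omission/addition with given probabilities
per phase; fragmentation by removing a thin strip through a contour; and a
fixed-magnitude, random-direction reference-point shift. Noise draws that
would self-intersect are redrawn (up to 20 times, then the clean polygon is
kept); everything is deterministic given the perturbation seed. Cohorts
derive per-case seeds from the master seed via
`SeedSequence(master, spawn_key=(case_index, k))` and add Gaussian
anatomical jitter (8 % SD) to the basal radius.

What the phantoms do **not** emulate: image intensities and partial-volume
effects, real myocardial shape (non-circular cross-sections, trabeculation),
through-plane motion, pathology beyond scar wedges, and reader behaviour
correlated with image content (e.g. difficulty concentrated at genuinely
ambiguous basal anatomy). Passing phantom tests therefore demonstrates the
correctness of the *computations* — metrics, parameters, statistics, traces —
on controlled geometry, not the clinical performance of any reader.

## Numerical choices and problem sizes

- Boundary densification for Hausdorff: 0.05 mm; Dice/area computations are
  exact polygon arithmetic (shapely/GEOS).
- CI critical value 1.96 (normal); tolerance default `z95`; both method tags
  are recorded in every tolerance range.
- Degenerate inputs: zero-area or one-sided slices follow the inclusion rules
  above; epi smaller than endo clamps the ring at 0; EDV = 0 leaves EF
  undefined; a single-slice reference extent classifies basal.
- Cohort-level tests and the acceptance script use reduced phantoms (4–6
  slices, 120–150-gon contours, 8–30 cases) — small enough to run the whole
  suite in about a minute while every property they assert is
  size-independent (conservation and partition identities are exact at any
  size; closed-form agreements only improve with more vertices).
- Report rendering is deterministic (no timestamps, Agg backend, fixed
  ordering), so regenerating a report from identical inputs is
  byte-identical.

## Limitations

- DICOM ingestion and vendor workspace formats are out of scope; cases enter
  through the JSON interchange format.
- Dice/HD are 2-D per-slice metrics; average-surface-distance and 3-D
  Hausdorff variants are not provided.
- The atrial long-axis length definition (maximum caliper) is one reasonable
  convention among several; biplane atrial volumes are not computed.
- The interactive click-through exploration of statistical plots is replaced
  by static report figures and case-labelled plot data structures.
- Tolerance-range acceptability is a statistical criterion; it does not
  measure per-patient clinical impact near decision thresholds.
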