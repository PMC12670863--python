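# cmrcompare

Multi-level comparison of two readers' contour annotations on cardiovascular
MR images — for quality assurance of AI contouring methods, trainee feedback
and inter-/intraobserver reproducibility studies.

Quantitative cardiac MR rests on contours: clinicians, trainees and automatic
methods draw left- and right-ventricular endocardial and epicardial polygons
on short-axis cine stacks, myocardial rings on T1/T2 maps, scar regions on
late-gadolinium-enhancement images and atrial contours on long-axis views.
Two readers of the same study rarely agree exactly, and the interesting
question is not only *how much* their clinical parameters differ but *why*.
`cmrcompare` links three levels of analysis:

1. **Segmentation metrics** — per-slice Dice similarity coefficient
   (2·|A∩B|/(|A|+|B|) on exact polygon-intersection areas), symmetric
   Hausdorff distance between contour boundaries (mm), and the per-slice
   volumetric impact |A₁−A₂|·D/1000 (ml), with D = slice thickness + gap.
2. **Clinical parameters** — Simpson slice-summation volumes (EDV, ESV), SV
   = EDV−ESV, EF = 100·SV/EDV, myocardial and papillary-muscle masses
   (ring volume × 1.05 g/ml), scar mass and fraction, global T1/T2 mapping
   values with a 6-segment model about a reference point, and monoplane
   area–length ellipsoid atrial volumes V = 8A²/(3πL).
3. **Study statistics** — paired reader differences (reader 1 − reader 2),
   bias with a 95 % CI (mean ± 1.96·SD/√n), and *tolerance ranges*: a
   symmetric interval ±1.96·SD of an expert's intrareader differences
   (optionally a Howe-k normal tolerance interval). A bias is **acceptable**
   when its CI lies entirely inside the tolerance range; a per-case
   difference beyond the range flags that case as an **outlier**.

The distinguishing feature is **error tracing**: every volume or mass
difference decomposes exactly into signed per-slice contributions
(A₁−A₂)·D/1000, so an unacceptable bias or an outlier case can be traced to
the specific slices — typically basal-slice decisions — that caused it.
Ratio parameters (EF, scar fraction) are traced through their ingredient
traces plus an explicitly reported nonlinearity residual, keeping the
decomposition auditable. Position tables aggregate metrics by basal /
midventricular / apical location and contour type, with two Dice inclusion
rules (all slices annotated by ≥1 reader vs. slices annotated by both) that
isolate missed-slice effects from drawing differences.

Because annotated patient data are rarely shareable, the package ships a
**synthetic phantom cohort generator**: tapering disk-stack ventricles with
analytic ground truth, plus a parameterized second-reader perturbation model
(radial contour noise, systematic dilation, basal-slice omission/addition,
fragmentation, reference-point shift) emulating documented reader and AI
failure modes. Every pipeline stage is testable against closed forms without
any download.

## Worked example

```python
import numpy as np
from cmrcompare import (PhantomParams, Perturbation, generate_cohort,
                        compare_study, ToleranceRange)

# 20 phantom cases; reader 2 adds contour noise, dilates the LV endocardium
# by 0.5 mm and misses the basal slice in ~30% of stacks
params = PhantomParams(n_slices=6)
pert = Perturbation(radial_sigma=0.4, dilation_mm={"lv_endo": 0.5},
                    p_miss_basal=0.3, seed=0)
pairs = generate_cohort(20, params, pert, seed=11)

tolerances = {"LVEDV": ToleranceRange("LVEDV", 10.8, 144),
              "LVSV": ToleranceRange("LVSV", 4.5, 144)}
study = compare_study([(p.reader1, p.reader2) for p in pairs],
                      tolerances=tolerances)

cols = ["parameter", "n", "mean_diff", "sd_diff", "ci_low", "ci_high", "acceptable"]
sel = study.bias[study.bias.parameter.isin(["LVEDV", "LVESV", "LVSV", "LVM"])]
print(sel[cols].round(2).to_string(index=False))
for rec in study.outliers[:3]:
    print(f"outlier {rec.case_id} {rec.parameter}: "
          f"diff {rec.diff:+.1f} ml exceeds ±{rec.half_width} ml")
top = study.traces[(study.outliers[0].case_id, study.outliers[0].parameter)][0]
print(f"largest contribution: slice {top.slice_index} {top.phase} "
      f"{top.ctype}, {top.contribution:+.2f} ml (dice {top.dice})")
```

prints

```
parameter  n  mean_diff  sd_diff  ci_low  ci_high acceptable
    LVEDV 20       1.98     9.33   -2.11     6.07       True
    LVESV 20      -0.92     3.31   -2.37     0.53       None
      LVM 20       8.25     6.66    5.33    11.17       None
     LVSV 20       2.91     7.45   -0.36     6.17      False
outlier phantom_008 LVSV: diff +24.8 ml exceeds ±4.5 ml
outlier phantom_008 LVEDV: diff +21.8 ml exceeds ±10.8 ml
outlier phantom_001 LVEDV: diff +18.8 ml exceeds ±10.8 ml
largest contribution: slice 1 ED lv_endo, +25.40 ml (dice 0.0)
```

Reading the output: the LVEDV bias (2.0 ml, CI −2.1…6.1) sits inside its
±10.8 ml tolerance range — acceptable — while the stroke volume is not
(no `acceptable` verdict is given for parameters without a tolerance range).
Case `phantom_008` is an outlier for both parameters, and the trace pins the
entire 25.4 ml down to the basal ED slice that reader 2 did not annotate
(Dice 0 on that slice).

## Command line

```sh
cmrcompare simulate --n 20 --seed 11 --out cohort/       # phantom cohort + truth.csv
cmrcompare tolerance --intra intra_diffs.csv --out tol.csv
cmrcompare compare --reader1 r1/ --reader2 r2/ --tolerance tol.csv \
    --style extensive --out report/
```

`compare` writes `report.html` plus CSV tables (bias summary, outliers,
per-slice metrics, position table) and figures (Bland-Altman / paired / QQ
plots, red-blue-green contour overlays per outlier case: reader 1 red,
reader 2 blue, agreement green). Case files use a documented JSON
interchange format (`src/cmrcompare/schema/case.schema.json`).

## Layout

- `src/cmrcompare/annotation.py` — data model and JSON interchange I/O
- `src/cmrcompare/metrics.py` — polygon areas, Dice, Hausdorff, ml impact
- `src/cmrcompare/params.py` — clinical parameters per sequence
- `src/cmrcompare/position.py` — basal/mid/apical classification and tables
- `src/cmrcompare/stats.py` — bias, tolerance ranges, outliers, plot data
- `src/cmrcompare/tracing.py` — parameter-difference decomposition
- `src/cmrcompare/study.py` / `reporting.py` — pipeline and report bundles
- `src/cmrcompare/phantom.py` — synthetic cohorts with analytic truth
- `docs/methods.md` — models, conventions, numerical choices, limitations
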