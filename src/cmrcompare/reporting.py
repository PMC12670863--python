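"""Comparison reports: "simple" and "extensive" document bundles.

A report bundle is one HTML document plus the underlying CSV tables and PNG
figures, written into an output directory. The *simple* style contains the
per-parameter bias summary with tolerance verdicts, the outlier list and any
investigator notes; the *extensive* style adds per-case metric tables, the
position table, Bland-Altman / paired / QQ figures per parameter and a
contour-overlay figure per outlier case. Overlays follow the fixed colour
convention: reader 1 red, reader 2 blue, agreement green.

Rendering is deterministic: no timestamps are embedded and figure content is
a pure function of the study inputs.
"""

from __future__ import annotations

import html
import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.path import Path as MplPath
from matplotlib.patches import PathPatch

from .annotation import pair_cases
from .metrics import COMPARED_CTYPES, slice_ctype_geometry
from .position import position_table_wide
from .stats import bland_altman, plot_data
from .study import StudyComparison

__all__ = ["ReportSpec", "build_report"]

COLOR_R1 = "#c62828"  # reader 1: red
COLOR_R2 = "#1565c0"  # reader 2: blue
COLOR_AGREE = "#2e7d32"  # agreement: green


@dataclass
class ReportSpec:
    style: str = "simple"
    title: str = "Reader comparison"
    notes: list[tuple[str, str]] = field(default_factory=list)  # (anchor, text)
    parameters: list[str] | None = None  # subset to report; None = all

    def __post_init__(self):
        if self.style not in ("simple", "extensive"):
            raise ValueError(f"unknown report style {self.style!r}")


def _validate_notes(spec: ReportSpec, study: StudyComparison) -> None:
    anchors = set(study.case_ids) | set(study.bias["parameter"])
    for anchor, _ in spec.notes:
        if anchor not in anchors:
            raise ValueError(f"note anchor {anchor!r} matches no case or parameter")


def _geom_patch(ax, geom, color, alpha=0.55):
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    for poly in polys:
        if poly.is_empty or poly.geom_type != "Polygon":
            continue
        verts = list(poly.exterior.coords)
        codes = [MplPath.MOVETO] + [MplPath.LINETO] * (len(verts) - 2) + [MplPath.CLOSEPOLY]
        for interior in poly.interiors:
            iv = list(interior.coords)
            verts += iv
            codes += [MplPath.MOVETO] + [MplPath.LINETO] * (len(iv) - 2) + [MplPath.CLOSEPOLY]
        ax.add_patch(PathPatch(MplPath(verts, codes), facecolor=color, edgecolor="none", alpha=alpha))


def overlay_figure(r1, r2, path) -> None:
    """Contour overlay per slice pair: reader1-only red, reader2-only blue,
    agreement green."""
    pairs = pair_cases(r1, r2)
    n = len(pairs)
    ncols = min(n, 4)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    for ax, pair in zip(axes.ravel(), pairs):
        for ctype in COMPARED_CTYPES:
            g1 = slice_ctype_geometry(pair.s1, ctype, r1.geometry)
            g2 = slice_ctype_geometry(pair.s2, ctype, r1.geometry)
            if g1 is None and g2 is None:
                continue
            if g1 is not None and g2 is not None:
                _geom_patch(ax, g1.difference(g2), COLOR_R1)
                _geom_patch(ax, g2.difference(g1), COLOR_R2)
                _geom_patch(ax, g1.intersection(g2), COLOR_AGREE)
            elif g1 is not None:
                _geom_patch(ax, g1, COLOR_R1)
            else:
                _geom_patch(ax, g2, COLOR_R2)
        ax.set_title(f"slice {pair.slice_index} {pair.phase}", fontsize=8)
        ax.relim()
        ax.autoscale_view()
        ax.set_aspect("equal")
        ax.invert_yaxis()  # image convention: row axis points down
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _stat_figure(study: StudyComparison, parameter: str, path) -> None:
    grp = study.diffs[study.diffs["parameter"] == parameter]
    pairs = grp[["value_r1", "value_r2"]].to_numpy()
    pdata = plot_data(pairs, labels=list(grp["case_id"]))
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    # paired plot with case-labelled segments
    for (v1, v2), label in zip(pdata.paired, pdata.labels):
        axes[0].plot([0, 1], [v1, v2], "-o", color="grey", ms=3, lw=0.8)
    axes[0].set_xticks([0, 1], ["reader 1", "reader 2"])
    axes[0].set_title(f"{parameter}: paired values")
    # QQ
    axes[1].plot(pdata.qq_theoretical, pdata.qq_observed, "o", ms=3)
    lims = [pdata.qq_theoretical.min(), pdata.qq_theoretical.max()]
    axes[1].plot(lims, lims, "k--", lw=0.8)
    axes[1].set_title("QQ plot of differences")
    # Bland-Altman
    if len(pairs) >= 2:
        ba = bland_altman(pairs)
        axes[2].plot(ba.points[:, 0], ba.points[:, 1], "o", ms=3)
        for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            axes[2].axhline(y, color="k", lw=0.8, ls=style[0] if style == "-" else "--")
        tol = study.tolerances.get(parameter)
        if tol is not None:
            axes[2].axhspan(-tol.half_width, tol.half_width, color="grey", alpha=0.25)
        axes[2].set_title("Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _fmt_bias_table(study: StudyComparison, parameters=None) -> str:
    df = study.bias.copy()
    if parameters is not None:
        df = df[df["parameter"].isin(parameters)]
    df["mean ± SD"] = df.apply(lambda r: f"{r.mean_diff:.1f} ± {r.sd_diff:.1f}", axis=1)
    df["95% CI"] = df.apply(lambda r: f"({r.ci_low:.1f}, {r.ci_high:.1f})", axis=1)
    df["tolerance"] = df["tolerance"].map(
        lambda t: f"±{t:.1f}" if t is not None and t == t else ""
    )
    df["acceptable"] = df["acceptable"].map(
        {True: "yes", False: "NO", None: "", np.nan: ""}
    )
    cols = ["parameter", "unit", "n", "mean ± SD", "95% CI", "tolerance", "acceptable"]
    return df[cols].to_html(index=False)


def build_report(study: StudyComparison, spec: ReportSpec, outdir) -> str:
    """Write the report bundle; returns the path of the HTML document."""
    if not study.pairs:
        raise ValueError("empty study")
    _validate_notes(spec, study)
    os.makedirs(outdir, exist_ok=True)
    figdir = os.path.join(outdir, "figures")

    # CSV exports
    study.diffs.to_csv(os.path.join(outdir, "parameter_differences.csv"), index=False)
    study.bias.to_csv(os.path.join(outdir, "bias_summary.csv"), index=False)
    outlier_rows = [
        {"case_id": r.case_id, "parameter": r.parameter, "diff": r.diff,
         "tolerance_half_width": r.half_width}
        for r in study.outliers
    ]
    import pandas as pd

    pd.DataFrame(
        outlier_rows, columns=["case_id", "parameter", "diff", "tolerance_half_width"]
    ).to_csv(os.path.join(outdir, "outliers.csv"), index=False)

    parts = [f"<html><head><meta charset='utf-8'><title>{html.escape(spec.title)}</title>"
             "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
             "td,th{border:1px solid #999;padding:2px 8px}</style></head><body>"]
    parts.append(f"<h1>{html.escape(spec.title)}</h1>")
    parts.append(f"<p>{len(study.pairs)} compared case(s); style: {spec.style}.</p>")
    parts.append("<h2>Clinical parameter biases</h2>")
    parts.append(_fmt_bias_table(study, spec.parameters))

    parts.append("<h2>Outliers</h2>")
    if study.outliers:
        parts.append("<ul>")
        for r in study.outliers:
            parts.append(
                f"<li>{html.escape(r.case_id)} / {html.escape(r.parameter)}: "
                f"diff {r.diff:.2f} exceeds ±{r.half_width:.2f}</li>"
            )
        parts.append("</ul>")
    else:
        parts.append("<p>No outliers beyond the supplied tolerance ranges.</p>")

    if spec.notes:
        parts.append("<h2>Investigator notes</h2><ul>")
        for anchor, text in spec.notes:
            parts.append(f"<li><b>{html.escape(anchor)}</b>: {html.escape(text)}</li>")
        parts.append("</ul>")

    if spec.style == "extensive":
        os.makedirs(figdir, exist_ok=True)
        study.metrics.to_csv(os.path.join(outdir, "slice_metrics.csv"), index=False)
        if study.position is not None:
            wide = position_table_wide(study.position)
            wide.to_csv(os.path.join(outdir, "position_table.csv"))
            parts.append("<h2>Metrics by cardiac position and contour type</h2>")
            parts.append(wide.round(2).to_html())
        parts.append("<h2>Statistical plots</h2>")
        params = spec.parameters or sorted(study.bias["parameter"])
        for parameter in params:
            if (study.diffs["parameter"] == parameter).sum() < 1:
                continue
            fname = f"stats_{parameter}.png"
            _stat_figure(study, parameter, os.path.join(figdir, fname))
            parts.append(f"<h3>{parameter}</h3><img src='figures/{fname}' width='900'>")
        outlier_cases = sorted({r.case_id for r in study.outliers})
        if outlier_cases:
            parts.append("<h2>Outlier contour overlays "
                         "(reader 1 red, reader 2 blue, agreement green)</h2>")
            by_id = {r1.case_id: (r1, r2) for r1, r2 in study.pairs}
            for cid in outlier_cases:
                fname = f"overlay_{cid}.png"
                overlay_figure(*by_id[cid], os.path.join(figdir, fname))
                parts.append(f"<h3>{html.escape(cid)}</h3>"
                             f"<img src='figures/{fname}' width='900'>")
        if study.traces:
            parts.append("<h2>Outlier traces (largest slice contributions)</h2>")
            for (cid, parameter), entries in sorted(study.traces.items()):
                parts.append(f"<h3>{html.escape(cid)} / {html.escape(parameter)}</h3><ol>")
                for e in entries[:5]:
                    where = "residual" if e.slice_index is None else \
                        f"slice {e.slice_index} {e.phase} {e.ctype}"
                    parts.append(f"<li>{where}: {e.contribution:+.3f}</li>")
                parts.append("</ol>")

    parts.append("</body></html>")
    out_path = os.path.join(outdir, "report.html")
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts))
    return out_path
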