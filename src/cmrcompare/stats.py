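"""Study-level reader statistics: bias, tolerance ranges, outliers, plot data.

A new reader's bias on a clinical parameter is judged against a *tolerance
range*: a symmetric interval ``[-hw, +hw]`` derived from the distribution of
an expert's intrareader differences (an expert annotating at least 30 cases
twice). The bias of the new reader is *acceptable* when the 95% confidence
interval of the mean paired difference lies entirely inside the tolerance
range. A per-case *outlier* is a case whose two-reader difference exceeds the
tolerance range.

Differences are oriented ``reader1 - reader2`` throughout. Confidence
intervals use the normal critical value 1.96 (not Student-t), and tolerance
ranges are symmetric about zero rather than centred on the intrareader mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Z95",
    "ToleranceRange",
    "BiasAssessment",
    "OutlierRecord",
    "derive_tolerance_range",
    "summarize_bias",
    "bias_from_summary",
    "detect_outliers",
    "bland_altman",
    "plot_data",
    "paired_differences",
    "bias_table",
    "read_tolerance_csv",
    "write_tolerance_csv",
]

Z95 = 1.96  # normal 95% critical value


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class ToleranceRange:
    """Symmetric acceptability half-width for one clinical parameter."""

    parameter: str
    half_width: float
    n_intra: int
    method: str = "z95"

    def __post_init__(self):
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")


@dataclass(frozen=True)
class BiasAssessment:
    """Mean paired difference with 95% CI and tolerance verdict.

    ``acceptable`` is ``True`` iff ``[ci_low, ci_high]`` lies inside
    ``[-tolerance_half_width, +tolerance_half_width]``; it is ``None`` when no
    tolerance range was supplied.
    """

    parameter: str
    n: int
    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    tolerance_half_width: float | None = None
    acceptable: bool | None = None


@dataclass(frozen=True)
class OutlierRecord:
    """A case whose two-reader difference exceeds the tolerance range."""

    case_id: str
    parameter: str
    diff: float
    half_width: float


def _howe_k(n: int, coverage: float = 0.95, confidence: float = 0.95) -> float:
    """Howe's approximate k-factor for a two-sided normal tolerance interval."""
    nu = n - 1
    z = sps.norm.ppf((1 + coverage) / 2)
    chi2 = sps.chi2.ppf(1 - confidence, nu)
    return float(z * np.sqrt(nu * (1 + 1 / n) / chi2))


def derive_tolerance_range(
    intra_diffs, parameter: str = "", method: str = "z95"
) -> ToleranceRange:
    """Tolerance half-width from an expert's intrareader differences.

    ``method="z95"`` (default) uses ``1.96 x sample SD``; ``method="ki-factor"``
    uses a normal tolerance interval with Howe's k for 95% coverage at 95%
    confidence, which widens the interval for small samples. Fewer than 30
    intrareader cases triggers a warning.
    """
    d = np.asarray(list(intra_diffs), dtype=float)
    n = d.size
    if n < 2:
        raise InsufficientDataError("need >= 2 intrareader differences")
    if n < 30:
        warnings.warn(
            f"tolerance range derived from only {n} intrareader differences "
            "(at least 30 recommended)",
            stacklevel=2,
        )
    sd = float(d.std(ddof=1))
    if method == "z95":
        hw = Z95 * sd
    elif method == "ki-factor":
        hw = _howe_k(n) * sd
    else:
        raise ValueError(f"unknown tolerance method {method!r}")
    return ToleranceRange(parameter=parameter, half_width=hw, n_intra=n, method=method)


def bias_from_summary(
    mean: float,
    sd: float,
    n: int,
    tol: ToleranceRange | None = None,
    parameter: str = "",
) -> BiasAssessment:
    """Bias assessment from summary statistics: CI = mean +/- 1.96 SD / sqrt(n)."""
    if n < 2:
        raise InsufficientDataError("need n >= 2 paired differences")
    half = Z95 * sd / np.sqrt(n)
    ci_low, ci_high = mean - half, mean + half
    hw = tol.half_width if tol is not None else None
    acceptable = None if hw is None else bool(-hw <= ci_low and ci_high <= hw)
    return BiasAssessment(
        parameter=parameter or (tol.parameter if tol else ""),
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        ci_low=ci_low,
        ci_high=ci_high,
        tolerance_half_width=hw,
        acceptable=acceptable,
    )


def summarize_bias(
    diffs, tol: ToleranceRange | None = None, parameter: str = ""
) -> BiasAssessment:
    """Bias assessment from paired differences (reader1 - reader2)."""
    d = np.asarray(list(diffs), dtype=float)
    if d.size < 2:
        raise InsufficientDataError("need >= 2 paired differences")
    return bias_from_summary(
        float(d.mean()), float(d.std(ddof=1)), d.size, tol=tol, parameter=parameter
    )


def detect_outliers(per_case_diffs: dict, tol: ToleranceRange) -> list[OutlierRecord]:
    """Cases whose |difference| exceeds the tolerance half-width, largest first."""
    records = [
        OutlierRecord(str(cid), tol.parameter, float(d), tol.half_width)
        for cid, d in per_case_diffs.items()
        if abs(d) > tol.half_width
    ]
    return sorted(records, key=lambda r: abs(r.diff), reverse=True)


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    points: np.ndarray  # (n, 2): mean, diff


def bland_altman(pairs) -> BlandAltman:
    """Bland-Altman summary: per-case (mean, diff) points, bias and 95% LoA."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("need >= 2 (v1, v2) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - Z95 * sd,
        loa_high=bias + Z95 * sd,
        points=np.column_stack([means, diffs]),
    )


@dataclass(frozen=True)
class PlotData:
    """Data behind the paired boxplot and the QQ plot of differences.

    ``paired`` keeps the case label on every (v1, v2) segment so an outlier
    segment can be traced back to its case. ``qq_theoretical``/``qq_observed``
    are matched normal vs empirical quantiles of the differences, on the
    difference scale (a normal sample lies on the identity line).
    """

    labels: list[str]
    paired: np.ndarray  # (n, 2)
    qq_theoretical: np.ndarray
    qq_observed: np.ndarray


def plot_data(pairs, labels=None) -> PlotData:
    arr = np.asarray(list(pairs), dtype=float).reshape(-1, 2)
    n = arr.shape[0]
    if n < 1:
        raise InsufficientDataError("need >= 1 pair")
    labels = [str(x) for x in (labels if labels is not None else range(n))]
    if len(labels) != n:
        raise ValueError("labels/pairs length mismatch")
    diffs = np.sort(arr[:, 0] - arr[:, 1])
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    mu = diffs.mean()
    sd = diffs.std(ddof=1) if n > 1 else 0.0
    theo = mu + sd * sps.norm.ppf(probs)
    return PlotData(labels=labels, paired=arr, qq_theoretical=theo, qq_observed=diffs)


# ---------------------------------------------------------------------------
# study-table helpers

def paired_differences(
    params_r1: pd.DataFrame, params_r2: pd.DataFrame
) -> pd.DataFrame:
    """Join two long parameter tables on (case_id, parameter).

    Input frames are ``parameters_table`` outputs (one per reader); the result
    has columns case_id, parameter, unit, value_r1, value_r2,
    diff (= reader1 - reader2), keeping only combinations both readers computed.
    """
    merged = params_r1.merge(
        params_r2,
        on=["case_id", "parameter", "unit"],
        suffixes=("_r1", "_r2"),
    )
    merged["diff"] = merged["value_r1"] - merged["value_r2"]
    return merged[["case_id", "parameter", "unit", "value_r1", "value_r2", "diff"]]


def bias_table(
    diffs: pd.DataFrame, tolerances: dict[str, ToleranceRange] | None = None
) -> pd.DataFrame:
    """Per-parameter bias assessments from a paired-differences frame.

    Output columns mirror the summary-report layout: parameter, n, mean_diff,
    sd_diff, ci_low, ci_high, tolerance, acceptable.
    """
    tolerances = tolerances or {}
    rows = []
    for param, grp in diffs.groupby("parameter", sort=True):
        if len(grp) < 2:
            continue
        b = summarize_bias(grp["diff"], tolerances.get(param), parameter=param)
        rows.append(
            {
                "parameter": param,
                "unit": grp["unit"].iloc[0],
                "n": b.n,
                "mean_diff": b.mean_diff,
                "sd_diff": b.sd_diff,
                "ci_low": b.ci_low,
                "ci_high": b.ci_high,
                "tolerance": b.tolerance_half_width,
                "acceptable": b.acceptable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "parameter", "unit", "n", "mean_diff", "sd_diff",
            "ci_low", "ci_high", "tolerance", "acceptable",
        ],
    )


def read_tolerance_csv(path) -> dict[str, ToleranceRange]:
    """Read a tolerance table (parameter, half_width, method, n_intra)."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[row["parameter"]] = ToleranceRange(
            parameter=row["parameter"],
            half_width=float(row["half_width"]),
            n_intra=int(row.get("n_intra", 0) or 0),
            method=str(row.get("method", "supplied")),
        )
    return out


def write_tolerance_csv(tolerances: dict[str, ToleranceRange], path) -> None:
    pd.DataFrame(
        [
            {
                "parameter": t.parameter,
                "half_width": t.half_width,
                "method": t.method,
                "n_intra": t.n_intra,
            }
            for t in tolerances.values()
        ]
    ).to_csv(path, index=False)
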