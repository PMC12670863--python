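"""Study-level orchestration: run the full comparison pipeline on paired cases.

A *study* is a set of cases annotated by the same two readers on one
sequence. :func:`compare_study` computes, per case, the clinical parameters
of both readers and the slice-level metric table, then aggregates paired
differences into bias assessments, tolerance verdicts, outliers and the
position table, and finally attaches parameter traces for every outlier case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import CaseAnnotation
from .params import parameters_table
from .position import position_table
from .stats import (
    OutlierRecord,
    ToleranceRange,
    bias_table,
    detect_outliers,
    paired_differences,
)
from .tracing import TraceError, case_table, trace_parameter

__all__ = ["StudyComparison", "compare_study"]


@dataclass
class StudyComparison:
    """All artifacts of a two-reader study comparison."""

    pairs: list[tuple[CaseAnnotation, CaseAnnotation]]
    diffs: pd.DataFrame  # case_id, parameter, unit, value_r1, value_r2, diff
    bias: pd.DataFrame  # per-parameter bias assessments
    outliers: list[OutlierRecord]
    metrics: pd.DataFrame  # per-slice metric rows over all cases
    position: pd.DataFrame | None  # position x ctype table (SAX stacks)
    tolerances: dict[str, ToleranceRange] = field(default_factory=dict)
    traces: dict[tuple[str, str], list] = field(default_factory=dict)

    @property
    def case_ids(self) -> list[str]:
        return [r1.case_id for r1, _ in self.pairs]


def compare_study(
    case_pairs: list[tuple[CaseAnnotation, CaseAnnotation]],
    tolerances: dict[str, ToleranceRange] | None = None,
    policy: str = "reader1",
    trace_outliers: bool = True,
) -> StudyComparison:
    """Run the multi-level comparison over a study of paired cases."""
    if not case_pairs:
        raise ValueError("need at least one paired case")
    tolerances = tolerances or {}

    p1 = parameters_table([r1 for r1, _ in case_pairs])
    p2 = parameters_table([r2 for _, r2 in case_pairs])
    diffs = paired_differences(p1, p2)
    bias = bias_table(diffs, tolerances)

    outliers: list[OutlierRecord] = []
    for param, tol in sorted(tolerances.items()):
        grp = diffs[diffs["parameter"] == param]
        per_case = dict(zip(grp["case_id"], grp["diff"]))
        outliers.extend(detect_outliers(per_case, tol))
    outliers.sort(key=lambda r: abs(r.diff), reverse=True)

    metrics = pd.concat(
        [case_table(r1, r2) for r1, r2 in case_pairs], ignore_index=True
    )

    sequence = case_pairs[0][0].sequence
    pos = position_table(case_pairs, policy=policy) if sequence.startswith("sax") else None

    traces: dict[tuple[str, str], list] = {}
    if trace_outliers:
        by_id = {r1.case_id: (r1, r2) for r1, r2 in case_pairs}
        for rec in outliers:
            r1, r2 = by_id[rec.case_id]
            try:
                traces[(rec.case_id, rec.parameter)] = trace_parameter(
                    r1, r2, rec.parameter
                )
            except TraceError:
                pass

    return StudyComparison(
        pairs=case_pairs,
        diffs=diffs,
        bias=bias,
        outliers=outliers,
        metrics=metrics,
        position=pos,
        tolerances=tolerances,
        traces=traces,
    )
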