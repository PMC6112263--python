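"""Endpoints: mean annual costs, stroke rates, avoided strokes and NNTs.

The primary endpoint is the difference in mean annual stroke-related cost
per patient between the atrial-sensing arm (98% AF detection) and the
conventional arm (15% detection).  The mean annual cost over a horizon of
``H`` years is

    (1/H) * sum_i [ discounted cohort cost in cycle i / patients alive at
                    the start of cycle i ]

Secondary endpoints are the mean annual number of strokes per 1,000
patients per arm, the strokes avoided by the atrial-sensing device, and the
numbers needed to treat to avoid one stroke (or one fatal stroke) per year.
Costs and effects are both discounted from the second cycle onward; the
undiscounted stroke counts are reported alongside because clinical NNTs are
often quoted undiscounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .engine import CohortTrace, run_cohort
from .parameters import CostParameters, ModelParameters, RiskTable, DEFAULT_RISK_TABLE

__all__ = [
    "ComparisonResult",
    "mean_annual_cost",
    "stroke_rates",
    "compare_arms",
    "per_score_analysis",
    "comparison_table",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Paired-arm outcome summary for one scenario.

    ``cost_difference`` is atrial-sensing minus conventional (positive means
    the atrial-sensing device costs more); ``strokes_avoided_per_1000`` is
    conventional minus atrial-sensing.  NNTs are ``inf`` when no strokes are
    avoided.  Per-1,000 stroke rates and NNTs use discounted expected
    events; the ``*_undiscounted`` fields carry the plain counts.
    """

    score_label: str
    mean_annual_cost_dx: float
    mean_annual_cost_conventional: float
    cost_difference: float
    strokes_per_1000_dx: float
    strokes_per_1000_conventional: float
    strokes_avoided_per_1000: float
    nnt_stroke: float
    nnt_fatal_stroke: float
    strokes_per_1000_dx_undiscounted: float
    strokes_per_1000_conventional_undiscounted: float
    strokes_avoided_per_1000_undiscounted: float


def mean_annual_cost(trace: CohortTrace) -> float:
    """Discounted mean annual cost per patient over the trace horizon."""
    total = 0.0
    for rec in trace.records:
        if rec.alive_at_start <= 0:
            raise ZeroDivisionError(
                f"no patients alive at the start of cycle {rec.cycle_index}"
            )
        total += rec.discounted_cost / rec.alive_at_start
    return total / trace.horizon_years


def _mean_events_per_1000(trace: CohortTrace, attr: str, discounted: bool) -> float:
    scale = 1000.0 / trace.cohort_size
    events = [
        getattr(rec, attr) * (rec.discount_factor if discounted else 1.0)
        for rec in trace.records
    ]
    return scale * sum(events) / trace.horizon_years


def _nnt(avoided_per_1000: float) -> float:
    return 1000.0 / avoided_per_1000 if avoided_per_1000 > 0 else math.inf


def stroke_rates(
    trace_dx: CohortTrace, trace_conv: CohortTrace
) -> dict[str, float]:
    """Per-1,000 mean annual stroke rates, avoided strokes and NNTs."""
    if trace_dx.horizon_years != trace_conv.horizon_years:
        raise ValueError("traces must share the same horizon")
    if trace_dx.cohort_size != trace_conv.cohort_size:
        raise ValueError("traces must share the same cohort size")

    out: dict[str, float] = {}
    for tag, disc in (("", True), ("_undiscounted", False)):
        dx = _mean_events_per_1000(trace_dx, "strokes", disc)
        cv = _mean_events_per_1000(trace_conv, "strokes", disc)
        out[f"strokes_per_1000_dx{tag}"] = dx
        out[f"strokes_per_1000_conventional{tag}"] = cv
        out[f"strokes_avoided_per_1000{tag}"] = cv - dx
    fatal_dx = _mean_events_per_1000(trace_dx, "fatal_strokes", True)
    fatal_cv = _mean_events_per_1000(trace_conv, "fatal_strokes", True)
    out["nnt_stroke"] = _nnt(out["strokes_avoided_per_1000"])
    out["nnt_fatal_stroke"] = _nnt(fatal_cv - fatal_dx)
    return out


def compare_arms(
    params: ModelParameters,
    costs: CostParameters,
    score_label: str = "base-case",
) -> ComparisonResult:
    """Run both arms under identical parameters and summarise endpoints."""
    trace_dx = run_cohort(params, costs, params.detection_prob_dx, "dx")
    trace_cv = run_cohort(
        params, costs, params.detection_prob_conventional, "conventional"
    )
    cost_dx = mean_annual_cost(trace_dx)
    cost_cv = mean_annual_cost(trace_cv)
    rates = stroke_rates(trace_dx, trace_cv)
    return ComparisonResult(
        score_label=score_label,
        mean_annual_cost_dx=cost_dx,
        mean_annual_cost_conventional=cost_cv,
        cost_difference=cost_dx - cost_cv,
        **rates,
    )


def per_score_analysis(
    score: int,
    params: ModelParameters,
    costs: CostParameters,
    risk_table: RiskTable = DEFAULT_RISK_TABLE,
) -> ComparisonResult:
    """Paired-arm comparison for a single-score cohort.

    Substitutes the adjusted annual stroke rate of the given CHA2DS2-VASc
    score for the weighted base-case rate and reruns both arms.
    """
    if not 0 <= score <= 9:
        raise ValueError(f"CHA2DS2-VASc score must be in [0, 9], got {score}")
    rate = risk_table.rate_for(score)
    scoped = replace(params, stroke_rate_untreated_af=rate)
    return compare_arms(scoped, costs, score_label=f"score-{score}")


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flat table of comparison results, one row per scenario."""
    return pd.DataFrame([vars(r) for r in results])
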