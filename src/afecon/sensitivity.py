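"""Deterministic (tornado) and probabilistic (Monte-Carlo) sensitivity analyses.

Both analyses perturb *primitive* inputs only; every derived quantity
(treated stroke incidence, weighted bleeding risk, weighted anticoagulation
cost, composed state costs) is re-derived from the perturbed primitives so
the model stays internally consistent.

The deterministic analysis re-runs the paired-arm comparison at the low and
high end of each parameter's range, holding everything else at base, and
ranks parameters by the span of the resulting cost difference.

The probabilistic analysis samples all primitives simultaneously — gamma
distributions for costs, normal (clamped to the valid domain) for
probabilities and risk ratios — with the mean at the base value and the
standard deviation chosen so the deterministic min-max range covers a 95%
interval, i.e. sd = (high - low) / (2 * 1.96).  Parameters are sampled
independently.  Each draw yields one point of the cost-effectiveness plane
(cost difference vs. strokes avoided); the probability of cost saving is
the fraction of draws with a negative cost difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import ModelConsistencyError
from .outcomes import compare_arms
from .parameters import CostParameters, ModelParameters

__all__ = [
    "SensitivityRange",
    "PsaResult",
    "PARAMETER_KINDS",
    "default_ranges",
    "apply_parameter",
    "one_way_sa",
    "probabilistic_sa",
]

logger = logging.getLogger(__name__)

#: parameter id -> ("model" | "mix" | "cost", distribution kind)
#: kind "cost" samples gamma; "probability" normal clamped to [0, 1];
#: "ratio" normal clamped to positive values.
PARAMETER_KINDS: dict[str, tuple[str, str]] = {
    "af_incidence": ("model", "probability"),
    "detection_prob_dx": ("model", "probability"),
    "detection_prob_conventional": ("model", "probability"),
    "stroke_rate_untreated_af": ("model", "probability"),
    "af_stroke_multiplier": ("model", "ratio"),
    "stroke_mortality_no_af": ("model", "probability"),
    "stroke_mortality_untreated_af": ("model", "probability"),
    "background_mortality": ("model", "probability"),
    "af_mortality_rr": ("model", "ratio"),
    "bleed_rate_no_oac": ("model", "probability"),
    "discount_rate": ("model", "probability"),
    "rrr_stroke_warfarin": ("mix", "probability"),
    "rrr_stroke_noac": ("mix", "probability"),
    "mortality_reduction_oac": ("mix", "probability"),
    "bleed_rate_warfarin": ("mix", "probability"),
    "bleed_rate_noac": ("mix", "probability"),
    "inpatient_stroke": ("cost", "cost"),
    "rehab_stroke": ("cost", "cost"),
    "outpatient_post_stroke": ("cost", "cost"),
    "oac_warfarin": ("cost", "cost"),
    "oac_noac": ("cost", "cost"),
    "asa": ("cost", "cost"),
    "bleed_event": ("cost", "cost"),
}


@dataclass(frozen=True)
class SensitivityRange:
    """Min-max range for one primitive parameter."""

    parameter_id: str
    base_value: float
    low_value: float
    high_value: float

    def __post_init__(self) -> None:
        if self.parameter_id not in PARAMETER_KINDS:
            raise KeyError(f"unknown parameter id {self.parameter_id!r}")
        if not self.low_value <= self.base_value <= self.high_value:
            raise ValueError(
                f"range for {self.parameter_id} must satisfy low <= base <= high"
            )


@dataclass(frozen=True)
class PsaResult:
    """Draws of the cost-effectiveness plane plus the cost-saving probability."""

    draws: pd.DataFrame
    probability_of_cost_saving: float


def _base_value(
    parameter_id: str, params: ModelParameters, costs: CostParameters
) -> float:
    owner, _ = PARAMETER_KINDS[parameter_id]
    if owner == "model":
        return getattr(params, parameter_id)
    if owner == "mix":
        return getattr(params.treatment_mix, parameter_id)
    return getattr(costs, parameter_id)


def apply_parameter(
    parameter_id: str,
    value: float,
    params: ModelParameters,
    costs: CostParameters,
) -> tuple[ModelParameters, CostParameters]:
    """Return copies of (params, costs) with one primitive replaced.

    Replacing an anticoagulant unit cost re-derives the weighted annual OAC
    cost from the (possibly new) unit costs; all other derived quantities
    are recomputed downstream from the primitives anyway.
    """
    owner, _ = PARAMETER_KINDS[parameter_id]
    if owner == "model":
        params = replace(params, **{parameter_id: value})
    elif owner == "mix":
        mix = replace(params.treatment_mix, **{parameter_id: value})
        params = replace(params, treatment_mix=mix)
    else:
        costs = replace(costs, **{parameter_id: value})
        if parameter_id in ("oac_warfarin", "oac_noac"):
            costs = replace(
                costs,
                oac_weighted=costs.recomputed_oac_weighted(params.treatment_mix),
            )
    return params, costs


def default_ranges(
    params: ModelParameters,
    costs: CostParameters,
    spread: float = 0.80,
) -> list[SensitivityRange]:
    """Predefined min-max ranges: +/-80% of base for every primitive.

    The discount rate is the exception and is varied between 2% and 4%.
    Upper ends of probability ranges are clamped to 1.
    """
    ranges = []
    for pid, (_, kind) in PARAMETER_KINDS.items():
        base = _base_value(pid, params, costs)
        if pid == "discount_rate":
            low, high = 0.02, 0.04
        else:
            low, high = base * (1.0 - spread), base * (1.0 + spread)
            if kind == "probability":
                high = min(high, 1.0)
        ranges.append(SensitivityRange(pid, base, low, high))
    return ranges


def one_way_sa(
    ranges: list[SensitivityRange],
    params: ModelParameters,
    costs: CostParameters,
) -> pd.DataFrame:
    """Tornado table: cost difference at each parameter's low and high end.

    One row per parameter with the paired-arm cost difference at the low
    and high value (all else at base) and the span between them, sorted by
    absolute span, descending.  Ranges that produce an invalid model are
    skipped with a warning.
    """
    base_diff = compare_arms(params, costs).cost_difference
    rows = []
    for rng in ranges:
        try:
            low_diff = compare_arms(
                *apply_parameter(rng.parameter_id, rng.low_value, params, costs)
            ).cost_difference
            high_diff = compare_arms(
                *apply_parameter(rng.parameter_id, rng.high_value, params, costs)
            ).cost_difference
        except (ValueError, ModelConsistencyError) as exc:
            logger.warning("skipping %s in one-way SA: %s", rng.parameter_id, exc)
            continue
        rows.append(
            {
                "parameter": rng.parameter_id,
                "low_value": rng.low_value,
                "high_value": rng.high_value,
                "cost_difference_low": low_diff,
                "cost_difference_high": high_diff,
                "span": high_diff - low_diff,
            }
        )
    frame = pd.DataFrame(rows)
    frame["base_cost_difference"] = base_diff
    return frame.reindex(
        frame["span"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


def _sample(
    rng: np.random.Generator, kind: str, base: float, low: float, high: float
) -> float:
    sd = (high - low) / (2.0 * 1.96)
    if sd == 0.0 or base == 0.0 and kind == "cost":
        return base
    if kind == "cost":
        shape = (base / sd) ** 2
        scale = sd**2 / base
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma parameters must be positive")
        return float(rng.gamma(shape, scale))
    value = float(rng.normal(base, sd))
    if kind == "probability":
        return min(max(value, 0.0), 1.0)
    # ratio: the normal tail can cross zero, where the model is undefined
    # (rates are divided by these multipliers) — truncate at the range floor
    if low <= 0:
        raise ValueError("ratio parameters need a positive lower range bound")
    return max(value, low)


def probabilistic_sa(
    params: ModelParameters,
    costs: CostParameters,
    n_runs: int = 1000,
    seed: int = 0,
    ranges: list[SensitivityRange] | None = None,
) -> PsaResult:
    """Monte-Carlo sensitivity analysis over all primitive inputs.

    Runs the paired-arm model ``n_runs`` times with all primitives sampled
    simultaneously and independently.  Reproducible for a fixed seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    ranges = ranges if ranges is not None else default_ranges(params, costs)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_runs):
        p, c = params, costs
        sampled: dict[str, float] = {}
        for spec in ranges:
            _, kind = PARAMETER_KINDS[spec.parameter_id]
            value = _sample(rng, kind, spec.base_value, spec.low_value, spec.high_value)
            sampled[spec.parameter_id] = value
            p, c = apply_parameter(spec.parameter_id, value, p, c)
        # the weighted OAC cost is a derived quantity: re-derive it from the
        # sampled unit costs even if neither unit cost was in the ranges
        c = replace(c, oac_weighted=c.recomputed_oac_weighted(p.treatment_mix))
        result = compare_arms(p, c)
        rows.append(
            {
                **sampled,
                "cost_difference": result.cost_difference,
                "strokes_avoided_per_1000": result.strokes_avoided_per_1000,
            }
        )
    draws = pd.DataFrame(rows)
    prob_saving = float((draws["cost_difference"] < 0.0).mean())
    return PsaResult(draws=draws, probability_of_cost_saving=prob_saving)
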