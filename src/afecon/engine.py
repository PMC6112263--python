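"""Annual-cycle Markov cohort engine.

A closed cohort starts AF-free and moves among three alive states —
``no_af``, ``af_detected_oac`` (AF found, anticoagulated) and
``af_undetected`` — plus cumulative ``dead``, in one-year cycles with
constant transition probabilities.  Stroke, stroke death, non-stroke death
and major bleeding are within-cycle events; stroke survivors remain in their
state and can stroke again in later cycles.

Within one cycle, in order:

1. undetected AF patients are re-screened at the arm's detection
   probability (device follow-up; optional),
2. AF-free patients develop AF; the new cases are detected (and start
   anticoagulation) with the arm's detection probability, the rest join the
   undetected pool,
3. each alive state experiences strokes at its state-specific annual rate,
   and a state-specific fraction of those strokes is fatal,
4. non-stroke mortality is applied to the full state occupancy as an
   independent competing hazard,
5. major bleeding occurs at the state-specific annual rate (a cost-only
   event — no state change),
6. state and event costs are accrued and discounted (from the second cycle
   onward).

The engine is expectation-based: occupancies are continuous expected patient
counts, so a single run yields the exact cohort means without Monte-Carlo
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .parameters import (
    CostParameters,
    ModelParameters,
    derived_mortalities,
    no_af_stroke_incidence,
    oac_stroke_incidence,
    state_cost,
    weighted_bleed_risk,
)

__all__ = [
    "StateVector",
    "CycleRecord",
    "CohortTrace",
    "ModelConsistencyError",
    "cycle_step",
    "run_cohort",
    "trace_frame",
]

ALIVE_STATES = ("no_af", "af_detected_oac", "af_undetected")


class ModelConsistencyError(ValueError):
    """Raised when composed within-cycle probabilities leave [0, 1]."""


@dataclass(frozen=True)
class StateVector:
    """Expected patient counts per state (continuous occupancy)."""

    no_af: float
    af_detected_oac: float
    af_undetected: float
    dead: float

    def __post_init__(self) -> None:
        for name in ("no_af", "af_detected_oac", "af_undetected", "dead"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"negative occupancy in state {name}")

    @property
    def alive(self) -> float:
        return self.no_af + self.af_detected_oac + self.af_undetected

    @property
    def total(self) -> float:
        return self.alive + self.dead


@dataclass(frozen=True)
class CycleRecord:
    """Events, costs and end-of-cycle occupancy for one model year."""

    cycle_index: int                 # 1-based model year
    alive_at_start: float
    state_vector: StateVector        # occupancy after the cycle
    strokes_by_state: dict[str, float]
    strokes: float
    fatal_strokes: float
    bleeds: float
    non_stroke_deaths: float
    undiscounted_cost: float
    discounted_cost: float
    discount_factor: float


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle records for one treatment arm."""

    arm_label: str
    cohort_size: int
    horizon_years: int
    records: tuple[CycleRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) != self.horizon_years:
            raise ValueError("trace length must equal the model horizon")
        for i, rec in enumerate(self.records, start=1):
            if rec.cycle_index != i:
                raise ValueError("cycle records must be ordered 1..horizon")


@dataclass(frozen=True)
class _DerivedRates:
    """Per-state annual rates re-derived once per run from the primitives."""

    stroke_no_af: float
    stroke_oac: float
    stroke_untreated: float
    stroke_mortality_oac: float
    mortality_af_untreated: float
    mortality_af_oac: float
    bleed_oac: float

    @classmethod
    def from_params(cls, params: ModelParameters) -> "_DerivedRates":
        untreated = params.stroke_rate_untreated_af
        m_af, m_af_oac, sm_oac = derived_mortalities(params)
        rates = cls(
            stroke_no_af=no_af_stroke_incidence(untreated, params.af_stroke_multiplier),
            stroke_oac=oac_stroke_incidence(untreated, params.treatment_mix),
            stroke_untreated=untreated,
            stroke_mortality_oac=sm_oac,
            mortality_af_untreated=m_af,
            mortality_af_oac=m_af_oac,
            bleed_oac=weighted_bleed_risk(params.treatment_mix),
        )
        # the combined within-cycle exit fraction of each state must stay a
        # probability: stroke_rate * case_fatality + non-stroke mortality <= 1
        exits = {
            "no_af": rates.stroke_no_af * params.stroke_mortality_no_af
            + params.background_mortality,
            "af_detected_oac": rates.stroke_oac * sm_oac + m_af_oac,
            "af_undetected": untreated * params.stroke_mortality_untreated_af + m_af,
        }
        for name, frac in exits.items():
            if not 0.0 <= frac <= 1.0:
                raise ModelConsistencyError(
                    f"composed exit probability for state {name} is {frac:.4f}, "
                    "outside [0, 1]"
                )
        return rates


def cycle_step(
    state: StateVector,
    params: ModelParameters,
    costs: CostParameters,
    detection_prob: float,
    cycle_index: int = 1,
    rates: _DerivedRates | None = None,
) -> CycleRecord:
    """Advance the cohort by one year and account events and costs."""
    if not 0.0 <= detection_prob <= 1.0:
        raise ValueError("detection_prob must be in [0, 1]")
    r = rates or _DerivedRates.from_params(params)
    oac_annual = costs.oac_weighted

    no_af = state.no_af
    oac = state.af_detected_oac
    undet = state.af_undetected
    dead = state.dead
    alive_at_start = state.alive
    uptake = detection_prob * params.oac_uptake

    # 1. re-screening of the prevalent undetected pool
    if params.redetect_each_cycle:
        rescreened = undet * uptake
        undet -= rescreened
        oac += rescreened

    # 2. AF onset and detection of the new cases
    new_af = no_af * params.af_incidence
    detected = new_af * uptake
    no_af -= new_af
    oac += detected
    undet += new_af - detected

    # 3. strokes and stroke deaths
    s_no_af = no_af * r.stroke_no_af
    s_oac = oac * r.stroke_oac
    s_undet = undet * r.stroke_untreated
    f_no_af = s_no_af * params.stroke_mortality_no_af
    f_oac = s_oac * r.stroke_mortality_oac
    f_undet = s_undet * params.stroke_mortality_untreated_af

    # 4. non-stroke mortality as an independent hazard on the full occupancy
    d_no_af = no_af * params.background_mortality
    d_oac = oac * r.mortality_af_oac
    d_undet = undet * r.mortality_af_untreated

    # 5. major bleeding (cost-only)
    b_oac = oac * r.bleed_oac
    b_other = (no_af + undet) * params.bleed_rate_no_oac

    # 6. costs: stroke-year costs per survivor and per fatality, annual
    #    anticoagulation for the no-stroke detected patients (half-year for
    #    those dying within the cycle), bleeding per event
    cost = (
        (s_no_af - f_no_af) * state_cost("no_af_stroke_alive", costs)
        + f_no_af * state_cost("no_af_stroke_fatal", costs)
        + (s_oac - f_oac) * state_cost("af_oac_stroke_alive", costs, oac_annual)
        + f_oac * state_cost("af_oac_stroke_fatal", costs, oac_annual)
        + (s_undet - f_undet) * state_cost("af_undetected_stroke_alive", costs)
        + f_undet * state_cost("af_undetected_stroke_fatal", costs)
        + (oac - s_oac - d_oac) * state_cost("af_oac_no_stroke_alive", costs, oac_annual)
        + d_oac * state_cost("af_oac_no_stroke_dead", costs, oac_annual)
        + (b_oac + b_other) * state_cost("bleeding_event", costs)
    )

    # stroke survivors return to their state; net exits are fatalities plus
    # non-stroke deaths
    no_af -= f_no_af + d_no_af
    oac -= f_oac + d_oac
    undet -= f_undet + d_undet
    dead += f_no_af + d_no_af + f_oac + d_oac + f_undet + d_undet

    discount_factor = (1.0 + params.discount_rate) ** -(cycle_index - 1)
    return CycleRecord(
        cycle_index=cycle_index,
        alive_at_start=alive_at_start,
        state_vector=StateVector(no_af, oac, undet, dead),
        strokes_by_state={
            "no_af": s_no_af,
            "af_detected_oac": s_oac,
            "af_undetected": s_undet,
        },
        strokes=s_no_af + s_oac + s_undet,
        fatal_strokes=f_no_af + f_oac + f_undet,
        bleeds=b_oac + b_other,
        non_stroke_deaths=d_no_af + d_oac + d_undet,
        undiscounted_cost=cost,
        discounted_cost=cost * discount_factor,
        discount_factor=discount_factor,
    )


def run_cohort(
    params: ModelParameters,
    costs: CostParameters,
    detection_prob: float,
    arm_label: str = "dx",
) -> CohortTrace:
    """Run one arm over the full horizon, starting everyone AF-free."""
    rates = _DerivedRates.from_params(params)
    state = StateVector(float(params.cohort_size), 0.0, 0.0, 0.0)
    records = []
    for cycle in range(1, params.horizon_years + 1):
        rec = cycle_step(state, params, costs, detection_prob, cycle, rates)
        records.append(rec)
        state = rec.state_vector
    return CohortTrace(
        arm_label=arm_label,
        cohort_size=params.cohort_size,
        horizon_years=params.horizon_years,
        records=tuple(records),
    )


def trace_frame(trace: CohortTrace) -> pd.DataFrame:
    """Tabular view of a trace: one row per cycle, plot-ready."""
    rows = []
    for rec in trace.records:
        sv = rec.state_vector
        rows.append(
            {
                "arm": trace.arm_label,
                "cycle": rec.cycle_index,
                "alive_at_start": rec.alive_at_start,
                "no_af": sv.no_af,
                "af_detected_oac": sv.af_detected_oac,
                "af_undetected": sv.af_undetected,
                "dead": sv.dead,
                "strokes": rec.strokes,
                "fatal_strokes": rec.fatal_strokes,
                "bleeds": rec.bleeds,
                "non_stroke_deaths": rec.non_stroke_deaths,
                "undiscounted_cost": rec.undiscounted_cost,
                "discounted_cost": rec.discounted_cost,
            }
        )
    return pd.DataFrame(rows)
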