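"""Model parameters and derivation rules.

Every quantity the cohort model consumes is either a *primitive* — a number
taken directly from the literature (annual AF incidence, per-score stroke
rates, unit costs, ...) — or *derived* from primitives by an explicit rule
(treatment-weighted stroke incidence under anticoagulation, composed annual
state costs, ...).  Primitives live in the three dataclasses below; every
derivation is a plain function in this module so that sensitivity analyses
can re-derive downstream quantities from sampled primitives.

Probabilities are annual (per one-year model cycle), costs are EUR per year
or per event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

__all__ = [
    "RiskTable",
    "TreatmentMix",
    "ModelParameters",
    "CostParameters",
    "DEFAULT_RISK_TABLE",
    "COSTED_STATES",
    "weighted_stroke_risk",
    "oac_stroke_incidence",
    "no_af_stroke_incidence",
    "derived_mortalities",
    "weighted_bleed_risk",
    "state_cost",
    "warfarin_only",
]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class RiskTable:
    """Per-CHA2DS2-VASc-score cohort counts and adjusted annual stroke rates.

    ``entries`` is a tuple of ``(score, count, adjusted_stroke_rate)``.
    Scores are the integer CHA2DS2-VASc values 0-9; counts describe the
    reference cohort used for weighting; rates are annual stroke
    probabilities for an untreated AF patient with that score.
    """

    entries: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        scores = [s for s, _, _ in self.entries]
        if len(set(scores)) != len(scores):
            raise ValueError("duplicate CHA2DS2-VASc scores in risk table")
        for score, count, rate in self.entries:
            if not 0 <= score <= 9:
                raise ValueError(f"CHA2DS2-VASc score out of range: {score}")
            if count < 0:
                raise ValueError(f"negative count for score {score}")
            _check_prob(f"stroke rate for score {score}", rate)
            if score == 0 and rate != 0.0:
                raise ValueError("score 0 must carry zero stroke risk")

    @property
    def total_count(self) -> int:
        return sum(c for _, c, _ in self.entries)

    def rate_for(self, score: int) -> float:
        for s, _, r in self.entries:
            if s == score:
                return r
        raise ValueError(f"score {score} not present in risk table")

    def fraction_for(self, score: int) -> float:
        total = self.total_count
        if total == 0:
            raise ValueError("risk table has zero total count")
        for s, c, _ in self.entries:
            if s == score:
                return c / total
        raise ValueError(f"score {score} not present in risk table")


#: Score distribution of the 171-patient single-chamber ICD reference cohort
#: (German Heart Centre Munich) with the adjusted annual stroke rate per score.
DEFAULT_RISK_TABLE = RiskTable(
    entries=(
        (0, 13, 0.000),
        (1, 16, 0.013),
        (2, 28, 0.022),
        (3, 31, 0.032),
        (4, 40, 0.040),
        (5, 27, 0.067),
        (6, 13, 0.098),
        (7, 2, 0.096),
        (8, 1, 0.067),
        (9, 0, 0.152),
    )
)


@dataclass(frozen=True)
class TreatmentMix:
    """Anticoagulant treatment mix and per-agent effect sizes.

    Defaults reflect routine-care shares of Warfarin vs. Rivaroxaban among
    newly anticoagulated AF patients, the relative stroke-risk reductions of
    each agent versus no treatment, the one-third mortality reduction under
    anticoagulation, and per-agent annual major-bleeding risks.
    """

    warfarin_share: float = 0.479
    noac_share: float = 0.521
    rrr_stroke_warfarin: float = 0.64
    rrr_stroke_noac: float = 0.66
    mortality_reduction_oac: float = 1.0 / 3.0
    bleed_rate_warfarin: float = 0.034
    bleed_rate_noac: float = 0.036

    def __post_init__(self) -> None:
        if abs(self.warfarin_share + self.noac_share - 1.0) > 1e-12:
            raise ValueError("warfarin_share and noac_share must sum to 1")
        for name in (
            "warfarin_share",
            "noac_share",
            "rrr_stroke_warfarin",
            "rrr_stroke_noac",
            "mortality_reduction_oac",
            "bleed_rate_warfarin",
            "bleed_rate_noac",
        ):
            _check_prob(name, getattr(self, name))


@dataclass(frozen=True)
class ModelParameters:
    """Primitive transition probabilities and cohort settings.

    Derived rates (stroke incidence under OAC, AF mortality, ...) are never
    stored here; obtain them from the derivation functions so they always
    stay consistent with the primitives.
    """

    af_incidence: float = 0.2094
    detection_prob_dx: float = 0.98
    detection_prob_conventional: float = 0.15
    stroke_rate_untreated_af: float = 0.0396
    af_stroke_multiplier: float = 4.8
    stroke_mortality_no_af: float = 0.34
    stroke_mortality_untreated_af: float = 0.63
    background_mortality: float = 0.06
    af_mortality_rr: float = 1.85
    bleed_rate_no_oac: float = 0.0295
    female_share: float = 0.19
    oac_eligibility_min_score_male: int = 1
    oac_eligibility_min_score_female: int = 2
    treatment_mix: TreatmentMix = field(default_factory=TreatmentMix)
    discount_rate: float = 0.03
    horizon_years: int = 9
    cohort_size: int = 1000
    # Fraction of detected-AF patients who actually start OAC.  The published
    # base case starts anticoagulation in every detected patient; a
    # score/sex-eligibility fraction from cohort_synthesis can be plugged in
    # here to explore guideline-threshold uptake instead.
    oac_uptake: float = 1.0
    # Undetected AF patients are re-screened at the arm's detection
    # probability every cycle (device follow-up); switching this off makes
    # detection a one-off decision at AF onset.
    redetect_each_cycle: bool = True

    def __post_init__(self) -> None:
        for name in (
            "af_incidence",
            "detection_prob_dx",
            "detection_prob_conventional",
            "stroke_rate_untreated_af",
            "stroke_mortality_no_af",
            "stroke_mortality_untreated_af",
            "background_mortality",
            "bleed_rate_no_oac",
            "female_share",
            "discount_rate",
            "oac_uptake",
        ):
            _check_prob(name, getattr(self, name))
        if self.af_stroke_multiplier <= 0 or self.af_mortality_rr <= 0:
            raise ValueError("risk multipliers must be positive")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be at least 1")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be at least 1")


@dataclass(frozen=True)
class CostParameters:
    """Unit costs (EUR) and cost-composition fractions.

    ``oac_weighted`` is the mix-weighted annual anticoagulation cost as
    printed in the source cost table (678.18).  Recomputing it from the unit
    costs and the default mix gives 678.03; the printed value is kept as the
    default because the composed state costs only reproduce with it.  Use
    :meth:`recomputed_oac_weighted` for the consistent re-derivation.
    """

    inpatient_stroke: float = 6731.0
    rehab_stroke: float = 6822.0
    outpatient_post_stroke: float = 3287.0
    oac_warfarin: float = 65.70
    oac_noac: float = 1241.00
    oac_weighted: float = 678.18
    asa: float = 14.60
    bleed_event: float = 1995.0
    untreated_af_inpatient_multiplier: float = 1.34
    rehab_survival_fraction: float = 0.46
    deceased_half_year_fraction: float = 0.50

    def __post_init__(self) -> None:
        for name in (
            "inpatient_stroke",
            "rehab_stroke",
            "outpatient_post_stroke",
            "oac_warfarin",
            "oac_noac",
            "oac_weighted",
            "asa",
            "bleed_event",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.untreated_af_inpatient_multiplier < 0:
            raise ValueError("untreated_af_inpatient_multiplier must be non-negative")
        _check_prob("rehab_survival_fraction", self.rehab_survival_fraction)
        _check_prob("deceased_half_year_fraction", self.deceased_half_year_fraction)

    def recomputed_oac_weighted(self, mix: TreatmentMix | None = None) -> float:
        """Mix-weighted annual OAC cost re-derived from the unit costs."""
        mix = mix or TreatmentMix()
        return mix.warfarin_share * self.oac_warfarin + mix.noac_share * self.oac_noac


# ---------------------------------------------------------------------------
# Derivation rules
# ---------------------------------------------------------------------------

def weighted_stroke_risk(table: RiskTable) -> float:
    """Cohort-weighted annual stroke risk for untreated AF.

    The base-case untreated stroke rate is the count-weighted mean of the
    per-score adjusted rates: sum(count_s * rate_s) / sum(count_s).
    """
    total = table.total_count
    if total <= 0:
        raise ValueError("risk table total count must be positive for weighting")
    return sum(c * r for _, c, r in table.entries) / total


def oac_stroke_incidence(untreated_rate: float, mix: TreatmentMix) -> float:
    """Annual stroke incidence of AF patients on anticoagulation.

    Mix-weighted mean of the per-agent treated rates, each computed as the
    untreated rate times (1 - relative risk reduction).
    """
    _check_prob("untreated_rate", untreated_rate)
    return untreated_rate * (
        mix.warfarin_share * (1.0 - mix.rrr_stroke_warfarin)
        + mix.noac_share * (1.0 - mix.rrr_stroke_noac)
    )


def no_af_stroke_incidence(untreated_rate: float, multiplier: float) -> float:
    """Annual stroke incidence without AF: untreated-AF rate / multiplier.

    AF raises stroke risk ``multiplier``-fold (4.8 in the base case), so the
    AF-free incidence is obtained by dividing it back out.
    """
    if multiplier <= 0:
        raise ValueError("AF stroke multiplier must be positive")
    return untreated_rate / multiplier


def derived_mortalities(params: ModelParameters) -> tuple[float, float, float]:
    """(untreated-AF mortality, on-OAC AF mortality, on-OAC stroke mortality).

    Untreated AF multiplies background mortality by the AF mortality relative
    risk; anticoagulation removes one third of both the AF mortality excess
    state rate and the stroke case fatality.
    """
    af_untreated = params.background_mortality * params.af_mortality_rr
    reduction = params.treatment_mix.mortality_reduction_oac
    af_oac = af_untreated * (1.0 - reduction)
    stroke_oac = params.stroke_mortality_untreated_af * (1.0 - reduction)
    return af_untreated, af_oac, stroke_oac


def weighted_bleed_risk(mix: TreatmentMix) -> float:
    """Mix-weighted annual major-bleeding risk under anticoagulation."""
    return (
        mix.warfarin_share * mix.bleed_rate_warfarin
        + mix.noac_share * mix.bleed_rate_noac
    )


# ---------------------------------------------------------------------------
# Annual state costs
# ---------------------------------------------------------------------------

#: The costed state x event combinations of the annual cost table.
COSTED_STATES = (
    "af_oac_stroke_alive",
    "af_oac_stroke_fatal",
    "af_oac_no_stroke_alive",
    "af_oac_no_stroke_dead",
    "af_undetected_stroke_alive",
    "af_undetected_stroke_fatal",
    "af_undetected_no_stroke_alive",
    "af_undetected_no_stroke_dead",
    "no_af_stroke_alive",
    "no_af_stroke_fatal",
    "no_af_no_stroke_alive",
    "no_af_no_stroke_dead",
    "bleeding_event",
)


def state_cost(
    state_label: str,
    costs: CostParameters,
    oac_annual: float | None = None,
) -> float:
    """Composed annual cost (EUR) for one state x event combination.

    Stroke-year costs sum inpatient treatment, rehabilitation, post-stroke
    outpatient care and the state's antithrombotic medication (weighted OAC
    cost for detected/anticoagulated patients, ASA otherwise).  Fatal strokes
    scale rehabilitation by the four-week-survival fraction and outpatient
    care plus medication by the deceased half-year fraction.  Undetected-AF
    strokes multiply inpatient costs by the untreated-AF factor.  States
    without stroke and without OAC carry no cost; major bleeding is costed
    per event.

    ``oac_annual`` overrides the weighted OAC cost (e.g. Warfarin-only
    scenarios or per-draw re-derivation in the probabilistic SA).
    """
    oac = costs.oac_weighted if oac_annual is None else oac_annual
    surv = costs.rehab_survival_fraction
    half = costs.deceased_half_year_fraction
    inp = costs.inpatient_stroke
    inp_untreated = inp * costs.untreated_af_inpatient_multiplier

    table = {
        "af_oac_stroke_alive": inp + costs.rehab_stroke + costs.outpatient_post_stroke + oac,
        "af_oac_stroke_fatal": inp + surv * costs.rehab_stroke + half * (costs.outpatient_post_stroke + oac),
        "af_oac_no_stroke_alive": oac,
        "af_oac_no_stroke_dead": half * oac,
        "af_undetected_stroke_alive": inp_untreated + costs.rehab_stroke + costs.outpatient_post_stroke + costs.asa,
        "af_undetected_stroke_fatal": inp_untreated + surv * costs.rehab_stroke + half * (costs.outpatient_post_stroke + costs.asa),
        "af_undetected_no_stroke_alive": 0.0,
        "af_undetected_no_stroke_dead": 0.0,
        "no_af_stroke_alive": inp + costs.rehab_stroke + costs.outpatient_post_stroke + costs.asa,
        "no_af_stroke_fatal": inp + surv * costs.rehab_stroke + half * (costs.outpatient_post_stroke + costs.asa),
        "no_af_no_stroke_alive": 0.0,
        "no_af_no_stroke_dead": 0.0,
        "bleeding_event": costs.bleed_event,
    }
    try:
        return table[state_label]
    except KeyError:
        raise ValueError(f"unknown cost state {state_label!r}") from None


def warfarin_only(
    params: ModelParameters, costs: CostParameters
) -> tuple[ModelParameters, CostParameters]:
    """Counterfactual in which every anticoagulated patient receives Warfarin.

    Sets the Warfarin share to 1 (stroke RRR 64%, bleeding 3.4%/yr) and the
    annual OAC cost to the Warfarin cost.
    """
    mix = replace(params.treatment_mix, warfarin_share=1.0, noac_share=0.0)
    return (
        replace(params, treatment_mix=mix),
        replace(costs, oac_weighted=costs.oac_warfarin),
    )
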