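"""Structured configuration: every model input in one YAML file.

The bundled default configuration reproduces the base case exactly; any
run can swap in an edited copy.  Sections mirror the three input tables:
``risk_table`` (per-score counts and adjusted stroke rates), ``transitions``
(annual probabilities), ``treatment`` (anticoagulant mix and effects),
``costs`` (unit costs and composition fractions) and ``model`` (horizon,
discounting, cohort settings).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

from .parameters import (
    CostParameters,
    ModelParameters,
    RiskTable,
    TreatmentMix,
)

__all__ = ["ModelConfig", "load_config", "save_config", "default_config_path"]


@dataclass(frozen=True)
class ModelConfig:
    """All model inputs, ready to feed the engine."""

    params: ModelParameters
    costs: CostParameters
    risk_table: RiskTable


def default_config_path() -> Path:
    """Path of the bundled base-case configuration."""
    return Path(importlib.resources.files("afecon") / "data" / "default.yaml")


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a configuration file (the bundled default when ``path`` is None)."""
    path = Path(path) if path is not None else default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    table = RiskTable(
        entries=tuple(
            (int(row["score"]), int(row["count"]), float(row["stroke_rate"]))
            for row in raw["risk_table"]
        )
    )
    mix = TreatmentMix(**{k: float(v) for k, v in raw["treatment"].items()})
    costs = CostParameters(**{k: float(v) for k, v in raw["costs"].items()})

    model = dict(raw["model"])
    transitions = {k: float(v) for k, v in raw["transitions"].items()}
    params = ModelParameters(
        treatment_mix=mix,
        **transitions,
        female_share=float(model.pop("female_share")),
        oac_eligibility_min_score_male=int(model.pop("oac_eligibility_min_score_male")),
        oac_eligibility_min_score_female=int(
            model.pop("oac_eligibility_min_score_female")
        ),
        discount_rate=float(model.pop("discount_rate")),
        horizon_years=int(model.pop("horizon_years")),
        cohort_size=int(model.pop("cohort_size")),
        oac_uptake=float(model.pop("oac_uptake")),
        redetect_each_cycle=bool(model.pop("redetect_each_cycle")),
    )
    if model:
        raise ValueError(f"unknown keys in model section: {sorted(model)}")
    return ModelConfig(params=params, costs=costs, risk_table=table)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration in the same layout as the bundled default."""
    p, c = config.params, config.costs
    raw = {
        "risk_table": [
            {"score": s, "count": n, "stroke_rate": r}
            for s, n, r in config.risk_table.entries
        ],
        "transitions": {
            "af_incidence": p.af_incidence,
            "detection_prob_dx": p.detection_prob_dx,
            "detection_prob_conventional": p.detection_prob_conventional,
            "stroke_rate_untreated_af": p.stroke_rate_untreated_af,
            "af_stroke_multiplier": p.af_stroke_multiplier,
            "stroke_mortality_no_af": p.stroke_mortality_no_af,
            "stroke_mortality_untreated_af": p.stroke_mortality_untreated_af,
            "background_mortality": p.background_mortality,
            "af_mortality_rr": p.af_mortality_rr,
            "bleed_rate_no_oac": p.bleed_rate_no_oac,
        },
        "treatment": {
            "warfarin_share": p.treatment_mix.warfarin_share,
            "noac_share": p.treatment_mix.noac_share,
            "rrr_stroke_warfarin": p.treatment_mix.rrr_stroke_warfarin,
            "rrr_stroke_noac": p.treatment_mix.rrr_stroke_noac,
            "mortality_reduction_oac": p.treatment_mix.mortality_reduction_oac,
            "bleed_rate_warfarin": p.treatment_mix.bleed_rate_warfarin,
            "bleed_rate_noac": p.treatment_mix.bleed_rate_noac,
        },
        "costs": {
            "inpatient_stroke": c.inpatient_stroke,
            "rehab_stroke": c.rehab_stroke,
            "outpatient_post_stroke": c.outpatient_post_stroke,
            "oac_warfarin": c.oac_warfarin,
            "oac_noac": c.oac_noac,
            "oac_weighted": c.oac_weighted,
            "asa": c.asa,
            "bleed_event": c.bleed_event,
            "untreated_af_inpatient_multiplier": c.untreated_af_inpatient_multiplier,
            "rehab_survival_fraction": c.rehab_survival_fraction,
            "deceased_half_year_fraction": c.deceased_half_year_fraction,
        },
        "model": {
            "female_share": p.female_share,
            "oac_eligibility_min_score_male": p.oac_eligibility_min_score_male,
            "oac_eligibility_min_score_female": p.oac_eligibility_min_score_female,
            "discount_rate": p.discount_rate,
            "horizon_years": p.horizon_years,
            "cohort_size": p.cohort_size,
            "oac_uptake": p.oac_uptake,
            "redetect_each_cycle": p.redetect_each_cycle,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
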