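"""Synthetic patient cohorts with the reference score structure.

The cohort model itself is expectation-based and needs only a weighted
stroke rate, but individual cohorts are useful for testing the weighting
logic end-to-end and for exploring alternative populations.  A synthetic
patient is a (CHA2DS2-VASc score, sex, anticoagulation eligibility) triple;
scores are drawn from a categorical distribution (by default the 171-patient
reference cohort), sex independently of score, and eligibility follows the
guideline thresholds: males qualify for anticoagulation from score 1,
females from score 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import DEFAULT_RISK_TABLE, ModelParameters, RiskTable

__all__ = [
    "SyntheticCohort",
    "sample_cohort",
    "cohort_to_risk_inputs",
    "eligible_fraction",
    "write_cohort",
    "read_cohort",
]

#: Female share reported for the trial population the model assumes (19%).
#: The reference score-distribution cohort itself had 15.79% women.
DEFAULT_FEMALE_SHARE = 0.19
REFERENCE_COHORT_FEMALE_SHARE = 0.1579


@dataclass(frozen=True)
class SyntheticCohort:
    """Sampled patients: columns ``score``, ``sex``, ``oac_eligible``."""

    patients: pd.DataFrame
    source_seed: int

    def __post_init__(self) -> None:
        missing = {"score", "sex", "oac_eligible"} - set(self.patients.columns)
        if missing:
            raise ValueError(f"cohort frame lacks columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.patients)


def _eligibility(
    scores: np.ndarray,
    female: np.ndarray,
    min_score_male: int = 1,
    min_score_female: int = 2,
) -> np.ndarray:
    return np.where(female, scores >= min_score_female, scores >= min_score_male)


def sample_cohort(
    n: int,
    score_distribution: RiskTable = DEFAULT_RISK_TABLE,
    female_share: float = DEFAULT_FEMALE_SHARE,
    seed: int = 0,
    min_score_male: int = 1,
    min_score_female: int = 2,
) -> SyntheticCohort:
    """Draw ``n`` patients from the categorical score distribution.

    Sex is sampled independently of score (the reference table is not
    sex-stratified); eligibility applies the score/sex thresholds.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    total = score_distribution.total_count
    if total <= 0:
        raise ValueError("score distribution has zero total count")
    fractions = np.array([c / total for _, c, _ in score_distribution.entries])
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("score distribution fractions must sum to 1")
    scores_avail = np.array([s for s, _, _ in score_distribution.entries])

    rng = np.random.default_rng(seed)
    scores = rng.choice(scores_avail, size=n, p=fractions)
    female = rng.random(n) < female_share
    eligible = _eligibility(scores, female, min_score_male, min_score_female)
    frame = pd.DataFrame(
        {
            "score": scores.astype(int),
            "sex": np.where(female, "female", "male"),
            "oac_eligible": eligible.astype(bool),
        }
    )
    return SyntheticCohort(patients=frame, source_seed=seed)


def cohort_to_risk_inputs(
    cohort: SyntheticCohort, risk_table: RiskTable = DEFAULT_RISK_TABLE
) -> tuple[float, float]:
    """Empirical (weighted untreated stroke rate, anticoagulation-eligible fraction).

    The rate is the mean per-score adjusted stroke rate over the cohort's
    patients — the plug-in replacement for the base-case weighted rate; the
    eligible fraction can serve as the anticoagulation uptake of detected
    patients.
    """
    rates = cohort.patients["score"].map(
        {s: r for s, _, r in risk_table.entries}
    )
    if rates.isna().any():
        unknown = sorted(cohort.patients.loc[rates.isna(), "score"].unique())
        raise ValueError(f"scores missing from risk table: {unknown}")
    return float(rates.mean()), float(cohort.patients["oac_eligible"].mean())


def eligible_fraction(
    risk_table: RiskTable = DEFAULT_RISK_TABLE,
    female_share: float = DEFAULT_FEMALE_SHARE,
    params: ModelParameters | None = None,
) -> float:
    """Expected eligible fraction under the threshold rule (no sampling).

    Sex is assumed independent of score, so each score contributes its
    population share times the fraction of that score's patients above
    their sex-specific threshold.
    """
    min_m = params.oac_eligibility_min_score_male if params else 1
    min_f = params.oac_eligibility_min_score_female if params else 2
    total = risk_table.total_count
    frac = 0.0
    for score, count, _ in risk_table.entries:
        share = count / total
        per_sex = (1.0 - female_share) * (score >= min_m) + female_share * (
            score >= min_f
        )
        frac += share * per_sex
    return frac


def write_cohort(cohort: SyntheticCohort, path) -> None:
    """Export as delimited text (score, sex, oac_eligible)."""
    cohort.patients.to_csv(path, index=False)


def read_cohort(path, source_seed: int = -1) -> SyntheticCohort:
    """Load a cohort previously written with :func:`write_cohort`."""
    frame = pd.read_csv(path)
    frame["oac_eligible"] = frame["oac_eligible"].astype(bool)
    return SyntheticCohort(patients=frame, source_seed=source_seed)
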