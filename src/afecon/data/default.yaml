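# Base-case model inputs.
# risk_table: CHA2DS2-VASc distribution of the 171-patient reference cohort
# with adjusted annual stroke rates per score.
risk_table:
- {score: 0, count: 13, stroke_rate: 0.0}
- {score: 1, count: 16, stroke_rate: 0.013}
- {score: 2, count: 28, stroke_rate: 0.022}
- {score: 3, count: 31, stroke_rate: 0.032}
- {score: 4, count: 40, stroke_rate: 0.040}
- {score: 5, count: 27, stroke_rate: 0.067}
- {score: 6, count: 13, stroke_rate: 0.098}
- {score: 7, count: 2, stroke_rate: 0.096}
- {score: 8, count: 1, stroke_rate: 0.067}
- {score: 9, count: 0, stroke_rate: 0.152}
transitions:
  af_incidence: 0.2094
  detection_prob_dx: 0.98
  detection_prob_conventional: 0.15
  stroke_rate_untreated_af: 0.0396
  af_stroke_multiplier: 4.8
  stroke_mortality_no_af: 0.34
  stroke_mortality_untreated_af: 0.63
  background_mortality: 0.06
  af_mortality_rr: 1.85
  bleed_rate_no_oac: 0.0295
treatment:
  warfarin_share: 0.479
  noac_share: 0.521
  rrr_stroke_warfarin: 0.64
  rrr_stroke_noac: 0.66
  mortality_reduction_oac: 0.3333333333333333
  bleed_rate_warfarin: 0.034
  bleed_rate_noac: 0.036
costs:
  inpatient_stroke: 6731.0
  rehab_stroke: 6822.0
  outpatient_post_stroke: 3287.0
  oac_warfarin: 65.70
  oac_noac: 1241.00
  oac_weighted: 678.18   # printed mix-weighted value; recomputed would be 678.03
  asa: 14.60
  bleed_event: 1995.0
  untreated_af_inpatient_multiplier: 1.34
  rehab_survival_fraction: 0.46
  deceased_half_year_fraction: 0.50
model:
  female_share: 0.19
  oac_eligibility_min_score_male: 1
  oac_eligibility_min_score_female: 2
  discount_rate: 0.03
  horizon_years: 9
  cohort_size: 1000
  oac_uptake: 1.0
  redetect_each_cycle: true
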