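# Methods

## Model structure

`afecon` is an expectation-based Markov cohort model: occupancies are
continuous expected patient counts, so one run yields exact cohort means
with no Monte-Carlo noise. A closed cohort (default 1,000 patients) starts
AF-free and is followed for nine one-year cycles — the device battery life —
under constant annual transition probabilities.

States are *no AF*, *AF detected + OAC*, *AF undetected*, and cumulative
*dead*. Stroke, stroke death, non-stroke death and major bleeding are
within-cycle events. The two treatment arms differ **only** in the AF
detection probability (98 % atrial-sensing vs. 15 % conventional); AF
incidence itself is identical, so any outcome difference is attributable to
earlier anticoagulation onset.

Within a cycle, in order:

1. **Re-screening.** The prevalent undetected-AF pool is re-screened at the
   arm's detection probability. AF in this population is recurrent and
   device follow-up is periodic, so detection is a per-cycle opportunity,
   not a one-off decision at onset. (A `redetect_each_cycle=False` switch
   makes detection status permanent instead.)
2. **AF onset and detection.** AF-free patients develop AF at 20.94 %/yr;
   detected cases start anticoagulation immediately and are exposed to
   their new state's risks in the same cycle.
3. **Strokes**, at the state-specific annual rate, with a state-specific
   case fatality. Survivors return to their state and can stroke again in
   later cycles (stroke is a transient event — the cost table defines
   year-of-stroke costs and no chronic post-stroke state).
4. **Non-stroke mortality**, applied to the **full** state occupancy as an
   independent competing hazard (see "Reconstruction choices").
5. **Bleeding**, a cost-only event (3.50 %/yr on OAC, 2.95 % otherwise);
   no treatment discontinuation is modelled.

Costs accrue per state × event per the published composition rules
(deceased patients receive half a year of outpatient care and medication;
fatal strokes scale rehabilitation by the 46 % four-week survival fraction;
undetected-AF strokes carry a ×1.34 inpatient multiplier and ASA instead of
OAC). Costs **and** effects are discounted at 3 %/yr from the second cycle.
No half-cycle correction is applied.

## Parameters

All primitives sit in one YAML configuration (`afecon/data/default.yaml`);
derived quantities are always recomputed from primitives. The key defaults:

| parameter | default | note |
|---|---|---|
| AF incidence | 0.2094 /yr | ICD population |
| detection, atrial sensing / conventional | 0.98 / 0.15 | per cycle |
| untreated AF stroke rate (base case) | 0.0396 /yr | CHA₂DS₂-VASc-weighted over the 171-patient reference cohort |
| AF stroke multiplier | 4.8 | no-AF rate = untreated / 4.8 |
| stroke RRR Warfarin / Rivaroxaban | 0.64 / 0.66 | mix 47.9 % / 52.1 % |
| stroke case fatality no-AF / untreated / OAC | 0.34 / 0.63 / 0.42 | OAC = untreated × (1 − ⅓) |
| non-stroke mortality no-AF / untreated / OAC | 0.06 / 0.111 / 0.074 | untreated = 0.06 × 1.85 |
| bleeding on/off OAC | 0.035 / 0.0295 | cost-only, €1,995/event |
| OAC cost | €678.18 /yr | printed mix-weighted value |
| discount rate | 0.03 | costs and effects, from year 2 |

The printed weighted OAC cost (€678.18) is kept rather than the value
recomputed from the unit costs (0.479×65.70 + 0.521×1241.00 = €678.03),
because the published composed state costs (€17,518 …) only reproduce with
the former; `CostParameters.recomputed_oac_weighted()` gives the
re-derivation, and the probabilistic SA always re-derives the weighted cost
from its sampled unit costs.

Every detected patient starts anticoagulation (`oac_uptake = 1.0`).
Guideline eligibility thresholds (men from CHA₂DS₂-VASc 1, women from 2)
are implemented in the cohort module; feeding the resulting eligible
fraction (≈ 0.91 for the reference distribution at 19 % women) into
`oac_uptake` models threshold-restricted uptake, but the published
base-case outputs correspond to full uptake.

## Reconstruction choices

The source model's exact state diagram is not published; the structure here
was chosen so that the derivation layer and all published outputs reproduce
from the printed inputs. Two choices deserve emphasis:

* **Per-cycle re-screening** of undetected AF. Without it, untreated AF
  accumulates in the conventional arm and stroke counts overshoot the
  published values by ~30 %.
* **Independent (additive) competing hazards**: non-stroke mortality is
  applied to a state's full occupancy, not only to its non-stroke fraction.
  The sequential alternative changes the nine-year outputs by ~1–2 % and
  moves the score-9 NNT from 74 to 69.

With these choices the model reproduces the published first-year costs
(€337/€295), discounted stroke rates (7.9/12.5 per 1,000/yr), score-9 NNT
(74) and saving (€228), score-1 NNTs (617/800), Warfarin-only saving
(≈ €96 vs. €95) and the detection-rate sensitivity endpoints (€125/€52 vs.
€126/€52). The nine-year mean annual costs come out ~1.2 % below the
published €570/€491 in **both** arms (€563/€484); the gap is
arm-independent, so all cost differences match, and its source (some small
per-alive-patient cost component) could not be identified from the printed
information.

The per-1,000 stroke rates and NNTs are reported **discounted** (matching
the published secondary outcomes; the undiscounted counts are ~11 % higher
and are carried alongside in every `ComparisonResult`).

## Sensitivity analyses

One-way: each primitive is varied to the ends of a predefined min–max range
with everything else at base; the default range is ±80 % of base (the
convention the source states for the one range it prints: detection
15 % → 3–27 %), discount rate 2–4 %, probability ranges capped at 1.
Parameters are ranked by the span of the arm cost difference.

Probabilistic: all primitives sampled independently per run — gamma for
costs (shape/scale with mean = base), normal for probabilities (truncated
to [0, 1]) and risk ratios (truncated at the range floor, which must be
positive) — with sd = (high − low)/(2 × 1.96), i.e. the deterministic range
read as a 95 % interval. Derived quantities are re-derived per draw.
Default 1,000 runs; bit-reproducible for a fixed seed
(`numpy.random.default_rng`).

Because the actual ranges behind the published probabilistic analysis are
not printed, its headline probability of cost saving is reproduced only
qualitatively: under the ±80 % assumption this model gives ≈ 20 % (published
11.3 %), while the robust findings — strokes avoided in essentially every
draw, cost saving in a minority — hold. The PSA mean converges to the
deterministic base case up to a small truncation/nonlinearity gap (the
checks allow five Monte-Carlo standard errors).

## Synthetic cohorts

`sample_cohort` draws patients (score, sex, OAC eligibility) from the
reference CHA₂DS₂-VASc distribution; sex is sampled independently of score
(the reference table is not sex-stratified — an assumption), female share
19 % by default (the reference cohort's own 15.79 % is available as a
constant). The generator exists to exercise the weighting and eligibility
logic end-to-end and to explore alternative populations; the cohort model
itself is expectation-based, and passing these tests does not validate the
model against patient-level heterogeneity (risk-factor progression over
time, score drift) that real cohorts show.

## Numerical notes and degenerate inputs

* Occupancy conservation (alive + dead = cohort size) holds to 1e-9 at
  every cycle; composed within-cycle exit probabilities are validated and a
  `ModelConsistencyError` is raised if a parameter combination pushes a
  state's exit fraction outside [0, 1].
* A zero-count risk table cannot be used for weighting (error); a score-0
  cohort yields zero strokes in every state and infinite NNTs, which the
  reporting layer passes through as `inf` rather than masking.
* NNTs are stored as floats and rounded only for display.
* Reported euro values are full precision in machine-readable output and
  rounded integers in console output.

## Limitations

* Constant transition probabilities: no ageing, no risk-factor or score
  progression over the nine years — costs in later cycles are likely
  underestimated.
* Payer perspective only: no indirect costs, no INR-monitoring costs for
  Warfarin, no ICD implantation or remote-monitoring costs (equal in both
  arms), no QALYs.
* Stroke effect sizes for anticoagulation come from clinical-AF trial
  populations; applying them to device-detected AF may overstate the
  preventable stroke burden.
* The probabilistic analysis inherits unpublished range assumptions; its
  absolute probabilities should be read as indicative.
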