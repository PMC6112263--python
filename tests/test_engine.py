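"""Cohort engine: conservation, dominance, discounting, one-step oracle."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afecon import (
    ModelConsistencyError,
    ModelParameters,
    StateVector,
    cycle_step,
    run_cohort,
    trace_frame,
)


def _no_event_params(params, **extra):
    """Parameters with all stroke and death probabilities switched off."""
    mix = dataclasses.replace(
        params.treatment_mix, mortality_reduction_oac=0.0
    )
    return dataclasses.replace(
        params,
        stroke_rate_untreated_af=0.0,
        stroke_mortality_no_af=0.0,
        stroke_mortality_untreated_af=0.0,
        background_mortality=0.0,
        treatment_mix=mix,
        **extra,
    )


class TestCycleStep:
    def test_single_step_matches_independent_arithmetic(self, params, costs):
        """One cycle from 1,000 AF-free patients, recomputed spreadsheet-style.

        Every expected value below is derived by explicit arithmetic from the
        primitive inputs, independently of the engine's internals.
        """
        state = StateVector(1000.0, 0.0, 0.0, 0.0)
        rec = cycle_step(state, params, costs, detection_prob=0.98)

        new_af = 1000 * 0.2094
        assert new_af == pytest.approx(209.4)
        n_oac = new_af * 0.98
        n_undet = new_af - n_oac
        n_noaf = 1000 - new_af

        rate_oac = 0.0396 * (0.479 * (1 - 0.64) + 0.521 * (1 - 0.66))
        s_noaf = n_noaf * 0.0396 / 4.8
        s_oac = n_oac * rate_oac
        s_undet = n_undet * 0.0396
        assert rec.strokes_by_state["no_af"] == pytest.approx(s_noaf)
        assert rec.strokes_by_state["af_detected_oac"] == pytest.approx(s_oac)
        assert rec.strokes_by_state["af_undetected"] == pytest.approx(s_undet)

        f_total = s_noaf * 0.34 + s_oac * (0.63 * 2 / 3) + s_undet * 0.63
        assert rec.fatal_strokes == pytest.approx(f_total)

        d_total = n_noaf * 0.06 + n_oac * (0.06 * 1.85 * 2 / 3) + n_undet * (0.06 * 1.85)
        assert rec.non_stroke_deaths == pytest.approx(d_total)

        bleeds = n_oac * (0.479 * 0.034 + 0.521 * 0.036) + (n_noaf + n_undet) * 0.0295
        assert rec.bleeds == pytest.approx(bleeds)

        f_oac = s_oac * 0.63 * 2 / 3
        d_oac = n_oac * 0.06 * 1.85 * 2 / 3
        cost = (
            (s_noaf - s_noaf * 0.34) * (6731 + 6822 + 3287 + 14.60)
            + s_noaf * 0.34 * (6731 + 0.46 * 6822 + 0.5 * (3287 + 14.60))
            + (s_oac - f_oac) * (6731 + 6822 + 3287 + 678.18)
            + f_oac * (6731 + 0.46 * 6822 + 0.5 * (3287 + 678.18))
            + (s_undet - s_undet * 0.63) * (6731 * 1.34 + 6822 + 3287 + 14.60)
            + s_undet * 0.63 * (6731 * 1.34 + 0.46 * 6822 + 0.5 * (3287 + 14.60))
            + (n_oac - s_oac - d_oac) * 678.18
            + d_oac * 0.5 * 678.18
            + bleeds * 1995
        )
        assert rec.undiscounted_cost == pytest.approx(cost)
        assert rec.discounted_cost == rec.undiscounted_cost  # year one undiscounted

    def test_no_events_leaves_only_af_migration(self, params, costs):
        quiet = _no_event_params(params)
        state = StateVector(1000.0, 0.0, 0.0, 0.0)
        rec = cycle_step(state, quiet, costs, detection_prob=0.5)
        sv = rec.state_vector
        assert rec.strokes == 0.0 and rec.fatal_strokes == 0.0
        assert rec.non_stroke_deaths == 0.0 and sv.dead == 0.0
        assert sv.no_af == pytest.approx(1000 * (1 - 0.2094))
        assert sv.af_detected_oac == pytest.approx(209.4 * 0.5)
        assert sv.af_undetected == pytest.approx(209.4 * 0.5)

    def test_complete_detection_leaves_no_undetected(self, params, costs):
        state = StateVector(1000.0, 0.0, 0.0, 0.0)
        rec = cycle_step(state, params, costs, detection_prob=1.0)
        assert rec.state_vector.af_undetected == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_probabilities_rejected(self, params, costs):
        lethal = dataclasses.replace(
            params,
            stroke_rate_untreated_af=1.0,
            stroke_mortality_untreated_af=1.0,
        )
        with pytest.raises(ModelConsistencyError):
            cycle_step(StateVector(1000.0, 0.0, 0.0, 0.0), lethal, costs, 0.5)


class TestRunCohort:
    def test_conservation_every_cycle(self, params, costs):
        """Alive plus cumulative dead equals the initial cohort each cycle."""
        for detect in (params.detection_prob_dx, params.detection_prob_conventional):
            trace = run_cohort(params, costs, detect)
            for rec in trace.records:
                assert rec.state_vector.total == pytest.approx(1000.0, abs=1e-9)

    @given(
        af_inc=st.floats(min_value=0.0, max_value=0.5),
        stroke_rate=st.floats(min_value=0.0, max_value=0.2),
        background=st.floats(min_value=0.0, max_value=0.15),
        detect=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_conservation_under_parameter_variation(
        self, af_inc, stroke_rate, background, detect, params, costs
    ):
        varied = dataclasses.replace(
            params,
            af_incidence=af_inc,
            stroke_rate_untreated_af=stroke_rate,
            background_mortality=background,
        )
        trace = run_cohort(varied, costs, detect)
        for rec in trace.records:
            assert rec.state_vector.total == pytest.approx(1000.0, abs=1e-9)
            assert rec.fatal_strokes <= rec.strokes + 1e-12
            assert min(rec.strokes, rec.bleeds, rec.non_stroke_deaths) >= 0.0

    def test_zero_mortality_keeps_cohort_alive(self, params, costs):
        quiet = _no_event_params(params)
        trace = run_cohort(quiet, costs, 0.98)
        for rec in trace.records:
            assert rec.state_vector.alive == pytest.approx(1000.0)

    def test_equal_detection_gives_identical_traces(self, params, costs):
        a = run_cohort(params, costs, 0.5, "dx")
        b = run_cohort(params, costs, 0.5, "conventional")
        assert trace_frame(a).drop(columns="arm").equals(
            trace_frame(b).drop(columns="arm")
        )

    def test_atrial_sensing_dominates_every_cycle(self, params, costs):
        """More anticoagulated patients and fewer strokes at every cycle."""
        dx = run_cohort(params, costs, params.detection_prob_dx)
        cv = run_cohort(params, costs, params.detection_prob_conventional)
        for rec_dx, rec_cv in zip(dx.records, cv.records):
            assert (
                rec_dx.state_vector.af_detected_oac
                > rec_cv.state_vector.af_detected_oac
            )
            assert rec_dx.strokes <= rec_cv.strokes

    def test_discounting_relation(self, params, costs):
        trace = run_cohort(params, costs, 0.98)
        for rec in trace.records:
            expected = rec.undiscounted_cost / 1.03 ** (rec.cycle_index - 1)
            assert rec.discounted_cost == pytest.approx(expected)
            if rec.cycle_index == 1:
                assert rec.discounted_cost == rec.undiscounted_cost
            else:
                assert rec.discounted_cost < rec.undiscounted_cost

    def test_single_year_horizon(self, params, costs):
        short = dataclasses.replace(params, horizon_years=1)
        trace = run_cohort(short, costs, 0.98)
        assert len(trace.records) == 1
        assert trace.records[0].discount_factor == 1.0

    def test_trace_frame_layout(self, params, costs):
        frame = trace_frame(run_cohort(params, costs, 0.98, "dx"))
        assert len(frame) == params.horizon_years
        assert list(frame["cycle"]) == list(range(1, 10))
        assert set(frame["arm"]) == {"dx"}
        assert {"strokes", "discounted_cost", "dead"} <= set(frame.columns)

    def test_redetection_toggle_changes_conventional_arm_only_weakly(
        self, params, costs
    ):
        """Without re-screening, the undetected pool keeps accumulating."""
        sticky = dataclasses.replace(params, redetect_each_cycle=False)
        with_re = run_cohort(params, costs, 0.15)
        without = run_cohort(sticky, costs, 0.15)
        assert (
            without.records[-1].state_vector.af_undetected
            > with_re.records[-1].state_vector.af_undetected
        )
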