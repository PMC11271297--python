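"""Cohort engine: transition construction, trace dynamics, accumulation."""

import dataclasses
import math

import numpy as np
import pytest

from her2cua import (
    EfficacyMode,
    HealthState,
    Perspective,
    accumulate,
    background_mortality,
    ef_event_probability,
    hazard_scale,
    run_cohort,
    run_strategy,
    transition_distribution,
)


class TestHazardScale:
    def test_rate_transform_value(self):
        # two routes: closed form vs explicit rate conversion
        p, hr = 0.01015, 0.54
        direct = hazard_scale(p, hr)
        via_rate = 1.0 - math.exp(hr * math.log(1.0 - p))
        assert direct == pytest.approx(0.0054938, abs=1e-7)
        assert direct == pytest.approx(via_rate, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 0.2, 0.97])
    def test_identity_at_hr_one(self, p):
        assert hazard_scale(p, 1.0) == pytest.approx(p, abs=1e-15)

    def test_zero_hazard(self):
        assert hazard_scale(0.0, 0.54) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hazard_scale(1.0, 0.54)
        with pytest.raises(ValueError):
            hazard_scale(0.5, 0.0)
        with pytest.raises(ValueError):
            hazard_scale(1.2, 0.5)


class TestEfEventProbability:
    def test_comparator_flat(self, base_params):
        s1 = base_params.strategy("S1")
        for cycle in (0, 30, 59, 60, 300):
            assert ef_event_probability(s1, cycle) == 0.01015

    def test_hr_applied_within_effect_window(self, base_params):
        s2 = base_params.strategy("S2")
        assert ef_event_probability(s2, 30) == pytest.approx(0.0054938, abs=1e-7)
        assert ef_event_probability(s2, 100) == pytest.approx(
            hazard_scale(0.01015, 0.54), abs=1e-15
        )

    def test_effect_expires_after_twelve_years(self, base_params):
        s2 = base_params.strategy("S2")
        s5 = base_params.strategy("S5")
        assert ef_event_probability(s2, 144) == 0.01015
        assert ef_event_probability(s5, 200) == 0.01015

    def test_trial_baseline_strategies(self, base_params):
        s4 = base_params.strategy("S4")
        # default mode rescales the trial baseline by the hazard ratio
        assert ef_event_probability(s4, 6) == pytest.approx(
            hazard_scale(0.00118, 0.54), abs=1e-15
        )
        # the alternative composition uses the trial schedule unscaled
        assert ef_event_probability(s4, 6, EfficacyMode.TRIAL_THEN_HR) == 0.00118
        assert ef_event_probability(s4, 100, EfficacyMode.TRIAL_THEN_HR) == (
            pytest.approx(hazard_scale(0.01015, 0.54), abs=1e-15)
        )
        s5 = base_params.strategy("S5")
        assert ef_event_probability(s5, 30, EfficacyMode.BASELINE_ONLY) == 0.00798

    def test_negative_cycle_rejected(self, base_params):
        with pytest.raises(ValueError):
            ef_event_probability(base_params.strategy("S1"), -1)


class TestBackgroundMortality:
    @pytest.mark.parametrize(
        "age,expected", [(52, 0.00027), (84.9, 0.00708), (99, 0.00708), (50, 0.00027)]
    )
    def test_band_lookup(self, base_params, age, expected):
        assert background_mortality(age, base_params.life_table) == expected

    def test_age_below_table(self, base_params):
        with pytest.raises(ValueError):
            background_mortality(30, base_params.life_table)


class TestTransitionDistribution:
    def test_event_free_row_comparator_cycle0(self, base_params):
        row = transition_distribution(
            HealthState.EVENT_FREE, 0, 0, base_params.strategy("S1"), base_params
        )
        assert row[HealthState.LOCOREGIONAL] == pytest.approx(0.0025375, abs=1e-12)
        assert row[HealthState.METASTASIS] == pytest.approx(0.0076125, abs=1e-12)
        assert row[HealthState.DEAD] == 0.00027
        assert row[HealthState.EVENT_FREE] == pytest.approx(0.98958, abs=1e-12)

    def test_locoregional_stay_probability_zero(self, base_params):
        row = transition_distribution(
            HealthState.LOCOREGIONAL, 0, 10, base_params.strategy("S1"), base_params
        )
        assert row[HealthState.LOCOREGIONAL] == pytest.approx(0.0, abs=1e-12)

    def test_dead_absorbing(self, base_params):
        row = transition_distribution(
            HealthState.DEAD, 40, 99, base_params.strategy("S3"), base_params
        )
        assert row == {HealthState.DEAD: 1.0}

    @pytest.mark.parametrize("state", list(HealthState))
    @pytest.mark.parametrize("cycle", [0, 11, 60, 143, 400])
    def test_rows_are_stochastic(self, base_params, state, cycle):
        for strategy in base_params.strategies:
            row = transition_distribution(state, 3, cycle, strategy, base_params)
            assert abs(sum(row.values()) - 1.0) < 1e-12
            assert all(p >= 0.0 for p in row.values())


class TestRunCohort:
    def test_initial_condition(self, base_params):
        trace = run_cohort("S1", base_params)
        first = trace.occupancy[0]
        assert first[HealthState.EVENT_FREE, 0] == 1.0
        assert first.sum() == 1.0

    def test_mass_conserved_and_dead_monotone(self, base_params):
        trace = run_cohort("S2", base_params)
        totals = trace.occupancy.sum(axis=(1, 2))
        assert np.all(np.abs(totals - 1.0) < 1e-10)
        dead = trace.state_totals()[:, HealthState.DEAD]
        assert np.all(np.diff(dead) >= -1e-15)

    def test_event_free_survival_closed_form(self, base_params):
        """EF occupancy equals the survival product of its exit hazards."""
        trace = run_cohort("S1", base_params)
        ef60 = trace.state_totals()[60, HealthState.EVENT_FREE]
        prod = 1.0
        for t in range(60):
            m = base_params.life_table.monthly_death_probability(50 + t / 12.0)
            prod *= 1.0 - 0.01015 - m
        assert ef60 == pytest.approx(prod, abs=1e-12)

    def test_hr_one_reproduces_comparator_dynamics(self, base_params):
        """With its hazard ratio forced to 1 the intervention's trace
        collapses onto the comparator's (only costs differ)."""
        neutral = base_params.with_values({"hr.s2": 1.0})
        t1 = run_cohort("S1", neutral).state_totals()
        t2 = run_cohort("S2", neutral).state_totals()
        assert np.allclose(t1, t2, atol=1e-12)

    def test_lower_hazard_ratio_never_loses_life_years(self, base_params):
        lys = []
        for hr in (0.5, 0.7, 0.9, 1.0):
            ps = base_params.with_values({"hr.s2": hr})
            lys.append(run_strategy("S2", ps, Perspective.PUBLIC).ly_discounted)
        assert all(a >= b - 1e-12 for a, b in zip(lys, lys[1:]))

    def test_tenure_advances_and_resets(self, base_params):
        trace = run_cohort("S1", base_params)
        # entrants to locoregional recurrence always carry tenure 0: with exit
        # probabilities summing to 1 nothing survives into tenure >= 1
        lrr = trace.occupancy[:, HealthState.LOCOREGIONAL, :]
        assert lrr[:, 1:].sum() == 0.0
        assert lrr[1:, 0].max() > 0.0
        # remission accumulates long tenures up to the cap
        rem = trace.occupancy[:, HealthState.REMISSION, :]
        assert rem[-1, base_params.tenure_cap_months] > 0.0


class TestAccumulate:
    def test_unit_utilities_make_qaly_equal_ly(self, base_params):
        ps = base_params.with_values(
            {
                "util.ef_year1": 1.0,
                "util.ef_after_year1": 1.0,
                "util.lrr": 1.0,
                "util.remission": 1.0,
                "util.metastasis": 1.0,
            }
        )
        res = run_strategy("S3", ps, Perspective.PUBLIC)
        assert res.qaly_discounted == pytest.approx(res.ly_discounted, abs=1e-9)

    def test_zero_discount_collapses_streams(self, base_params):
        ps = dataclasses.replace(
            base_params, discount_rate_costs=0.0, discount_rate_outcomes=0.0
        )
        res = run_strategy("S1", ps, Perspective.SOCIETAL)
        assert res.ly_discounted == pytest.approx(res.ly_undiscounted, rel=1e-12)
        assert res.cost_discounted == pytest.approx(res.cost_undiscounted, rel=1e-12)

    @pytest.mark.parametrize("sid", ["S1", "S2", "S3", "S4", "S5"])
    def test_outcome_orderings(self, public_results, societal_results, sid):
        pub, soc = public_results[sid], societal_results[sid]
        for res in (pub, soc):
            assert res.qaly_discounted <= res.ly_discounted
            assert res.ly_discounted <= res.ly_undiscounted
            assert res.qaly_discounted <= res.qaly_undiscounted
            assert res.cost_discounted <= res.cost_undiscounted
        assert soc.cost_discounted >= pub.cost_discounted
        assert soc.ly_discounted == pub.ly_discounted

    def test_cost_stream_starts_with_neoadjuvant_lump(self, base_params, public_results):
        stream = public_results["S2"].per_cycle_cost_stream
        assert stream[0] > base_params.strategy("S2").neoadjuvant_dmc
        assert stream.sum() == pytest.approx(
            public_results["S2"].cost_undiscounted, rel=1e-12
        )

    def test_unknown_perspective_rejected(self, base_params):
        trace = run_cohort("S1", base_params)
        with pytest.raises(ValueError):
            accumulate(trace, "S1", base_params, "payer")

    def test_trace_strategy_mismatch_rejected(self, base_params):
        trace = run_cohort("S1", base_params)
        with pytest.raises(ValueError):
            accumulate(trace, "S2", base_params, Perspective.PUBLIC)


def test_trace_export_schema(base_params):
    trace = run_cohort("S1", base_params)
    frame = trace.to_frame(base_params.start_age_years)
    assert list(frame.columns) == [
        "cycle", "age_years", "state", "months_in_state", "fraction",
    ]
    cycle0 = frame[frame.cycle == 0]
    assert len(cycle0) == 1
    assert cycle0.iloc[0]["state"] == "EVENT_FREE"
    assert cycle0.iloc[0]["fraction"] == 1.0
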