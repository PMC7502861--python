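import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adjuvance.cohort_engine import (
    HealthState,
    SurvivalModel,
    TransitionInputs,
    aggregate_traces,
    apply_hazard_ratio,
    build_transition_row,
    default_horizon,
    hazard_to_probability,
    probability_to_hazard,
    run_cohort,
    run_cohorts,
)
from adjuvance.population import Subgroup, SubgroupWeights

REFERENCE_SUBGROUP = Subgroup("ge10", "T3", "left", "70-75", "MSS_no_mutation")


def flat_inputs(rec_rate=0.0, cc_rate=0.0, oc_hazard=0.0, q90=0.0):
    """Transition inputs with constant (possibly zero) hazards for closed-form checks."""
    return TransitionInputs(
        recurrence_model=SurvivalModel("exponential", {"rate": rec_rate}),
        cc_death_model=SurvivalModel("exponential", {"rate": cc_rate}),
        other_cause_monthly_hazard={age: oc_hazard for age in range(50, 111)},
        ninety_day_mortality={REFERENCE_SUBGROUP: q90},
    )


class TestConversions:
    @pytest.mark.parametrize(
        "ch, expected",
        [(0.0, 0.0), (0.01, 1.0 - np.exp(-0.01)), (50.0, 1.0 - np.exp(-50.0))],
    )
    def test_hazard_to_probability_closed_form(self, ch, expected):
        assert hazard_to_probability(ch) == pytest.approx(expected, abs=1e-15)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            hazard_to_probability(-0.1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=0.0, max_value=20.0), st.floats(min_value=0.0, max_value=20.0))
    def test_hazard_to_probability_monotone_and_bounded(self, h1, h2):
        p1, p2 = hazard_to_probability(h1), hazard_to_probability(h2)
        assert 0.0 <= p1 < 1.0
        if h1 < h2:
            assert p1 <= p2

    @pytest.mark.parametrize(
        "p, hr, expected",
        [(0.1, 1.0, 0.1), (0.2, 2.0, 0.36), (0.3, 0.73, 1.0 - 0.7**0.73)],
    )
    def test_apply_hazard_ratio_closed_form(self, p, hr, expected):
        assert apply_hazard_ratio(p, hr) == pytest.approx(expected, rel=1e-12)

    def test_apply_hazard_ratio_domain_errors(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(1.0, 0.73)
        with pytest.raises(ValueError):
            apply_hazard_ratio(0.5, 0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=0.0, max_value=0.99), st.floats(min_value=0.01, max_value=5.0))
    def test_hazard_ratio_acts_on_hazard_scale(self, p, hr):
        # the implied hazard of the output is exactly hr times the input hazard
        out = apply_hazard_ratio(p, hr)
        assert probability_to_hazard(out) == pytest.approx(hr * probability_to_hazard(p), rel=1e-9)


class TestTransitionRow:
    def test_death_states_are_absorbing(self):
        inputs = flat_inputs(rec_rate=0.02, oc_hazard=0.001, q90=0.05)
        for state in (
            HealthState.NINETY_DAY_MORTALITY,
            HealthState.DEATH_OTHER_CAUSES,
            HealthState.DEATH_COLON_CANCER,
        ):
            row = build_transition_row(state, 7, REFERENCE_SUBGROUP, inputs, 1.0)
            expected = np.zeros(5)
            expected[state] = 1.0
            assert np.array_equal(row, expected)

    def test_zero_hazards_keep_cohort_in_diagnosis(self):
        row = build_transition_row(HealthState.DIAGNOSIS, 1, REFERENCE_SUBGROUP, flat_inputs(), 1.0)
        assert np.array_equal(row, np.array([1.0, 0.0, 0.0, 0.0, 0.0]))

    def test_rows_sum_to_one(self):
        inputs = flat_inputs(rec_rate=0.02, cc_rate=0.03, oc_hazard=0.001, q90=0.04)
        for state in HealthState:
            for cycle in (1, 2, 3, 4, 50):
                row = build_transition_row(state, cycle, REFERENCE_SUBGROUP, inputs, 0.73)
                assert row.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(row >= 0.0)

    def test_ninety_day_mortality_only_in_first_three_cycles(self):
        inputs = flat_inputs(q90=0.06)
        for cycle in (1, 2, 3):
            row = build_transition_row(HealthState.DIAGNOSIS, cycle, REFERENCE_SUBGROUP, inputs, 1.0)
            assert row[HealthState.NINETY_DAY_MORTALITY] > 0.0
        row = build_transition_row(HealthState.DIAGNOSIS, 4, REFERENCE_SUBGROUP, inputs, 1.0)
        assert row[HealthState.NINETY_DAY_MORTALITY] == 0.0

    def test_three_equal_monthly_hazards_reproduce_q90(self):
        q90 = 0.06
        inputs = flat_inputs(q90=q90)
        alive, dead = 1.0, 0.0
        for cycle in (1, 2, 3):
            row = build_transition_row(HealthState.DIAGNOSIS, cycle, REFERENCE_SUBGROUP, inputs, 1.0)
            dead += alive * row[HealthState.NINETY_DAY_MORTALITY]
            alive *= row[HealthState.DIAGNOSIS]
        assert dead == pytest.approx(q90, rel=1e-12)

    def test_competing_allocation_matches_numerical_integration(self):
        # constant hazards within the cycle: allocation share equals the
        # probability of the cause firing first, obtained by fine-grained
        # numerical integration of the competing-risk integral
        h_rec, h_oc = 0.02 * 0.73, 0.001
        inputs = flat_inputs(rec_rate=0.02, oc_hazard=h_oc)
        row = build_transition_row(HealthState.DIAGNOSIS, 5, REFERENCE_SUBGROUP, inputs, 0.73)
        t = np.linspace(0.0, 1.0, 200_001)
        total = h_rec + h_oc
        dens = total * np.exp(-total * t)
        p_rec_numeric = np.trapezoid(dens * h_rec / total, t)
        assert row[HealthState.RECURRENCE] == pytest.approx(p_rec_numeric, rel=1e-6)
        # and the exit mass before allocation is 1 - exp(-effective cumulative hazard)
        assert row[HealthState.RECURRENCE] + row[HealthState.DEATH_OTHER_CAUSES] == pytest.approx(
            1.0 - np.exp(-total), rel=1e-12
        )

    def test_recurrence_row_uses_months_since_recurrence(self):
        inputs = TransitionInputs(
            recurrence_model=SurvivalModel("exponential", {"rate": 0.0}),
            cc_death_model=SurvivalModel("weibull", {"shape": 0.7, "scale": 30.0}),
            other_cause_monthly_hazard={age: 0.0 for age in range(50, 111)},
            ninety_day_mortality={REFERENCE_SUBGROUP: 0.0},
        )
        early = build_transition_row(
            HealthState.RECURRENCE, 10, REFERENCE_SUBGROUP, inputs, 1.0, months_since_recurrence=1
        )
        late = build_transition_row(
            HealthState.RECURRENCE, 10, REFERENCE_SUBGROUP, inputs, 1.0, months_since_recurrence=48
        )
        # decreasing Weibull hazard: death probability shrinks with time since recurrence
        assert early[HealthState.DEATH_COLON_CANCER] > late[HealthState.DEATH_COLON_CANCER]

    def test_errors(self):
        inputs = flat_inputs()
        with pytest.raises(ValueError):
            build_transition_row(HealthState.DIAGNOSIS, 0, REFERENCE_SUBGROUP, inputs, 1.0)
        with pytest.raises(ValueError):
            build_transition_row(HealthState.DIAGNOSIS, 1, REFERENCE_SUBGROUP, inputs, -0.5)
        with pytest.raises(ValueError):
            build_transition_row("alive", 1, REFERENCE_SUBGROUP, inputs, 1.0)


class TestRunCohort:
    def test_zero_hazards_leave_occupancy_unchanged(self):
        trace = run_cohort(REFERENCE_SUBGROUP, flat_inputs(), 1.0, horizon=120)
        trace.validate()
        assert np.array_equal(
            trace.occupancy, np.tile(np.array([1.0, 0, 0, 0, 0]), (121, 1))
        )

    def test_constant_hazard_life_expectancy_matches_geometric_series(self):
        # monthly death probability p with deaths at the end of each cycle:
        # expected months lived = (1 - p) / p
        p = 0.05
        inputs = flat_inputs(oc_hazard=float(-np.log1p(-p)))
        trace = run_cohort(REFERENCE_SUBGROUP, inputs, 1.0, horizon=600)
        months_alive = trace.alive[1:].sum()
        assert months_alive == pytest.approx((1.0 - p) / p, abs=1e-10)

    def test_trace_invariants_on_synthetic_inputs(self, params):
        sub = Subgroup("ge10", "T4", "right", "75-80", "MSS_mutation")
        trace = run_cohort(sub, params.transition_inputs, 0.73, horizon=240)
        trace.validate(tol=1e-12)
        death_flows = sum(
            trace.event_flows[k].sum() for k in ("cc_death", "other_death", "ninety_day_death")
        )
        assert death_flows == pytest.approx(trace.occupancy[-1, [1, 2, 4]].sum(), abs=1e-12)
        # everyone in RECURRENCE at the end entered it at some point
        assert trace.cumulative_flow("recurrence") >= trace.occupancy[-1, 3]

    def test_cumulative_cc_deaths_monotone_in_effective_hr(self, params):
        sub = Subgroup("ge10", "T4", "left", "65-70", "MSS_no_mutation")
        deaths = [
            run_cohort(sub, params.transition_inputs, hr, horizon=300).cumulative_flow("cc_death")
            for hr in (0.5, 0.73, 1.0, 1.4)
        ]
        assert np.all(np.diff(deaths) > 0.0)

    def test_event_flows_reconcile_with_occupancy_differences(self, params):
        sub = Subgroup("lt10", "T4", "right", "60-65", "MSS_no_mutation")
        trace = run_cohort(sub, params.transition_inputs, 1.022, horizon=120)
        f = trace.event_flows
        for m in range(1, 121):
            for name, state in (
                ("cc_death", HealthState.DEATH_COLON_CANCER),
                ("other_death", HealthState.DEATH_OTHER_CAUSES),
                ("ninety_day_death", HealthState.NINETY_DAY_MORTALITY),
            ):
                diff = trace.occupancy[m, state] - trace.occupancy[m - 1, state]
                assert f[name][m] == pytest.approx(diff, abs=1e-12)

    def test_non_finite_hazard_is_named(self):
        inputs = TransitionInputs(
            recurrence_model=SurvivalModel("exponential", {"rate": float("nan")}),
            cc_death_model=SurvivalModel("exponential", {"rate": 0.0}),
            other_cause_monthly_hazard={age: 0.0 for age in range(50, 111)},
            ninety_day_mortality={REFERENCE_SUBGROUP: 0.0},
        )
        with pytest.raises(ValueError, match="recurrence"):
            run_cohort(REFERENCE_SUBGROUP, inputs, 1.0, horizon=12)

    def test_default_horizon_reaches_age_100(self):
        assert default_horizon([Subgroup("ge10", "T3", "left", "50-55", "MSI")]) == 570


class TestAggregation:
    def test_single_trace_identity(self, params):
        sub = Subgroup("ge10", "T4", "left", "70-75", "MSS_no_mutation")
        trace = run_cohort(sub, params.transition_inputs, 0.73, horizon=60)
        agg = aggregate_traces({sub: trace}, SubgroupWeights({sub: 1.0}))
        assert np.array_equal(agg.occupancy, trace.occupancy)

    def test_weighted_mean_elementwise(self, params):
        s1 = Subgroup("ge10", "T4", "left", "60-65", "MSS_no_mutation")
        s2 = Subgroup("lt10", "T4", "right", "80-85", "MSS_mutation")
        t1 = run_cohort(s1, params.transition_inputs, 0.73, horizon=60)
        t2 = run_cohort(s2, params.transition_inputs, 0.73, horizon=60)
        agg = aggregate_traces({s1: t1, s2: t2}, SubgroupWeights({s1: 0.3, s2: 0.7}))
        agg.validate()
        assert np.allclose(agg.occupancy, 0.3 * t1.occupancy + 0.7 * t2.occupancy, atol=1e-15)
        assert np.allclose(
            agg.event_flows["recurrence"],
            0.3 * t1.event_flows["recurrence"] + 0.7 * t2.event_flows["recurrence"],
            atol=1e-15,
        )

    def test_mismatched_horizons_rejected(self, params):
        s1 = Subgroup("ge10", "T4", "left", "60-65", "MSS_no_mutation")
        s2 = Subgroup("lt10", "T4", "right", "80-85", "MSS_mutation")
        t1 = run_cohort(s1, params.transition_inputs, 0.73, horizon=60)
        t2 = run_cohort(s2, params.transition_inputs, 0.73, horizon=61)
        with pytest.raises(ValueError, match="horizon"):
            aggregate_traces({s1: t1, s2: t2}, SubgroupWeights({s1: 0.5, s2: 0.5}))

    def test_batch_matches_single_runs(self, params):
        subs = [
            Subgroup("ge10", "T4", "left", "60-65", "MSS_no_mutation"),
            Subgroup("lt10", "T4", "right", "80-85", "MSS_mutation"),
        ]
        batch = run_cohorts(subs, params.transition_inputs, 0.73, horizon=60)
        for s, t in zip(subs, batch):
            single = run_cohort(s, params.transition_inputs, 0.73, horizon=60)
            assert np.array_equal(single.occupancy, t.occupancy)


class TestSurvivalModels:
    @pytest.mark.parametrize(
        "family, mparams",
        [
            ("exponential", {"rate": 0.01}),
            ("weibull", {"shape": 0.8, "scale": 300.0}),
            ("gompertz", {"rate": 0.001, "shape": 0.01}),
            ("loglogistic", {"shape": 1.4, "scale": 80.0}),
            ("lognormal", {"mu": 3.0, "sigma": 1.1}),
        ],
    )
    def test_cumulative_hazard_starts_at_zero_and_increases(self, family, mparams):
        model = SurvivalModel(family, mparams)
        t = np.arange(0.0, 241.0)
        ch = model.cum_hazard(t)
        assert ch[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(ch) >= 0.0)
        assert np.all(np.isfinite(ch))

    def test_proportional_hazards_multiplier(self):
        model = SurvivalModel(
            "weibull",
            {"shape": 0.8, "scale": 300.0},
            covariate_log_hrs={"t_stage=T4": 0.79, "age_per_bin": 0.03},
        )
        t3 = Subgroup("ge10", "T3", "left", "70-75", "MSS_no_mutation")
        t4 = Subgroup("ge10", "T4", "left", "70-75", "MSS_no_mutation")
        assert model.hazard_multiplier(t3) == pytest.approx(1.0)
        assert model.hazard_multiplier(t4) == pytest.approx(np.exp(0.79))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            SurvivalModel("gamma", {"rate": 0.1})
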