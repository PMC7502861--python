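import dataclasses

import numpy as np
import pytest

from adjuvance.cea import (
    DistributionSpecError,
    ceac_from_samples,
    compare,
    hr_grid_from_ci,
    oneway_utilities,
    run_psa,
    threshold_analysis,
)
from adjuvance.economics import StrategyOutcomes
from adjuvance.strategies import UtilityPeriod, UtilitySchedule


def printed_outcomes(rec, dead, ly_u, ly_d, q_u, q_d, c_u, c_d):
    return StrategyOutcomes(
        recurrences_per_1000=rec, cc_deaths_per_1000=dead,
        ly=ly_u, ly_discounted=ly_d, qaly=q_u, qaly_discounted=q_d,
        cost=c_u, cost_discounted=c_d,
    )


# published base-case endpoint table, used as frozen comparison inputs
CAPOX_6M = printed_outcomes(369, 316, 9.09, 8.05, 7.60, 6.71, 43_328, 41_257)
CAPOX_3M = printed_outcomes(369, 316, 9.09, 8.05, 7.60, 6.80, 39_640, 37_645)
FOLFOX_6M = printed_outcomes(369, 316, 9.09, 8.05, 7.60, 6.71, 49_301, 47_135)
FOLFOX_3M = printed_outcomes(457, 393, 8.36, 7.43, 6.99, 6.19, 46_632, 44_389)


class TestCompare:
    def test_capox_printed_table_arithmetic(self):
        c = compare(CAPOX_6M, CAPOX_3M, wtp=50_000)
        assert c.delta_cost == pytest.approx(-3_612.0)
        assert c.delta_qaly == pytest.approx(0.09, abs=1e-12)
        assert c.inmb == pytest.approx(0.09 * 50_000 + 3_612, abs=1e-6)  # 8112 from rounded inputs
        assert c.quadrant == "SE" and c.dominant
        assert c.icer < 0  # dominant comparison reported as a negative ratio

    def test_folfox_printed_table_arithmetic(self):
        c = compare(FOLFOX_6M, FOLFOX_3M, wtp=50_000)
        assert c.quadrant == "SW" and not c.dominant
        assert c.delta_qaly == pytest.approx(-0.52, abs=1e-12)
        assert c.icer == pytest.approx((-2_746) / (-0.52), rel=1e-9)
        assert c.inmb < 0

    def test_inmb_identity(self):
        for wtp in (0.0, 20_000.0, 50_000.0, 80_000.0):
            c = compare(CAPOX_6M, CAPOX_3M, wtp=wtp)
            assert c.inmb == c.delta_qaly * wtp - c.delta_cost

    def test_inmb_linear_and_increasing_in_wtp_when_qaly_gain(self):
        wtps = [0.0, 25_000.0, 50_000.0, 100_000.0]
        inmbs = [compare(CAPOX_6M, CAPOX_3M, wtp=w).inmb for w in wtps]
        slopes = np.diff(inmbs) / np.diff(wtps)
        assert np.allclose(slopes, slopes[0])
        assert np.all(np.diff(inmbs) > 0)
        inmbs_loss = [compare(FOLFOX_6M, FOLFOX_3M, wtp=w).inmb for w in wtps]
        assert np.all(np.diff(inmbs_loss) < 0)

    def test_zero_deltas_flag_icer_undefined(self):
        c = compare(CAPOX_6M, CAPOX_6M, wtp=50_000)
        assert c.icer is None
        assert c.inmb == 0.0


class TestThresholdAnalysis:
    def test_curve_passes_through_base_case(self, params, capox_runner):
        base = compare(capox_runner.outcomes(6), capox_runner.outcomes(3))
        curve = threshold_analysis(
            capox_runner.outcomes(6),
            [1.0, 1.05, 1.10],
            lambda hr: capox_runner.outcomes(3, hr_3v6_override=hr),
        )
        assert curve.delta_qaly[0] == pytest.approx(base.delta_qaly, abs=1e-10)
        assert curve.delta_cost[0] == pytest.approx(base.delta_cost, abs=1e-10)

    def test_capox_flips_inside_the_confidence_interval(self, params, capox_runner):
        grid = hr_grid_from_ci(params.treatment_effects["CAPOX"])
        assert grid[0] == pytest.approx(1.0) and grid[-1] == pytest.approx(1.17)
        curve = threshold_analysis(
            capox_runner.outcomes(6), grid, lambda hr: capox_runner.outcomes(3, hr_3v6_override=hr)
        )
        assert curve.first_hr_qaly_loss is not None
        assert 1.0 < curve.first_hr_qaly_loss <= 1.17
        assert curve.first_hr_not_cost_effective is not None
        assert curve.first_hr_qaly_loss <= curve.first_hr_not_cost_effective
        # losing effectiveness monotonically as the HR worsens
        assert np.all(np.diff(curve.delta_qaly) < 0)

    def test_folfox_never_gains_qalys_over_its_interval(self, params, folfox_runner):
        grid = hr_grid_from_ci(params.treatment_effects["FOLFOX"])
        assert grid[0] == pytest.approx(1.19) and grid[-1] == pytest.approx(1.40)
        curve = threshold_analysis(
            folfox_runner.outcomes(6), grid, lambda hr: folfox_runner.outcomes(3, hr_3v6_override=hr)
        )
        assert np.all(curve.delta_qaly < 0)

    def test_grid_validation(self, capox_runner):
        runner = lambda hr: capox_runner.outcomes(3, hr_3v6_override=hr)
        with pytest.raises(ValueError, match="empty"):
            threshold_analysis(capox_runner.outcomes(6), [], runner)
        with pytest.raises(ValueError, match="increasing"):
            threshold_analysis(capox_runner.outcomes(6), [1.1, 1.0], runner)


@pytest.fixture(scope="module")
def results(capox_runner):
    runner = lambda d, b: capox_runner.outcomes(d, utility_bound=b)
    return {
        bound: oneway_utilities(bound, runner) for bound in ("lower", "upper")
    } | {"point": {"6m": capox_runner.outcomes(6), "3m": capox_runner.outcomes(3)}}


class TestOnewayUtilities:
    def test_epidemiology_unchanged_by_utility_bounds(self, results):
        for arm in ("6m", "3m"):
            recs = {b: results[b][arm].recurrences_per_1000 for b in ("lower", "point", "upper")}
            deaths = {b: results[b][arm].cc_deaths_per_1000 for b in ("lower", "point", "upper")}
            assert len(set(recs.values())) == 1
            assert len(set(deaths.values())) == 1

    def test_qalys_ordered_by_bound(self, results):
        for arm in ("6m", "3m"):
            assert (
                results["lower"][arm].qaly_discounted
                <= results["point"][arm].qaly_discounted
                <= results["upper"][arm].qaly_discounted
            )

    def test_costs_unchanged_by_utility_bounds(self, results):
        for arm in ("6m", "3m"):
            assert results["lower"][arm].cost_discounted == results["upper"][arm].cost_discounted

    def test_invalid_bound_rejected(self, capox_runner):
        with pytest.raises(ValueError):
            oneway_utilities("middle", lambda d, b: capox_runner.outcomes(d, utility_bound=b))


class TestPSA:
    def test_bitwise_reproducibility_under_fixed_seed(self, params):
        a = run_psa(params, "CAPOX", n=25, seed=42)
        b = run_psa(params, "CAPOX", n=25, seed=42)
        assert np.array_equal(a.samples.cost_discounted, b.samples.cost_discounted)
        assert np.array_equal(a.samples.qaly_discounted, b.samples.qaly_discounted)
        for key in a.samples.draws:
            assert np.array_equal(a.samples.draws[key], b.samples.draws[key])
        c = run_psa(params, "CAPOX", n=25, seed=43)
        assert not np.array_equal(a.samples.cost_discounted, c.samples.cost_discounted)

    def test_degenerate_single_iteration_hits_the_base_case(self, params, capox_runner):
        res = run_psa(params, "CAPOX", n=1, seed=5, uncertainty_scale=0.0)
        o6, o3 = capox_runner.outcomes(6), capox_runner.outcomes(3)
        assert res.samples.cost_discounted[0, 0] == pytest.approx(o6.cost_discounted, rel=1e-9)
        assert res.samples.cost_discounted[0, 1] == pytest.approx(o3.cost_discounted, rel=1e-9)
        assert res.samples.qaly_discounted[0, 0] == pytest.approx(o6.qaly_discounted, rel=1e-9)
        assert res.samples.qaly_discounted[0, 1] == pytest.approx(o3.qaly_discounted, rel=1e-9)
        assert res.ce_plane["delta_qaly"][0] == pytest.approx(
            o3.qaly_discounted - o6.qaly_discounted, rel=1e-6
        )

    def test_ceac_probabilities_partition(self, params):
        res = run_psa(params, "FOLFOX", n=40, seed=9)
        probs = res.ceac.probabilities
        assert np.all((probs >= 0.0) & (probs <= 1.0))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_capox_three_month_arm_preferred_under_joint_uncertainty(self, params):
        res = run_psa(params, "CAPOX", n=200, seed=11)
        # pure cost minimisation: the cheaper 3-month arm essentially always wins
        assert res.ceac.probability("3m", 0.0) > 0.9
        # at the decision threshold the 3-month arm remains the likely winner
        assert res.ceac.probability("3m", 50_000.0) > 0.5

    def test_invalid_distribution_names_the_parameter(self, params):
        broken_schedule = UtilitySchedule(
            periods=(UtilityPeriod(1, None, 0.0, (0.0, 0.1), 0.9, (0.88, 0.92)),),
            recurrence_utility=0.45,
        )
        broken = dataclasses.replace(params, utility_schedule=broken_schedule)
        with pytest.raises(DistributionSpecError, match="utility_6m"):
            run_psa(broken, "CAPOX", n=2, seed=0)

    def test_ties_go_to_the_cheaper_strategy(self, params):
        res = run_psa(params, "CAPOX", n=3, seed=2, uncertainty_scale=0.0)
        ceac = ceac_from_samples(res.samples, np.array([0.0]))
        cheaper = int(np.argmin(res.samples.cost_discounted[0]))
        # at wtp 0 the winner is decided by cost alone
        assert ceac.probabilities[0, cheaper] == 1.0
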