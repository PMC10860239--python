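"""Decision tree, transition composition and Markov cohort engine."""

import dataclasses

import numpy as np
import pytest

from stroke_cea.cohort import (
    accumulate_outcomes,
    build_transition_matrix,
    drug_course_cost,
    run_arm,
    run_decision_tree,
    run_markov,
)
from stroke_cea.params import (
    CostInputs,
    DrugRegimen,
    HealthState,
    StateDistribution,
    UtilityInputs,
)
from stroke_cea.sensitivity import set_parameter

from helpers import microsimulate, random_distribution, random_valid_params


class TestDrugCost:
    def test_intervention_regimen(self, params):
        reg = params.arms["intervention"].regimen
        assert reg.daily_cost() == pytest.approx(198.0)
        assert drug_course_cost(reg) == pytest.approx(2772.0)

    def test_comparator_regimen(self, params):
        reg = params.arms["comparator"].regimen
        assert reg.daily_cost() == pytest.approx(233.52)
        assert drug_course_cost(reg) == pytest.approx(3269.28)

    def test_zero_duration(self):
        reg = DrugRegimen(unit_price=50.0, units_per_dose=2, doses_per_day=3,
                          duration_days=0)
        assert drug_course_cost(reg) == 0.0


class TestDecisionTree:
    def test_comparator_arm_90day_cost(self, params):
        arm = params.arms["comparator"]
        res = run_decision_tree(arm.name, arm.day90_distribution, arm.regimen,
                                params.costs, params.utilities, 90)
        assert res.cost_drug == pytest.approx(3269.28)
        assert res.cost_hospitalization == pytest.approx(14282.13, abs=0.01)
        assert res.cost_rehab == pytest.approx(2428.20, abs=0.01)
        assert res.cost == pytest.approx(19979.61, abs=0.01)

    def test_intervention_arm_90day_cost(self, params):
        arm = params.arms["intervention"]
        res = run_decision_tree(arm.name, arm.day90_distribution, arm.regimen,
                                params.costs, params.utilities, 90)
        assert res.cost == pytest.approx(19299.92, abs=0.01)

    def test_breakdown_sums_to_total(self, params):
        arm = params.arms["intervention"]
        res = run_decision_tree(arm.name, arm.day90_distribution, arm.regimen,
                                params.costs, params.utilities, 90)
        parts = (res.cost_drug + res.cost_hospitalization + res.cost_rehab
                 + res.cost_recurrence)
        assert parts == pytest.approx(res.cost, abs=1e-6)

    def test_zero_costs_and_forced_qaly(self, params):
        zero_costs = CostInputs(
            hospitalization={s: 0.0 for s in HealthState},
            annual_rehab_secondary_prevention={
                HealthState.MRS01: 0.0, HealthState.MRS25: 0.0},
            mean_length_of_stay_days=9.9,
        )
        free = DrugRegimen(unit_price=1e-12, units_per_dose=1, doses_per_day=1)
        util = UtilityInputs(
            utilities={HealthState.MRS01: 0.84, HealthState.MRS25: 0.47},
            recurrence_disutility=0.09,
        )
        res = run_decision_tree("x", StateDistribution(1.0, 0.0, 0.0), free,
                                zero_costs, util, 90)
        assert res.cost == pytest.approx(0.0, abs=1e-9)
        assert res.qaly == pytest.approx(0.84 * 90 / 365)

    def test_invalid_distribution_rejected(self, params):
        arm = params.arms["intervention"]
        with pytest.raises(ValueError, match="sums"):
            run_decision_tree(arm.name, StateDistribution(0.5, 0.3, 0.0),
                              arm.regimen, params.costs, params.utilities, 90)


class TestTransitionMatrix:
    def test_hand_composed_disabled_row(self, params):
        # origin mRS 2-5 at age 62, cycle 1: recurrence 5.9% with acute case
        # fatality 21.01%; survivors face 0.75% mortality times HR 2.5
        tm = build_transition_matrix(62, 1, params)
        row = tm.row(HealthState.MRS25)
        p_dead = 0.059 * 0.2101 + (1 - 0.059 * 0.2101) * (0.0075 * 2.5)
        assert row[2] == pytest.approx(p_dead, abs=1e-9)
        assert row[1] == pytest.approx(1 - p_dead, abs=1e-9)
        assert row[0] == 0.0

    def test_null_dynamics_identity_on_alive(self, params):
        p = set_parameter(params, "recurrence.annual_rates", (0.0,) * 9)
        p = set_parameter(p, "recurrence.terminal_rate", 0.0)
        bands = tuple(dataclasses.replace(b, rate=0.0)
                      for b in p.mortality.bands)
        p = set_parameter(p, "mortality.bands", bands)
        tm = build_transition_matrix(70, 3, p)
        assert np.allclose(tm.matrix, np.eye(3))

    def test_dead_row_absorbing(self, params):
        tm = build_transition_matrix(80, 5, params)
        assert np.array_equal(tm.row(HealthState.DEAD), [0.0, 0.0, 1.0])

    def test_rows_sum_to_one(self, params):
        for age, cycle in [(61, 1), (75, 15), (99, 39)]:
            tm = build_transition_matrix(age, cycle, params)
            assert np.allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_uncovered_age_rejected(self, params):
        with pytest.raises(ValueError, match="not covered"):
            build_transition_matrix(150, 1, params)


class TestMarkov:
    def test_dead_cohort_accrues_nothing(self, params):
        tr = run_markov(StateDistribution(0.0, 0.0, 1.0), params)
        assert tr.qaly_undiscounted.sum() == 0.0
        assert tr.cost_undiscounted.sum() == 0.0
        assert np.allclose(tr.occupancy_end[:, 2], 1.0)

    def test_null_dynamics_closed_form(self, params):
        # zero mortality/recurrence/discount, fill accrual on: QALYs are
        # u * (39 full cycles + 275/365 fill), exactly
        p = set_parameter(params, "recurrence.annual_rates", (0.0,) * 9)
        p = set_parameter(p, "recurrence.terminal_rate", 0.0)
        bands = tuple(dataclasses.replace(b, rate=0.0)
                      for b in p.mortality.bands)
        p = set_parameter(p, "mortality.bands", bands)
        p = set_parameter(p, "model.discount_rate", 0.0)
        p = set_parameter(p, "model.cycle0_fill", "accrue")
        tr = run_markov(StateDistribution(1.0, 0.0, 0.0), p)
        expected = 0.84 * (39 + 275 / 365)
        assert tr.qaly_undiscounted.sum() == pytest.approx(expected, abs=1e-9)

    def test_dead_occupancy_monotone_base_case(self, params):
        for role in ("intervention", "comparator"):
            tr = run_markov(params.arms[role].day90_distribution, params)
            dead = tr.occupancy_end[:, 2]
            assert np.all(np.diff(dead) >= -1e-12)

    def test_discounted_equals_undiscounted_times_factor(self, params):
        tr = run_markov(params.arms["intervention"].day90_distribution, params)
        t = np.arange(tr.n_cycles, dtype=float)
        factor = np.ones_like(t)
        factor[1:] = 1.05 ** (-t[1:])
        assert np.allclose(tr.qaly_discounted, tr.qaly_undiscounted * factor)
        assert np.allclose(tr.cost_discounted, tr.cost_undiscounted * factor)

    def test_horizon_beyond_mortality_table_rejected(self, params):
        p = set_parameter(params, "model.horizon_years", 80)
        with pytest.raises(ValueError, match="mortality"):
            run_markov(params.arms["intervention"].day90_distribution, p)

    def test_probability_conservation_and_dead_monotone_random(self, params):
        """Occupancy stays a probability distribution and death is absorbing
        across 1,000 random valid parameter sets."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            p = random_valid_params(rng, base=params)
            init = random_distribution(rng)
            tr = run_markov(init, p)
            sums = tr.occupancy_end.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)
            assert np.all(tr.occupancy_end >= -1e-12)
            assert np.all(np.diff(tr.occupancy_end[:, 2]) >= -1e-12)


class TestAccumulate:
    def test_totals_are_tree_plus_discounted_markov(self, arm_results):
        for res in arm_results.values():
            expected_cost = res.tree.cost + res.trace.cost_discounted.sum()
            expected_qaly = res.tree.qaly + res.trace.qaly_discounted.sum()
            assert res.total_cost == pytest.approx(expected_cost, abs=1e-6)
            assert res.total_qaly == pytest.approx(expected_qaly, abs=1e-6)

    def test_one_year_horizon_equals_tree(self, params):
        # with a single (fill) cycle and the calendar-only policy the Markov
        # stage adds nothing
        p = set_parameter(params, "model.horizon_years", 1)
        res = run_arm("intervention", p)
        assert res.total_cost == pytest.approx(res.tree.cost)
        assert res.total_qaly == pytest.approx(res.tree.qaly)

    def test_arm_label_mismatch_rejected(self, params):
        a = run_arm("intervention", params)
        b = run_arm("comparator", params)
        with pytest.raises(ValueError, match="arm mismatch"):
            accumulate_outcomes(a.tree, b.trace, params)

    def test_doubling_costs_doubles_total_cost_only(self, params):
        p = params
        for path in ("costs.hospitalization.MRS01", "costs.hospitalization.MRS25",
                     "costs.hospitalization.DEAD",
                     "costs.annual_rehab_secondary_prevention.MRS01",
                     "costs.annual_rehab_secondary_prevention.MRS25",
                     "arms.intervention.regimen.unit_price"):
            from stroke_cea.sensitivity import get_parameter

            p = set_parameter(p, path, 2.0 * get_parameter(params, path))
        base = run_arm("intervention", params)
        doubled = run_arm("intervention", p)
        assert doubled.total_cost == pytest.approx(2 * base.total_cost, rel=1e-12)
        assert doubled.total_qaly == pytest.approx(base.total_qaly, rel=1e-12)

    def test_discount_monotonicity(self, params):
        totals = []
        for r in (0.0, 0.03, 0.05, 0.08):
            p = set_parameter(params, "model.discount_rate", r)
            res = run_arm("intervention", p)
            totals.append((res.total_cost, res.total_qaly))
        costs, qalys = zip(*totals)
        assert all(a >= b for a, b in zip(costs, costs[1:]))
        assert all(a >= b for a, b in zip(qalys, qalys[1:]))

    def test_utility_monotonicity(self, params):
        base = run_arm("intervention", params).total_qaly
        p = set_parameter(params, "utilities.by_state.MRS01", 0.90)
        assert run_arm("intervention", p).total_qaly > base


def test_cohort_model_agrees_with_microsimulation(params):
    """A 1e5-patient Monte-Carlo simulation with the same transition rules
    reproduces the cohort model's undiscounted QALYs and costs within 3
    Monte-Carlo standard errors."""
    initial = params.arms["intervention"].day90_distribution
    tr = run_markov(initial, params)
    cohort_qaly = tr.qaly_undiscounted.sum()
    cohort_cost = tr.cost_undiscounted.sum()
    micro = microsimulate(initial, params, n_patients=100_000, seed=314)
    assert abs(micro["qaly_mean"] - cohort_qaly) < 3 * micro["qaly_se"]
    assert abs(micro["cost_mean"] - cohort_cost) < 3 * micro["cost_se"]
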