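"""One-way (tornado) and probabilistic sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

from stroke_cea.cea import incremental_analysis
from stroke_cea.cohort import run_arm
from stroke_cea.params import SensitivitySpec
from stroke_cea.sensitivity import (
    PSAResults,
    ceac,
    fit_psa_distribution,
    get_parameter,
    one_way_sensitivity,
    run_psa,
    sample_psa_parameters,
    set_parameter,
)


class TestParameterPaths:
    def test_get_and_set_round_trip(self, params):
        assert get_parameter(params, "utilities.by_state.MRS01") == 0.84
        p = set_parameter(params, "utilities.by_state.MRS01", 0.7)
        assert get_parameter(p, "utilities.by_state.MRS01") == 0.7
        assert get_parameter(params, "utilities.by_state.MRS01") == 0.84
        assert get_parameter(params, "model.discount_rate") == 0.05

    def test_unknown_path_rejected(self, params):
        with pytest.raises(KeyError, match="not found"):
            get_parameter(params, "costs.nonexistent.MRS01")
        with pytest.raises(KeyError, match="not found"):
            set_parameter(params, "utilities.by_state.MRS99", 0.5)


class TestOneWay:
    def test_zero_width_range_gives_zero_swing(self, params):
        spec = SensitivitySpec("utilities.by_state.MRS01", 0.84, 0.84, "beta")
        entries = one_way_sensitivity(params, [spec])
        assert entries[0].swing == pytest.approx(0.0, abs=1e-9)

    def test_outcome_at_base_equals_base_case(self, params):
        base = incremental_analysis(
            run_arm("intervention", params), run_arm("comparator", params)
        ).icer
        spec = SensitivitySpec("model.discount_rate", 0.05, 0.05, "fixed")
        entries = one_way_sensitivity(params, [spec])
        assert entries[0].outcome_low == pytest.approx(base)
        assert entries[0].outcome_high == pytest.approx(base)

    def test_drug_price_upper_bound_shifts_cost_by_course_formula(self, params):
        # unit price 33.00 -> 48.80 raises the 14-day course by
        # (48.80 - 33.00) * 6 units/day * 14 days = 1327.20 CNY
        base = incremental_analysis(
            run_arm("intervention", params), run_arm("comparator", params)
        )
        p_high = set_parameter(params, "arms.intervention.regimen.unit_price",
                               48.80)
        high = incremental_analysis(
            run_arm("intervention", p_high), run_arm("comparator", p_high)
        )
        assert high.delta_cost - base.delta_cost == pytest.approx(1327.20)
        assert high.delta_qaly == pytest.approx(base.delta_qaly)

    def test_entries_sorted_by_descending_swing(self, params):
        entries = one_way_sensitivity(params)
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)

    def test_unknown_parameter_path_rejected(self, params):
        spec = SensitivitySpec("no.such.parameter", 0.0, 1.0, "fixed")
        with pytest.raises(KeyError):
            one_way_sensitivity(params, [spec])


class TestDistributionFitting:
    def test_gamma_mean_matches_base(self):
        dist = fit_psa_distribution(12613.70, 12428.04, 12801.87, "gamma")
        assert dist.mean() == pytest.approx(12613.70, rel=1e-9)
        draws = dist.rvs(10_000, random_state=np.random.default_rng(0))
        assert draws.mean() == pytest.approx(12613.70, rel=0.01)
        assert (draws > 0).all()

    def test_beta_mean_and_support(self):
        dist = fit_psa_distribution(0.84, 0.66, 0.92, "beta")
        assert dist.mean() == pytest.approx(0.84, rel=1e-9)
        draws = dist.rvs(10_000, random_state=np.random.default_rng(1))
        assert ((draws > 0) & (draws < 1)).all()

    def test_lognormal_median_at_base(self):
        dist = fit_psa_distribution(2.5, 1.7, 3.8, "lognormal")
        assert dist.median() == pytest.approx(2.5, rel=1e-9)
        lo, hi = dist.ppf(0.025), dist.ppf(0.975)
        assert hi / lo == pytest.approx(3.8 / 1.7, rel=1e-6)

    def test_fixed_returns_none(self):
        assert fit_psa_distribution(33.0, 33.0, 48.8, "fixed") is None

    def test_infeasible_beta_names_parameter(self):
        with pytest.raises(ValueError, match="utilities.odd"):
            fit_psa_distribution(0.5, -3.0, 4.0, "beta", path="utilities.odd")

    def test_beta_requires_unit_interval_base(self):
        with pytest.raises(ValueError, match="beta"):
            fit_psa_distribution(1.2, 1.0, 1.4, "beta")


class TestPSA:
    def test_all_fixed_specs_reproduce_base(self, params):
        specs = [SensitivitySpec(s.path, s.low, s.high, "fixed")
                 for s in params.sensitivity]
        sampled, values = sample_psa_parameters(params, specs, rng=0)
        assert sampled == params
        res = run_psa(params, specs, n_iter=1, seed=0)
        base_i = run_arm("intervention", params)
        assert res.draws.loc[0, "cost_intervention"] == pytest.approx(
            base_i.total_cost
        )
        assert res.draws.loc[0, "qaly_intervention"] == pytest.approx(
            base_i.total_qaly
        )

    def test_same_seed_same_draw(self, params):
        a, va = sample_psa_parameters(params, rng=42)
        b, vb = sample_psa_parameters(params, rng=42)
        assert a == b and va == vb

    def test_fixed_families_never_vary(self, params):
        res = run_psa(params, n_iter=20, seed=5)
        assert (res.draws["arms.intervention.regimen.unit_price"] == 33.0).all()
        assert (res.draws["model.discount_rate"] == 0.05).all()
        # sampled families do vary
        assert res.draws["utilities.by_state.MRS01"].nunique() > 1

    def test_sampled_values_within_support(self, params):
        res = run_psa(params, n_iter=50, seed=9)
        assert ((res.draws["utilities.by_state.MRS01"] > 0)
                & (res.draws["utilities.by_state.MRS01"] < 1)).all()
        assert (res.draws["costs.hospitalization.MRS01"] > 0).all()
        assert (res.draws["transitions.death_hazard_ratio.MRS25"] > 0).all()

    def test_mean_incremental_qaly_near_base_case(self, params):
        # distributions are centred on the base values
        res = run_psa(params, n_iter=400, seed=11)
        base = incremental_analysis(
            run_arm("intervention", params), run_arm("comparator", params)
        )
        se = res.delta_qaly.std(ddof=1) / np.sqrt(res.n_iter)
        assert abs(res.delta_qaly.mean() - base.delta_qaly) < 3 * se


class TestCEAC:
    def _fake_results(self, dc, dq):
        n = len(dc)
        df = pd.DataFrame({
            "draw": range(n),
            "cost_intervention": dc, "cost_comparator": np.zeros(n),
            "qaly_intervention": dq, "qaly_comparator": np.zeros(n),
        })
        return PSAResults(draws=df, n_iter=n, seed=0)

    def test_all_dominant_draws_give_probability_one(self):
        res = self._fake_results(np.full(10, -5.0), np.full(10, 0.1))
        curve = ceac(res, [0.0, 1e4, 1e5])
        assert (curve.probability == 1.0).all()

    def test_half_split_at_threshold(self):
        # at lambda = 1000: NMB = 1000*0.1 - dc; dc = 50 -> +50, dc = 150 -> -50
        dc = np.array([50.0] * 5 + [150.0] * 5)
        res = self._fake_results(dc, np.full(10, 0.1))
        curve = ceac(res, [1000.0])
        assert curve.probability[0] == pytest.approx(0.5)

    def test_zero_threshold_counts_cost_saving_draws(self):
        dc = np.array([-1.0, -2.0, 3.0, 4.0])
        res = self._fake_results(dc, np.zeros(4))
        curve = ceac(res, [0.0])
        assert curve.probability[0] == pytest.approx(0.5)

    def test_monotone_when_all_gains_positive(self):
        rng = np.random.default_rng(3)
        res = self._fake_results(rng.normal(0, 100, 200),
                                 rng.uniform(0.01, 0.3, 200))
        curve = ceac(res, np.linspace(0, 3e5, 20))
        assert np.all(np.diff(curve.probability) >= -1e-12)

    def test_empty_grid_rejected(self):
        res = self._fake_results(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            ceac(res, [])
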