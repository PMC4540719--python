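import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coolcea.cohort_model import (
    discounted_duration,
    evaluate_all,
    evaluate_strategy,
    hospital_cost,
    lifetime_qaly,
    outcome_distribution,
    posthospital_cost,
)
from coolcea.parameters import Param
from coolcea.synthetic_params import branch_oracle

probs = st.floats(0.0, 1.0)

from coolcea.parameters import base_case_config as _base_case_config

_BASE = _base_case_config()


class TestOutcomeDistribution:
    def test_conventional_care_base_case(self, base_config):
        d = outcome_distribution(base_config.strategy("Conventional Care"))
        assert d.p_dead == 0.54
        assert d.p_good == pytest.approx(0.3174)
        assert d.p_poor == pytest.approx(0.1426)

    @pytest.mark.parametrize(
        "p_death, p_good_surv, expected",
        [(1.0, 0.5, (0.0, 0.0, 1.0)), (0.0, 1.0, (1.0, 0.0, 0.0))],
    )
    def test_degenerate_probabilities(self, base_config, p_death, p_good_surv, expected):
        s = base_config.strategies[0]
        d = outcome_distribution(s, p_death=p_death, p_good_given_survival=p_good_surv)
        assert (d.p_good, d.p_poor, d.p_dead) == expected

    def test_out_of_range_rejected(self, base_config):
        with pytest.raises(ValueError):
            outcome_distribution(base_config.strategies[0], p_death=1.5)

    @settings(derandomize=True, max_examples=200)
    @given(d=probs, g=probs)
    def test_probabilities_sum_to_one(self, d, g):
        out = outcome_distribution(
            _BASE.strategies[0], p_death=d, p_good_given_survival=g
        )
        assert out.p_good + out.p_poor + out.p_dead == pytest.approx(1.0)


class TestDiscountedDuration:
    @pytest.mark.parametrize(
        "years, rate, expected",
        [
            (1.0, 0.03, 1.0),
            (5.5, 0.0, 5.5),
            (2.0, 0.03, 1.0 + 1.0 / 1.03),
            (0.0, 0.03, 0.0),
        ],
    )
    def test_examples(self, years, rate, expected):
        assert discounted_duration(years, rate) == pytest.approx(expected, rel=1e-12)

    def test_matches_explicit_cycle_sum(self):
        for years in (0.3, 1.0, 2.5, 5.5, 10.0):
            for rate in (0.0, 0.03, 0.05, 0.2):
                expected = sum(
                    min(1.0, years - t) / (1 + rate) ** t
                    for t in range(int(np.ceil(years)))
                )
                assert discounted_duration(years, rate) == pytest.approx(
                    expected, rel=1e-12
                )

    @settings(derandomize=True, max_examples=200)
    @given(
        years=st.floats(0.0, 60.0),
        rate=st.floats(0.0, 0.5),
        bump=st.floats(0.01, 5.0),
    )
    def test_bounded_and_monotone(self, years, rate, bump):
        d = discounted_duration(years, rate)
        assert d <= years + 1e-9
        assert discounted_duration(years, 0.0) == years
        assert discounted_duration(years + bump, rate) >= d  # increasing in years
        if years > 1:
            assert discounted_duration(years, rate + 0.01) < d  # decreasing in rate

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discounted_duration(-1.0, 0.03)
        with pytest.raises(ValueError):
            discounted_duration(1.0, -0.03)

    def test_vectorized_over_years(self):
        ys = np.array([0.5, 1.0, 2.0, 5.5])
        out = discounted_duration(ys, 0.03)
        assert out.shape == ys.shape
        assert out[2] == pytest.approx(1.0 + 1.0 / 1.03)


class TestCostComponents:
    def test_conventional_survivor_hospital_cost(self, base_config):
        conv = base_config.strategy("Conventional Care")
        expected = 3 * 4973 + 18 * 2365  # 57,489
        assert hospital_cost(conv, base_config.shared, "good") == expected
        assert hospital_cost(conv, base_config.shared, "poor") == expected

    def test_blanket_nonsurvivor_hospital_cost(self, base_config):
        blanket = base_config.strategy("Cooling Blankets")
        assert hospital_cost(blanket, base_config.shared, "dead") == 6729 + 1197 + 4973

    def test_zero_daily_costs_leave_only_cooling_and_sedation(self, base_config):
        shared = dataclasses.replace(
            base_config.shared,
            c_icu_day=Param.fixed("c_icu_day", 0.0, "cost_usd"),
            c_floor_day=Param.fixed("c_floor_day", 0.0, "cost_usd"),
        )
        blanket = base_config.strategy("Cooling Blankets")
        for outcome in ("good", "poor", "dead"):
            assert hospital_cost(blanket, shared, outcome) == 6729 + 1197

    def test_posthospital_dead_is_zero(self, base_config):
        assert posthospital_cost(base_config.shared, "dead") == 0.0

    def test_posthospital_good_undiscounted(self, base_config):
        shared = dataclasses.replace(
            base_config.shared,
            discount_rate=Param.fixed("discount_rate", 0.0, "rate"),
        )
        # 35,868 + 1443*30 + (1305 + 22 + 175)*5.5
        assert posthospital_cost(shared, "good") == pytest.approx(87_419.0)

    def test_posthospital_poor_pure_ltc_undiscounted(self, base_config):
        shared = dataclasses.replace(
            base_config.shared,
            discount_rate=Param.fixed("discount_rate", 0.0, "rate"),
            f_vent=Param.fixed("f_vent", 0.0, "rate"),
        )
        # 257*365 + 2345 + 44 + 36,410 over a 1-year poor-outcome horizon
        assert posthospital_cost(shared, "poor") == pytest.approx(132_604.0)

    def test_lifetime_qaly(self, base_config):
        undiscounted = dataclasses.replace(
            base_config.shared,
            discount_rate=Param.fixed("discount_rate", 0.0, "rate"),
        )
        assert lifetime_qaly(undiscounted, "good") == pytest.approx(0.76 * 5.5)
        assert lifetime_qaly(base_config.shared, "dead") == 0.0
        # 1-year horizon: single cycle at t=0 is undiscounted at any rate
        assert lifetime_qaly(base_config.shared, "poor") == pytest.approx(0.35)


class TestEvaluate:
    def test_degenerate_all_dead_zero_cost(self, base_config):
        s = dataclasses.replace(
            base_config.strategy("Conventional Care"),
            p_death=Param.fixed("p_death", 1.0, "probability"),
            icu_days_nonsurvivor=Param.fixed("icu_days_nonsurvivor", 0.0, "duration_days"),
        )
        r = evaluate_strategy(s, base_config.shared)
        assert (r.expected_cost, r.expected_qaly) == (0.0, 0.0)

    def test_equals_branch_oracle_on_base_case(self, base_config):
        for s in base_config.strategies:
            mine = evaluate_strategy(s, base_config.shared)
            ref = branch_oracle(s, base_config.shared)
            assert mine.expected_cost == pytest.approx(ref.expected_cost, rel=1e-9)
            assert mine.expected_qaly == pytest.approx(ref.expected_qaly, rel=1e-9)

    @pytest.mark.parametrize(
        "param_id", ["shared/c_icu_day", "shared/icd_cost", "Cooling Blankets/cooling_cost"]
    )
    def test_cost_monotone_in_cost_parameters(self, base_config, param_id):
        lo = evaluate_all(base_config)
        hi = evaluate_all(
            base_config.with_value(param_id, base_config.get_param(param_id).base * 1.5)
        )
        for a, b in zip(lo, hi):
            assert b.expected_cost >= a.expected_cost
            assert b.expected_qaly == a.expected_qaly

    def test_qaly_monotone_in_utility(self, base_config):
        hi = evaluate_all(base_config.with_value("shared/u_good", 0.9))
        for a, b in zip(evaluate_all(base_config), hi):
            assert b.expected_qaly >= a.expected_qaly
            assert b.expected_cost == a.expected_cost

    def test_deterministic_bit_for_bit(self, base_config):
        assert evaluate_all(base_config) == evaluate_all(base_config)

    def test_evaluate_all_preserves_order(self, base_config):
        results = evaluate_all(base_config)
        assert [r.name for r in results] == [s.name for s in base_config.strategies]
        reversed_cfg = dataclasses.replace(
            base_config, strategies=base_config.strategies[::-1]
        )
        assert evaluate_all(reversed_cfg) == results[::-1]

    def test_conventional_costs_more_than_blankets(self, base_results):
        by_name = {r.name: r for r in base_results}
        assert (
            by_name["Conventional Care"].expected_cost
            > by_name["Cooling Blankets"].expected_cost
        )
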