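import math

import numpy as np
import pandas as pd
import pytest

from psmatlp import (
    DEFAULT_RULES,
    backward_eliminate,
    cox_fit,
    dichotomize,
    km_estimate,
    logrank_test,
    median_follow_up,
    simulate_survival_data,
    univariate_screen,
)

from _oracles import reverse_km_median


def _rule(name):
    return next(r for r in DEFAULT_RULES if r.name == name)


class TestDichotomize:
    @pytest.mark.parametrize(
        "rule,column,value,indicator",
        [
            ("alp_ge_220", "alp", 220.0, 1),  # cutoff itself is the risk level
            ("alp_ge_220", "alp", 219.9, 0),
            ("age_ge_65", "age", 64.9, 0),
            ("age_ge_65", "age", 65.0, 1),
            ("hemoglobin_lt_13", "hemoglobin", 13.0, 0),  # ">= 13" is reference
            ("hemoglobin_lt_13", "hemoglobin", 12.9, 1),
            ("activity_le_14", "cumulative_activity", 14.0, 1),
            ("ecog_ge_2", "ecog", 2, 1),
            ("tlp_ge_5710", "tlp_baseline", 5710.0, 1),
            ("psa_ge_145", "psa_baseline", 144.0, 0),
        ],
    )
    def test_cutoff_directions(self, rule, column, value, indicator):
        df = pd.DataFrame({column: [value]})
        out = dichotomize(df, [_rule(rule)])
        assert out[rule].iloc[0] == indicator

    def test_response_dichotomy_pr_vs_rest(self):
        df = pd.DataFrame({"molecular": ["PR", "SD", "PD"]})
        out = dichotomize(df, [_rule("tlp_response_sdpd")])
        assert out["tlp_response_sdpd"].tolist() == [0, 1, 1]

    def test_missing_covariate_raises(self):
        with pytest.raises(KeyError):
            dichotomize(pd.DataFrame({"age": [70]}), [_rule("alp_ge_220")])

    def test_every_record_assigned_to_one_level(self):
        df = simulate_survival_data(50, seed=0)
        df["alp"] = np.random.default_rng(0).uniform(30, 400, 50)
        out = dichotomize(df, [_rule("alp_ge_220")])
        assert set(out["alp_ge_220"].unique()) <= {0, 1}
        assert len(out) == 50


class TestKaplanMeier:
    def test_uncensored_odd_sample_median(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert km.median == pytest.approx(3.0)

    def test_all_censored_median_not_reached(self):
        km = km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
        assert math.isinf(km.median)
        assert not km.median_reached

    def test_curve_nonincreasing_from_one(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 200)
        e = rng.random(200) < 0.7
        km = km_estimate(t, e)
        assert km.survival[0] <= 1.0 + 1e-12
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_equals_empirical_survival_when_uncensored(self):
        t = np.array([2.0, 1.0, 4.0, 3.0, 5.0, 2.0])
        km = km_estimate(t, np.ones_like(t, dtype=bool))
        for time, s in zip(km.timeline, km.survival):
            assert s == pytest.approx((t > time).mean())

    def test_exponential_median_matches_closed_form(self):
        # rate ln2/18 per month -> median 18 months
        rng = np.random.default_rng(10)
        t = rng.exponential(18 / math.log(2), 4000)
        km = km_estimate(t, np.ones_like(t, dtype=bool))
        assert km.median == pytest.approx(18.0, abs=1.0)
        lo, hi = km.median_ci
        assert lo <= km.median <= hi

    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        t = np.array([3.0, 5.0, 7.0, 9.0, 11.0])
        times = np.concatenate([t, t])
        events = np.ones(10, dtype=bool)
        groups = np.array([0] * 5 + [1] * 5)
        res = logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])

    def test_type_one_error_near_nominal_under_null(self):
        """Permutation-style null: both arms drawn from the same exponential;
        the rejection rate at alpha=0.05 stays near nominal."""
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng(20_000 + s)
            t = rng.exponential(12.0, 60)
            g = np.array([0] * 30 + [1] * 30)
            res = logrank_test(t, np.ones(60, dtype=bool), g)
            rejections += res.p_value < 0.05
        assert 0.01 <= rejections / n_sim <= 0.10

    def test_power_under_strong_effect(self):
        rng = np.random.default_rng(8)
        t0 = rng.exponential(18.0, 500)
        t1 = rng.exponential(6.0, 500)  # hazard ratio 3
        times = np.concatenate([t0, t1])
        events = np.ones(1000, dtype=bool)
        groups = np.array([0] * 500 + [1] * 500)
        assert logrank_test(times, events, groups).p_value < 1e-3


class TestCox:
    def test_null_covariate_hr_near_one(self):
        df = simulate_survival_data(2000, seed=4, hazard_ratios={"noise": 1.0})
        res = cox_fit(df, ["noise"])
        assert 0.85 <= res.hr("noise") <= 1.18

    def test_parameter_recovery_improves_with_n(self):
        err = {}
        for n in (200, 2000):
            df = simulate_survival_data(n, seed=9, hazard_ratios={"x": 2.0})
            err[n] = abs(math.log(cox_fit(df, ["x"]).hr("x")) - math.log(2.0))
        assert err[2000] < 0.12  # tight at large n
        assert err[200] < 0.5  # loose at small n

    def test_duplicated_covariate_is_collinearity_error(self):
        df = simulate_survival_data(300, seed=5, hazard_ratios={"x": 2.0})
        df["x_copy"] = df["x"]
        with pytest.raises(ValueError):
            cox_fit(df, ["x", "x_copy"])

    def test_too_few_events_raises(self):
        df = simulate_survival_data(5, seed=6, hazard_ratios={"x": 2.0})
        df["event"] = [True] + [False] * 4
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])

    def test_wald_and_logrank_agree_on_two_group_data(self):
        df = simulate_survival_data(400, seed=7, hazard_ratios={"x": 2.5})
        cox_p = cox_fit(df, ["x"]).p("x")
        lr_p = logrank_test(df["os_months"], df["event"], df["x"]).p_value
        assert (cox_p < 0.05) == (lr_p < 0.05)
        assert math.isclose(math.log10(cox_p), math.log10(lr_p), abs_tol=2.0)


class TestBackwardElimination:
    def test_single_significant_candidate_retained(self):
        df = simulate_survival_data(500, seed=11, hazard_ratios={"x": 3.0})
        res = backward_eliminate(df, ["x"])
        assert res.retained == ["x"]
        assert res.trace == []

    def test_noise_removed_and_trace_records_steps(self):
        df = simulate_survival_data(1000, seed=12, hazard_ratios={"x": 3.0, "noise": 1.0})
        res = backward_eliminate(df, ["x", "noise"])
        assert "x" in res.retained
        assert "noise" not in res.retained
        assert [s.removed for s in res.trace] == ["noise"]
        # the full entry model is reported alongside the pruned one
        assert set(res.full_model.variables) == {"x", "noise"}

    def test_all_noise_candidates_can_empty_the_model(self):
        found_empty = False
        for s in range(10):
            df = simulate_survival_data(300, seed=100 + s,
                                        hazard_ratios={"a": 1.0, "b": 1.0})
            res = backward_eliminate(df, ["a", "b"])
            assert len(res.trace) == len(res.full_model.variables) - len(res.retained)
            if res.final_model is None:
                found_empty = True
        assert found_empty

    def test_empty_candidate_set_raises(self):
        df = simulate_survival_data(100, seed=13)
        with pytest.raises(ValueError):
            backward_eliminate(df, [])


class TestScreenAndFollowUp:
    def test_univariate_screen_selects_true_effect(self):
        df = simulate_survival_data(800, seed=14, hazard_ratios={"x": 3.0, "noise": 1.0})
        screen = univariate_screen(df, ["x", "noise"])
        assert bool(screen.loc["x", "selected"])
        assert screen.loc["x", "p"] < 0.001

    def test_all_censored_at_ten_months(self):
        assert median_follow_up([10.0] * 6, [0] * 6) == pytest.approx(10.0)

    def test_reverse_km_matches_hand_computation_on_toy_data(self):
        times = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
        events = [1, 0, 1, 0, 1, 0]
        assert median_follow_up(times, events) == pytest.approx(
            reverse_km_median(times, events)
        )
        assert median_follow_up(times, events) == pytest.approx(12.0)

    def test_all_dead_cohort_uses_flipped_events(self):
        # no censoring events at all -> follow-up median never reached
        assert math.isinf(median_follow_up([3.0, 6.0, 9.0], [1, 1, 1]))
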