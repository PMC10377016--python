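import numpy as np
import pandas as pd
import pytest

import trnachip as t
from trnachip.survival import _cox_newton_breslow


def make_table(times, events, unit="years"):
    frame = pd.DataFrame(
        {"time": times, "event": events},
        index=pd.Index([f"pt{i}" for i in range(len(times))], name="patient_id"),
    )
    return t.SurvivalTable(frame=frame, time_unit=unit)


class TestKaplanMeier:
    def test_no_events_curve_is_constant_one(self):
        curve = t.km_curve([3.0, 5.0, 7.0], [0, 0, 0])
        assert curve.at(0.0) == 1.0
        assert curve.at(100.0) == 1.0
        assert curve.n_events == 0

    def test_three_subjects_all_events(self):
        curve = t.km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve.at(1.0) == pytest.approx(2 / 3)
        assert curve.at(2.0) == pytest.approx(1 / 3)
        assert curve.at(3.0) == pytest.approx(0.0)

    def test_five_subject_mixed_censoring_product_limit_table(self):
        # times 1, 2+, 3, 4, 5+ : steps 4/5, 4/5*2/3, then *1/2
        curve = t.km_curve([1.0, 2.0, 3.0, 4.0, 5.0], [1, 0, 1, 1, 0])
        assert curve.at(1.0) == pytest.approx(0.8)
        assert curve.at(3.0) == pytest.approx(0.8 * 2 / 3)
        assert curve.at(4.5) == pytest.approx(0.8 * 2 / 3 * 0.5)
        assert curve.at(10.0) == pytest.approx(0.8 * 2 / 3 * 0.5)

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(2.0, size=50)
        curve = t.km_curve(times, np.ones(50, dtype=int))
        for q in (0.1, 0.5, 0.9):
            cut = np.quantile(times, q)
            assert curve.at(cut) == pytest.approx(np.mean(times > cut))

    def test_requires_subjects(self):
        with pytest.raises(ValueError, match="at least one"):
            t.km_curve([], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 0, 1, 1]
        stat, p = t.logrank_test(times, events, times, events)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_death_hypergeometric_hand_case(self):
        # One death at t=1 in group A with one subject at risk per group:
        # E = 0.5, Var = 0.25, chi-square = 1, p = 0.3173.
        stat, p = t.logrank_test([1.0], [1], [2.0], [0])
        assert stat == pytest.approx(1.0)
        assert p == pytest.approx(0.31731, abs=1e-4)

    def test_no_events_is_undefined(self):
        stat, p = t.logrank_test([1.0, 2.0], [0, 0], [3.0], [0])
        assert np.isnan(stat) and np.isnan(p)


class TestQuartileComparison:
    def _cohort(self, n=100, effect=0.0, seed=1):
        rng = np.random.default_rng(seed)
        expr = pd.Series(rng.normal(size=n),
                         index=[f"pt{i}" for i in range(n)], name="u")
        hazard = 0.3 * np.exp(effect * expr.to_numpy())
        times = rng.exponential(1.0 / hazard)
        surv = make_table(np.maximum(times, 1e-3), np.ones(n, dtype=int))
        return expr, surv

    def test_quartile_membership_matches_sort_based_oracle(self):
        expr, surv = self._cohort(n=80)
        res = t.quartile_km_compare(expr, surv)
        ranked = expr.sort_values()
        q1, q3 = np.quantile(expr, [0.25, 0.75])
        assert res.n_low == (expr <= q1).sum()
        assert res.n_high == (expr >= q3).sum()
        assert set(ranked.index[: res.n_low]) == set(
            expr[expr <= q1].index
        )

    def test_strong_effect_gives_small_p_null_gives_large(self):
        expr, surv = self._cohort(n=200, effect=1.5, seed=2)
        strong = t.quartile_km_compare(expr, surv)
        assert strong.p < 1e-4
        expr0, surv0 = self._cohort(n=200, effect=0.0, seed=3)
        null = t.quartile_km_compare(expr0, surv0)
        assert null.p > 0.01

    def test_degenerate_expression_rejected(self):
        surv = make_table(np.arange(1.0, 11.0), np.ones(10, dtype=int))
        expr = pd.Series(1.0, index=surv.frame.index)
        with pytest.raises(ValueError, match="no quartile separation"):
            t.quartile_km_compare(expr, surv)

    def test_horizon_before_first_event_gives_missing_p(self):
        surv = make_table(np.arange(6.0, 16.0), np.ones(10, dtype=int))
        rng = np.random.default_rng(4)
        expr = pd.Series(rng.normal(size=10), index=surv.frame.index)
        res = t.quartile_km_compare(expr, surv, horizon_years=5.0)
        assert np.isnan(res.p)
        assert res.curve_low.n_events == 0

    def test_minimum_cohort_size_enforced(self):
        surv = make_table([1.0, 2.0, 3.0], [1, 1, 1])
        expr = pd.Series([1.0, 2.0, 3.0], index=surv.frame.index)
        with pytest.raises(ValueError, match=">=8"):
            t.quartile_km_compare(expr, surv)


class TestCoxFit:
    def _cohort(self, n=400, beta=0.6, seed=5):
        rng = np.random.default_rng(seed)
        expr = pd.Series(rng.normal(size=n),
                         index=[f"pt{i}" for i in range(n)], name="u")
        hazard = 0.3 * np.exp(beta * expr.to_numpy())
        times = np.maximum(rng.exponential(1.0 / hazard), 1e-4)
        return expr, make_table(times, np.ones(n, dtype=int))

    def test_null_expression_gives_hr_near_one(self):
        rng = np.random.default_rng(6)
        expr, surv = self._cohort(beta=0.0, seed=6)
        res = t.cox_fit(expr, surv)
        assert res.hr == pytest.approx(1.0, abs=0.15)
        assert res.ci_low < res.hr < res.ci_high

    def test_recovers_simulated_coefficient(self):
        expr, surv = self._cohort(n=600, beta=0.6, seed=7)
        res = t.cox_fit(expr, surv)
        assert res.beta == pytest.approx(0.6, abs=0.12)

    def test_beta_scales_inversely_with_expression_units(self):
        expr, surv = self._cohort(n=200, seed=8)
        raw = t.cox_fit(expr, surv, standardize=False)
        scaled = t.cox_fit(expr * 2.0, surv, standardize=False)
        assert scaled.beta == pytest.approx(raw.beta / 2.0, rel=1e-4)
        # per-SD HR is scale-free
        z1 = t.cox_fit(expr, surv, standardize=True)
        z2 = t.cox_fit(expr * 7.5, surv, standardize=True)
        assert z2.beta == pytest.approx(z1.beta, rel=1e-8)

    def test_efron_and_breslow_agree_without_ties(self):
        expr, surv = self._cohort(n=150, seed=9)
        efron = t.cox_fit(expr, surv, ties="efron")
        breslow = t.cox_fit(expr, surv, ties="breslow")
        assert breslow.beta == pytest.approx(efron.beta, abs=2e-4)
        assert breslow.se == pytest.approx(efron.se, rel=1e-3)

    def test_breslow_solver_against_two_group_exponential_limit(self):
        # two groups with exponential hazards differing by rate ratio r:
        # the Cox coefficient converges to log r
        rng = np.random.default_rng(10)
        n = 2000
        x = np.repeat([0.0, 1.0], n // 2)
        rates = np.where(x == 1, 0.6, 0.2)
        times = rng.exponential(1.0 / rates)
        beta, se, converged = _cox_newton_breslow(
            x, times, np.ones(n, dtype=int)
        )
        assert converged
        assert beta == pytest.approx(np.log(3.0), abs=3 * se)

    def test_logrank_agrees_with_cox_on_two_group_data(self):
        rng = np.random.default_rng(11)
        n = 500
        x = np.repeat([0.0, 1.0], n // 2)
        rates = np.where(x == 1, 0.45, 0.3)
        times = rng.exponential(1.0 / rates)
        events = np.ones(n, dtype=int)
        stat, p_lr = t.logrank_test(times[x == 0], events[x == 0],
                                    times[x == 1], events[x == 1])
        surv = make_table(times, events)
        expr = pd.Series(x, index=surv.frame.index)
        res = t.cox_fit(expr, surv, standardize=False)
        assert p_lr == pytest.approx(res.p, abs=0.02)

    def test_monotone_likelihood_flagged_not_raised(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.ones(6, dtype=int)
        surv = make_table(times, events)
        expr = pd.Series(np.arange(6.0)[::-1], index=surv.frame.index)
        res = t.cox_fit(expr, surv)
        assert not res.converged

    def test_requires_events_and_variation(self):
        surv = make_table([1.0, 2.0], [0, 0])
        expr = pd.Series([1.0, 2.0], index=surv.frame.index)
        with pytest.raises(ValueError, match="event"):
            t.cox_fit(expr, surv)
        surv2 = make_table([1.0, 2.0], [1, 1])
        const = pd.Series([3.0, 3.0], index=surv2.frame.index)
        with pytest.raises(ValueError, match="vary"):
            t.cox_fit(const, surv2)


class TestScreen:
    def test_effect_unit_ranks_at_hr_extreme(self):
        rng = np.random.default_rng(12)
        n_units, n_pat = 12, 300
        expr = pd.DataFrame(
            rng.normal(size=(n_units, n_pat)),
            index=[f"tRNA-Ala-AGC-1-{i + 1}" for i in range(n_units)],
            columns=[f"pt{i}" for i in range(n_pat)],
        )
        cfg = t.SyntheticConfig(seed=12, effect_unit="tRNA-Ala-AGC-1-3",
                                beta_true=0.8, n_patients=n_pat)
        surv, _ = t.simulate_survival_cohort(cfg, expr)
        table = t.screen(expr, surv)
        assert table.index[0] == "tRNA-Ala-AGC-1-3"
        assert bool(table.loc["tRNA-Ala-AGC-1-3", "significant"])

    def test_screen_is_ordered_by_hazard_ratio(self):
        rng = np.random.default_rng(13)
        expr = pd.DataFrame(rng.normal(size=(5, 120)),
                            index=[f"u{i}" for i in range(5)],
                            columns=[f"pt{i}" for i in range(120)])
        times = np.maximum(rng.exponential(3.0, 120), 1e-3)
        surv = make_table(times, (rng.random(120) < 0.7).astype(int))
        surv.frame.index = expr.columns
        table = t.screen(expr, surv)
        hrs = table["hr"].to_numpy()
        assert (np.diff(hrs) <= 1e-12).all()
        assert {"p", "q", "ci_low", "ci_high", "n_events"} <= set(table.columns)

    def test_degenerate_unit_recorded_and_screen_continues(self):
        rng = np.random.default_rng(14)
        expr = pd.DataFrame(
            {"pt%d" % i: [1.0, rng.normal()] for i in range(60)},
            index=["constant", "ok"],
        )
        times = np.maximum(rng.exponential(3.0, 60), 1e-3)
        surv = make_table(times, np.ones(60, dtype=int))
        surv.frame.index = expr.columns
        table = t.screen(expr, surv)
        assert table.loc["constant", "error"] is not None
        assert np.isfinite(table.loc["ok", "beta"])

    def test_empty_unit_list_gives_empty_output(self):
        surv = make_table([1.0, 2.0], [1, 1])
        expr = pd.DataFrame(columns=surv.frame.index)
        table = t.screen(expr, surv)
        assert len(table) == 0


class TestSurvivalTable:
    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            make_table([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError, match="event"):
            make_table([1.0, 2.0], [1, 2])

    def test_tsv_round_trip(self, tmp_path):
        table = make_table([1.0, 2.0, 3.0], [1, 0, 1], unit="days")
        path = tmp_path / "surv.tsv"
        table.to_tsv(path)
        back = t.SurvivalTable.read_tsv(path, time_unit="days")
        pd.testing.assert_frame_equal(back.frame, table.frame)

    def test_horizon_conversion(self):
        table = make_table([1.0], [1], unit="days")
        assert table.horizon_in_unit(5.0) == pytest.approx(5 * 365.25)
        months = make_table([1.0], [1], unit="months")
        assert months.horizon_in_unit(5.0) == pytest.approx(60.0)
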