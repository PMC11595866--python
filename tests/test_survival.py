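import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from lungmorph import (
    CohortSpec,
    cox_fit,
    dichotomize_at_median,
    harrell_c,
    kaplan_meier,
    logrank_test,
    schoenfeld_test,
    simulate_cohort,
)

from conftest import (
    concordance_oracle,
    cox_partial_loglik,
    km_oracle,
    logrank_oracle,
)


def _frame(times, events, **cols):
    return pd.DataFrame({"time_months": times, "event": events, **cols})


class TestDichotomize:
    def test_175_distinct_values_split_88_87(self):
        vals = np.random.default_rng(0).permutation(175).astype(float)
        labels = dichotomize_at_median(vals)
        assert (labels == "upper").sum() == 88
        assert (labels == "lower").sum() == 87

    def test_even_n(self):
        labels = dichotomize_at_median([1, 2, 3, 4])
        np.testing.assert_array_equal(labels, ["lower", "lower", "upper", "upper"])

    def test_all_ties_go_upper(self):
        assert np.all(dichotomize_at_median([5, 5, 5]) == "upper")

    @pytest.mark.parametrize("n", [3, 10, 175, 176])
    def test_partition_property(self, n):
        vals = np.random.default_rng(n).permutation(n).astype(float)
        labels = dichotomize_at_median(vals)
        n_up = (labels == "upper").sum()
        n_lo = (labels == "lower").sum()
        assert n_up + n_lo == n
        if n % 2 == 1:
            assert n_up == n_lo + 1


class TestKaplanMeier:
    def test_no_events_survival_is_one(self):
        df = _frame([3.0, 5.0, 7.0], [False, False, False])
        km = kaplan_meier(df, "event", ["a"] * 3)
        assert np.all(km.strata["a"]["survival"] == 1.0)

    def test_single_event_first_factor(self):
        n = 8
        df = _frame([2.0] + [10.0] * (n - 1), [True] + [False] * (n - 1))
        km = kaplan_meier(df, "event", ["a"] * n)
        surv = km.strata["a"]
        at_t = surv.loc[surv["time"] >= 2.0, "survival"].iloc[0]
        assert at_t == pytest.approx(1 - 1 / n)

    def test_matches_hand_worked_product_limit(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True, False, True, True, False, True]
        df = _frame(times, events)
        km = kaplan_meier(df, "event", ["a"] * 6)
        curve = km.strata["a"].set_index("time")["survival"]
        for t, s in km_oracle(times, events):
            assert curve.loc[t] == pytest.approx(s, rel=1e-12)

    def test_survival_non_increasing(self):
        df = simulate_cohort(CohortSpec(n_subjects=120, seed=5))
        strata = dichotomize_at_median(df["index_mst"])
        km = kaplan_meier(df, "event_grade2", strata)
        for curve in km.strata.values():
            s = curve["survival"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12)
            assert s[0] == pytest.approx(1.0)

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 40)
        df = _frame(times, [True] * 40)
        km = kaplan_meier(df, "event", ["a"] * 40)
        curve = km.strata["a"]
        for t, s in zip(curve["time"][1:], curve["survival"][1:]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_negative_times_rejected(self):
        df = _frame([-1.0, 2.0], [True, True])
        with pytest.raises(ValueError, match="negative"):
            kaplan_meier(df, "event", ["a", "a"])


class TestLogrank:
    def test_identical_strata_give_null(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [True, True, False, True]
        df = _frame(times * 2, events * 2)
        chi2, p = logrank_test(df, "event", ["a"] * 4 + ["b"] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_risk_table_oracle(self):
        rng = np.random.default_rng(4)
        n = 30
        times = rng.permutation(n) + 1.0
        events = rng.random(n) < 0.7
        group = np.where(rng.random(n) < 0.5, "a", "b")
        df = _frame(times, events)
        chi2, _ = logrank_test(df, "event", group)
        assert chi2 == pytest.approx(logrank_oracle(times, events, group), rel=1e-9)


class TestCoxFit:
    def test_beta_matches_partial_likelihood_scan(self):
        """1-D maximizer of the partial likelihood on a 10-subject fixture."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0], bool)
        x = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0], float)
        df = _frame(times, events, x=x)
        fit = cox_fit(df, "event", ["x"])
        res = minimize_scalar(
            lambda b: -cox_partial_loglik(b, times, events, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coefficients["x"][0] == pytest.approx(res.x, abs=1e-4)

    def test_score_test_equals_logrank_chi2(self):
        """Cox score test at beta=0 for a binary covariate is the log-rank."""
        rng = np.random.default_rng(7)
        n = 40
        times = rng.permutation(n) + rng.random(n) * 0.01  # distinct times
        events = rng.random(n) < 0.7
        x = (rng.random(n) < 0.5).astype(float)
        u_score = 0.0
        info = 0.0
        for i in np.where(events)[0]:
            at_risk = times >= times[i]
            u_score += x[i] - x[at_risk].mean()
            info += x[at_risk].mean() - x[at_risk].mean() ** 2
        chi2_score = u_score**2 / info
        df = _frame(times, events)
        chi2_lr, _ = logrank_test(df, "event", np.where(x > 0, "a", "b"))
        assert chi2_lr == pytest.approx(chi2_score, abs=1e-6)

    def test_null_coverage_of_wald_ci(self):
        """Permuted labels (true HR 1): 95% CI covers 0 in ~95% of seeds."""
        cover = 0
        n_seeds = 200
        for s in range(n_seeds):
            df = simulate_cohort(
                CohortSpec(n_subjects=120, hr_low_stratum=1.0, seed=20_000 + s)
            )
            rng = np.random.default_rng(s)
            df["stratum"] = rng.permutation(
                dichotomize_at_median(df["index_mst"])
            )
            fit = cox_fit(df, "event_grade2", ["stratum"])
            beta, se = fit.coefficients["stratum_lower"]
            if beta - 1.96 * se <= 0 <= beta + 1.96 * se:
                cover += 1
        assert 0.90 <= cover / n_seeds <= 0.99

    def test_hazard_ratio_is_exp_beta_with_wald_ci(self):
        df = simulate_cohort(CohortSpec(n_subjects=175, seed=8))
        df["stratum"] = dichotomize_at_median(df["index_mst"])
        fit = cox_fit(df, "event_grade2", ["stratum"])
        beta, se = fit.coefficients["stratum_lower"]
        hr, lo, hi, _ = fit.hazard_ratios["stratum_lower"]
        assert hr == pytest.approx(np.exp(beta), rel=1e-12)
        assert lo == pytest.approx(np.exp(beta - 1.96 * se), rel=1e-12)
        assert hi == pytest.approx(np.exp(beta + 1.96 * se), rel=1e-12)

    def test_c_index_orientation_follows_beta_sign(self):
        df = simulate_cohort(CohortSpec(n_subjects=175, hr_low_stratum=3.0, seed=9))
        df["stratum"] = dichotomize_at_median(df["index_mst"])
        fit = cox_fit(df, "event_grade2", ["stratum"])
        assert fit.coefficients["stratum_lower"][0] > 0
        assert fit.c_index > 0.5

    def test_no_events_rejected(self):
        df = _frame([1.0, 2.0], [False, False], x=[0.0, 1.0])
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, "event", ["x"])

    def test_categorical_reference_levels(self):
        df = simulate_cohort(CohortSpec(n_subjects=175, seed=10))
        df["stratum"] = dichotomize_at_median(df["index_mst"])
        fit = cox_fit(df, "event_grade2", ["stratum", "sex", "lung_disease"])
        terms = set(fit.coefficients)
        # reference levels upper / female / none are absorbed, not estimated
        assert terms == {
            "stratum_lower", "sex_male", "lung_disease_COPD", "lung_disease_IPF",
        }


class TestSchoenfeld:
    def test_residuals_sum_to_zero(self):
        df = simulate_cohort(CohortSpec(n_subjects=150, seed=12))
        df["stratum"] = dichotomize_at_median(df["index_mst"])
        fit = cox_fit(df, "event_grade2", ["stratum"])
        resid = fit.model.compute_residuals(fit.design, "schoenfeld")
        assert abs(float(resid.sum().iloc[0])) <= 1e-8

    def test_reports_per_term_chi2_and_p(self):
        df = simulate_cohort(CohortSpec(n_subjects=150, seed=13))
        df["stratum"] = dichotomize_at_median(df["index_mst"])
        fit = cox_fit(df, "event_grade2", ["stratum", "age"])
        ph = schoenfeld_test(fit)
        assert set(ph) == {"stratum_lower", "age"}
        for chi2, p in ph.values():
            assert chi2 >= 0 and 0 <= p <= 1

    def test_detects_time_crossing_hazards(self):
        """Effect reversing sign mid-follow-up is flagged in >=80% of seeds."""
        def crossing_cohort(seed, n=150, beta=1.5, h0=0.08, t_cross=8.0,
                            horizon=40.0):
            rng = np.random.default_rng(seed)
            x = rng.random(n) < 0.5
            h1 = np.where(x, h0 * np.exp(beta), h0)
            h2 = np.where(x, h0 * np.exp(-beta), h0)
            u = rng.standard_exponential(n)
            t = np.where(u < h1 * t_cross, u / h1,
                         t_cross + (u - h1 * t_cross) / h2)
            ev = t <= horizon
            return _frame(np.minimum(t, horizon), ev, x=x.astype(float))

        n_seeds = 200
        rejections = 0
        for s in range(n_seeds):
            fit = cox_fit(crossing_cohort(s), "event", ["x"])
            rejections += fit.ph_test["x"][1] < 0.05
        assert rejections / n_seeds >= 0.80


class TestHarrellC:
    def test_perfect_ordering(self):
        times = np.arange(1.0, 11.0)
        risk = -times  # highest risk dies first
        assert harrell_c(times, risk, np.ones(10, bool)) == 1.0

    def test_reversed_ordering(self):
        times = np.arange(1.0, 11.0)
        assert harrell_c(times, times, np.ones(10, bool)) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        times = rng.exponential(10, n).round(3)
        risk = rng.normal(size=n)
        events = rng.random(n) < 0.6
        if not events.any():
            events[0] = True
        got = harrell_c(times, risk, events)
        assert got == concordance_oracle(times, risk, events)
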