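"""Kaplan-Meier, log-rank and Cox: hand examples, lifelines oracles, selection rules."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from immunocyt import (
    build_score_frame,
    cox_fit,
    generate_cohort,
    km_fit,
    log_rank,
    null_config,
    two_factor_stratification,
    univariate_screen_then_multivariate,
)
from immunocyt.simulate import default_config
from immunocyt.errors import DegenerateInputError, SingularityError
from immunocyt.survival import NOT_REACHED
from tests.conftest import two_group_exponential


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10.0, size=60)
        fit = km_fit(times, np.ones_like(times, dtype=int))
        for t in fit.event_times:
            empirical = (times > t).mean()
            assert fit.survival_at(t) == pytest.approx(empirical, abs=1e-12)

    def test_deaths_at_1_2_3_step_down_thirds(self):
        fit = km_fit([1, 2, 3], [1, 1, 1])
        assert np.allclose(fit.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        """Deaths at 1 and 2, censoring at 3: S(1)=2/3, S(3)=1/3."""
        fit = km_fit([1, 2, 3], [1, 1, 0])
        assert fit.survival_at(1) == pytest.approx(2 / 3)
        assert fit.survival_at(3) == pytest.approx(1 / 3)

    def test_all_censored_curve_stays_at_one(self):
        fit = km_fit([5, 8, 2], [0, 0, 0])
        assert fit.survival_at(100.0) == 1.0
        assert fit.median_survival == NOT_REACHED
        assert fit.median_ci95 == (NOT_REACHED, NOT_REACHED)

    def test_against_lifelines_with_censoring(self):
        rng = np.random.default_rng(5)
        times = np.round(rng.exponential(20.0, size=120), 0) + 1
        events = rng.integers(0, 2, size=120)
        fit = km_fit(times, events)
        ref = KaplanMeierFitter().fit(times, events)
        for t, s in zip(fit.event_times, fit.survival):
            assert s == pytest.approx(ref.predict(t), abs=1e-10)

    def test_median_and_ci_cross_half(self):
        time, event, _ = two_group_exponential(3, n=300, hr=1.0)
        fit = km_fit(time, event)
        ref = KaplanMeierFitter().fit(time, event)
        if fit.median_survival != NOT_REACHED:
            assert fit.median_survival == pytest.approx(ref.median_survival_time_)
            lo, hi = fit.median_ci95
            if lo != NOT_REACHED and hi != NOT_REACHED:
                assert lo <= fit.median_survival <= hi

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            km_fit([], [])

    def test_restricted_mean_of_flat_curve(self):
        fit = km_fit([10.0], [0])
        assert fit.restricted_mean(25.0) == pytest.approx(25.0)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        time, event, _ = two_group_exponential(1, n=50, hr=1.0)
        t2 = np.concatenate([time, time])
        e2 = np.concatenate([event, event])
        g = np.array([0] * 50 + [1] * 50)
        res = log_rank(t2, e2, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            log_rank([1, 2], [1, 1], ["a", "a"])

    def test_matches_lifelines_two_group(self):
        time, event, X = two_group_exponential(9, n=400, hr=0.6)
        res = log_rank(time, event, X["group"].to_numpy())
        g = X["group"].to_numpy()
        ref = logrank_test(time[g == 0], time[g == 1], event[g == 0], event[g == 1])
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_matches_lifelines_four_group(self):
        rng = np.random.default_rng(13)
        time = rng.exponential(20, 200)
        event = rng.integers(0, 2, 200)
        group = rng.integers(0, 4, 200)
        res = log_rank(time, event, group)
        ref = multivariate_logrank_test(time, group, event)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.extras["df"] == 3

    def test_df1_equals_squared_standardized_oe(self):
        """Binary log-rank equals the square of the standardized O-E statistic."""
        time, event, X = two_group_exponential(21, n=150, hr=0.7)
        g = X["group"].to_numpy()
        res = log_rank(time, event, g)
        # independent O-E accumulation
        o_minus_e, var = 0.0, 0.0
        for t in np.unique(time[event == 1]):
            at = time >= t
            n, n1 = at.sum(), (at & (g == 1)).sum()
            dead = at & (time == t) & (event == 1)
            d, d1 = dead.sum(), (dead & (g == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
        assert res.statistic == pytest.approx(o_minus_e**2 / var, rel=1e-9)


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        time, event, X = two_group_exponential(2, n=2000, hr=0.5)
        res = cox_fit(time, event, X)
        assert res.converged
        assert 0.4 < res.hazard_ratio("group") < 0.62
        assert res.score_norm < 1e-6

    def test_matches_lifelines_with_heavy_ties(self):
        rng = np.random.default_rng(8)
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        time = np.round(rng.exponential(20 * np.exp(-0.4 * x1)), 0) + 1
        event = rng.integers(0, 2, n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        res = cox_fit(time, event, X)
        df = X.assign(T=time, E=event)
        ref = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(res.summary["coef"], ref.params_.to_numpy(), atol=1e-7)
        assert np.allclose(res.summary["se"], ref.standard_errors_.to_numpy(), atol=1e-7)

    def test_efron_and_breslow_agree_without_ties(self):
        time, event, X = two_group_exponential(5, n=500, hr=0.7)
        efron = cox_fit(time, event, X, ties="efron")
        breslow = cox_fit(time, event, X, ties="breslow")
        assert np.allclose(
            efron.summary["coef"], breslow.summary["coef"], atol=1e-10
        )

    def test_duplicated_covariate_is_singular(self):
        time, event, X = two_group_exponential(6, n=100)
        X = X.assign(group_copy=X["group"])
        with pytest.raises(SingularityError):
            cox_fit(time, event, X)

    def test_constant_covariate_named(self):
        time, event, X = two_group_exponential(6, n=100)
        X = X.assign(flat=1.0)
        with pytest.raises(SingularityError, match="flat"):
            cox_fit(time, event, X)

    def test_complete_separation_flagged_not_silent(self):
        # the covariate perfectly orders event times: monotone likelihood
        n = 40
        time = np.arange(1, n + 1, dtype=float)
        event = np.ones(n, dtype=int)
        X = pd.DataFrame({"x": -np.arange(n, dtype=float)})
        res = cox_fit(time, event, X)
        assert not res.converged

    def test_wald_ci_orders_and_exponentiates(self):
        time, event, X = two_group_exponential(7, n=800, hr=0.6)
        res = cox_fit(time, event, X)
        row = res.summary.loc["group"]
        assert row["ci_low"] < row["hr"] < row["ci_high"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))


@pytest.fixture(scope="module")
def cohort_and_frame():
    cohort = generate_cohort(default_config(n_samples=400, seed=19))
    frame = build_score_frame(cohort.expression)
    return cohort, frame


class TestScreening:

    def test_alpha_one_selects_every_candidate(self, cohort_and_frame):
        cohort, frame = cohort_and_frame
        table, multi = univariate_screen_then_multivariate(
            cohort.clinical, frame, "OS", alpha=1.0
        )
        assert table["selected"].all()
        assert multi is not None
        assert "cyt_high" in multi.summary.index

    def test_factor_with_one_significant_level_enters_whole(self, cohort_and_frame):
        """Any-level selection: the full factor joins the multivariate model."""
        cohort, frame = cohort_and_frame
        table, multi = univariate_screen_then_multivariate(
            cohort.clinical, frame, "OS", alpha=0.05
        )
        for cand in table.loc[table["selected"], "candidate"].unique():
            cols = table.loc[table["candidate"] == cand, "covariate"]
            if multi is not None:
                present = [c for c in cols if c in multi.summary.index]
                assert len(present) == len([c for c in cols])

    def test_no_selection_returns_empty_model_with_warning(self, caplog):
        cohort = generate_cohort(null_config(120, 5))
        frame = build_score_frame(cohort.expression)
        with caplog.at_level("WARNING"):
            table, multi = univariate_screen_then_multivariate(
                cohort.clinical, frame, "OS", alpha=1e-12
            )
        assert multi is None
        assert not table.empty

    def test_protective_cyt_selected_under_planted_hazard(self):
        """With only the survival effect planted, the CYT group drives the model."""
        hits = 0
        for seed in range(10):
            cfg = default_config(
                n_samples=400, seed=seed,
                apobec_effect=0.0, checkpoint_effect=0.0,
                scna_heat_slope=0.0, repertoire_heat_slope=0.0, til_logit_slope=0.0,
            )
            cohort = generate_cohort(cfg)
            frame = build_score_frame(cohort.expression)
            _, multi = univariate_screen_then_multivariate(cohort.clinical, frame, "OS")
            if multi is not None and "cyt_high" in multi.summary.index:
                hits += 1
        assert hits >= 9


class TestTwoFactorStratification:
    def test_four_groups_and_protective_ordering(self, hot_cohort):
        frame = build_score_frame(hot_cohort.expression)
        frame.data["checkpoint_index_group"] = (
            frame.data["checkpoint_index"]
            > frame.data["checkpoint_index"].median()
        ).map({True: "high", False: "low"})
        strat = two_factor_stratification(
            hot_cohort.clinical, frame, "cyt", "checkpoint_index", endpoint="OS"
        )
        assert set(strat.fits) == {"high/high", "high/low", "low/high", "low/low"}
        assert strat.logrank.extras["df"] == 3

    def test_identical_factors_collapse_to_two_groups(self, hot_cohort):
        frame = build_score_frame(hot_cohort.expression, dichotomize=("cyt",))
        frame.data["mirror_group"] = frame.data["cyt_group"]
        strat = two_factor_stratification(
            hot_cohort.clinical, frame, "cyt", "mirror", endpoint="OS"
        )
        assert set(strat.fits) == {"high/high", "low/low"}
        assert strat.logrank.extras["df"] == 1
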