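import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from methrisk.errors import ConvergenceError, ValidationError
from methrisk.survival import (
    CoxFit,
    _pl_derivatives,
    cox_fit,
    hazard_ratio,
    km_estimate,
    likelihood_ratio_test,
    logrank_test,
)


def grid_search_beta(times, events, x, lo=-10.0, hi=10.0, step=1e-4):
    """Brute-force 1-D maximizer of the Breslow partial log-likelihood,
    written directly from its definition (independent of the package)."""
    order = np.argsort(np.asarray(times, float), kind="stable")
    ts = np.asarray(times, float)[order]
    es = np.asarray(events)[order]
    xs = np.asarray(x, float)[order]
    betas = np.arange(lo, hi + step, step)
    ll = np.zeros_like(betas)
    for i in np.flatnonzero(es == 1):
        risk = ts >= ts[i]  # includes ties
        ll += betas * xs[i] - np.log(
            np.exp(np.outer(betas, xs[risk])).sum(axis=1)
        )
    k = int(np.argmax(ll))
    return float(betas[k]), float(ll[k])


def surv_frame(times, events, **covs):
    return pd.DataFrame({"time": times, "event": events, **covs})


class TestKaplanMeier:
    def test_product_limit_arithmetic(self):
        km = km_estimate(surv_frame([1, 2, 3], [1, 1, 0]))
        assert km.loc[km.time == 1, "survival"].item() == pytest.approx(2 / 3)
        assert km.loc[km.time == 2, "survival"].item() == pytest.approx(1 / 3)
        assert km.loc[km.time == 3, "survival"].item() == pytest.approx(1 / 3)

    def test_no_events_gives_flat_curve(self):
        km = km_estimate(surv_frame([1, 2, 5], [0, 0, 0]))
        assert (km.survival == 1.0).all()

    def test_single_subject_event(self):
        km = km_estimate(surv_frame([5.0], [1]))
        assert km.survival.iloc[-1] == 0.0

    def test_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 40)
        km = km_estimate(surv_frame(t, np.ones(40, int)))
        for _, row in km.iterrows():
            assert row.survival == pytest.approx((t > row.time).mean())


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        g = surv_frame([1, 2, 3, 4], [1, 0, 1, 1])
        res = logrank_test([g, g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_three_identical_groups_df(self):
        g = surv_frame([1, 2, 3], [1, 1, 0])
        res = logrank_test([g, g.copy(), g.copy()])
        assert res.df == 2
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_ordered_groups_give_positive_statistic(self):
        a = surv_frame([1, 2, 3], [1, 1, 1])
        b = surv_frame([10, 11, 12], [1, 1, 1])
        assert logrank_test([a, b]).statistic > 0

    def test_zero_events_rejected(self):
        g = surv_frame([1, 2], [0, 0])
        with pytest.raises(ValidationError):
            logrank_test([g, g.copy()])

    def test_matches_lifelines(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(5, 120)
        e = rng.binomial(1, 0.7, 120)
        g = rng.integers(0, 3, 120)
        groups = [surv_frame(t[g == j], e[g == j]) for j in range(3)]
        mine = logrank_test(groups)
        ref = multivariate_logrank_test(t, g, e)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_two_group_statistic_equals_squared_cox_score(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(5, 80)
        e = rng.binomial(1, 0.8, 80)
        z = rng.binomial(1, 0.5, 80).astype(float)
        groups = [
            surv_frame(t[z == 0], e[z == 0]),
            surv_frame(t[z == 1], e[z == 1]),
        ]
        lr = logrank_test(groups)
        order = np.argsort(t, kind="stable")
        _, grad, hess = _pl_derivatives(
            t[order], e[order], z[order][:, None], np.zeros(1), "breslow"
        )
        score_stat = float(grad @ np.linalg.solve(-hess, grad))
        assert lr.statistic == pytest.approx(score_stat, abs=1e-6)


class TestCoxFit:
    def test_matches_grid_search_oracle_on_four_subjects(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 0.0]
        beta_star, ll_star = grid_search_beta(t, e, x)
        fit = cox_fit(surv_frame(t, e, x=x), ["x"])
        assert fit.converged
        assert fit.coef[0] == pytest.approx(beta_star, abs=1e-4)
        assert fit.loglik == pytest.approx(ll_star, abs=1e-6)
        hr, *_ = hazard_ratio(fit, "x")
        assert hr == pytest.approx(np.exp(beta_star), abs=1e-3)

    @pytest.mark.parametrize("tie_method", ["breslow", "efron"])
    def test_matches_lifelines(self, tie_method):
        rng = np.random.default_rng(2)
        n = 250
        x = rng.standard_normal(n)
        z = rng.binomial(1, 0.4, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(0.6 * x - 0.4 * z)))
        c = rng.exponential(12, n)
        df = surv_frame(np.minimum(t, c), (t <= c).astype(int), x=x, z=z)
        fit = cox_fit(df, ["x", "z"], tie_method=tie_method)
        # continuous times: Breslow and Efron coincide; lifelines uses Efron
        ref = CoxPHFitter().fit(df, "time", "event")
        assert fit.coef == pytest.approx(ref.params_.values, abs=1e-5)
        assert fit.se == pytest.approx(ref.standard_errors_.values, abs=1e-5)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_efron_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(3)
        n = 150
        x = rng.standard_normal(n)
        t = np.ceil(rng.exponential(1 / (0.2 * np.exp(0.5 * x))))  # heavy ties
        e = rng.binomial(1, 0.8, n)
        e[0] = 1
        df = surv_frame(t, e, x=x)
        fit = cox_fit(df, ["x"], tie_method="efron")
        ref = CoxPHFitter().fit(df, "time", "event")
        assert fit.coef[0] == pytest.approx(ref.params_.iloc[0], abs=1e-5)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_covariate_rescaling_halves_coefficient(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.standard_normal(n)
        t = rng.exponential(1 / np.exp(0.5 * x))
        df = surv_frame(t, np.ones(n, int), x=x, x2=2 * x)
        f1 = cox_fit(df, ["x"])
        f2 = cox_fit(df[["time", "event", "x2"]], ["x2"])
        assert f2.coef[0] == pytest.approx(f1.coef[0] / 2, rel=1e-6)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-8)

    def test_null_covariate_gives_small_coefficient(self):
        rng = np.random.default_rng(5)
        n = 200
        df = surv_frame(
            rng.exponential(5, n), rng.binomial(1, 0.8, n), x=rng.standard_normal(n)
        )
        fit = cox_fit(df, ["x"])
        assert abs(fit.coef[0]) < 3 * fit.se[0] + 0.3

    def test_perfect_separation_flagged_non_converged(self):
        # covariate perfectly orders the event times: monotone likelihood
        t = np.arange(1.0, 21.0)
        x = np.arange(20.0)
        fit = cox_fit(surv_frame(t, np.ones(20, int), x=x), ["x"])
        assert not fit.converged
        with pytest.raises(ConvergenceError):
            hazard_ratio(fit, "x")

    def test_rejects_constant_covariate_and_no_events(self):
        df = surv_frame([1, 2, 3], [1, 1, 0], x=[1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(df, ["x"])
        df2 = surv_frame([1, 2, 3], [0, 0, 0], x=[1.0, 2.0, 3.0])
        with pytest.raises(ValidationError, match="zero events"):
            cox_fit(df2, ["x"])


class TestHazardRatio:
    def test_closed_form_ci(self):
        fit = CoxFit(
            coef=np.array([0.0]), cov=np.array([[0.25]]), loglik=0.0, loglik_null=0.0,
            covariate_names=["x"], n=10, n_events=5, converged=True,
            tie_method="breslow", n_iter=1,
        )
        hr, lo, hi, p = hazard_ratio(fit, "x")
        assert hr == pytest.approx(1.0)
        assert lo == pytest.approx(0.375, abs=5e-4)
        assert hi == pytest.approx(2.664, abs=5e-4)
        assert p == pytest.approx(1.0)

    def test_ci_collapses_as_se_vanishes(self):
        fit = CoxFit(
            coef=np.array([np.log(2.0)]), cov=np.array([[1e-18]]), loglik=0.0,
            loglik_null=0.0, covariate_names=["x"], n=10, n_events=5,
            converged=True, tie_method="breslow", n_iter=1,
        )
        hr, lo, hi, _ = hazard_ratio(fit, "x")
        assert (hr, lo, hi) == pytest.approx((2.0, 2.0, 2.0), rel=1e-6)


class TestLikelihoodRatio:
    def test_fit_against_itself(self):
        rng = np.random.default_rng(6)
        df = surv_frame(
            rng.exponential(3, 50), np.ones(50, int), x=rng.standard_normal(50)
        )
        fit = cox_fit(df, ["x"])
        res = likelihood_ratio_test(fit, fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_duplicated_covariate_adds_nothing(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(60)
        df = surv_frame(
            rng.exponential(1 / np.exp(0.5 * x)), np.ones(60, int), x=x, xc=x.copy()
        )
        f1 = cox_fit(df, ["x"])
        f2 = cox_fit(df, ["x", "xc"])
        res = likelihood_ratio_test(f1, f2)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_detects_strong_effect(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            n = 500
            z = rng.binomial(1, 0.5, n).astype(float)
            x = rng.standard_normal(n)
            t = rng.exponential(1 / (0.2 * np.exp(1.0 * z)))
            df = surv_frame(t, np.ones(n, int), x=x, z=z)
            f0 = cox_fit(df, ["x"])
            f1 = cox_fit(df, ["x", "z"])
            hits += likelihood_ratio_test(f0, f1).p_value < 1e-6
        assert hits == 5

    def test_nesting_violation_rejected(self):
        rng = np.random.default_rng(8)
        z = rng.binomial(1, 0.5, 100).astype(float)
        x = rng.standard_normal(100)
        t = rng.exponential(1 / np.exp(z))
        df = surv_frame(t, np.ones(100, int), x=x, z=z)
        full = cox_fit(df, ["x", "z"])
        null = cox_fit(df, ["z"])
        with pytest.raises(ValidationError):
            likelihood_ratio_test(full, null)  # arguments swapped
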