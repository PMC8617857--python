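import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import ztnb_grid_mle_loglik
from pgxlos.ztnb_model import (
    RankDeficientDesignError,
    ZtnbFit,
    fit_ztnb,
    rate_ratio_table,
    solve_mu_for_truncated_mean,
    ztnb_log_pmf,
    ztnb_rvs,
    ztnb_truncated_mean,
)


class TestLogPmf:
    def test_normalization(self):
        y = np.arange(1, 10_001)
        total = np.exp(ztnb_log_pmf(y, 3.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_poisson_limit_truncated_mean(self):
        # theta -> inf reduces NB2 to Poisson; truncated mean mu/(1-e^-mu)
        got = ztnb_truncated_mean(1.0, 1e8)
        assert got == pytest.approx(1.0 / (1.0 - np.exp(-1.0)), rel=1e-6)

    def test_poisson_limit_pmf(self):
        y = np.arange(1, 30)
        ours = np.exp(ztnb_log_pmf(y, 2.5, 1e9))
        poisson = stats.poisson.pmf(y, 2.5) / (1 - stats.poisson.pmf(0, 2.5))
        np.testing.assert_allclose(ours, poisson, rtol=1e-5)

    def test_matches_extended_precision_evaluation(self):
        """Direct log-gamma arithmetic at 50 digits via sympy."""
        import sympy

        mu_, theta_ = sympy.Rational(3), sympy.Rational(2)
        ratio = theta_ / (theta_ + mu_)
        ys = np.arange(1, 51)
        expected = []
        for y in ys:
            expr = (
                sympy.loggamma(y + theta_) - sympy.loggamma(theta_)
                - sympy.loggamma(y + 1)
                + theta_ * sympy.log(ratio)
                + y * sympy.log(mu_ / (theta_ + mu_))
                - sympy.log(1 - ratio**theta_)
            )
            expected.append(float(sympy.N(expr, 50)))
        np.testing.assert_allclose(
            ztnb_log_pmf(ys, 3.0, 2.0), expected, atol=1e-12)

    def test_large_arguments_stay_finite(self):
        vals = ztnb_log_pmf(np.array([1, 500, 5000]), 200.0, 1e7)
        assert np.all(np.isfinite(vals))

    @pytest.mark.parametrize("y, mu, theta", [
        (0, 3.0, 2.0), (1.5, 3.0, 2.0), (1, -1.0, 2.0), (1, 3.0, 0.0),
    ])
    def test_domain_violations(self, y, mu, theta):
        with pytest.raises(ValueError):
            ztnb_log_pmf(y, mu, theta)


class TestTruncatedMeanInversion:
    def test_round_trip(self):
        mu = solve_mu_for_truncated_mean(12.5, 1.5)
        assert ztnb_truncated_mean(mu, 1.5) == pytest.approx(12.5, abs=1e-8)

    def test_rejects_impossible_target(self):
        with pytest.raises(ValueError):
            solve_mu_for_truncated_mean(0.9, 1.5)


class TestSampler:
    def test_support_and_mean(self, rng):
        y = ztnb_rvs(np.full(200_000, 3.0), 2.0, rng)
        assert y.min() >= 1
        assert y.mean() == pytest.approx(ztnb_truncated_mean(3.0, 2.0),
                                         rel=0.01)


class TestFit:
    def _simulate(self, n, seed, beta=(2.3, 0.15, -0.1), theta=1.5):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({
            "a": rng.integers(0, 2, n).astype(float),
            "b": rng.integers(0, 2, n).astype(float),
        })
        mu = np.exp(beta[0] + beta[1] * X["a"] + beta[2] * X["b"]).to_numpy()
        y = ztnb_rvs(mu, theta, rng)
        return X, y, np.asarray(beta), theta

    def test_parameter_recovery_within_3se(self):
        X, y, beta, theta = self._simulate(20_000, seed=5)
        fit = fit_ztnb(X, y)
        assert fit.converged
        err = (fit.beta.to_numpy() - beta) / fit.se.to_numpy()
        assert np.all(np.abs(err) < 3.0)
        assert fit.theta == pytest.approx(theta, rel=0.1)

    def test_agrees_with_statsmodels_truncated_nb(self):
        """Independent cross-check against the reference zero-truncated
        NB2 implementation."""
        import statsmodels.api as sm
        from statsmodels.discrete.truncated_model import (
            TruncatedLFNegativeBinomialP,
        )

        X, y, _, _ = self._simulate(5_000, seed=11)
        fit = fit_ztnb(X, y)
        ref = TruncatedLFNegativeBinomialP(
            y, sm.add_constant(X.to_numpy()), truncation=0).fit(disp=0)
        np.testing.assert_allclose(fit.beta.to_numpy(), ref.params[:3],
                                   atol=2e-4)
        np.testing.assert_allclose(fit.theta, 1.0 / ref.params[3], rtol=2e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=2e-3)
        np.testing.assert_allclose(fit.se.to_numpy(), ref.bse[:3], rtol=2e-2)

    def test_intercept_only_matches_grid_search_mle(self):
        rng = np.random.default_rng(3)
        y = ztnb_rvs(np.full(300, np.exp(1.0)), 2.0, rng)
        fit = fit_ztnb(pd.DataFrame(index=range(300)), y)
        assert fit.converged
        assert fit.loglik == pytest.approx(ztnb_grid_mle_loglik(y), abs=1e-4)

    def test_loglik_dominates_generating_parameters(self):
        for seed in (1, 2, 3):
            X, y, beta, theta = self._simulate(2_000, seed=seed)
            fit = fit_ztnb(X, y)
            eta = beta[0] + X.to_numpy() @ beta[1:]
            ll_true = float(np.sum(ztnb_log_pmf(y, np.exp(eta), theta)))
            assert fit.loglik >= ll_true - 1e-8

    def test_truncation_aware_fit_not_inflated(self):
        """An untruncated NB fitted to zero-truncated data overestimates
        the mean; the ZTNB fit does not."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n, b0, theta = 20_000, 0.3, 1.0  # low mean -> heavy truncation
        y = ztnb_rvs(np.full(n, np.exp(b0)), theta, rng)
        fit = fit_ztnb(pd.DataFrame(index=range(n)), y)
        nb = sm.NegativeBinomial(y, np.ones((n, 1))).fit(disp=0)
        assert nb.params[0] > b0 + 0.2       # naive fit inflated
        assert abs(fit.beta["intercept"] - b0) < 0.05

    def test_consistency_error_shrinks_with_n(self):
        X2, y2, beta, _ = self._simulate(2_000, seed=21)
        fit2 = fit_ztnb(X2, y2)
        X20, y20, _, _ = self._simulate(20_000, seed=22)
        fit20 = fit_ztnb(X20, y20)
        for fit in (fit2, fit20):
            err = (fit.beta.to_numpy() - beta) / fit.se.to_numpy()
            assert np.all(np.abs(err) < 3.0)
        assert np.all(fit20.se.to_numpy() < fit2.se.to_numpy())

    def test_wald_ci_coverage_for_null_covariate(self):
        """A covariate with no true effect: its 95% CI covers RR=1 at
        close to the nominal rate."""
        covered = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 800
            X = pd.DataFrame({
                "signal": rng.integers(0, 2, n).astype(float),
                "null": rng.integers(0, 2, n).astype(float),
            })
            mu = np.exp(2.3 + 0.15 * X["signal"]).to_numpy()
            y = ztnb_rvs(mu, 1.5, rng)
            fit = fit_ztnb(X, y)
            rr = fit.rate_ratios.loc["null"]
            if rr["ci_low"] <= 1.0 <= rr["ci_high"]:
                covered += 1
        assert covered >= 93

    def test_duplicate_column_rejected_with_names(self):
        X, y, _, _ = self._simulate(500, seed=4)
        X["a_twice"] = 2.0 * X["a"]
        with pytest.raises(RankDeficientDesignError) as err:
            fit_ztnb(X, y)
        assert set(err.value.columns) & {"a", "a_twice"}

    def test_rejects_zeros_and_non_integers(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(ValueError):
            fit_ztnb(X, np.array([0, 2, 3, 4]))
        with pytest.raises(ValueError):
            fit_ztnb(X, np.array([1.5, 2, 3, 4]))


class TestRateRatioTable:
    def _fake_fit(self, beta, se, converged=True):
        names = list(beta.keys())
        cov = pd.DataFrame(
            np.diag([se[n] ** 2 for n in names] + [0.01]),
            index=names + ["log_theta"], columns=names + ["log_theta"],
        )
        return ZtnbFit(
            beta=pd.Series(beta), theta=1.5, covariance=cov, loglik=-1.0,
            converged=converged, n_obs=100, grad_norm=0.0, n_iter=10,
        )

    def test_zero_coefficient_gives_unit_rr_symmetric_ci(self):
        fit = self._fake_fit({"intercept": 2.0, "x": 0.0},
                             {"intercept": 0.1, "x": 0.05})
        row = rate_ratio_table(fit).set_index("term").loc["x"]
        assert row["rate_ratio"] == 1.0
        assert row["ci_low"] * row["ci_high"] == pytest.approx(1.0)

    def test_display_matches_published_rounding_convention(self):
        fit = self._fake_fit(
            {"intercept": 2.0, "x": np.log(1.16)},
            {"intercept": 0.1, "x": 0.033})
        row = rate_ratio_table(fit).set_index("term").loc["x"]
        assert row["display"] == "1.16 (1.09, 1.24)"

    def test_labels_permute_rows_not_values(self):
        fit = self._fake_fit(
            {"intercept": 2.0, "x": 0.1, "z": -0.2},
            {"intercept": 0.1, "x": 0.05, "z": 0.05})
        t1 = rate_ratio_table(fit, labels={"x": "X", "z": "Z"})
        t2 = rate_ratio_table(fit, labels={"z": "Z", "x": "X"})
        pd.testing.assert_frame_equal(
            t1.drop(columns="label"), t2.drop(columns="label"))

    def test_non_converged_fit_refuses_to_report(self):
        fit = self._fake_fit({"intercept": 2.0, "x": 0.1},
                             {"intercept": 0.1, "x": 0.05}, converged=False)
        assert fit.rate_ratios is None
        with pytest.raises(ValueError):
            rate_ratio_table(fit)
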