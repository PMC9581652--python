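"""Gibbs sampler unit tests, including the conjugacy quadrature oracles.

The closed-form conditionals are the central derivation of the package, so
they are checked against brute numeric integration of likelihood x prior on
toy problems, independent of the sampler code path.
"""

import numpy as np
import pytest

from bayar import (
    GibbsConfig,
    PosteriorDraws,
    PriorSpec,
    chain_diagnostics,
    coef_conditional,
    fit_least_squares,
    gibbs_sample,
    posterior_aic,
    var_conditional,
)
from bayar.ar_baseline import aic


def quadrature_moments(logpdf, grid):
    """Mean and variance of an unnormalized log-density on a grid."""
    logw = logpdf(grid)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    mean = float(w @ grid)
    var = float(w @ (grid - mean) ** 2)
    return mean, var


class TestCoefConditional:
    # shared toy problem: single coefficient, x=[1,2,3], y=[2,4,6], sigma2=1
    X = np.array([[1.0], [2.0], [3.0]])
    Y = np.array([2.0, 4.0, 6.0])

    def test_matches_quadrature_oracle(self):
        prior = PriorSpec()  # N(0, 1)
        mean, var = coef_conditional(0, np.array([0.0, 1.0]), self.X, self.Y, prior)

        def logpost(beta):
            resid = self.Y[None, :] - beta[:, None] * self.X[:, 0][None, :]
            return -0.5 * np.sum(resid**2, axis=1) - 0.5 * beta**2

        grid = np.arange(-10.0, 10.0, 1e-4)
        q_mean, q_var = quadrature_moments(logpost, grid)
        assert mean == pytest.approx(q_mean, rel=1e-5)
        assert var == pytest.approx(q_var, rel=1e-5)

    def test_two_coefficient_conditionals_match_quadrature(self):
        # intercept + slope toy; condition each coefficient on the other
        prior = PriorSpec(coef_mean=0.2, coef_var=2.0)
        X = np.column_stack([np.ones(4), np.array([1.0, 2.0, 3.0, 4.0])])
        y = np.array([1.1, 2.3, 2.8, 4.2])
        state = np.array([0.4, 0.9, 0.5])  # (intercept, slope, sigma2)
        grid = np.arange(-10.0, 10.0, 1e-4)
        for j in range(2):
            mean, var = coef_conditional(j, state, X, y, prior)

            def logpost(theta_j, j=j):
                th = np.tile(state[:2], (theta_j.size, 1))
                th[:, j] = theta_j
                resid = y[None, :] - th @ X.T
                loglik = -0.5 * np.sum(resid**2, axis=1) / state[2]
                logpri = -0.5 * (theta_j - prior.coef_mean) ** 2 / prior.coef_var
                return loglik + logpri

            q_mean, q_var = quadrature_moments(logpost, grid)
            assert mean == pytest.approx(q_mean, rel=1e-5)
            assert var == pytest.approx(q_var, rel=1e-5)

    def test_empty_data_returns_prior(self):
        prior = PriorSpec(coef_mean=0.7, coef_var=3.0)
        mean, var = coef_conditional(
            0, np.array([0.0, 1.0]), np.empty((0, 1)), np.empty(0), prior
        )
        assert (mean, var) == (0.7, 3.0)

    def test_flat_prior_limit_is_least_squares(self):
        prior = PriorSpec(coef_var=1e12)
        mean, _ = coef_conditional(0, np.array([0.0, 1.0]), self.X, self.Y, prior)
        assert mean == pytest.approx(2.0, abs=1e-6)  # sum(xy)/sum(x^2) = 28/14

    def test_nonpositive_sigma2_rejected(self):
        with pytest.raises(ValueError, match="sigma2"):
            coef_conditional(0, np.array([0.0, 0.0]), self.X, self.Y, PriorSpec())


class TestVarConditional:
    def test_no_data_returns_prior(self):
        shape, scale = var_conditional([], PriorSpec())
        assert (shape, scale) == (0.5, 1 / 20)

    def test_zero_residuals(self):
        shape, scale = var_conditional(np.zeros(10), PriorSpec())
        assert (shape, scale) == (0.5 + 5, 1 / 20)

    def test_hand_computed_sse(self):
        shape, scale = var_conditional([1.0, -1.0, 2.0], PriorSpec())
        assert shape == pytest.approx(0.5 + 1.5)
        assert scale == pytest.approx(1 / 20 + 3.0)

    def test_matches_quadrature_oracle(self):
        # 5 residuals so the inverse-gamma mean and variance both exist;
        # log-spaced trapezoid grid to capture the heavy right tail
        resid = np.array([1.0, -0.5, 2.0, 0.3, -1.2])
        prior = PriorSpec()
        shape, scale = var_conditional(resid, prior)
        sse = float(resid @ resid)

        grid = np.logspace(-4, 7, 400_001)
        logpdf = (
            -0.5 * resid.size * np.log(grid)
            - sse / (2 * grid)
            + (-prior.var_shape - 1) * np.log(grid)
            - prior.var_scale / grid
        )
        w = np.exp(logpdf - logpdf.max())
        z = np.trapezoid(w, grid)
        q_mean = np.trapezoid(w * grid, grid) / z
        q_var = np.trapezoid(w * (grid - q_mean) ** 2, grid) / z
        ig_mean = scale / (shape - 1)
        ig_var = scale**2 / ((shape - 1) ** 2 * (shape - 2))
        assert ig_mean == pytest.approx(q_mean, rel=1e-5)
        assert ig_var == pytest.approx(q_var, rel=1e-5)


class TestGibbsSample:
    def test_seed_determinism(self, ar2_series):
        cfg = GibbsConfig(iterations=500, burn_in=100, seed=9)
        a = gibbs_sample(ar2_series, 2, config=cfg)
        b = gibbs_sample(ar2_series, 2, config=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_retained_count_and_positive_variance(self, ar2_draws):
        assert ar2_draws.n_retained == 2500
        assert np.all(ar2_draws.draws[:, -1] > 0)

    def test_point_mass_prior_pins_coefficients(self, ar2_series):
        draws = gibbs_sample(
            ar2_series,
            2,
            prior=PriorSpec(coef_var=1e-12),
            config=GibbsConfig(iterations=1000, burn_in=200, seed=2),
        )
        assert np.all(np.abs(draws.posterior_mean()[:3]) < 1e-4)

    def test_high_order_requires_override(self, ar2_series):
        with pytest.raises(ValueError, match="allow_high_order"):
            gibbs_sample(ar2_series, 120, config=GibbsConfig(iterations=200, burn_in=0))

    def test_scan_order_invariance(self, vague_prior):
        # exchanging the beta scan order leaves posterior means within MC error
        from bayar import generate_pure_ar

        series = generate_pure_ar(8.0, (0.5, 0.3), 6.0, 400, seed=7)
        cfg = GibbsConfig(iterations=20_000, burn_in=4_000, seed=5)
        fwd = gibbs_sample(series, 2, prior=vague_prior, config=cfg)
        rev = gibbs_sample(
            series, 2, prior=vague_prior, config=cfg, scan_order=[0, 2, 1]
        )

        def batch_se(x, nbatch=40):
            bs = x[: (x.size // nbatch) * nbatch].reshape(nbatch, -1).mean(axis=1)
            return bs.std(ddof=1) / np.sqrt(nbatch)

        for k in range(4):
            se = np.hypot(batch_se(fwd.draws[:, k]), batch_se(rev.draws[:, k]))
            gap = abs(fwd.posterior_mean()[k] - rev.posterior_mean()[k])
            assert gap <= 3 * se + 1e-12

    def test_init_choice_immaterial_after_burn_in(self, vague_prior):
        from bayar import generate_pure_ar

        series = generate_pure_ar(8.0, (0.5, 0.3), 6.0, 400, seed=7)
        means = {}
        for init in ("least_squares", "zeros"):
            cfg = GibbsConfig(iterations=20_000, burn_in=4_000, seed=6, init=init)
            d = gibbs_sample(series, 2, prior=vague_prior, config=cfg)
            means[init] = (d.posterior_mean(), d.posterior_sd(), d.n_retained)
        m1, sd1, n1 = means["least_squares"]
        m2, _, _ = means["zeros"]
        # generous MC allowance: 3 naive SEs times a mixing factor
        assert np.all(np.abs(m1 - m2) <= 15 * sd1 / np.sqrt(n1))


class TestChainDiagnostics:
    def _dummy_draws(self, column):
        d = np.column_stack([column, np.abs(column) + 1.0])
        return PosteriorDraws(draws=d, order=0, config=GibbsConfig(iterations=d.shape[0], burn_in=0))

    def test_iid_chain_not_flagged(self):
        rng = np.random.default_rng(0)
        diag = chain_diagnostics(self._dummy_draws(rng.normal(size=5000)))
        assert diag.summary.loc["alpha", "split_gap"] < 0.1
        assert bool(diag.summary.loc["alpha", "converged"])

    def test_trending_chain_flagged(self):
        diag = chain_diagnostics(self._dummy_draws(np.linspace(1, 10_000, 10_000)))
        assert not bool(diag.summary.loc["alpha", "converged"])

    def test_gap_matches_direct_arithmetic(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=1000)
        diag = chain_diagnostics(self._dummy_draws(col))
        expected = abs(col[:500].mean() - col[500:].mean()) / col.std(ddof=1)
        assert diag.summary.loc["alpha", "split_gap"] == pytest.approx(expected)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="200"):
            chain_diagnostics(self._dummy_draws(np.ones(50)))


class TestPosteriorAic:
    def test_exact_fit_parameter_set_hits_sentinel(self, recurrence_series):
        # draws all identical to the exact recurrence parameters
        row = np.array([10.0, 0.5, 1.0])
        draws = PosteriorDraws(
            draws=np.tile(row, (300, 1)),
            order=1,
            config=GibbsConfig(iterations=300, burn_in=0),
        )
        assert posterior_aic(recurrence_series, draws) == float("-inf")

    def test_flat_prior_chain_matches_baseline_aic(self, vague_prior):
        from bayar import generate_pure_ar

        series = generate_pure_ar(8.0, (0.5, 0.3), 6.0, 400, seed=7)
        fit = fit_least_squares(series, 2)
        baseline = aic(fit.sse, len(series), 2)
        draws = gibbs_sample(
            series, 2, prior=vague_prior,
            config=GibbsConfig(iterations=20_000, burn_in=4_000, seed=8),
        )
        assert posterior_aic(series, draws) == pytest.approx(baseline, abs=0.02)

    def test_ols_sse_never_rises_with_extra_lags(self):
        from bayar import generate_pure_ar

        series = generate_pure_ar(20.0, (0.4,), 5.0, 150, seed=13)
        sses = [fit_least_squares(series, p).sse for p in range(1, 7)]
        assert all(b <= a + 1e-8 for a, b in zip(sses, sses[1:]))
        T = len(series)
        penalties = [(T + p) / (T - p) for p in range(1, 7)]
        assert all(b > a for a, b in zip(penalties, penalties[1:]))
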