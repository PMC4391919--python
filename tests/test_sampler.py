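"""Unit tests for the Gibbs samplers and their full-conditional building blocks."""
import numpy as np
import pytest

import lassospace as ls
from lassospace import _kernels
from lassospace.sampler import mcse


def _rng(seed=0):
    return np.random.Generator(np.random.PCG64(seed))


class TestFullConditionals:
    """Each frozen full conditional must match its analytic moments
    (4 standard errors at 1e5 draws)."""

    N = 100_000

    def test_sigma2_is_inverse_gamma(self):
        r = np.array([1.0, -2.0, 0.5, 1.5, -0.5])
        pen = 2.0
        n, m = 5, 3
        rng = _rng(1)
        draws = np.array(
            [_kernels.draw_sigma2(r, pen, n, m, rng) for _ in range(self.N)]
        )
        a = 0.5 * (n + m)
        b = 0.5 * (float(r @ r) + pen)
        mean = b / (a - 1)
        sd = b / ((a - 1) * np.sqrt(a - 2))
        assert abs(draws.mean() - mean) < 4 * sd / np.sqrt(self.N)

    def test_inv_tau2_is_inverse_gaussian(self):
        beta = np.array([0.7])
        lam2, sigma2 = 4.0, 2.0
        mu_ig = np.sqrt(lam2 * sigma2) / 0.7
        rng = _rng(2)
        tau2 = np.empty(1)
        itau = np.empty(self.N)
        for i in range(self.N):
            _kernels.draw_tau2(beta, tau2, lam2, sigma2, rng)
            itau[i] = 1.0 / tau2[0]
        sd = np.sqrt(mu_ig**3 / lam2)
        assert abs(itau.mean() - mu_ig) < 4 * sd / np.sqrt(self.N)

    def test_lambda2_is_gamma(self):
        tau2 = np.array([0.5, 1.5, 2.0])
        rate = 0.5 * tau2.sum()
        m = 3
        rng = _rng(3)
        draws = np.array(
            [_kernels.draw_lambda2_lasso(tau2, 0.0, 0.0, rng) for _ in range(self.N)]
        )
        mean, sd = m / rate, np.sqrt(m) / rate
        assert abs(draws.mean() - mean) < 4 * sd / np.sqrt(self.N)

    def test_ridge_lambda_is_gamma(self):
        beta = np.array([1.0, -2.0])
        sigma2 = 2.0
        rate = 0.5 * float(beta @ beta) / sigma2
        rng = _rng(4)
        draws = np.array(
            [
                _kernels.draw_lambda_ridge(beta, sigma2, 0.0, 0.0, rng)
                for _ in range(self.N)
            ]
        )
        mean, sd = 1.0 / rate, 1.0 / rate
        assert abs(draws.mean() - mean) < 4 * sd / np.sqrt(self.N)

    def test_mu_shift_is_normal(self):
        r0 = np.array([2.0, -1.0, 1.0, 0.0])
        sigma2 = 3.0
        rng = _rng(5)
        shifts = np.empty(self.N)
        for i in range(self.N):
            r = r0.copy()
            shifts[i] = _kernels.draw_mu_shift(r, sigma2, rng)
        mean, sd = r0.mean(), np.sqrt(sigma2 / r0.size)
        assert abs(shifts.mean() - mean) < 4 * sd / np.sqrt(self.N)
        assert abs(shifts.std(ddof=1) - sd) < 4 * sd / np.sqrt(2 * self.N)

    def test_beta_single_site_is_normal(self):
        # m=1 sweep with frozen tau2/sigma2: beta_1 | rest ~ N(c/p, sigma2/p)
        Xt = np.array([[1.0, -1.0, 1.0, 1.0]])
        s = np.array([4.0])
        y = np.array([2.0, -1.5, 2.5, 1.0])
        tau2 = np.array([2.0])
        sigma2 = 1.5
        rng = _rng(6)
        draws = np.empty(self.N)
        for i in range(self.N):
            beta = np.zeros(1)
            r = y.copy()
            _kernels.sweep_beta_lasso(Xt, s, r, beta, tau2, sigma2, rng)
            draws[i] = beta[0]
        prec = s[0] + 1.0 / tau2[0]
        mean = float(Xt[0] @ y) / prec
        sd = np.sqrt(sigma2 / prec)
        assert abs(draws.mean() - mean) < 4 * sd / np.sqrt(self.N)
        assert abs(draws.std(ddof=1) - sd) < 4 * sd / np.sqrt(2 * self.N)


class TestSamplerBehavior:
    def test_sign_symmetry_zero_phenotype(self):
        X = ls.GenotypeMatrix(np.resize([1.0, -1.0], 40).reshape(40, 1))
        y = ls.Phenotypes(np.zeros(40) + 1e-300)  # finite zero-vector
        cfg = ls.SamplerConfig(lam=1.0, burn_in=1000, thin=1, n_draws=4000, seed=1)
        d = ls.gibbs_blasso(X, y, cfg)
        se = mcse(d.beta[:, 0])
        assert abs(d.beta[:, 0].mean()) < 4 * max(se, 1e-12) + 1e-9

    def test_ridge_sign_symmetry_and_heavy_penalty_limit(self):
        rng = np.random.default_rng(3)
        X = ls.GenotypeMatrix(rng.choice((-1.0, 1.0), size=(30, 2)))
        y = ls.Phenotypes(X.values @ np.array([2.0, -1.0]) + rng.normal(0, 1, 30))
        cfg = ls.SamplerConfig(
            model="ridge", lam=1e6, burn_in=1000, thin=1, n_draws=3000, seed=2
        )
        d = ls.gibbs_bridge(X, y, cfg)
        # infinite-penalty limit: prior precision ~1e6 crushes the effects
        assert np.all(np.abs(d.beta.mean(axis=0)) < 0.05)

    def test_shrinkage_monotone_in_lambda(self, small_collinear_data):
        X, y, _ = small_collinear_data
        norms = []
        for i, lam in enumerate((10**-0.7, 10**0.5, 10**2.0)):
            cfg = ls.SamplerConfig(
                lam=lam, burn_in=1500, thin=1, n_draws=3000, seed=40 + i
            )
            d = ls.gibbs_blasso(X, y, cfg)
            norms.append(np.abs(d.beta.mean(axis=0)).sum())
        # strict decrease between the grid endpoints; interior value between
        # them up to MC tolerance
        assert norms[2] < norms[0]
        assert norms[1] < norms[0] + 0.1

    def test_determinism_bit_identical(self, small_collinear_data):
        X, y, _ = small_collinear_data
        cfg = ls.SamplerConfig(lam=2.0, burn_in=200, thin=2, n_draws=300, seed=77)
        d1 = ls.gibbs_blasso(X, y, cfg)
        d2 = ls.gibbs_blasso(X, y, cfg)
        assert np.array_equal(d1.beta, d2.beta)
        assert np.array_equal(d1.sigma2, d2.sigma2)
        cfg_r = ls.SamplerConfig(
            lambda_mode="random", burn_in=200, thin=2, n_draws=300, seed=77
        )
        r1 = ls.gibbs_blasso(X, y, cfg_r)
        r2 = ls.gibbs_blasso(X, y, cfg_r)
        assert np.array_equal(r1.lam, r2.lam)

    def test_random_lambda_draws_present_and_positive(self, small_collinear_data):
        X, y, _ = small_collinear_data
        cfg = ls.SamplerConfig(
            lambda_mode="random", burn_in=500, thin=1, n_draws=500, seed=3
        )
        d = ls.gibbs_blasso(X, y, cfg)
        assert d.lam is not None and np.all(d.lam > 0)
        assert np.all(d.sigma2 > 0)

    def test_center_y_fixes_mu(self, small_collinear_data):
        X, y, _ = small_collinear_data
        cfg = ls.SamplerConfig(
            lam=2.0, burn_in=200, thin=1, n_draws=100, seed=5, center_y=True
        )
        d = ls.gibbs_blasso(X, y, cfg)
        assert np.allclose(d.mu, y.y.mean())


class TestValidation:
    def test_nonfinite_phenotype_rejected(self):
        X = ls.GenotypeMatrix(np.ones((4, 1)))
        with pytest.raises(ValueError, match="finite"):
            ls.Phenotypes(np.array([1.0, np.nan, 0.0, 2.0]))

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            ls.GenotypeMatrix(np.empty((4, 0)))

    def test_missing_entries_rejected_by_sampler(self):
        V = np.ones((4, 2))
        V[0, 0] = np.nan
        X = ls.GenotypeMatrix(V)
        cfg = ls.SamplerConfig(lam=1.0, burn_in=10, thin=1, n_draws=10, seed=0)
        with pytest.raises(ValueError, match="missing"):
            ls.gibbs_blasso(X, ls.Phenotypes(np.ones(4)), cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ls.SamplerConfig(lam=-1.0)
        with pytest.raises(ValueError):
            ls.SamplerConfig(lambda_mode="fixed", lam=None)
        with pytest.raises(ValueError):
            ls.SamplerConfig(lam=1.0, thin=0)


class TestPosteriorSummary:
    def test_counts_match_hand_example(self):
        d = ls.PosteriorDraws(
            beta=np.array([[1.0], [1.0], [-1.0], [1.0]]),
            mu=np.zeros(4),
            sigma2=np.ones(4),
            tau2=None,
            lam=None,
            config=ls.SamplerConfig(lam=1.0),
            marker_names=["m1"],
        )
        s = ls.posterior_summary(d)
        assert s.loc["m1", "mean"] == 0.5
        assert s.loc["m1", "p_pos"] == 0.75
        assert s.loc["m1", "p_neg"] == 0.25

    def test_all_positive_column(self):
        d = ls.PosteriorDraws(
            beta=np.abs(np.random.default_rng(0).normal(size=(50, 1))) + 0.1,
            mu=np.zeros(50), sigma2=np.ones(50), tau2=None, lam=None,
            config=ls.SamplerConfig(lam=1.0), marker_names=["m1"],
        )
        assert ls.posterior_summary(d).loc["m1", "p_pos"] == 1.0

    def test_mean_matches_direct_summation(self, tiny_draws):
        s = ls.posterior_summary(tiny_draws)
        direct = np.array(
            [sum(tiny_draws.beta[:, j]) / tiny_draws.n_draws for j in range(3)]
        )
        np.testing.assert_allclose(s["mean"].to_numpy(), direct, rtol=1e-12)
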