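"""Hierarchical Bayesian consensus models: algebra, limits, equivariance."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from kctree.bayes import (
    HierModelSpec,
    MCMCConfig,
    _loglike_laplace,
    fit_hier_gauss_gauss,
    fit_hier_laplace_gauss,
    fit_hier_skew_t_gauss,
    sample_skew_t_effects,
    skew_t_mean_zero_offset,
    skew_t_sd_factor,
)
from kctree.consistency import weighted_mean

from .conftest import make_study

FAST = MCMCConfig(warmup=1200, samples=2000, seed=7)


def _skew_t_pdf(x, xi, omega, alpha, nu):
    z = (x - xi) / omega
    return (
        2.0
        / omega
        * stats.t.pdf(z, nu)
        * stats.t.cdf(alpha * z * np.sqrt((nu + 1) / (nu + z**2)), nu + 1)
    )


class TestSkewTOffset:
    def test_symmetric_case_zero(self):
        assert skew_t_mean_zero_offset(1.0, 0.0, 10.0) == 0.0

    def test_odd_in_alpha(self):
        xi_p = skew_t_mean_zero_offset(2.0, 3.0, 8.0)
        xi_m = skew_t_mean_zero_offset(2.0, -3.0, 8.0)
        assert xi_p == pytest.approx(-xi_m, rel=1e-12)

    def test_quadrature_mean_zero(self):
        omega, alpha, nu = 1.0, 3.0, 10.0
        xi = skew_t_mean_zero_offset(omega, alpha, nu)
        mean, _ = integrate.quad(
            lambda x: x * _skew_t_pdf(x, xi, omega, alpha, nu), -50, 50, limit=200
        )
        assert mean == pytest.approx(0.0, abs=1e-6)

    def test_rejects_nu_at_most_one(self):
        with pytest.raises(ValueError):
            skew_t_mean_zero_offset(1.0, 1.0, 1.0)

    def test_sd_factor_matches_quadrature(self):
        omega, alpha, nu = 1.0, -4.0, 9.0
        xi = skew_t_mean_zero_offset(omega, alpha, nu)
        var, _ = integrate.quad(
            lambda x: x**2 * _skew_t_pdf(x, xi, omega, alpha, nu), -80, 80, limit=400
        )
        assert math.sqrt(var) == pytest.approx(
            float(skew_t_sd_factor(alpha, nu)), rel=1e-5
        )


class TestEffectSampling:
    @pytest.mark.parametrize("alpha,nu", [(0.0, 10.0), (-4.0, 9.0), (6.0, 5.0)])
    def test_mean_zero_and_sd_tau(self, alpha, nu):
        rng = np.random.default_rng(1)
        tau = 2.5
        lam = sample_skew_t_effects(rng, tau, alpha, nu, 200000)
        assert lam.mean() == pytest.approx(0.0, abs=0.03)
        assert lam.std() == pytest.approx(tau, rel=0.02)

    def test_alpha_zero_symmetric(self):
        rng = np.random.default_rng(2)
        lam = sample_skew_t_effects(rng, 1.0, 0.0, 12.0, 100000)
        assert stats.skew(lam) == pytest.approx(0.0, abs=0.05)


class TestLaplaceMarginal:
    def test_matches_numerical_convolution(self):
        # oracle: quadrature of the Laplace x Gaussian convolution integral
        tau, sigma, mu = 1.7, 0.8, 0.0
        b = tau / math.sqrt(2)
        for d in (-3.0, -0.5, 0.0, 1.2, 6.0):
            oracle, _ = integrate.quad(
                lambda lam: stats.norm.pdf(d - lam, 0, sigma)
                * stats.laplace.pdf(lam, 0, b),
                -60,
                60,
                limit=400,
            )
            got = _loglike_laplace(
                np.array([[d]]), np.array([[sigma]]), np.array([tau])
            )[0]
            assert got == pytest.approx(math.log(oracle), rel=1e-8)

    def test_tiny_tau_limit_is_gaussian(self):
        d = np.array([[0.7]])
        sigma = np.array([[0.5]])
        got = _loglike_laplace(d, sigma, np.array([1e-14]))[0]
        expected = stats.norm.logpdf(0.7, 0, 0.5)
        assert got == pytest.approx(expected, rel=1e-9)


class TestFits:
    def test_skew_t_with_alpha_fixed_zero_matches_gauss(self):
        # alpha ~ N(0, tiny) and nu pushed large: the skew-t leaf must
        # agree with the Gauss+Gauss leaf on a common study
        s = make_study(
            [10.1, 9.4, 10.9, 10.3, 9.8, 10.6, 9.1, 10.2, 10.5, 9.9],
            [0.3] * 10,
        )
        cg, _ = fit_hier_gauss_gauss(s, mcmc=FAST)
        spec = HierModelSpec(
            effects_family="skew_t",
            prior_alpha_sd=1e-3,
            prior_nu_df=(60.0, 1.0),  # concentrates nu near 60
        )
        cs, _ = fit_hier_skew_t_gauss(s, spec, FAST)
        assert cs.kcrv == pytest.approx(cg.kcrv, abs=0.5 * cg.std_unc)
        assert cs.std_unc == pytest.approx(cg.std_unc, rel=0.25)

    def test_tau_forced_to_zero_recovers_weighted_mean(self):
        s = make_study(
            [5.2, 5.0, 5.4, 4.9, 5.1, 5.3], [0.2, 0.3, 0.25, 0.2, 0.35, 0.3]
        )
        spec = HierModelSpec(effects_family="gauss", prior_tau_scale=1e-6)
        c, _ = fit_hier_gauss_gauss(s, spec, FAST)
        wm = weighted_mean(s)
        assert c.kcrv == pytest.approx(wm.estimate, abs=0.3 * wm.internal_std_unc)
        assert c.std_unc == pytest.approx(wm.internal_std_unc, rel=0.15)

    @pytest.mark.parametrize(
        "fit",
        [fit_hier_gauss_gauss, fit_hier_laplace_gauss, fit_hier_skew_t_gauss],
        ids=["gauss", "laplace", "skew_t"],
    )
    def test_location_scale_equivariance(self, fit):
        x = [10.0, 12.5, 9.0, 11.0, 10.5, 13.5, 9.5, 10.8]
        u = [0.4, 0.5, 0.3, 0.6, 0.4, 0.5, 0.35, 0.45]
        a, c = 100.0, 4.0
        r0, _ = fit(make_study(x, u), mcmc=FAST)
        r1, _ = fit(
            make_study([a + c * v for v in x], [c * w for w in u]), mcmc=FAST
        )
        # agreement within Monte Carlo error of two independent chains
        tol = 4.0 * c * r0.std_unc / math.sqrt(200)
        assert r1.kcrv == pytest.approx(a + c * r0.kcrv, abs=10 * tol)
        assert r1.std_unc == pytest.approx(c * r0.std_unc, rel=0.2)
        assert r1.tau.tau_hat == pytest.approx(c * r0.tau.tau_hat, rel=0.25)

    def test_finite_dof_treats_error_scales_as_unknown(self):
        # reported uncertainties understate the scatter; with few dof the
        # posterior error scales must move up toward the empirical spread
        x = [10.0, 10.8, 9.1, 10.4, 9.5, 11.2, 10.1]
        u = [0.15] * 7
        c_fin, s_fin = fit_hier_gauss_gauss(
            make_study(x, u, dof=[4.0] * 7), mcmc=FAST
        )
        assert all(e["sd"] > 0 for e in s_fin.sigma)
        assert np.mean([e["mean"] for e in s_fin.sigma]) > 0.15
        # infinite dof: scales stay pinned at the reported values
        _, s_inf = fit_hier_gauss_gauss(make_study(x, u), mcmc=FAST)
        assert all(e["mean"] == pytest.approx(0.15) for e in s_inf.sigma)
        assert all(e["sd"] == 0.0 for e in s_inf.sigma)

    def test_minimum_sample_sizes(self):
        s = make_study([1.0, 2.0, 3.0, 4.0], [0.1] * 4)
        with pytest.raises(ValueError):
            fit_hier_skew_t_gauss(s, mcmc=FAST)
        s2 = make_study([1.0, 2.0], [0.1] * 2)
        with pytest.raises(ValueError):
            fit_hier_gauss_gauss(s2, mcmc=FAST)

    def test_diagnostics_reported(self, ccem):
        c, s = fit_hier_laplace_gauss(ccem, mcmc=FAST)
        assert "mu" in s.diagnostics and "rhat" in s.diagnostics["mu"]
        assert s.diagnostics["mu"]["rhat"] < 1.1
        assert c.n_draws == len(c.draws["mu"])

    def test_seed_reproducibility(self, ccem):
        a, _ = fit_hier_laplace_gauss(ccem, mcmc=FAST)
        b, _ = fit_hier_laplace_gauss(ccem, mcmc=FAST)
        assert a.kcrv == b.kcrv
        assert np.array_equal(a.draws["mu"], b.draws["mu"])
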