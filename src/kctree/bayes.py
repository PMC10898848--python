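"""Bayesian hierarchical random-effects consensus models.

All three leaves share the random-effects structure x_j = mu + lambda_j +
eps_j with Gaussian measurement errors eps_j ~ N(0, sigma_j); they differ
in the distribution of the laboratory effects lambda_j, always scaled so
that tau is the effects' standard deviation (dark uncertainty):

* Gauss + Gauss: lambda_j ~ N(0, tau).
* Laplace + Gauss: lambda_j ~ Laplace(0, b) with b = tau/sqrt(2), whose
  heavier tails dampen the pull of results that sit far from the bulk.
* Skew Student + Gauss: lambda_j follows an Azzalini skew-t with skewness
  alpha (alpha > 0 = right skew), tail dof nu_df, and location offset
  chosen so the effects have mean zero; it accommodates asymmetric
  arrangements of the measured values.

When a laboratory reports finite degrees of freedom nu_j, its error scale
sigma_j is unknown and the reported u_j enters the likelihood through
nu_j u_j^2 / sigma_j^2 ~ chi-squared(nu_j); with nu_j infinite, sigma_j is
fixed at u_j.

Sampling strategy: the per-lab effects are marginalized out of the
likelihood (exactly for Gauss and Laplace effects, by Gauss-Hermite
quadrature against the Gaussian error kernel for skew-t), leaving a 2-4
dimensional posterior over (mu, tau[, alpha, nu_df][, sigma_j...]) that an
affine-invariant ensemble sampler explores cheaply and reliably.  Split-
Rhat and effective sample sizes are computed per parameter, treating
walkers as chains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import arviz as az
import emcee
import numpy as np
from scipy import special, stats

from .consistency import TauEstimate, dersimonian_laird_tau
from .data import KCStudy
from .results import ConsensusResult

__all__ = [
    "HierModelSpec",
    "MCMCConfig",
    "PosteriorSummary",
    "ConvergenceError",
    "fit_hier_gauss_gauss",
    "fit_hier_laplace_gauss",
    "fit_hier_skew_t_gauss",
    "fit_hierarchical",
    "skew_t_mean_zero_offset",
    "skew_t_sd_factor",
]

_SQRT2 = math.sqrt(2.0)
_GH_NODES = 48


class ConvergenceError(RuntimeError):
    """MCMC failed its convergence gate; carries the offending diagnostics."""


@dataclass(frozen=True)
class HierModelSpec:
    """Priors and family choice for a hierarchical consensus model.

    Scale-type defaults of None are resolved from the data at fit time:
    ``prior_mu = (median x, 1e5 * mad x)`` (effectively flat),
    ``prior_tau`` = half-Cauchy with scale mad(x), and ``prior_sigma`` =
    half-Cauchy with scale median(u) (used only for finite-dof labs).
    The skew-t tail dof has a Gamma(shape, rate) prior truncated at
    ``nu_df_min``; truncation at 3 keeps the effects' sd finite so that
    tau means the same thing in every leaf.
    """

    effects_family: str = "gauss"  # gauss | laplace | skew_t
    prior_mu: tuple[float, float] | None = None
    prior_tau_scale: float | None = None
    prior_sigma_scale: float | None = None
    prior_alpha_sd: float = 4.0
    prior_nu_df: tuple[float, float] = (2.0, 0.2)
    nu_df_min: float = 3.0

    def __post_init__(self) -> None:
        if self.effects_family not in {"gauss", "laplace", "skew_t"}:
            raise ValueError(f"unknown effects family {self.effects_family!r}")
        if self.nu_df_min <= 2.0:
            raise ValueError("nu_df_min must exceed 2 (effects sd must exist)")


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    samples: int = 2500  # retained draws per chain
    seed: int | None = None
    walkers: int = 32
    rhat_warn: float = 1.05
    rhat_fail: float = 1.2
    ess_min: float = 400.0

    @property
    def total_draws(self) -> int:
        return self.chains * self.samples


@dataclass
class PosteriorSummary:
    """Posterior summaries for a hierarchical fit.

    ``mu`` and ``tau`` are dicts with mean/sd/median and central quantiles;
    ``lambda_`` holds per-lab effect summaries (conditional on the data),
    ``sigma`` per-lab error-scale summaries (degenerate at u_j for
    infinite-dof labs).  ``diagnostics`` records split-Rhat and bulk ESS
    per sampled parameter, plus any convergence warnings.
    """

    mu: dict[str, float]
    tau: dict[str, float]
    lambda_: list[dict[str, float]]
    sigma: list[dict[str, float]]
    alpha: dict[str, float] | None = None
    nu_df: dict[str, float] | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "tau": self.tau,
            "lambda": self.lambda_,
            "sigma": self.sigma,
            "alpha": self.alpha,
            "nu_df": self.nu_df,
            "diagnostics": self.diagnostics,
        }


# --------------------------------------------------------------------------
# skew-t helpers (Azzalini parameterization)
# --------------------------------------------------------------------------

def _b_nu(nu):
    """b(nu) = sqrt(nu/pi) * Gamma((nu-1)/2) / Gamma(nu/2), for nu > 1."""
    nu = np.asarray(nu, dtype=float)
    return np.sqrt(nu / np.pi) * np.exp(
        special.gammaln((nu - 1.0) / 2.0) - special.gammaln(nu / 2.0)
    )


def skew_t_mean_zero_offset(omega: float, alpha: float, nu_df: float) -> float:
    """Location offset xi making a skew-t(xi, omega, alpha, nu_df) have mean 0.

    xi = -omega * delta * b(nu) with delta = alpha/sqrt(1+alpha^2); requires
    nu_df > 1 for the mean to exist.
    """
    if not omega > 0:
        raise ValueError("omega must be > 0")
    if not nu_df > 1:
        raise ValueError("skew-t mean undefined for nu_df <= 1")
    delta = alpha / math.sqrt(1.0 + alpha**2)
    return float(-omega * delta * _b_nu(nu_df))


def skew_t_sd_factor(alpha, nu_df):
    """sd of a skew-t with unit omega: sqrt(nu/(nu-2) - delta^2 b(nu)^2); nu > 2."""
    alpha = np.asarray(alpha, dtype=float)
    nu_df = np.asarray(nu_df, dtype=float)
    delta2 = alpha**2 / (1.0 + alpha**2)
    var = nu_df / (nu_df - 2.0) - delta2 * _b_nu(nu_df) ** 2
    return np.sqrt(var)


def _skew_t_logpdf_std(z, alpha, nu):
    """log density of the standard Azzalini skew-t (xi=0, omega=1)."""
    t_log = stats.t.logpdf(z, nu)
    arg = alpha * z * np.sqrt((nu + 1.0) / (nu + z**2))
    cdf_log = stats.t.logcdf(arg, nu + 1.0)
    return math.log(2.0) + t_log + cdf_log


def sample_skew_t_effects(rng, tau, alpha, nu_df, size):
    """Draw mean-zero skew-t effects with sd tau (vector-friendly).

    Uses the scale-mixture representation: a skew-normal deviate
    delta|z0| + sqrt(1-delta^2) z1 divided by sqrt(chi2_nu/nu), then
    shifted/scaled to mean 0 and sd tau.
    """
    tau = np.asarray(tau, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    nu_df = np.asarray(nu_df, dtype=float)
    delta = alpha / np.sqrt(1.0 + alpha**2)
    z0 = np.abs(rng.standard_normal(size))
    z1 = rng.standard_normal(size)
    sn = delta * z0 + np.sqrt(1.0 - delta**2) * z1
    w = rng.chisquare(np.broadcast_to(nu_df, size)) / nu_df
    raw = sn / np.sqrt(w)  # standard skew-t (xi=0, omega=1)
    sd = skew_t_sd_factor(alpha, nu_df)
    omega = tau / sd
    xi = -omega * delta * _b_nu(nu_df)
    return xi + omega * raw


# --------------------------------------------------------------------------
# marginal log-likelihoods (effects integrated out)
# --------------------------------------------------------------------------

def _loglike_gauss(d, sigma, tau):
    """d = x - mu; Gauss effects: marginal N(0, sqrt(sigma^2 + tau^2))."""
    v = sigma**2 + tau[..., None] ** 2
    return -0.5 * np.sum(np.log(2.0 * np.pi * v) + d**2 / v, axis=-1)


def _log_erfcx(z):
    """log(erfcx(z)), stable for all real z.

    For z >= 0, erfcx(z) <= 1 and the direct log is safe; for z < 0,
    erfcx(z) = 2 exp(z^2) - erfcx(-z), factored to avoid overflow.
    """
    z = np.asarray(z, dtype=float)
    pos = np.log(special.erfcx(np.abs(z)))
    neg = z**2 + np.log(2.0 - np.exp(-(z**2) + pos))
    return np.where(z >= 0, pos, neg)


def _loglike_laplace(d, sigma, tau):
    """Exact Laplace(0, tau/sqrt(2)) + N(0, sigma) convolution, log space."""
    b = tau[..., None] / _SQRT2
    tiny = b < 1e-10 * np.maximum(sigma, 1e-300)
    b_safe = np.where(tiny, 1.0, b)
    s_over_b2 = sigma / (b_safe * _SQRT2)
    d_over_s2 = d / (_SQRT2 * sigma)
    t1 = _log_erfcx(s_over_b2 + d_over_s2)
    t2 = _log_erfcx(s_over_b2 - d_over_s2)
    conv = (
        -(d**2) / (2.0 * sigma**2)
        - np.log(4.0 * b_safe)
        + np.logaddexp(t1, t2)
    )
    gauss = -0.5 * (np.log(2.0 * np.pi * sigma**2) + d**2 / sigma**2)
    return np.sum(np.where(tiny, gauss, conv), axis=-1)


_gh_x, _gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
_gh_logw = np.log(_gh_w) - 0.5 * math.log(math.pi)


def _loglike_skew_t(d, sigma, tau, alpha, nu):
    """Marginal likelihood with skew-t effects by Gauss-Hermite quadrature.

    f(x_j) = E_{lam ~ N(x_j - mu, sigma_j)}[ st(lam) ], evaluated at the
    Hermite nodes lam_k = d_j + sqrt(2) sigma_j t_k.  The skew-t density is
    smooth, so ~50 nodes resolve the integral to well below MC error.
    """
    sd = skew_t_sd_factor(alpha, nu)
    omega = tau / sd
    delta = alpha / np.sqrt(1.0 + alpha**2)
    xi = -omega * delta * _b_nu(nu)
    lam = d[..., None] + _SQRT2 * sigma[..., None] * _gh_x  # (..., n, K)
    z = (lam - xi[..., None, None]) / omega[..., None, None]
    logst = _skew_t_logpdf_std(
        z, alpha[..., None, None], nu[..., None, None]
    ) - np.log(omega[..., None, None])
    return np.sum(special.logsumexp(_gh_logw + logst, axis=-1), axis=-1)


# --------------------------------------------------------------------------
# posterior construction and sampling
# --------------------------------------------------------------------------

def _half_cauchy_logpdf(t, scale):
    return np.where(
        t > 0,
        math.log(2.0 / math.pi) - np.log(scale) - np.log1p((t / scale) ** 2),
        -np.inf,
    )


class _HierPosterior:
    """Log-posterior over theta = (mu, tau[, alpha, log(nu-nu_min)][, log sigma_f...])."""

    def __init__(self, study: KCStudy, spec: HierModelSpec):
        x, u, nu = study.arrays(included_only=True)
        self.x, self.u, self.nu = x, u, nu
        self.spec = spec
        self.family = spec.effects_family
        self.finite = np.isfinite(nu)
        self.n_finite = int(self.finite.sum())
        mad = stats.median_abs_deviation(x, scale="normal")
        if mad == 0:
            mad = max(np.std(x), np.median(u))
        self.mu0, self.mu_sd = spec.prior_mu or (float(np.median(x)), 1e5 * mad)
        self.tau_scale = spec.prior_tau_scale or float(mad)
        self.sigma_scale = spec.prior_sigma_scale or float(np.median(u))
        self.ndim = 2
        self.idx_alpha = self.idx_nu = None
        if self.family == "skew_t":
            self.idx_alpha, self.idx_nu = 2, 3
            self.ndim = 4
        self.idx_sigma = self.ndim
        self.ndim += self.n_finite

    def unpack(self, theta):
        theta = np.atleast_2d(theta)
        mu, tau = theta[:, 0], theta[:, 1]
        alpha = theta[:, self.idx_alpha] if self.idx_alpha is not None else None
        nu_df = (
            self.spec.nu_df_min + np.exp(theta[:, self.idx_nu])
            if self.idx_nu is not None
            else None
        )
        log_sig = theta[:, self.idx_sigma :] if self.n_finite else None
        return mu, tau, alpha, nu_df, log_sig

    def __call__(self, theta):
        theta = np.atleast_2d(theta)
        mu, tau, alpha, nu_df, log_sig = self.unpack(theta)
        lp = np.full(theta.shape[0], -np.inf)
        ok = tau > 0
        if self.family == "skew_t":
            # quadrature degenerates as tau -> 0 and b(nu) overflows as
            # nu -> inf; both regions carry negligible posterior mass
            ok &= tau > 1e-8 * self.sigma_scale
            ok &= nu_df < 1e8
        if not ok.any():
            return lp
        sigma = np.broadcast_to(self.u, (theta.shape[0], len(self.u))).copy()
        prior = stats.norm.logpdf(mu, self.mu0, self.mu_sd)
        prior = prior + _half_cauchy_logpdf(tau, self.tau_scale)
        if self.n_finite:
            sig_f = np.exp(log_sig)
            sigma[:, self.finite] = sig_f
            # half-Cauchy prior on sigma with log-scale Jacobian
            prior = prior + np.sum(
                _half_cauchy_logpdf(sig_f, self.sigma_scale) + log_sig, axis=1
            )
            # reported u_j as data: nu u^2 / sigma^2 ~ chi2(nu)
            nu_f = self.nu[self.finite]
            u_f = self.u[self.finite]
            s2 = u_f**2
            prior = prior + np.sum(
                0.5 * nu_f * np.log(nu_f * s2 / (2.0 * sig_f**2))
                - special.gammaln(0.5 * nu_f)
                - np.log(s2)
                - 0.5 * nu_f * s2 / sig_f**2,
                axis=1,
            )
        if self.family == "skew_t":
            shape, rate = self.spec.prior_nu_df
            prior = prior + stats.norm.logpdf(alpha, 0.0, self.spec.prior_alpha_sd)
            # Gamma prior on nu (truncated at nu_df_min) with log Jacobian
            prior = prior + stats.gamma.logpdf(nu_df, shape, scale=1.0 / rate)
            prior = prior + np.log(nu_df - self.spec.nu_df_min)
        d = self.x - mu[:, None]
        ll = np.full(theta.shape[0], -np.inf)
        idx = np.where(ok & np.isfinite(prior))[0]
        if idx.size:
            if self.family == "gauss":
                ll[idx] = _loglike_gauss(d[idx], sigma[idx], tau[idx])
            elif self.family == "laplace":
                ll[idx] = _loglike_laplace(d[idx], sigma[idx], tau[idx])
            else:
                ll[idx] = _loglike_skew_t(
                    d[idx], sigma[idx], tau[idx], alpha[idx], nu_df[idx]
                )
        lp[idx] = prior[idx] + ll[idx]
        return np.where(np.isnan(lp), -np.inf, lp)

    def initial_state(self, rng, nwalkers):
        x, u = self.x, self.u
        tau0 = max(dersimonian_laird_tau_arrays(x, u), 0.1 * float(np.median(u)))
        # a deliberately squeezed tau prior moves the posterior mass with it;
        # start the walkers inside that region
        tau0 = min(tau0, 5.0 * self.tau_scale)
        base = [float(np.median(x)), tau0]
        scales = [max(float(np.median(u)), 1e-3 * abs(base[0]) + 1e-12), 0.5 * tau0]
        if self.family == "skew_t":
            base += [0.0, math.log(10.0 - self.spec.nu_df_min)]
            scales += [1.0, 0.5]
        if self.n_finite:
            base += list(np.log(u[self.finite]))
            scales += [0.3] * self.n_finite
        base = np.array(base)
        scales = np.array(scales)
        p0 = base + scales * rng.standard_normal((nwalkers, self.ndim))
        p0[:, 1] = np.abs(p0[:, 1]) + 1e-6 * tau0
        return p0


def dersimonian_laird_tau_arrays(x, u) -> float:
    w = 1.0 / u**2
    s1, s2 = w.sum(), (w**2).sum()
    xbar = (w * x).sum() / s1
    q = (w * (x - xbar) ** 2).sum()
    denom = s1 - s2 / s1
    return math.sqrt(max(0.0, (q - (len(x) - 1)) / denom)) if denom > 0 else 0.0


def _summ(draws, qs=(0.025, 0.25, 0.5, 0.75, 0.975)):
    d = np.asarray(draws, dtype=float)
    out = {"mean": float(d.mean()), "sd": float(d.std(ddof=1)), "median": float(np.median(d))}
    for q in qs:
        out[f"q{q:g}"] = float(np.quantile(d, q))
    return out


def fit_hierarchical(
    study: KCStudy,
    spec: HierModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> tuple[ConsensusResult, PosteriorSummary]:
    """Fit a hierarchical random-effects model and return consensus + posterior.

    The KCRV is the posterior mean of mu and its standard uncertainty the
    posterior sd; ``ConsensusResult.draws`` retains the joint draws of
    (mu, tau[, alpha, nu_df][, sigma]) needed to propagate dark uncertainty
    into the degrees of equivalence.
    """
    spec = spec or HierModelSpec()
    mcmc = mcmc or MCMCConfig()
    n_min = 5 if spec.effects_family == "skew_t" else 3
    if study.n_included < n_min:
        raise ValueError(
            f"{spec.effects_family} hierarchical fit requires >= {n_min} included results"
        )
    post = _HierPosterior(study, spec)
    rng = np.random.default_rng(mcmc.seed)
    nwalkers = max(mcmc.walkers, 2 * post.ndim + 2)
    # short chains cannot beat the ensemble autocorrelation time
    steps_keep = max(int(math.ceil(mcmc.total_draws / nwalkers)), 200)
    nsteps = mcmc.warmup + steps_keep

    sampler = emcee.EnsembleSampler(
        nwalkers,
        post.ndim,
        post,
        vectorize=True,
        moves=[
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ],
    )
    state = post.initial_state(rng, nwalkers)
    # emcee uses np.random.RandomState internally; seed it from our generator
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)
    ).get_state()
    sampler.run_mcmc(state, nsteps, progress=False)

    chain = sampler.get_chain(discard=mcmc.warmup)  # (steps, walkers, dim)
    theta = chain.reshape(-1, post.ndim)
    mu_d, tau_d, alpha_d, nu_d, log_sig_d = post.unpack(theta)

    # diagnostics: walkers as chains
    names = ["mu", "tau"] + (
        ["alpha", "nu_df"] if spec.effects_family == "skew_t" else []
    )
    diag = {}
    warnings_list = []
    per_param = {
        "mu": chain[:, :, 0],
        "tau": chain[:, :, 1],
    }
    if spec.effects_family == "skew_t":
        per_param["alpha"] = chain[:, :, 2]
        per_param["nu_df"] = spec.nu_df_min + np.exp(chain[:, :, 3])
    for name, arr in per_param.items():
        da = az.convert_to_dataset(np.swapaxes(arr, 0, 1))  # (chain, draw)
        rhat = float(az.rhat(da)["x"].values)
        ess = float(az.ess(da)["x"].values)
        diag[name] = {"rhat": rhat, "ess_bulk": ess}
    bad = {k: v for k, v in diag.items() if k in ("mu", "tau")}
    worst = max(v["rhat"] for v in bad.values())
    if worst > mcmc.rhat_fail:
        raise ConvergenceError(f"MCMC did not converge: {diag}")
    if worst > mcmc.rhat_warn or any(
        v["ess_bulk"] < mcmc.ess_min for v in bad.values()
    ):
        msg = f"convergence warning for {study.name}: {diag}"
        warnings_list.append(msg)
        warnings.warn(msg, RuntimeWarning)

    # per-lab conditional summaries of lambda_j and sigma_j
    lam_summ, sig_summ = _lambda_sigma_summaries(
        post, mu_d, tau_d, alpha_d, nu_d, log_sig_d, study
    )

    kcrv = float(mu_d.mean())
    sd = float(mu_d.std(ddof=1))
    method = f"hier_{spec.effects_family}_gauss"
    tau_summary = _summ(tau_d)
    draws = {"mu": mu_d, "tau": tau_d}
    if alpha_d is not None:
        draws["alpha"] = alpha_d
        draws["nu_df"] = nu_d
    if post.n_finite:
        sig_full = np.broadcast_to(post.u, (len(mu_d), len(post.u))).copy()
        sig_full[:, post.finite] = np.exp(log_sig_d)
        draws["sigma"] = sig_full

    summary = PosteriorSummary(
        mu=_summ(mu_d),
        tau=tau_summary,
        lambda_=lam_summ,
        sigma=sig_summ,
        alpha=_summ(alpha_d) if alpha_d is not None else None,
        nu_df=_summ(nu_d) if nu_d is not None else None,
        diagnostics={**diag, "warnings": warnings_list},
    )
    consensus = ConsensusResult(
        kcrv=kcrv,
        std_unc=sd,
        method=method,
        unit=study.unit,
        tau=TauEstimate(
            tau_hat=tau_summary["mean"],
            ci_low=tau_summary["q0.025"],
            ci_high=tau_summary["q0.975"],
            ci_level=0.95,
            method="posterior",
        ),
        draws=draws,
        n_draws=len(mu_d),
        seed=mcmc.seed,
        details={"labs": study.labs(), "effects_family": spec.effects_family},
    )
    return consensus, summary


def _lambda_sigma_summaries(post, mu_d, tau_d, alpha_d, nu_d, log_sig_d, study):
    """Conditional posterior mean/sd of lambda_j (and sigma_j) per lab.

    Uses a thinned subsample of the joint draws; lambda_j given the
    hyperparameters has a closed form for Gaussian effects and is computed
    by quadrature on Gaussian-error nodes otherwise.
    """
    take = np.linspace(0, len(mu_d) - 1, min(400, len(mu_d))).astype(int)
    mu_s, tau_s = mu_d[take], tau_d[take]
    n = len(post.x)
    sigma = np.broadcast_to(post.u, (len(take), n)).copy()
    if post.n_finite:
        sigma[:, post.finite] = np.exp(log_sig_d[take])
    d = post.x - mu_s[:, None]
    if post.family == "gauss":
        shrink = tau_s[:, None] ** 2 / (tau_s[:, None] ** 2 + sigma**2)
        cond_mean = shrink * d
        cond_var = shrink * sigma**2
    else:
        lam = d[..., None] + _SQRT2 * sigma[..., None] * _gh_x
        if post.family == "laplace":
            b = tau_s[:, None, None] / _SQRT2
            logg = -np.abs(lam) / b - np.log(2.0 * b)
        else:
            a_s = alpha_d[take][:, None, None]
            nu_s = nu_d[take][:, None, None]
            sd = skew_t_sd_factor(a_s, nu_s)
            omega = tau_s[:, None, None] / sd
            delta = a_s / np.sqrt(1 + a_s**2)
            xi = -omega * delta * _b_nu(nu_s)
            logg = _skew_t_logpdf_std((lam - xi) / omega, a_s, nu_s) - np.log(omega)
        wts = np.exp(logg - logg.max(axis=-1, keepdims=True)) * _gh_w
        wts /= wts.sum(axis=-1, keepdims=True)
        cond_mean = (wts * lam).sum(axis=-1)
        cond_var = (wts * lam**2).sum(axis=-1) - cond_mean**2
    # law of total variance across hyperparameter draws
    lam_mean = cond_mean.mean(axis=0)
    lam_sd = np.sqrt(cond_var.mean(axis=0) + cond_mean.var(axis=0))
    labs = study.labs()
    lam_summ = [
        {"lab": labs[j], "mean": float(lam_mean[j]), "sd": float(lam_sd[j])}
        for j in range(n)
    ]
    sig_summ = [
        {
            "lab": labs[j],
            "mean": float(sigma[:, j].mean()),
            "sd": float(sigma[:, j].std(ddof=1)) if post.finite[j] else 0.0,
        }
        for j in range(n)
    ]
    return lam_summ, sig_summ


def fit_hier_gauss_gauss(study, spec=None, mcmc=None):
    """Hierarchical Gauss + Gauss fit (Gaussian lab effects)."""
    spec = spec or HierModelSpec(effects_family="gauss")
    if spec.effects_family != "gauss":
        raise ValueError("spec.effects_family must be 'gauss'")
    return fit_hierarchical(study, spec, mcmc)


def fit_hier_laplace_gauss(study, spec=None, mcmc=None):
    """Hierarchical Laplace + Gauss fit (heavy-tailed lab effects)."""
    spec = spec or HierModelSpec(effects_family="laplace")
    if spec.effects_family != "laplace":
        raise ValueError("spec.effects_family must be 'laplace'")
    return fit_hierarchical(study, spec, mcmc)


def fit_hier_skew_t_gauss(study, spec=None, mcmc=None):
    """Hierarchical Skew Student + Gauss fit (asymmetric lab effects)."""
    spec = spec or HierModelSpec(effects_family="skew_t")
    if spec.effects_family != "skew_t":
        raise ValueError("spec.effects_family must be 'skew_t'")
    return fit_hierarchical(study, spec, mcmc)
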