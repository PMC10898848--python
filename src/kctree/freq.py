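"""Non-Bayesian consensus estimators: adaptive weighted average and weighted median.

The adaptive weighted average is the DerSimonian-Laird procedure: weights
1/(u_j^2 + tau_hat^2) with tau_hat from the DL moment estimator, so it
collapses to the plain weighted mean when tau_hat = 0.  Its uncertainty is
evaluated by a parametric bootstrap that honors finite degrees of freedom:
each replicate redraws lab effects with sd tau_hat, redraws each error
scale as u_j * sqrt(nu_j / chi2_nu_j) when nu_j is finite, and re-runs the
whole DL estimation, so the spread of replicate means carries the
uncertainty of tau_hat itself.

The weighted median (weights proportional to 1/u_j^2) is the robust
consensus under Laplace-error assumptions; its uncertainty and bootstrap
bias correction come from either a nonparametric bootstrap (resampling
(x_j, u_j) pairs) or a parametric one, chosen by sample size in auto mode.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .consistency import dersimonian_laird_tau, weighted_mean
from .data import KCStudy
from .results import ConsensusResult

__all__ = [
    "adaptive_weighted_average",
    "weighted_median_point",
    "weighted_median_consensus",
]

AWA = "adaptive_weighted_average"
WMEDIAN = "weighted_median"


def _dl_mean(x: np.ndarray, u: np.ndarray) -> tuple[float, float]:
    """DerSimonian-Laird tau and the corresponding weighted mean, on arrays."""
    w = 1.0 / u**2
    s1 = w.sum()
    s2 = (w**2).sum()
    xbar = (w * x).sum() / s1
    q = (w * (x - xbar) ** 2).sum()
    denom = s1 - s2 / s1
    tau2 = max(0.0, (q - (len(x) - 1)) / denom) if denom > 0 else 0.0
    wa = 1.0 / (u**2 + tau2)
    return math.sqrt(tau2), float((wa * x).sum() / wa.sum())


def adaptive_weighted_average(
    study: KCStudy, n_boot: int = 5000, seed: int | None = None
) -> ConsensusResult:
    """DerSimonian-Laird adaptive weighted average with parametric bootstrap.

    Returns a :class:`ConsensusResult` whose ``std_unc`` is the larger of
    the bootstrap standard deviation and the internal (fixed-effects)
    standard uncertainty, and whose ``draws`` retain the replicate means,
    replicate tau estimates, and the simulated per-lab values needed for
    the degrees of equivalence.
    """
    if study.n_included < 2:
        raise ValueError("adaptive_weighted_average requires >= 2 included results")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    x, u, nu = study.arrays(included_only=True)
    n = len(x)
    tau_est = dersimonian_laird_tau(study)
    tau = tau_est.tau_hat
    wm = weighted_mean(study, tau=tau)
    kcrv = wm.estimate
    internal = weighted_mean(study, tau=0.0).internal_std_unc

    rng = np.random.default_rng(seed)
    lam = rng.normal(0.0, tau, size=(n_boot, n)) if tau > 0 else np.zeros((n_boot, n))
    sigma = np.broadcast_to(u, (n_boot, n)).copy()
    finite = np.isfinite(nu)
    if finite.any():
        chi2 = rng.chisquare(nu[finite], size=(n_boot, finite.sum()))
        sigma[:, finite] = u[finite] * np.sqrt(nu[finite] / chi2)
    eps = rng.normal(0.0, 1.0, size=(n_boot, n)) * sigma
    x_rep = kcrv + lam + eps

    # re-run DL on each replicate (weights from reported u_j)
    w = 1.0 / u**2
    s1, s2 = w.sum(), (w**2).sum()
    xbar_rep = (x_rep * w).sum(axis=1) / s1
    q_rep = (w * (x_rep - xbar_rep[:, None]) ** 2).sum(axis=1)
    tau2_rep = np.maximum(0.0, (q_rep - (n - 1)) / (s1 - s2 / s1))
    wa = 1.0 / (u**2 + tau2_rep[:, None])
    mu_rep = (wa * x_rep).sum(axis=1) / wa.sum(axis=1)

    boot_sd = float(mu_rep.std(ddof=1))
    return ConsensusResult(
        kcrv=kcrv,
        std_unc=max(boot_sd, internal),
        method=AWA,
        unit=study.unit,
        tau=tau_est,
        draws={
            "mu": mu_rep,
            "tau": np.sqrt(tau2_rep),
            "x_rep": x_rep,
        },
        n_draws=n_boot,
        seed=seed,
        details={
            "internal_std_unc": internal,
            "bootstrap_std_unc": boot_sd,
            "labs": study.labs(),
        },
    )


def weighted_median_point(x, w, interpolate: bool = False) -> float:
    """Weighted median of x with positive weights w.

    With ``interpolate=False`` (default) this is the exact minimizer of
    sum w_j |x_j - m|: sort by x, accumulate normalized weights, and return
    the first x_k at which the cumulative weight reaches 1/2 (the midpoint
    of x_k and x_{k+1} if it hits 1/2 exactly).  With ``interpolate=True``
    the centered weighted ECDF (mass points at (cum_k - w_k/2)/W) is
    linearly interpolated at probability 1/2, which is unbiased on
    symmetric samples; the two conventions agree up to a fraction of the
    gap around the crossing point.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size == 0:
        raise ValueError("weighted_median_point: empty input")
    if x.shape != w.shape:
        raise ValueError("x and w must have the same length")
    if not (w > 0).all():
        raise ValueError("weights must be positive")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ws = w[order] / w.sum()
    cum = np.cumsum(ws)
    if interpolate:
        return float(np.interp(0.5, cum - 0.5 * ws, xs))
    k = int(np.searchsorted(cum, 0.5))
    if k >= len(xs):  # numerical guard
        return float(xs[-1])
    if abs(cum[k] - 0.5) <= 1e-12 and k + 1 < len(xs):
        return float(0.5 * (xs[k] + xs[k + 1]))
    return float(xs[k])


def _wmedian_rows(x_rows: np.ndarray, w_rows: np.ndarray) -> np.ndarray:
    """Row-wise centered-ECDF interpolating weighted medians (bootstrap workhorse)."""
    order = np.argsort(x_rows, axis=1, kind="stable")
    xs = np.take_along_axis(x_rows, order, axis=1)
    ws = np.take_along_axis(w_rows, order, axis=1)
    cum = np.cumsum(ws, axis=1)
    cum = (cum - 0.5 * ws) / cum[:, -1:]
    k = (cum < 0.5).sum(axis=1)  # first index with cum >= 0.5
    k = np.minimum(k, xs.shape[1] - 1)
    rows = np.arange(xs.shape[0])
    med = xs[rows, k]
    prev = k > 0
    kp = np.maximum(k - 1, 0)
    f0, f1 = cum[rows, kp], cum[rows, k]
    x0, x1 = xs[rows, kp], xs[rows, k]
    frac = np.where(f1 > f0, (0.5 - f0) / np.where(f1 > f0, f1 - f0, 1.0), 1.0)
    interp = x0 + frac * (x1 - x0)
    return np.where(prev, interp, med)


def weighted_median_consensus(
    study: KCStudy,
    n_boot: int = 5000,
    seed: int | None = None,
    bootstrap: str = "auto",
) -> ConsensusResult:
    """Weighted median consensus with bootstrap uncertainty and bias correction.

    ``bootstrap`` is ``nonparametric`` (resample (x_j, u_j) pairs with
    replacement), ``parametric`` (redraw x_j around the point estimate with
    scale u_j, Student-t when nu_j is finite), or ``auto`` (nonparametric
    for n >= 15 participants, parametric below).  The reported consensus is
    the bootstrap-smoothed (bagged) estimate, i.e. the mean of the
    replicate interpolated weighted medians, which removes the order-
    statistic bias of the raw weighted median; the standard uncertainty is
    the sd of the replicate medians.
    """
    if bootstrap not in {"auto", "parametric", "nonparametric"}:
        raise ValueError(f"unknown bootstrap mode {bootstrap!r}")
    x, u, nu = study.arrays(included_only=True)
    n = len(x)
    if bootstrap == "auto":
        bootstrap = "nonparametric" if n >= 15 else "parametric"
    n_min = 5 if bootstrap == "nonparametric" else 2
    if n < n_min:
        raise ValueError(f"{bootstrap} bootstrap requires >= {n_min} included results")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")

    w = 1.0 / u**2
    m_hat = weighted_median_point(x, w, interpolate=True)
    rng = np.random.default_rng(seed)
    if bootstrap == "nonparametric":
        idx = rng.integers(0, n, size=(n_boot, n))
        m_rep = _wmedian_rows(x[idx], w[idx])
    else:
        finite = np.isfinite(nu)
        z = rng.standard_normal((n_boot, n))
        if finite.any():
            z[:, finite] = rng.standard_t(nu[finite], size=(n_boot, finite.sum()))
        x_rep = m_hat + z * u
        m_rep = _wmedian_rows(x_rep, np.broadcast_to(w, (n_boot, n)))

    boot_sd = float(m_rep.std(ddof=1))
    if boot_sd == 0.0:
        warnings.warn(
            "weighted-median bootstrap is degenerate (all replicates identical); "
            "reported std_unc is 0",
            RuntimeWarning,
        )
    kcrv = float(m_rep.mean())
    return ConsensusResult(
        kcrv=kcrv,
        std_unc=boot_sd if boot_sd > 0 else np.finfo(float).tiny,
        method=WMEDIAN,
        unit=study.unit,
        tau=None,
        draws={"mu": m_rep},
        n_draws=n_boot,
        seed=seed,
        details={
            "point_estimate": m_hat,
            "bias_correction": kcrv - m_hat,
            "bootstrap": bootstrap,
            "labs": study.labs(),
        },
    )
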