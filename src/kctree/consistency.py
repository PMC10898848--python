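"""Mutual-consistency (homogeneity) assessment.

Under the common-mean model the measured values scatter around the
consensus no more than their reported uncertainties allow.  Cochran's Q
statistic, Q = sum w_j (x_j - xbar_w)^2 with w_j = 1/u_j^2, is referred to
a chi-squared distribution on n-1 degrees of freedom to test this.  Excess
dispersion ("dark uncertainty") is quantified by the between-laboratory
standard deviation tau, estimated here by the DerSimonian-Laird moment
estimator, with a Q-profile confidence interval obtained by inverting the
generalized statistic Q(tau) = sum (x_j - xbar_w(tau))^2 / (u_j^2 + tau^2),
which decreases monotonically in tau.

All operations act on the included subset only: exclusion of a participant
is a substantive decision made upstream of the statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .data import KCStudy
from .results import TestOutcome

__all__ = [
    "WeightedMean",
    "TauEstimate",
    "weighted_mean",
    "cochran_q",
    "dersimonian_laird_tau",
    "tau_qprofile_ci",
    "generalized_q",
]


class WeightedMean(NamedTuple):
    estimate: float
    internal_std_unc: float
    weights: np.ndarray  # normalized to sum 1


@dataclass(frozen=True)
class TauEstimate:
    """Point estimate and (optionally) a confidence interval for tau."""

    tau_hat: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None
    method: str = "DL"

    def __post_init__(self) -> None:
        if self.tau_hat < 0:
            raise ValueError("tau_hat must be >= 0")
        if self.ci_low is not None and self.ci_high is not None:
            if not (0 <= self.ci_low <= self.ci_high):
                raise ValueError("require 0 <= ci_low <= ci_high")

    def to_dict(self) -> dict:
        return {
            "tau_hat": float(self.tau_hat),
            "ci_low": None if self.ci_low is None else float(self.ci_low),
            "ci_high": None if self.ci_high is None else float(self.ci_high),
            "ci_level": self.ci_level,
            "method": self.method,
        }


def _require_included(study: KCStudy, n_min: int, what: str):
    if study.n_included < n_min:
        raise ValueError(
            f"{what} requires at least {n_min} included results; "
            f"{study.name!r} has {study.n_included}"
        )
    return study.arrays(included_only=True)


def weighted_mean(study: KCStudy, tau: float = 0.0) -> WeightedMean:
    """Weighted average with weights proportional to 1/(u_j^2 + tau^2).

    With tau=0 this is the classical fixed-effects weighted mean whose
    internal standard uncertainty is (sum 1/u_j^2)^(-1/2); with the
    DerSimonian-Laird tau it becomes the adaptive weighted average.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    x, u, _ = _require_included(study, 2, "weighted_mean")
    w = 1.0 / (u**2 + tau**2)
    total = w.sum()
    w_norm = w / total
    est = float(w_norm @ x)
    return WeightedMean(est, float(total**-0.5), w_norm)


def cochran_q(study: KCStudy, size: float = 0.10) -> TestOutcome:
    """Cochran's Q test of mutual consistency on the included results."""
    x, u, _ = _require_included(study, 2, "cochran_q")
    w = 1.0 / u**2
    xbar = float((w * x).sum() / w.sum())
    q = float((w * (x - xbar) ** 2).sum())
    dof = len(x) - 1
    p = float(stats.chi2.sf(q, dof))
    return TestOutcome("cochran_q", q, p, size, dof=dof)


def dersimonian_laird_tau(study: KCStudy) -> TauEstimate:
    """DerSimonian-Laird moment estimate of the dark-uncertainty sd tau.

    tau^2 = max(0, (Q - (n-1)) / (S1 - S2/S1)) with S1 = sum w_j,
    S2 = sum w_j^2, w_j = 1/u_j^2.  The truncation at zero makes the
    adaptive weighted average collapse to the plain weighted mean whenever
    Q does not exceed its null expectation.
    """
    x, u, _ = _require_included(study, 2, "dersimonian_laird_tau")
    w = 1.0 / u**2
    s1 = w.sum()
    s2 = (w**2).sum()
    xbar = float((w * x).sum() / s1)
    q = float((w * (x - xbar) ** 2).sum())
    denom = s1 - s2 / s1
    tau2 = max(0.0, (q - (len(x) - 1)) / denom) if denom > 0 else 0.0
    return TauEstimate(math.sqrt(tau2), method="DL")


def generalized_q(study: KCStudy, tau: float) -> float:
    """Q(tau) = sum (x_j - xbar_w(tau))^2 / (u_j^2 + tau^2), included labs."""
    x, u, _ = study.arrays(included_only=True)
    v = u**2 + tau**2
    w = 1.0 / v
    xbar = float((w * x).sum() / w.sum())
    return float(((x - xbar) ** 2 / v).sum())


def tau_qprofile_ci(study: KCStudy, level: float = 0.95) -> TauEstimate:
    """Q-profile confidence interval for tau.

    The bounds are the tau values at which Q(tau) crosses the upper and
    lower chi-squared quantiles on n-1 dof; Q(tau) is strictly decreasing,
    so each crossing is found by monotone root bracketing.  The lower bound
    is truncated at zero, and the upper bound is zero when even Q(0) falls
    below the lower quantile (no dispersion at all).  The point estimate
    reported alongside is the profile's own matching point, the tau at
    which Q(tau) equals its null expectation n-1; it always lies inside
    the interval (the DerSimonian-Laird tau need not, because it keeps the
    fixed-effects weights).
    """
    x, u, _ = _require_included(study, 3, "tau_qprofile_ci")
    if not (0 < level < 1):
        raise ValueError("level must be in (0,1)")
    n = len(x)
    alpha = 1.0 - level
    q_hi = stats.chi2.ppf(1 - alpha / 2, n - 1)  # crossing -> lower bound
    q_lo = stats.chi2.ppf(alpha / 2, n - 1)  # crossing -> upper bound
    qfun = lambda t: generalized_q(study, t)

    def solve(target: float) -> float:
        f = lambda t: qfun(t) - target
        if f(0.0) <= 0:
            return 0.0
        hi = 100.0 * float(u.max())
        for _ in range(8):
            if f(hi) < 0:
                break
            hi *= 10.0
        else:
            raise RuntimeError(
                f"Q-profile bracketing failed for target {target:.4g}"
            )
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-8))

    lo = solve(q_hi)
    hi = solve(q_lo)
    point = solve(float(n - 1))
    return TauEstimate(
        tau_hat=point, ci_low=lo, ci_high=hi, ci_level=level, method="Q-profile"
    )
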