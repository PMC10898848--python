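"""Unilateral degrees of equivalence with dark-uncertainty propagation.

A participant's degree of equivalence is D_j = x_j - KCRV together with an
expanded uncertainty U95(D_j) at 95 % coverage.  The U95 are evaluated
predictively: a replicate deviation d*_j is simulated by drawing a fresh
lab effect lambda* from the fitted effects distribution and a fresh error
eps* at the lab's error scale, so |D_j| > U95 flags results that lie
beyond the range the fitted model allows — which is the question the DoE
is meant to answer.  Dark uncertainty therefore widens every interval, and
the correlation between an included lab's result and the consensus is
carried automatically: for included labs the replicate consensus is
recomputed from (or drawn jointly with) the replicate data, while for
excluded labs the consensus uncertainty enters in full with no
correlation credit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import sample_skew_t_effects
from .data import KCStudy
from .freq import AWA, WMEDIAN, _wmedian_rows
from .results import ConsensusResult

__all__ = ["DoEEntry", "DoETable", "compute_does", "doe_plot_data"]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class DoEEntry:
    lab: str
    D: float
    U95: float
    included: bool

    @property
    def significant(self) -> bool:
        return abs(self.D) > self.U95


@dataclass
class DoETable:
    entries: list[DoEEntry]
    method: str
    n_draws: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lab": [e.lab for e in self.entries],
                "D": [e.D for e in self.entries],
                "U95": [e.U95 for e in self.entries],
                "included": [e.included for e in self.entries],
                "significant": [e.significant for e in self.entries],
            }
        )


def _effect_draws(rng, method, tau, alpha, nu_df, size):
    """Fresh lab-effect draws matching the fitted effects family."""
    if method == AWA or method.endswith("gauss_gauss"):
        return rng.normal(0.0, 1.0, size) * tau
    if method.endswith("laplace_gauss"):
        return rng.laplace(0.0, 1.0, size) * tau / _SQRT2
    if method.endswith("skew_t_gauss"):
        return sample_skew_t_effects(rng, tau, alpha, nu_df, size)
    raise ValueError(f"unknown method {method!r}")


def compute_does(
    study: KCStudy,
    consensus: ConsensusResult,
    n_rep: int = 10000,
    seed: int | None = None,
) -> DoETable:
    """Degrees of equivalence for all N participants of a study.

    ``consensus`` must carry Monte Carlo draws (bootstrap replicates or
    posterior draws); re-run the estimator with draws retained otherwise.
    U95 is the symmetric half-width of the equal-tailed 95 % interval of
    the replicate deviations.
    """
    if not consensus.draws or "mu" not in consensus.draws:
        raise ValueError(
            "consensus result carries no Monte Carlo draws; re-run the "
            "estimation with draws retained before computing DoEs"
        )
    rng = np.random.default_rng(seed)
    mu_draws = np.asarray(consensus.draws["mu"], dtype=float)
    idx = rng.integers(0, len(mu_draws), size=n_rep)
    kcrv = consensus.kcrv
    x_all, u_all, nu_all = study.arrays(included_only=False)
    included = np.array([r.include_in_kcrv for r in study.results])
    labs = study.labs(included_only=False)
    n_inc = int(included.sum())

    method = consensus.method
    mu_r = mu_draws[idx]

    if method == WMEDIAN:
        # parametric predictive: rebuild a pseudo-study around the KCRV,
        # recompute the weighted median from its included labs
        d_rep = _wmedian_predictive(
            rng, kcrv, x_all, u_all, nu_all, included, n_rep
        )
    else:
        if method == AWA:
            tau_r = np.asarray(consensus.draws["tau"], dtype=float)[idx]
            alpha_r = nu_r = None
            x_rep = np.asarray(consensus.draws["x_rep"], dtype=float)[idx]
        else:
            tau_r = np.asarray(consensus.draws["tau"], dtype=float)[idx]
            alpha_r = (
                np.asarray(consensus.draws["alpha"], dtype=float)[idx]
                if "alpha" in consensus.draws
                else None
            )
            nu_r = (
                np.asarray(consensus.draws["nu_df"], dtype=float)[idx]
                if "nu_df" in consensus.draws
                else None
            )
            x_rep = None
        sigma_draws = consensus.draws.get("sigma")

        d_rep = np.empty((n_rep, study.N))
        inc_pos = 0
        for j in range(study.N):
            if method == AWA and included[j]:
                # replicate data and replicate consensus share the draw:
                # the estimator-datum correlation is carried exactly
                d_rep[:, j] = x_rep[:, inc_pos] - mu_r
                inc_pos += 1
                continue
            lam = _broadcast_effects(rng, method, tau_r, alpha_r, nu_r, n_rep)
            sig_j = _sigma_for_lab(
                rng, j, u_all, nu_all, included, sigma_draws, idx, n_rep
            )
            eps = rng.normal(0.0, 1.0, n_rep) * sig_j
            if included[j]:
                # Bayesian leaves: x*_j = mu* + lam + eps, consensus = mu*
                d_rep[:, j] = lam + eps
                inc_pos += 1
            else:
                # no correlation credit: consensus uncertainty enters fully
                d_rep[:, j] = (kcrv + lam + eps) - mu_r

    lo = np.percentile(d_rep, 2.5, axis=0)
    hi = np.percentile(d_rep, 97.5, axis=0)
    u95 = 0.5 * (hi - lo)
    entries = [
        DoEEntry(
            lab=labs[j],
            D=float(x_all[j] - kcrv),
            U95=float(u95[j]),
            included=bool(included[j]),
        )
        for j in range(study.N)
    ]
    return DoETable(entries=entries, method=method, n_draws=n_rep)


def _broadcast_effects(rng, method, tau_r, alpha_r, nu_r, n_rep):
    if method.endswith("skew_t_gauss"):
        return sample_skew_t_effects(rng, tau_r, alpha_r, nu_r, n_rep)
    return _effect_draws(rng, method, tau_r, None, None, n_rep)


def _sigma_for_lab(rng, j, u_all, nu_all, included, sigma_draws, idx, n_rep):
    """Per-replicate error scale for lab j, honoring finite dof."""
    if sigma_draws is not None and included[j]:
        inc_idx = np.where(included)[0].tolist().index(j)
        return np.asarray(sigma_draws, dtype=float)[idx, inc_idx]
    if math.isfinite(nu_all[j]):
        chi2 = rng.chisquare(nu_all[j], n_rep)
        return u_all[j] * np.sqrt(nu_all[j] / chi2)
    return np.full(n_rep, u_all[j])


def _wmedian_predictive(rng, kcrv, x_all, u_all, nu_all, included, n_rep):
    """Monte Carlo DoE deviations for the weighted-median leaf.

    Simulates pseudo-studies x**_j = kcrv + eps_j for every participant,
    recomputes the interpolated weighted median from the included columns
    of each pseudo-study, and returns x**_j minus that replicate median.
    """
    N = len(x_all)
    z = rng.standard_normal((n_rep, N))
    finite = np.isfinite(nu_all)
    if finite.any():
        z[:, finite] = rng.standard_t(nu_all[finite], size=(n_rep, int(finite.sum())))
    x_star = kcrv + z * u_all
    w_inc = 1.0 / u_all[included] ** 2
    m_star = _wmedian_rows(
        x_star[:, included], np.broadcast_to(w_inc, (n_rep, int(included.sum())))
    )
    return x_star - m_star[:, None]


def doe_plot_data(table: DoETable) -> pd.DataFrame:
    """Ordered plotting frame (lab, D, lower, upper, included, significant)."""
    if not table.entries:
        raise ValueError("empty DoE table")
    df = table.to_frame()
    df["lower"] = df["D"] - df["U95"]
    df["upper"] = df["D"] + df["U95"]
    return df[["lab", "D", "lower", "upper", "U95", "included", "significant"]]
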