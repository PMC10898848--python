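"""Synthetic key-comparison generator.

Generates studies from the random-effects model x_j = mu + lambda_j +
eps_j, one generative mode per leaf of the tree: no effects (homogeneous
common-mean data), Gaussian, Laplace, or mean-zero skew-t effects, always
scaled so the effects' sd equals tau_true.  Reported uncertainties are
drawn log-uniformly over ``u_range`` to mimic the order-of-magnitude
spread seen in real comparisons, which stresses the weighting code.
Under a finite-dof policy the reported u_j are themselves noisy
(chi-squared) estimates of the true error scales, as they would be in
practice.  A truth record retains every latent quantity for parameter-
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bayes import sample_skew_t_effects
from .data import KCStudy, MeasurementResult

__all__ = ["SynthConfig", "generate_kc"]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the generative model.

    ``dof_policy`` is ``all_infinite``, ``("all_finite", nu)``, or
    ``"mixed"`` (each lab infinite with probability 1/2, otherwise a dof
    drawn uniformly from 4..30).
    """

    n_labs: int = 15
    mu_true: float = 100.0
    tau_true: float = 0.0
    effects_family: str = "none"  # none | gauss | laplace | skew_t
    alpha_true: float = 0.0
    nu_df_true: float = 10.0
    u_range: tuple[float, float] = (0.5, 2.0)
    dof_policy: object = "all_infinite"
    seed: int | None = None
    name: str = "synthetic"
    unit: str = "a.u."

    def __post_init__(self) -> None:
        if self.n_labs < 2:
            raise ValueError("n_labs must be >= 2")
        if self.effects_family not in {"none", "gauss", "laplace", "skew_t"}:
            raise ValueError(f"unknown effects family {self.effects_family!r}")
        if self.tau_true < 0:
            raise ValueError("tau_true must be >= 0")
        if self.effects_family == "none" and self.tau_true != 0:
            raise ValueError("tau_true must be 0 when effects_family='none'")
        lo, hi = self.u_range
        if not (0 < lo <= hi):
            raise ValueError("u_range must be positive with low <= high")
        if self.effects_family == "skew_t" and self.nu_df_true <= 2:
            raise ValueError("nu_df_true must exceed 2 (effects sd must exist)")


def _draw_effects(rng, cfg: SynthConfig, n: int) -> np.ndarray:
    tau = cfg.tau_true
    if cfg.effects_family == "none" or tau == 0.0:
        return np.zeros(n)
    if cfg.effects_family == "gauss":
        return rng.normal(0.0, tau, n)
    if cfg.effects_family == "laplace":
        return rng.laplace(0.0, tau / _SQRT2, n)
    return sample_skew_t_effects(rng, tau, cfg.alpha_true, cfg.nu_df_true, n)


def generate_kc(config: SynthConfig) -> tuple[KCStudy, dict]:
    """Generate one synthetic study plus its truth record."""
    rng = np.random.default_rng(config.seed)
    n = config.n_labs
    lo, hi = config.u_range
    sigma = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    lam = _draw_effects(rng, config, n)
    eps = rng.normal(0.0, sigma)
    x = config.mu_true + lam + eps

    policy = config.dof_policy
    if policy == "all_infinite":
        dof = np.full(n, math.inf)
    elif policy == "mixed":
        dof = np.where(
            rng.random(n) < 0.5, math.inf, rng.integers(4, 31, n).astype(float)
        )
    elif isinstance(policy, tuple) and policy[0] == "all_finite":
        dof = np.full(n, float(policy[1]))
    else:
        raise ValueError(f"unknown dof_policy {policy!r}")

    u = sigma.copy()
    finite = np.isfinite(dof)
    if finite.any():
        chi2 = rng.chisquare(dof[finite])
        u[finite] = sigma[finite] * np.sqrt(chi2 / dof[finite])

    results = tuple(
        MeasurementResult(
            lab=f"LAB{j + 1:02d}",
            value=float(x[j]),
            std_unc=float(u[j]),
            dof=float(dof[j]),
            include_in_kcrv=True,
        )
        for j in range(n)
    )
    study = KCStudy(config.name, config.unit, results)
    truth = {
        "mu_true": config.mu_true,
        "tau_true": config.tau_true,
        "effects_family": config.effects_family,
        "alpha_true": config.alpha_true,
        "nu_df_true": config.nu_df_true,
        "lambda": lam.tolist(),
        "eps": eps.tolist(),
        "sigma": sigma.tolist(),
        "dof": ["inf" if math.isinf(d) else d for d in dof],
        "seed": config.seed,
    }
    return study, truth
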