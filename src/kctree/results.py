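"""Shared result containers: test outcomes and consensus estimates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = ["TestOutcome", "ConsensusResult"]


@dataclass(frozen=True)
class TestOutcome:
    """Outcome of one gating statistical test.

    ``reject`` is True exactly when ``p_value < size`` (a tie at the nominal
    size does not reject).  ``extras`` carries test-specific detail, e.g. the
    individual Shapiro-Wilk and Anderson-Darling p-values in auto mode, or
    the bootstrap settings of the symmetry test.
    """

    test_name: str
    statistic: float
    p_value: float
    size: float
    dof: int | None = None
    extras: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")
        if not (0.0 < self.size < 1.0):
            raise ValueError(f"test size out of (0,1): {self.size}")

    @property
    def reject(self) -> bool:
        return self.p_value < self.size

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": float(self.statistic),
            "dof": self.dof,
            "p_value": float(self.p_value),
            "size": float(self.size),
            "reject": bool(self.reject),
            "extras": {k: _jsonable(v) for k, v in self.extras.items()},
        }


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


@dataclass
class ConsensusResult:
    """A consensus value (KCRV), its standard uncertainty, and the Monte
    Carlo material needed to propagate dark uncertainty into the DoEs.

    ``draws`` holds named replicate arrays: at minimum ``mu`` (replicate
    consensus values, i.e. bootstrap means/medians or posterior draws of the
    true value); estimator-specific entries (``tau``, ``alpha``, ``nu``,
    ``x_rep``, ``sigma``) are present when the method produces them.
    """

    kcrv: float
    std_unc: float
    method: str
    unit: str = ""
    tau: Any = None
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    n_draws: int = 0
    seed: int | None = None
    details: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.std_unc > 0):
            raise ValueError(f"std_unc must be > 0, got {self.std_unc}")

    def to_dict(self, include_draws: bool = True) -> dict:
        out = {
            "kcrv": float(self.kcrv),
            "std_unc": float(self.std_unc),
            "method": self.method,
            "unit": self.unit,
            "tau": _tau_dict(self.tau),
            "n_draws": int(self.n_draws),
            "seed": self.seed,
            "details": {k: _jsonable(v) for k, v in self.details.items()},
        }
        if include_draws:
            out["draws"] = {k: np.asarray(v).tolist() for k, v in self.draws.items()}
        return out


def _tau_dict(tau):
    if tau is None:
        return None
    if hasattr(tau, "to_dict"):
        return tau.to_dict()
    if isinstance(tau, Mapping):
        return {k: _jsonable(v) for k, v in tau.items()}
    return _jsonable(tau)
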