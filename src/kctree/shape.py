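"""Distributional-shape tests: symmetry about the median and Gaussian shape.

Symmetry is tested on the raw measured values with the Miao-Gel-Gastwirth
statistic T = (mean - median) / J, where J = sqrt(pi/2) * mean|x - median|
is a consistent estimate of the standard deviation under normality.  The
null reference distribution is built by a reflection bootstrap: the
deviations from the sample mean keep their magnitudes |x_j - mean(x)| and
receive independent random signs in each replicate, which symmetrizes the
sample while preserving its spread pattern.  No large-sample approximation
is involved; the p-value is the fraction of replicate |T| at least as
large as the observed |T|.

Gaussian shape is tested on the *roughly standardized* values
z_j = (x_j - median(x)) / u_j, which remove both location and the
lab-specific scales before asking whether the configuration looks like a
Gaussian sample.  Shapiro-Wilk works from n = 3; the Anderson-Darling
implementation requires n >= 8.  In ``auto`` mode both run when possible
and the smaller p-value decides, which mirrors using whichever test is
able to sound the alarm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .data import KCStudy
from .results import TestOutcome

__all__ = [
    "StandardizedSample",
    "standardize",
    "mgg_statistic",
    "symmetry_test",
    "gaussian_shape_test",
]

_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


@dataclass(frozen=True)
class StandardizedSample:
    """Roughly standardized values (x_j - median x)/u_j over included labs."""

    z: np.ndarray
    source_labs: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.z)


def standardize(study: KCStudy) -> StandardizedSample:
    if study.n_included < 3:
        raise ValueError("standardize requires at least 3 included results")
    x, u, _ = study.arrays(included_only=True)
    m = np.median(x)
    return StandardizedSample(z=(x - m) / u, source_labs=tuple(study.labs()))


def mgg_statistic(x) -> float:
    """Signed Miao-Gel-Gastwirth symmetry statistic (positive = right skew).

    Defined as (mean - median) / J with J = sqrt(pi/2) * mean|x - median|;
    a degenerate all-equal sample yields T = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("mgg_statistic requires at least 3 values")
    m = np.median(x)
    j = _SQRT_HALF_PI * np.mean(np.abs(x - m))
    if j == 0.0:
        return 0.0
    return float((np.mean(x) - m) / j)


def _mgg_rows(samples: np.ndarray) -> np.ndarray:
    """Vectorized |T| over rows of a 2-D array of bootstrap samples."""
    med = np.median(samples, axis=1, keepdims=True)
    j = _SQRT_HALF_PI * np.mean(np.abs(samples - med), axis=1)
    num = samples.mean(axis=1) - med[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(j > 0, num / np.where(j > 0, j, 1.0), 0.0)
    return np.abs(t)


def symmetry_test(
    study: KCStudy,
    n_boot: int = 10000,
    seed: int | None = None,
    size: float = 0.05,
) -> TestOutcome:
    """Bootstrap test of symmetry about the (unknown) median.

    Applied to the measured values of the included labs.  Each null
    replicate flips fair-coin signs on the fixed deviation magnitudes
    |x_j - mean(x)| and recomputes T in full; the two-sided p-value
    compares the observed |T| against that reference distribution.
    """
    if study.n_included < 4:
        raise ValueError("symmetry_test requires at least 4 included results")
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives unstable p-values")
    x, _, _ = study.arrays(included_only=True)
    n = len(x)
    t_obs = mgg_statistic(x)
    mag = np.abs(x - np.mean(x))
    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_boot, n))
    t_boot = _mgg_rows(signs * mag)
    p = float(np.mean(t_boot >= abs(t_obs)))
    return TestOutcome(
        "symmetry_mgg_bootstrap",
        t_obs,
        p,
        size,
        extras={"n_boot": n_boot, "seed": seed},
    )


def gaussian_shape_test(
    sample: StandardizedSample,
    method: str = "auto",
    size: float = 0.05,
) -> TestOutcome:
    """Shapiro-Wilk / Anderson-Darling test of Gaussian shape on z values.

    ``method`` is one of ``shapiro_wilk``, ``anderson_darling``, ``auto``.
    Anderson-Darling refuses samples smaller than 8; auto falls back to
    Shapiro-Wilk there, and with n >= 8 runs both, recording each p-value
    and letting the smaller one decide.
    """
    z = np.asarray(sample.z, dtype=float)
    n = len(z)
    if method not in {"shapiro_wilk", "anderson_darling", "auto"}:
        raise ValueError(f"unknown method {method!r}")
    if n < 3:
        raise ValueError("gaussian_shape_test requires n >= 3")
    if method == "anderson_darling" and n < 8:
        raise ValueError("anderson_darling cannot handle samples with fewer than 8 observations")

    def sw():
        s = stats.shapiro(z)
        return float(s.statistic), float(s.pvalue)

    def ad():
        a, p = normal_ad(z)
        return float(a), float(p)

    if method == "shapiro_wilk" or (method == "auto" and n < 8):
        stat, p = sw()
        name = "shapiro_wilk"
        extras = {"p_shapiro_wilk": p}
        if method == "auto":
            extras["auto_note"] = "n < 8: Anderson-Darling not applicable"
    elif method == "anderson_darling":
        stat, p = ad()
        name = "anderson_darling"
        extras = {"p_anderson_darling": p}
    else:  # auto, n >= 8: run both, smaller p decides
        stat_sw, p_sw = sw()
        stat_ad, p_ad = ad()
        extras = {"p_shapiro_wilk": p_sw, "p_anderson_darling": p_ad}
        if p_ad < p_sw:
            name, stat, p = "anderson_darling", stat_ad, p_ad
        else:
            name, stat, p = "shapiro_wilk", stat_sw, p_sw
        name = f"gaussian_shape[{name}]"
    return TestOutcome(name, stat, p, size, extras=extras)
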