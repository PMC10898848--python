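"""Data model for key-comparison measurement results.

A key comparison (KC) collects one measurement result per participating
laboratory: a measured value ``x_j``, the standard uncertainty ``u_j``
reported for it, and optionally the number of degrees of freedom ``nu_j``
supporting that uncertainty.  A finite ``nu_j`` means ``u_j`` is itself an
estimate of the unknown error scale ``sigma_j``; an infinite ``nu_j`` means
``sigma_j`` is taken to equal ``u_j`` exactly.  Participants may be excluded
from the consensus-value (KCRV) computation for substantive reasons, but
degrees of equivalence are still produced for them, so excluded rows are
carried along with an ``include_in_kcrv`` flag rather than dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MeasurementResult",
    "KCStudy",
    "ValidationError",
    "dof_from_coverage_factor",
    "load_kc_csv",
    "write_kc_csv",
    "DEFAULT_DIALECT",
]


class ValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


@dataclass(frozen=True)
class MeasurementResult:
    """One laboratory's result: the triplet (value, standard uncertainty, dof).

    Parameters
    ----------
    lab:
        Participant label (unique within a study).
    value:
        Measured value ``x_j`` in the units of the measurand.
    std_unc:
        Standard uncertainty ``u_j > 0`` in the same units.
    dof:
        Degrees of freedom ``nu_j`` supporting ``std_unc``; ``math.inf``
        (the default) means the error scale is treated as known exactly.
    include_in_kcrv:
        Whether this result contributes to the consensus value.
    """

    lab: str
    value: float
    std_unc: float
    dof: float = math.inf
    include_in_kcrv: bool = True

    def __post_init__(self) -> None:
        if not (self.std_unc > 0):
            raise ValidationError(
                f"lab {self.lab!r}: std_unc must be > 0, got {self.std_unc!r}"
            )
        if not (self.dof > 0):
            raise ValidationError(
                f"lab {self.lab!r}: dof must be > 0 (inf allowed), got {self.dof!r}"
            )


@dataclass(frozen=True)
class KCStudy:
    """A named collection of measurement results sharing one unit.

    This is the universe for the consistency/shape tests, the consensus
    estimators, and the degrees of equivalence.  ``n_included`` counts the
    results flagged for the KCRV; ``N`` counts all participants.
    """

    name: str
    unit: str
    results: tuple[MeasurementResult, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "results", tuple(self.results))
        labs = [r.lab for r in self.results]
        if len(set(labs)) != len(labs):
            dupes = sorted({l for l in labs if labs.count(l) > 1})
            raise ValidationError(f"duplicate lab labels: {dupes}")

    # -- derived counts ---------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.results)

    @property
    def n_included(self) -> int:
        return sum(r.include_in_kcrv for r in self.results)

    @property
    def included(self) -> tuple[MeasurementResult, ...]:
        return tuple(r for r in self.results if r.include_in_kcrv)

    # -- array views ------------------------------------------------------
    def arrays(self, included_only: bool = True):
        """Return (values, std_uncs, dofs) as float arrays."""
        rows = self.included if included_only else self.results
        x = np.array([r.value for r in rows], dtype=float)
        u = np.array([r.std_unc for r in rows], dtype=float)
        nu = np.array([r.dof for r in rows], dtype=float)
        return x, u, nu

    def labs(self, included_only: bool = True) -> list[str]:
        rows = self.included if included_only else self.results
        return [r.lab for r in rows]

    # -- functional updates ------------------------------------------------
    def including_all(self) -> "KCStudy":
        """Copy of the study with every participant flagged for the KCRV."""
        return KCStudy(
            self.name,
            self.unit,
            tuple(replace(r, include_in_kcrv=True) for r in self.results),
        )

    def add(self, result: MeasurementResult) -> "KCStudy":
        """Copy of the study with one extra result appended."""
        return KCStudy(self.name, self.unit, self.results + (result,))

    def subset(self, labs: Iterable[str]) -> "KCStudy":
        keep = set(labs)
        return KCStudy(
            self.name, self.unit, tuple(r for r in self.results if r.lab in keep)
        )

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lab": [r.lab for r in self.results],
                "value": [r.value for r in self.results],
                "u": [r.std_unc for r in self.results],
                "dof": [r.dof for r in self.results],
                "include": [r.include_in_kcrv for r in self.results],
            }
        )

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "unit": self.unit,
            "results": [
                {
                    "lab": r.lab,
                    "value": r.value,
                    "std_unc": r.std_unc,
                    "dof": None if math.isinf(r.dof) else r.dof,
                    "include_in_kcrv": r.include_in_kcrv,
                }
                for r in self.results
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "KCStudy":
        payload = json.loads(text)
        results = tuple(
            MeasurementResult(
                lab=r["lab"],
                value=r["value"],
                std_unc=r["std_unc"],
                dof=math.inf if r.get("dof") is None else r["dof"],
                include_in_kcrv=bool(r.get("include_in_kcrv", True)),
            )
            for r in payload["results"]
        )
        return cls(payload["name"], payload.get("unit", ""), results)


def dof_from_coverage_factor(k: float, p: float = 0.95, tol: float = 5e-3) -> float:
    """Invert the Student-t two-sided quantile to recover effective dof.

    A coverage factor ``k`` for coverage probability ``p`` implies the number
    of effective degrees of freedom ``nu`` for which the two-sided Student-t
    quantile equals ``k``.  Coverage factors at (or below) the Gaussian
    quantile correspond to infinite dof.  The returned ``nu`` is rounded to
    the nearest integer, matching how coverage factors are reported.
    """
    if k <= 0:
        raise ValidationError(f"coverage factor must be > 0, got {k!r}")
    if not (0 < p < 1):
        raise ValidationError(f"coverage probability must be in (0,1), got {p!r}")
    q = 0.5 + p / 2.0
    z = stats.norm.ppf(q)
    if k <= z + tol:
        return math.inf
    # t.ppf(q, nu) decreases monotonically in nu from +inf (nu->0) to z.
    f = lambda nu: stats.t.ppf(q, nu) - k
    nu = optimize.brentq(f, 1e-2, 1e6, xtol=1e-10)
    return float(round(nu))


DEFAULT_DIALECT: Mapping[str, str] = {
    "lab": "lab",
    "value": "value",
    "u": "u",
    "U": "U",
    "k": "k",
    "dof": "dof",
    "include": "include",
}

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def _parse_include(val, row_label: str) -> bool:
    if isinstance(val, bool):
        return val
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return True
    s = str(val).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"row {row_label!r}: cannot parse include flag {val!r}")


def load_kc_csv(
    path,
    dialect: Mapping[str, str] | None = None,
    name: str | None = None,
    unit: str = "",
) -> KCStudy:
    """Load a key-comparison table from CSV.

    The table must provide a lab column, a value column, and either a
    standard-uncertainty column ``u`` or an expanded-uncertainty pair
    ``(U, k)``; in the latter case ``u = U / k``.  A ``dof`` column is
    optional (missing entries mean infinite), as is an ``include`` flag
    (missing means included).  Column names are remapped via ``dialect``.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]

    def col(key):
        c = cols[key]
        return df[c] if c in df.columns else None

    lab_col, val_col = col("lab"), col("value")
    if lab_col is None or val_col is None:
        raise ValidationError(
            f"CSV must contain columns {cols['lab']!r} and {cols['value']!r}"
        )
    u_col, U_col, k_col = col("u"), col("U"), col("k")
    dof_col, inc_col = col("dof"), col("include")

    results = []
    for i in range(len(df)):
        lab = str(lab_col.iloc[i]).strip()
        value = float(val_col.iloc[i])
        u_val = None if u_col is None else u_col.iloc[i]
        has_u = u_val is not None and not pd.isna(u_val)
        if has_u:
            std_unc = float(u_val)
        elif U_col is not None and k_col is not None and not pd.isna(U_col.iloc[i]):
            kk = float(k_col.iloc[i])
            if kk <= 0:
                raise ValidationError(f"row {lab!r}: coverage factor k must be > 0")
            std_unc = float(U_col.iloc[i]) / kk
        else:
            raise ValidationError(
                f"row {lab!r}: needs either a standard uncertainty or (U, k)"
            )
        if not std_unc > 0:
            raise ValidationError(f"row {lab!r}: non-positive uncertainty {std_unc}")
        dof = math.inf
        if dof_col is not None and not pd.isna(dof_col.iloc[i]):
            dof = float(dof_col.iloc[i])
        include = True
        if inc_col is not None:
            include = _parse_include(inc_col.iloc[i], lab)
        results.append(
            MeasurementResult(
                lab=lab, value=value, std_unc=std_unc, dof=dof, include_in_kcrv=include
            )
        )
    study_name = name if name is not None else str(path)
    return KCStudy(study_name, unit, tuple(results))


def write_kc_csv(study: KCStudy, path) -> None:
    """Write a study to CSV in the default dialect (round-trips with the loader)."""
    df = study.to_frame()
    df["dof"] = [None if math.isinf(d) else d for d in df["dof"]]
    df["include"] = ["yes" if b else "no" for b in df["include"]]
    df.to_csv(path, index=False)
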