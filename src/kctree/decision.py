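"""Traversal of the decision tree that routes a study to a consensus estimator.

The tree has four branching nodes and five leaves.  Node 1 asks whether the
results are mutually consistent (Cochran's Q).  If they are, Node 2 asks
whether the standardized values look Gaussian: YES selects the adaptive
weighted average, NO the weighted median.  If the results are inconsistent,
Node 3 asks whether the measured values are symmetric: NO selects the
hierarchical skew-Student + Gauss model; YES leads to Node 4, where a
Gaussian shape selects hierarchical Gauss + Gauss and a non-Gaussian one
hierarchical Laplace + Gauss.

The traversal is advisory: it returns a recommendation together with a
full audit trail (every statistic, p-value, size, and branch) and small-n
power caveats; estimation is a separate call, so users remain free to
override the recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .consistency import cochran_q, tau_qprofile_ci
from .data import KCStudy
from .results import TestOutcome
from .shape import gaussian_shape_test, standardize, symmetry_test

__all__ = [
    "DecisionConfig",
    "DecisionTrace",
    "NodeOutcome",
    "bonferroni_sizes",
    "traverse",
    "LEAVES",
]

LEAVES = (
    "adaptive_weighted_average",
    "weighted_median",
    "hier_gauss_gauss",
    "hier_laplace_gauss",
    "hier_skew_t_gauss",
)


@dataclass(frozen=True)
class DecisionConfig:
    """Sizes of the gating tests and bootstrap settings for the traversal.

    The homogeneity node defaults to a generous 10% Type-I error because
    failing to detect dark uncertainty is costlier than falsely declaring
    it; the shape nodes default to the conventional 5%.  With
    ``bonferroni=True`` all three nominal sizes are replaced by
    ``overall_alpha / 3`` regardless of which nodes are visited.
    """

    size_homogeneity: float = 0.10
    size_symmetry: float = 0.05
    size_gaussian: float = 0.05
    bonferroni: bool = False
    overall_alpha: float = 0.05
    n_boot: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("size_homogeneity", "size_symmetry", "size_gaussian", "overall_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")

    def effective_sizes(self) -> tuple[float, float, float]:
        if self.bonferroni:
            s = self.overall_alpha / 3.0
            return (s, s, s)
        return (self.size_homogeneity, self.size_symmetry, self.size_gaussian)


def bonferroni_sizes(overall_alpha: float, n_tests: int) -> tuple[float, ...]:
    """Equal per-test sizes summing to the overall Type-I error."""
    if not (0.0 < overall_alpha < 1.0):
        raise ValueError("overall_alpha must be in (0,1)")
    if n_tests not in (2, 3):
        raise ValueError("the tree applies 2 or 3 tests")
    return tuple(overall_alpha / n_tests for _ in range(n_tests))


@dataclass(frozen=True)
class NodeOutcome:
    node: str
    outcome: TestOutcome
    branch: str  # "yes" / "no"

    def to_dict(self) -> dict:
        return {"node": self.node, "branch": self.branch, **self.outcome.to_dict()}


@dataclass
class DecisionTrace:
    leaf: str
    node_outcomes: list[NodeOutcome]
    warnings: list[str] = field(default_factory=list)
    config: DecisionConfig | None = None

    def to_dict(self) -> dict:
        return {
            "leaf": self.leaf,
            "nodes": [n.to_dict() for n in self.node_outcomes],
            "warnings": list(self.warnings),
            "config": None
            if self.config is None
            else {
                "size_homogeneity": self.config.size_homogeneity,
                "size_symmetry": self.config.size_symmetry,
                "size_gaussian": self.config.size_gaussian,
                "bonferroni": self.config.bonferroni,
                "overall_alpha": self.config.overall_alpha,
                "n_boot": self.config.n_boot,
                "seed": self.config.seed,
            },
        }


def traverse(study: KCStudy, config: DecisionConfig | None = None) -> DecisionTrace:
    """Walk the tree on the included results and recommend a leaf."""
    config = config or DecisionConfig()
    n = study.n_included
    if n < 3:
        raise ValueError("traverse requires at least 3 included results")
    size_q, size_sym, size_gauss = config.effective_sizes()

    warnings_list: list[str] = []
    if n < 5:
        warnings_list.append(
            f"only {n} results are included: the gating tests may be unreliable "
            "for fewer than 5 participants; treat the recommendation with caution"
        )
    if n < 30:
        warnings_list.append(
            f"symmetry testing is weakly powered below about 30 participants (n={n})"
        )
    if n < 10:
        warnings_list.append(
            f"Gaussian-shape tests can have very low power below 10 participants (n={n})"
        )

    nodes: list[NodeOutcome] = []
    q_out = replace(cochran_q(study), size=size_q)
    consistent = not q_out.reject
    nodes.append(
        NodeOutcome("homogeneity (Cochran Q)", q_out, "yes" if consistent else "no")
    )

    # tau Q-profile caveat: a wide upper bound can hide dark uncertainty
    # even when Q is not significant
    if consistent and n >= 3:
        try:
            tau_ci = tau_qprofile_ci(study)
            _, u, _ = study.arrays(included_only=True)
            if tau_ci.ci_high is not None and tau_ci.ci_high > 2.0 * float(np.median(u)):
                warnings_list.append(
                    "the 95 % Q-profile interval for tau reaches "
                    f"{tau_ci.ci_high:.3g}, well above the reported uncertainties: "
                    "absence of significant heterogeneity should not be accepted "
                    "automatically"
                )
        except (ValueError, RuntimeError):
            pass

    z = standardize(study)
    if consistent:
        g_out = replace(gaussian_shape_test(z, method="auto"), size=size_gauss)
        gaussian = not g_out.reject
        nodes.append(
            NodeOutcome("Gaussian shape", g_out, "yes" if gaussian else "no")
        )
        leaf = "adaptive_weighted_average" if gaussian else "weighted_median"
    else:
        s_out = replace(
            symmetry_test(study, n_boot=config.n_boot, seed=config.seed),
            size=size_sym,
        )
        symmetric = not s_out.reject
        nodes.append(NodeOutcome("symmetry", s_out, "yes" if symmetric else "no"))
        if not symmetric:
            leaf = "hier_skew_t_gauss"
        else:
            g_out = replace(gaussian_shape_test(z, method="auto"), size=size_gauss)
            gaussian = not g_out.reject
            nodes.append(
                NodeOutcome("Gaussian shape", g_out, "yes" if gaussian else "no")
            )
            leaf = "hier_gauss_gauss" if gaussian else "hier_laplace_gauss"

    return DecisionTrace(leaf=leaf, node_outcomes=nodes, warnings=warnings_list, config=config)
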