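"""End-to-end pipeline: decide -> estimate -> DoE -> plain-text report."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .bayes import HierModelSpec, MCMCConfig, fit_hierarchical
from .consistency import tau_qprofile_ci
from .data import KCStudy, load_kc_csv
from .decision import LEAVES, DecisionConfig, DecisionTrace, traverse
from .doe import DoETable, compute_does, doe_plot_data
from .freq import adaptive_weighted_average, weighted_median_consensus
from .results import ConsensusResult

__all__ = ["RunConfig", "PipelineResult", "estimate", "run_pipeline"]

log = logging.getLogger("kctree")


@dataclass(frozen=True)
class RunConfig:
    input_path: str | Path
    output_dir: str | Path
    name: str | None = None
    unit: str = ""
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    force_leaf: str | None = None
    n_boot: int = 5000
    mcmc: MCMCConfig | None = None
    n_rep_doe: int = 10000
    seed: int = 0
    save_draws: bool = True

    def __post_init__(self) -> None:
        if self.force_leaf is not None and self.force_leaf not in LEAVES:
            raise ValueError(f"force_leaf must be one of {LEAVES}")


@dataclass
class PipelineResult:
    study: KCStudy
    trace: DecisionTrace
    consensus: ConsensusResult
    doe: DoETable
    report_text: str


def estimate(
    study: KCStudy,
    leaf: str,
    n_boot: int = 5000,
    mcmc: MCMCConfig | None = None,
    seed: int | None = None,
) -> ConsensusResult:
    """Run the consensus estimator named by a tree leaf."""
    if leaf == "adaptive_weighted_average":
        return adaptive_weighted_average(study, n_boot=n_boot, seed=seed)
    if leaf == "weighted_median":
        return weighted_median_consensus(study, n_boot=n_boot, seed=seed)
    if leaf in ("hier_gauss_gauss", "hier_laplace_gauss", "hier_skew_t_gauss"):
        family = {"hier_gauss_gauss": "gauss", "hier_laplace_gauss": "laplace",
                  "hier_skew_t_gauss": "skew_t"}[leaf]
        cfg = mcmc or MCMCConfig(seed=seed)
        if seed is not None and cfg.seed is None:
            cfg = MCMCConfig(
                chains=cfg.chains, warmup=cfg.warmup, samples=cfg.samples, seed=seed
            )
        consensus, summary = fit_hierarchical(
            study, HierModelSpec(effects_family=family), cfg
        )
        consensus.details["posterior"] = summary.to_dict()
        return consensus
    raise ValueError(f"unknown leaf {leaf!r}; valid leaves: {LEAVES}")


_LEAF_LABELS = {
    "adaptive_weighted_average": "adaptive weighted average (DerSimonian-Laird)",
    "weighted_median": "weighted median",
    "hier_gauss_gauss": "hierarchical Gauss + Gauss",
    "hier_laplace_gauss": "hierarchical Laplace + Gauss",
    "hier_skew_t_gauss": "hierarchical Skew Student + Gauss",
}


def _format_report(study, trace, consensus, doe_table, cfg) -> str:
    unit = study.unit or "units"
    lines = []
    lines.append(f"Key comparison: {study.name}")
    lines.append(f"participants: {study.N}  included in KCRV: {study.n_included}")
    lines.append(f"seed: {cfg.seed}")
    lines.append("")
    lines.append("Gating tests")
    lines.append(f"{'node':28s} {'statistic':>10s} {'p-value':>9s} {'size':>6s} decision")
    for node in trace.node_outcomes:
        o = node.outcome
        lines.append(
            f"{node.node:28s} {o.statistic:10.4g} {o.p_value:9.4f} {o.size:6.3f} "
            f"{'reject' if o.reject else 'retain'} -> {node.branch.upper()}"
        )
    lines.append("")
    leaf_note = " (forced by user)" if cfg.force_leaf else ""
    lines.append(f"Recommended procedure: {_LEAF_LABELS[consensus.method]}{leaf_note}")
    lines.append(f"KCRV = {consensus.kcrv:.6g} {unit}")
    lines.append(f"u(KCRV) = {consensus.std_unc:.4g} {unit}")
    if consensus.tau is not None:
        t = consensus.tau.to_dict() if hasattr(consensus.tau, "to_dict") else consensus.tau
        lines.append(
            f"dark uncertainty tau = {t.get('tau_hat', float('nan')):.4g} {unit} "
            f"({t.get('method', '')})"
        )
    try:
        ci = tau_qprofile_ci(study)
        lines.append(
            f"tau 95 % Q-profile interval: ({ci.ci_low:.4g}, {ci.ci_high:.4g}) {unit}"
        )
    except (ValueError, RuntimeError):
        pass
    lines.append("")
    lines.append("Degrees of equivalence (D_j +/- U95)")
    for e in doe_table.entries:
        flag = " *" if e.significant else ""
        inc = "included" if e.included else "excluded"
        lines.append(
            f"  {e.lab:12s} D = {e.D:+10.4g}  U95 = {e.U95:9.4g}  ({inc}){flag}"
        )
    lines.append("  (* |D| exceeds U95: result beyond the range allowed by the model)")
    if trace.warnings:
        lines.append("")
        lines.append("WARNINGS")
        for w in trace.warnings:
            lines.append(f"  - {w}")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run decide -> estimate -> DoE and write the report bundle.

    Writes ``trace.json``, ``result.json``, ``doe.csv`` and ``report.txt``
    into the output directory; every artifact records the seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if isinstance(config.input_path, KCStudy):
        study = config.input_path
    else:
        study = load_kc_csv(config.input_path, name=config.name, unit=config.unit)
    log.info("loaded study %s: N=%d, included=%d", study.name, study.N, study.n_included)

    dec_cfg = config.decision
    if dec_cfg.seed is None:
        dec_cfg = DecisionConfig(
            size_homogeneity=dec_cfg.size_homogeneity,
            size_symmetry=dec_cfg.size_symmetry,
            size_gaussian=dec_cfg.size_gaussian,
            bonferroni=dec_cfg.bonferroni,
            overall_alpha=dec_cfg.overall_alpha,
            n_boot=dec_cfg.n_boot,
            seed=config.seed,
        )
    trace = traverse(study, dec_cfg)
    for node in trace.node_outcomes:
        log.info(
            "node %-28s p=%.4f size=%.3f -> %s",
            node.node, node.outcome.p_value, node.outcome.size, node.branch,
        )
    leaf = config.force_leaf or trace.leaf
    log.info("selected leaf: %s%s", leaf, " (forced)" if config.force_leaf else "")

    consensus = estimate(
        study, leaf, n_boot=config.n_boot, mcmc=config.mcmc, seed=config.seed
    )
    doe_table = compute_does(study, consensus, n_rep=config.n_rep_doe, seed=config.seed)
    report_text = _format_report(study, trace, consensus, doe_table, config)

    (out / "trace.json").write_text(
        json.dumps({"study": study.name, "seed": config.seed, **trace.to_dict()}, indent=1)
    )
    (out / "result.json").write_text(
        json.dumps(consensus.to_dict(include_draws=config.save_draws), indent=1)
    )
    doe_plot_data(doe_table).to_csv(out / "doe.csv", index=False)
    (out / "report.txt").write_text(report_text)
    return PipelineResult(study, trace, consensus, doe_table, report_text)
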