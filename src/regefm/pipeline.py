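"""End-to-end enumeration pipeline and the rule-subset sweep.

``enumerate_efms`` is the library entry point: read → split reversibles →
kernel (computed or loaded) → order rows → binarize → iterate with rule
patterns → futile-cycle removal → merge → post-processing rules → numeric
recovery.  ``run_pipeline`` wraps it with artifact writing for the command
line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from . import ddm_engine, postprocess
from .kernel_init import (
    KernelMatrix,
    compute_kernel,
    init_mode_matrix,
    load_kernel,
    order_rows,
)
from .network_io import MetabolicNetwork, read_network, split_reversibles
from .postprocess import BinaryEFM, NumericEFM
from .rule_engine import Rule, RuleClass, classify_rule, compile_patterns, parse_rules

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (mirrors the CLI flags)."""

    network: str | Path
    network_format: str | None = None
    kernel: str | Path | None = None
    generule: str | Path | None = None
    rule_sort: bool = False
    outdir: str | Path | None = None
    normalize_output: bool = True
    precision: int = 2
    log_level: str = "INFO"


@dataclass
class RunResult:
    """Everything a run computed, plus stage-by-stage mode counts."""

    network: MetabolicNetwork
    kernel: KernelMatrix
    rules: list[Rule]
    rule_classes: dict[str, str]
    stats: list[ddm_engine.IterationStats]
    binary_efms: list[BinaryEFM]
    numeric_efms: list[NumericEFM]
    counts: dict[str, int] = field(default_factory=dict)


def enumerate_efms(
    net: MetabolicNetwork,
    rules: Sequence[Rule] = (),
    kernel: KernelMatrix | None = None,
    rule_sort: bool = False,
    recover: bool = True,
    normalize_output: bool = True,
) -> RunResult:
    """Enumerate the feasible EFMs of a network under regulatory rules."""
    ext = split_reversibles(net)
    km = kernel if kernel is not None else compute_kernel(ext)
    km = order_rows(km, rules=rules, rule_sort=rule_sort)
    patterns = compile_patterns(rules, ext)
    matrix = init_mode_matrix(km)
    n_initial = len(matrix.modes)
    matrix, stats = ddm_engine.run(matrix, patterns)
    n_binary = len(matrix.modes)
    matrix = postprocess.remove_futile_cycles(matrix, ext)
    n_after_futile = len(matrix.modes)
    merged = postprocess.merge_all(matrix, ext)
    kept = postprocess.apply_post_rules(merged, rules, net)
    kept = sorted(kept, key=lambda e: tuple(
        (e.support >> j) & 1 for j in range(len(net.reactions))
    ))
    numeric: list[NumericEFM] = []
    if recover:
        for efm in kept:
            rec = postprocess.recover_numeric(efm, km, ext)
            if normalize_output:
                rec = NumericEFM(flux=postprocess.normalize(rec.flux))
            numeric.append(rec)
    counts = {
        "initial_modes": n_initial,
        "removed_by_iteration_rules": sum(s.removed_infeasible for s in stats),
        "binary_modes": n_binary,
        "futile_cycles_removed": n_binary - n_after_futile,
        "removed_by_post_rules": len(merged) - len(kept),
        "final_efms": len(kept),
    }
    return RunResult(
        network=net,
        kernel=km,
        rules=list(rules),
        rule_classes={r.rule_id or r.source_text: classify_rule(r).value for r in rules},
        stats=stats,
        binary_efms=kept,
        numeric_efms=numeric,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Artifact writing


def _efm_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"EFM{i + 1:0{width}d}" for i in range(n)]


def write_binary_tsv(result: RunResult, path: Path) -> None:
    net = result.network
    labels = _efm_labels(len(result.binary_efms))
    lines = ["#\t" + "\t".join(labels)]
    for j, rxn in enumerate(net.reactions):
        bits = [str((e.support >> j) & 1) for e in result.binary_efms]
        lines.append(rxn.id + "\t" + "\t".join(bits))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_numeric_tsv(result: RunResult, path: Path, precision: int = 2) -> None:
    net = result.network
    labels = _efm_labels(len(result.numeric_efms))
    lines = ["#\t" + "\t".join(labels)]
    for j, rxn in enumerate(net.reactions):
        vals = [f"{float(e.flux[j]):.{precision}f}" for e in result.numeric_efms]
        lines.append(rxn.id + "\t" + "\t".join(vals))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_stats_tsv(result: RunResult, path: Path) -> None:
    lines = ["iteration\tremoved_infeasible\tn_modes\tadjacency_candidates"]
    for s in result.stats:
        lines.append(
            f"{s.iteration_no}\t{s.removed_infeasible}\t{s.n_modes}\t{s.n_adjacency_candidates}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_activity_tsv(result: RunResult, path: Path) -> None:
    freqs = postprocess.activity_frequencies(result.binary_efms, result.network)
    lines = ["reaction\talpha_percent"]
    for rid, alpha in freqs.items():
        lines.append(f"{rid}\t{float(alpha):.2f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_manifest(result: RunResult, cfg: RunConfig, path: Path) -> None:
    manifest = {
        "inputs": {
            "network": str(cfg.network),
            "kernel": str(cfg.kernel) if cfg.kernel else None,
            "generule": str(cfg.generule) if cfg.generule else None,
            "rule_sort": cfg.rule_sort,
        },
        "rule_classes": result.rule_classes,
        "counts": result.counts,
    }
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run the full pipeline and, when ``cfg.outdir`` is set, write the
    binary/numeric/stats/activity tables and a run manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    net = read_network(cfg.network, format=cfg.network_format)
    ext = split_reversibles(net)
    kernel = load_kernel(cfg.kernel, ext) if cfg.kernel else None
    rules = parse_rules(cfg.generule, net) if cfg.generule else []
    result = enumerate_efms(
        net,
        rules=rules,
        kernel=kernel,
        rule_sort=cfg.rule_sort,
        normalize_output=cfg.normalize_output,
    )
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_binary_tsv(result, outdir / "binary_efms.tsv")
        write_numeric_tsv(result, outdir / "numeric_efms.tsv", cfg.precision)
        write_stats_tsv(result, outdir / "iteration_stats.tsv")
        if result.binary_efms:
            write_activity_tsv(result, outdir / "activity.tsv")
        write_manifest(result, cfg, outdir / "manifest.json")
    log.info("final EFM count: %d", result.counts["final_efms"])
    return result


# ---------------------------------------------------------------------------
# Rule-subset sweep


def rule_subset_sweep(
    net: MetabolicNetwork,
    rules: Sequence[Rule],
    kernel: KernelMatrix | None = None,
    rule_sort: bool = False,
):
    """Run the pipeline for every subset of ``rules``.

    Returns ``(runs, averages)`` DataFrames: one row per subset (subset id,
    cardinality, final EFM count, total removed, iterations) and the mean
    final count per cardinality.
    """
    import pandas as pd

    if len(rules) > 12:
        raise ValueError("sweep refuses more than 12 rules (2^n runs)")
    rows = []
    for mask in range(1 << len(rules)):
        subset = [r for k, r in enumerate(rules) if mask >> k & 1]
        res = enumerate_efms(net, rules=subset, kernel=kernel,
                             rule_sort=rule_sort, recover=False)
        rows.append(
            {
                "subset": "+".join(r.rule_id or f"rule{k}" for k, r in enumerate(subset))
                or "(none)",
                "n_rules": len(subset),
                "final_efms": res.counts["final_efms"],
                "removed_total": res.counts["removed_by_iteration_rules"]
                + res.counts["removed_by_post_rules"],
                "iterations": sum(1 for s in res.stats if s.iteration_no > 0),
            }
        )
    runs = pd.DataFrame(rows)
    averages = (
        runs.groupby("n_rules", as_index=False)["final_efms"]
        .mean()
        .rename(columns={"final_efms": "mean_final_efms"})
    )
    return runs, averages
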