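"""End-to-end orchestration: read -> exclude -> infer -> characterize -> report.

One or two cohorts (e.g. a young and an adult sample) are analyzed fully
independently; no joint estimation or formal between-network test is
performed — cohort differences are reported descriptively by
:func:`compare_cohorts`.  Every run writes a JSON manifest (config snapshot,
software version, seeds, per-stage durations, exclusions, edge/node counts)
sufficient to re-execute it bit-identically; the manifest is written last so
its presence marks a complete run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    ExclusionReport,
    PrevalenceSummary,
    SymptomMatrix,
    exclude_degenerate,
    prevalence_summary,
    read_symptom_matrix,
)
from .inference import SurrogateConfig, SymptomNetwork, build_network
from .metrics import NodeMetrics, compute_node_metrics, node_metric_table

__all__ = [
    "RunConfig",
    "RunManifest",
    "CohortResult",
    "PipelineError",
    "run_pipeline",
    "compare_cohorts",
]

logger = logging.getLogger("symptomnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a run needs: inputs, null-model settings, graph options."""

    cohorts: list[tuple[str, str]]  # (label, path to delimited matrix)
    out_dir: str
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    min_minority_count: int = 2
    betweenness_mode: str = "unweighted"
    gamma: float = 1.0
    restarts: int = 100
    delimiter: str = "\t"

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        labels = [label for label, _ in self.cohorts]
        if len(set(labels)) != len(labels):
            raise ValueError("cohort labels must be unique")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run config from YAML.

        Recognized keys: cohorts (list of [label, path]), out_dir,
        n_surrogates, fdr_q, seed, fdr_method, min_minority_count,
        betweenness_mode, gamma, restarts, delimiter.
        """
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        surrogate = SurrogateConfig(
            n_surrogates=int(doc.get("n_surrogates", 5000)),
            fdr_q=float(doc.get("fdr_q", 0.05)),
            seed=int(doc.get("seed", 0)),
            fdr_method=str(doc.get("fdr_method", "bh")),
        )
        return cls(
            cohorts=[(str(label), str(p)) for label, p in doc["cohorts"]],
            out_dir=str(doc["out_dir"]),
            surrogate=surrogate,
            min_minority_count=int(doc.get("min_minority_count", 2)),
            betweenness_mode=str(doc.get("betweenness_mode", "unweighted")),
            gamma=float(doc.get("gamma", 1.0)),
            restarts=int(doc.get("restarts", 100)),
            delimiter=str(doc.get("delimiter", "\t")),
        )


@dataclass
class RunManifest:
    """Machine-readable record of a completed run."""

    version: str
    config: dict
    cohorts: dict  # label -> {exclusions, n_nodes, n_edges, durations}

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"version": self.version, "config": self.config,
                       "cohorts": self.cohorts}, fh, indent=2, sort_keys=True)


@dataclass
class CohortResult:
    """In-memory artifacts for one analyzed cohort."""

    label: str
    matrix: SymptomMatrix
    prevalence: PrevalenceSummary
    exclusions: ExclusionReport
    network: SymptomNetwork
    metrics: NodeMetrics
    node_table: pd.DataFrame


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name!r}: {exc}") from exc
    return out, time.perf_counter() - t0


def _strongest_edges(net: SymptomNetwork, top: int = 10) -> pd.DataFrame:
    edges = net.edge_list(significant_only=True)
    return edges.sort_values("mi_bits", ascending=False).head(top).reset_index(
        drop=True
    )


def analyze_cohort(
    label: str, matrix: SymptomMatrix, cfg: RunConfig
) -> tuple[CohortResult, dict]:
    """Run every analysis stage for one cohort; returns the result and timings."""
    durations: dict[str, float] = {}
    prev, durations["prevalence"] = _stage("prevalence", prevalence_summary, matrix)
    (filtered, report), durations["exclude"] = _stage(
        "exclude", exclude_degenerate, matrix, cfg.min_minority_count
    )
    for name in report.excluded_names:
        logger.info("[%s] excluded %r (%s)", label, name, report.reasons[name])
    net, durations["network"] = _stage(
        "network", build_network, filtered, cfg.surrogate
    )
    logger.info(
        "[%s] %d nodes, %d significant edges (n_surrogates=%d, q=%g, seed=%d)",
        label, net.n_nodes, net.n_edges, cfg.surrogate.n_surrogates,
        cfg.surrogate.fdr_q, cfg.surrogate.seed,
    )
    metrics, durations["metrics"] = _stage(
        "metrics",
        compute_node_metrics,
        net,
        cfg.betweenness_mode,
        cfg.gamma,
        cfg.restarts,
        np.random.default_rng(cfg.surrogate.seed),
    )
    table, durations["report"] = _stage(
        "report", node_metric_table, net, prev, metrics
    )
    result = CohortResult(
        label=label,
        matrix=matrix,
        prevalence=prev,
        exclusions=report,
        network=net,
        metrics=metrics,
        node_table=table,
    )
    return result, durations


def run_pipeline(cfg: RunConfig) -> tuple[RunManifest, dict[str, CohortResult]]:
    """Execute the full analysis for every configured cohort and write artifacts.

    Per cohort: prevalence table, exclusion report, edge-list CSV, GraphML
    network, MI matrix TSV, node-metric table, strongest-edges summary.
    Returns the manifest and the in-memory results keyed by cohort label.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = logging.FileHandler(out / "run.log")
    log_file.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_file)
    results: dict[str, CohortResult] = {}
    manifest_cohorts: dict[str, dict] = {}
    try:
        for label, path in cfg.cohorts:
            matrix, t_read = _stage(
                "read", read_symptom_matrix, path, cfg.delimiter, label
            )
            result, durations = analyze_cohort(label, matrix, cfg)
            durations["read"] = t_read
            result.prevalence.write_tsv(out / f"{label}_prevalence.tsv")
            result.exclusions.write_tsv(out / f"{label}_exclusions.tsv")
            result.network.write_edge_csv(out / f"{label}_edges.csv")
            result.network.write_graphml(out / f"{label}_network.graphml")
            result.network.write_mi_tsv(out / f"{label}_mi_matrix.tsv")
            result.node_table.to_csv(
                out / f"{label}_nodes.tsv", sep="\t", index=False
            )
            _strongest_edges(result.network).to_csv(
                out / f"{label}_top_edges.csv", index=False, float_format="%.10g"
            )
            results[label] = result
            manifest_cohorts[label] = {
                "input": str(path),
                "n_patients": matrix.n_patients,
                "n_variables": matrix.n_variables,
                "excluded": {
                    name: result.exclusions.reasons[name]
                    for name in result.exclusions.excluded_names
                },
                "n_nodes": result.network.n_nodes,
                "n_edges": result.network.n_edges,
                "durations_s": {k: round(v, 4) for k, v in durations.items()},
            }
        manifest = RunManifest(
            version=__version__,
            config={
                "cohorts": [list(c) for c in cfg.cohorts],
                "out_dir": str(cfg.out_dir),
                "surrogate": asdict(cfg.surrogate),
                "min_minority_count": cfg.min_minority_count,
                "betweenness_mode": cfg.betweenness_mode,
                "gamma": cfg.gamma,
                "restarts": cfg.restarts,
                "delimiter": cfg.delimiter,
            },
            cohorts=manifest_cohorts,
        )
        manifest.write_json(out / "manifest.json")  # written last: marks success
    finally:
        logger.removeHandler(log_file)
        log_file.close()
    return manifest, results


def compare_cohorts(
    a: CohortResult | pd.DataFrame, b: CohortResult | pd.DataFrame
) -> dict:
    """Descriptive side-by-side comparison of two analyzed cohorts.

    Returns a dict with a merged per-symptom table (degree, strength,
    betweenness, module and core flag from each cohort, suffixed _a/_b) and
    the set differences of core membership: ``core_gained`` lists symptoms
    core in B but not A, ``core_lost`` the converse.
    """
    ta = a.node_table if isinstance(a, CohortResult) else a
    tb = b.node_table if isinstance(b, CohortResult) else b
    va, vb = set(ta["variable"]), set(tb["variable"])
    if not (va & vb):
        raise ValueError("cohorts share no variables; nothing to compare")
    merged = ta.merge(tb, on="variable", how="outer", suffixes=("_a", "_b"))
    core_a = set(ta.loc[ta["core_periphery"] == "Core", "variable"])
    core_b = set(tb.loc[tb["core_periphery"] == "Core", "variable"])
    return {
        "table": merged,
        "core_gained": sorted(core_b - core_a),
        "core_lost": sorted(core_a - core_b),
    }
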