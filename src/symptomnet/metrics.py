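"""Node-level and mesoscale characterization of the significant-edge network.

Degree, strength and betweenness centrality describe individual symptoms;
core-periphery decomposition and modularity communities describe the
network's mesoscale organization.  Betweenness defaults to unweighted
shortest paths (a path's length is its number of links); an inverse-weight
mode (edge length = 1/MI) is available because stronger dependencies can be
read as "shorter" connections.  Core-periphery is a discrete two-block
Borgatti-Everett decomposition: the assignment maximizing the Pearson
correlation between the weight matrix and the ideal pattern in which
core-core and core-periphery dyads are 1 and periphery-periphery dyads are 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .data import PrevalenceSummary, round_half_up
from .inference import SymptomNetwork

__all__ = [
    "NodeMetrics",
    "PartitionResult",
    "degree",
    "strength",
    "betweenness",
    "core_periphery",
    "core_periphery_quality",
    "modularity_partition",
    "compute_node_metrics",
    "node_metric_table",
]

BETWEENNESS_MODES = ("unweighted", "inverse-weight")


@dataclass
class NodeMetrics:
    """The per-symptom row of the network-parameter table."""

    variable_names: list[str]
    degree: np.ndarray
    strength: np.ndarray
    betweenness: np.ndarray
    module_id: np.ndarray
    is_core: np.ndarray
    betweenness_mode: str = "unweighted"


@dataclass
class PartitionResult:
    """A community partition with its recomputed quality."""

    labels: np.ndarray  # 1-based module ids, renumbered by descending size
    quality: float
    n_restarts_used: int
    seed: int


def degree(net: SymptomNetwork) -> np.ndarray:
    """Number of significant edges incident to each symptom."""
    return net.significant.sum(axis=1).astype(int)


def strength(net: SymptomNetwork) -> np.ndarray:
    """Sum of incident significant-edge MI weights (bits) per symptom."""
    return (net.weights * net.significant).sum(axis=1)


def betweenness(net: SymptomNetwork, mode: str = "unweighted") -> np.ndarray:
    """Betweenness centrality over the significant-edge graph.

    Unnormalized pair-count convention: each unordered pair (s, t) of other
    nodes contributes the fraction of its shortest paths passing through the
    node.  Pairs in different components contribute nothing.
    """
    if mode not in BETWEENNESS_MODES:
        raise ValueError(
            f"unknown betweenness mode {mode!r}; expected one of {BETWEENNESS_MODES}"
        )
    g = net.to_graph()
    if mode == "inverse-weight":
        for _, _, attrs in g.edges(data=True):
            attrs["length"] = 1.0 / attrs["weight"]
        bc = nx.betweenness_centrality(g, normalized=False, weight="length")
    else:
        bc = nx.betweenness_centrality(g, normalized=False, weight=None)
    return np.array([bc[name] for name in net.variable_names], dtype=float)


def core_periphery_quality(weights: np.ndarray, is_core: np.ndarray) -> float:
    """Borgatti-Everett quality of a two-block assignment.

    Pearson correlation between the off-diagonal weight entries and the ideal
    core-periphery pattern (1 where at least one endpoint is core, 0 for
    periphery-periphery dyads).  Undefined (NaN) when either the weights or
    the pattern are constant over dyads, e.g. for an edgeless network or an
    all-core/all-periphery assignment.
    """
    w = np.asarray(weights, dtype=float)
    c = np.asarray(is_core, dtype=bool)
    iu = np.triu_indices(w.shape[0], k=1)
    pattern = (c[:, None] | c[None, :])[iu].astype(float)
    wv = w[iu]
    if wv.std() == 0.0 or pattern.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(wv, pattern)[0, 1])


def _local_search_core(
    w: np.ndarray, start: np.ndarray
) -> tuple[np.ndarray, float]:
    """Single-flip hill climbing on the Borgatti-Everett quality."""
    c = start.copy()
    q = core_periphery_quality(w, c)
    if np.isnan(q):
        q = -np.inf
    improved = True
    while improved:
        improved = False
        best_flip, best_q = -1, q
        for i in range(c.size):
            c[i] = ~c[i]
            qi = core_periphery_quality(w, c)
            c[i] = ~c[i]
            if not np.isnan(qi) and qi > best_q + 1e-12:
                best_flip, best_q = i, qi
        if best_flip >= 0:
            c[best_flip] = ~c[best_flip]
            q = best_q
            improved = True
    return c, q


def core_periphery(
    net: SymptomNetwork,
    restarts: int = 50,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Two-block core/periphery assignment of the significant-edge network.

    Hill-climbing label switching from `restarts` random initial assignments;
    the best assignment by Borgatti-Everett quality is returned, with ties
    broken toward the lexicographically smallest boolean vector for
    determinism.  An edgeless network is all periphery (quality NaN).
    Isolated nodes gravitate to the periphery because attaching them to the
    core only dilutes the pattern correlation.
    """
    k = net.n_nodes
    if k < 3:
        raise ValueError("core-periphery decomposition needs at least 3 nodes")
    if rng is None:
        rng = np.random.default_rng(0)
    w = net.weights * net.significant
    if not net.significant.any():
        return np.zeros(k, dtype=bool), float("nan")
    best_c: np.ndarray | None = None
    best_q = -np.inf
    for _ in range(max(1, restarts)):
        start = rng.random(k) < 0.5
        if start.all() or not start.any():
            start[rng.integers(k)] = not start[0]
        c, q = _local_search_core(w, start)
        key = tuple(c.astype(int))
        if q > best_q + 1e-12 or (
            abs(q - best_q) <= 1e-12
            and best_c is not None
            and key < tuple(best_c.astype(int))
        ):
            best_c, best_q = c, q
    assert best_c is not None
    return best_c, best_q


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..M by descending size; ties by smallest member index."""
    labels = np.asarray(labels)
    keys = sorted(
        set(labels.tolist()),
        key=lambda m: (-int(np.sum(labels == m)), int(np.argmax(labels == m))),
    )
    remap = {old: new for new, old in enumerate(keys, start=1)}
    return np.array([remap[m] for m in labels], dtype=int)


def modularity_partition(
    net: SymptomNetwork,
    gamma: float = 1.0,
    restarts: int = 100,
    rng: np.random.Generator | None = None,
) -> PartitionResult:
    """Weighted Newman modularity communities via multi-restart Louvain.

    The greedy multi-level optimization is run `restarts` times from seeded
    starts; the best partition by the modularity objective at resolution
    `gamma` is kept, with exact ties broken by the lexicographically smallest
    renumbered label vector.  Isolated nodes become singleton modules.  The
    reported quality is recomputed from the returned labels.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    g = net.to_graph()
    names = net.variable_names
    k = len(names)
    if g.number_of_edges() == 0:
        return PartitionResult(
            labels=np.arange(1, k + 1), quality=0.0, n_restarts_used=0, seed=-1
        )
    best_labels: np.ndarray | None = None
    best_q = -np.inf
    best_seed = -1
    n_used = 0
    for _ in range(max(1, restarts)):
        seed = int(rng.integers(2**31 - 1))
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=gamma, seed=seed
        )
        q = nx.community.modularity(g, comms, weight="weight", resolution=gamma)
        raw = np.empty(k, dtype=int)
        for mid, members in enumerate(comms):
            for name in members:
                raw[names.index(name)] = mid
        labels = _renumber_by_size(raw)
        n_used += 1
        if q > best_q + 1e-12 or (
            abs(q - best_q) <= 1e-12
            and best_labels is not None
            and tuple(labels) < tuple(best_labels)
        ):
            best_labels, best_q, best_seed = labels, q, seed
    assert best_labels is not None
    # recompute the objective from the labels we return
    comms = [
        {names[i] for i in range(k) if best_labels[i] == m}
        for m in sorted(set(best_labels.tolist()))
    ]
    quality = nx.community.modularity(g, comms, weight="weight", resolution=gamma)
    return PartitionResult(
        labels=best_labels, quality=quality, n_restarts_used=n_used, seed=best_seed
    )


def compute_node_metrics(
    net: SymptomNetwork,
    betweenness_mode: str = "unweighted",
    gamma: float = 1.0,
    restarts: int = 100,
    rng: np.random.Generator | None = None,
) -> NodeMetrics:
    """All per-node measures in one pass (the full table row per symptom)."""
    if rng is None:
        rng = np.random.default_rng(0)
    part = modularity_partition(net, gamma=gamma, restarts=restarts, rng=rng)
    if net.n_nodes >= 3:
        is_core, _ = core_periphery(net, restarts=restarts, rng=rng)
    else:
        is_core = np.zeros(net.n_nodes, dtype=bool)
    return NodeMetrics(
        variable_names=list(net.variable_names),
        degree=degree(net),
        strength=strength(net),
        betweenness=betweenness(net, mode=betweenness_mode),
        module_id=part.labels,
        is_core=is_core,
        betweenness_mode=betweenness_mode,
    )


def node_metric_table(
    net: SymptomNetwork,
    prevalence: PrevalenceSummary,
    metrics: NodeMetrics,
) -> pd.DataFrame:
    """Assemble the per-variable report table.

    One row per *original* variable in input order (prevalence covers the
    pre-exclusion variable set); variables absent from the network render
    their count and percent followed by dashes.  Strength to one decimal,
    betweenness rounded to integer, core flag rendered Core/Periphery.
    Columns: variable, n_pct, degree, strength, betweenness, module,
    core_periphery.
    """
    net_names = set(metrics.variable_names)
    if not net_names.issubset(set(prevalence.variable_names)):
        missing = sorted(net_names - set(prevalence.variable_names))
        raise ValueError(f"network variables missing from prevalence table: {missing}")
    idx = {name: i for i, name in enumerate(metrics.variable_names)}
    rows = []
    for j, name in enumerate(prevalence.variable_names):
        n_pct = (
            f"{int(prevalence.count_present[j])} "
            f"({prevalence.percent_present[j]:.1f})"
        )
        if name in idx:
            i = idx[name]
            rows.append(
                (
                    name,
                    n_pct,
                    int(metrics.degree[i]),
                    f"{round_half_up(metrics.strength[i], 1):.1f}",
                    int(round_half_up(metrics.betweenness[i], 0)),
                    int(metrics.module_id[i]),
                    "Core" if metrics.is_core[i] else "Periphery",
                )
            )
        else:
            rows.append((name, n_pct, "-", "-", "-", "-", "-"))
    return pd.DataFrame(
        rows,
        columns=[
            "variable",
            "n_pct",
            "degree",
            "strength",
            "betweenness",
            "module",
            "core_periphery",
        ],
    )
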