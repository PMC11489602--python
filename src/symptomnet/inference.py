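"""Surrogate-permutation significance testing and FDR-selected network assembly.

For every symptom pair the observed plug-in MI is compared against a null
distribution built by repeatedly permuting one of the two series across
patients.  Permutation (rather than Bernoulli resampling) preserves each
variable's ones-count exactly, so every surrogate lives on the same
entropy-bounded MI scale as the observed statistic.  The p-value uses the
add-one correction p = (1 + #{MI_surr >= MI_obs}) / (n_surrogates + 1), which
is never zero and yields a valid (slightly conservative) test; ties count
toward the null.

Edges surviving Benjamini-Hochberg FDR over all pairwise p-values form the
symptom network; non-significant weights are retained in the weight matrix
for inspection but are never exported as edges.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from statsmodels.stats.multitest import multipletests

from .data import SymptomMatrix
from .information import mi_bits_from_counts, pairwise_mi

__all__ = [
    "SurrogateConfig",
    "SymptomNetwork",
    "surrogate_pvalue",
    "fdr_select",
    "build_network",
    "pair_rng",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Settings for the surrogate null and edge selection.

    n_surrogates:
        Number of permutation surrogates per pair (default 5000).  Values in
        the low hundreds are usable for smoke tests but coarsen the attainable
        p-value grid; outputs produced with fewer than 5000 surrogates should
        be labeled scaled-down.
    fdr_q:
        Benjamini-Hochberg false-discovery-rate level over the C(k,2)
        pairwise p-values (default 0.05).
    fdr_method:
        "bh" (step-up under independence/PRDS, the default) or "by"
        (Benjamini-Yekutieli, valid under arbitrary dependence).
    seed:
        Master seed; per-pair substreams are derived from it and the pair's
        sorted variable names, so results do not depend on column order.
    """

    n_surrogates: int = 5000
    fdr_q: float = 0.05
    seed: int = 0
    fdr_method: str = "bh"

    def __post_init__(self) -> None:
        if self.n_surrogates < 100:
            raise ValueError("n_surrogates must be >= 100")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must lie strictly between 0 and 1")
        if self.fdr_method not in ("bh", "by"):
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")


def pair_rng(seed: int, name_a: str, name_b: str) -> np.random.Generator:
    """Deterministic RNG substream for one variable pair.

    Keyed by the master seed and the SHA-256 digest of the *sorted* name pair,
    so the stream is identical regardless of argument order or the pair's
    position in the matrix, and stable across platforms.
    """
    a, b = sorted((str(name_a), str(name_b)))
    digest = hashlib.sha256(f"{a}\x00{b}".encode("utf-8")).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    ss = np.random.SeedSequence(entropy=[int(seed) & 0xFFFFFFFF, *map(int, words)])
    return np.random.default_rng(ss)


def _null_mi_sample(
    x: np.ndarray, y: np.ndarray, n_surrogates: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Observed MI and the surrogate MI sample for one pair.

    One series is permuted uniformly at random for each surrogate.  The pair
    is canonicalized internally (by ones-count, then byte content) so that
    swapping the arguments reproduces the identical realization, not merely
    the same distribution.
    """
    x = np.asarray(x, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be one-dimensional and equally long")
    if (int(x.sum()), x.tobytes()) > (int(y.sum()), y.tobytes()):
        x, y = y, x
    n = x.size
    sx = int(x.sum())
    sy = int(y.sum())
    n11_obs = int(np.dot(x.astype(np.int64), y.astype(np.int64)))
    obs = mi_bits_from_counts(
        n - sx - sy + n11_obs, sy - n11_obs, sx - n11_obs, n11_obs
    )
    # permute y in a block; only the cross count n11 varies across surrogates
    block = np.tile(y, (n_surrogates, 1))
    rng.permuted(block, axis=1, out=block)
    n11 = block.astype(np.int64) @ x.astype(np.int64)
    n11 = n11.astype(np.float64)
    null = mi_bits_from_counts(n - sx - sy + n11, sy - n11, sx - n11, n11)
    return obs, null


def surrogate_pvalue(
    x, y, n_surrogates: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the MI of one binary pair.

    Returns ``(p, null_sample)`` with ``p = (1 + #{MI_surr >= MI_obs}) /
    (n_surrogates + 1)``; p lies in (0, 1].  A constant series gives p = 1:
    every surrogate MI equals the observed 0.
    """
    if n_surrogates < 100:
        raise ValueError("n_surrogates must be >= 100")
    obs, null = _null_mi_sample(
        np.asarray(x), np.asarray(y), n_surrogates, rng
    )
    # exact-tie comparison is safe: observed and surrogate MI come from the
    # same integer-count formula, so equal tables give bit-identical floats
    count = int(np.count_nonzero(null >= obs))
    return (1 + count) / (n_surrogates + 1), null


def fdr_select(
    pvalues: np.ndarray, q: float = 0.05, method: str = "bh"
) -> np.ndarray:
    """Benjamini-Hochberg selection over the upper-triangle p-values.

    Returns a symmetric boolean mask with a False diagonal.  Selection is
    monotone in p by construction of the step-up rule.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("pvalues must be a square matrix")
    iu = np.triu_indices(p.shape[0], k=1)
    flat = p[iu]
    if np.any(flat <= 0) or np.any(flat > 1):
        raise ValueError("p-values must lie in (0, 1]")
    mt_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject = multipletests(flat, alpha=q, method=mt_method)[0]
    mask = np.zeros_like(p, dtype=bool)
    mask[iu] = reject
    return mask | mask.T


@dataclass
class SymptomNetwork:
    """MI weight matrix, p-values, and the FDR-significant edge mask."""

    variable_names: list[str]
    weights: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    config: SurrogateConfig = field(default_factory=SurrogateConfig)

    def __post_init__(self) -> None:
        k = len(self.variable_names)
        for name, mat in (
            ("weights", self.weights),
            ("pvalues", self.pvalues),
            ("significant", self.significant),
        ):
            mat = np.asarray(mat)
            if mat.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}, got {mat.shape}")
            if not np.array_equal(mat, mat.T):
                raise ValueError(f"{name} must be symmetric")
        if self.significant.diagonal().any():
            raise ValueError("diagonal cannot be significant")

    @property
    def n_nodes(self) -> int:
        return len(self.variable_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.significant, k=1)))

    def edge_list(self, significant_only: bool = True) -> pd.DataFrame:
        """Long-form table of pairs: source, target, mi_bits, p_value, significant."""
        rows = []
        k = self.n_nodes
        for i in range(k):
            for j in range(i + 1, k):
                if significant_only and not self.significant[i, j]:
                    continue
                rows.append(
                    (
                        self.variable_names[i],
                        self.variable_names[j],
                        self.weights[i, j],
                        self.pvalues[i, j],
                        bool(self.significant[i, j]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["source", "target", "mi_bits", "p_value", "significant"]
        )

    def to_graph(self) -> nx.Graph:
        """Undirected graph over all nodes; only significant edges, weighted by MI."""
        g = nx.Graph()
        g.add_nodes_from(self.variable_names)
        for _, row in self.edge_list(significant_only=True).iterrows():
            g.add_edge(row["source"], row["target"], weight=float(row["mi_bits"]))
        return g

    def write_edge_csv(self, path, significant_only: bool = True) -> None:
        self.edge_list(significant_only).to_csv(
            path, index=False, float_format="%.10g"
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)

    def to_json(self, path) -> None:
        """Full round-trippable dump (names, weights, p-values, mask, config)."""
        import json

        doc = {
            "variable_names": self.variable_names,
            "weights": self.weights.tolist(),
            "pvalues": self.pvalues.tolist(),
            "significant": self.significant.astype(int).tolist(),
            "config": {
                "n_surrogates": self.config.n_surrogates,
                "fdr_q": self.config.fdr_q,
                "seed": self.config.seed,
                "fdr_method": self.config.fdr_method,
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "SymptomNetwork":
        import json

        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            variable_names=list(doc["variable_names"]),
            weights=np.asarray(doc["weights"], dtype=float),
            pvalues=np.asarray(doc["pvalues"], dtype=float),
            significant=np.asarray(doc["significant"], dtype=bool),
            config=SurrogateConfig(**doc["config"]),
        )

    def write_mi_tsv(self, path) -> None:
        pd.DataFrame(
            self.weights, index=self.variable_names, columns=self.variable_names
        ).to_csv(path, sep="\t", float_format="%.10g")


def build_network(m: SymptomMatrix, cfg: SurrogateConfig) -> SymptomNetwork:
    """Full edge inference for a (already degeneracy-filtered) symptom matrix.

    Computes the pairwise MI matrix, a surrogate-permutation p-value per pair
    (each pair on its own seed-derived substream), and the FDR-selected edge
    mask.  Deterministic for a fixed config; invariant to column order up to
    the corresponding row/column permutation.
    """
    weights = pairwise_mi(m)
    k = m.n_variables
    pvals = np.ones((k, k), dtype=float)
    for i in range(k):
        xi = m.values[:, i]
        for j in range(i + 1, k):
            rng = pair_rng(cfg.seed, m.variable_names[i], m.variable_names[j])
            p, _ = surrogate_pvalue(xi, m.values[:, j], cfg.n_surrogates, rng)
            pvals[i, j] = pvals[j, i] = p
    mask = fdr_select(pvals, q=cfg.fdr_q, method=cfg.fdr_method)
    return SymptomNetwork(
        variable_names=list(m.variable_names),
        weights=weights,
        pvalues=pvals,
        significant=mask,
        config=cfg,
    )
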