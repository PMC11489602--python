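"""Entropy and plug-in mutual information for binary series.

All quantities are in bits (base-2 logarithms).  The estimator is the plain
plug-in (maximum-likelihood) estimator: empirical cell frequencies of the 2x2
contingency table are substituted for the true probabilities in

    I(X;Y) = H(X) - H(X|Y) = sum_{x,y} p(x,y) log2[ p(x,y) / (p(x) p(y)) ]

with the 0*log(0) = 0 convention applied cell-wise.  No bias correction
(Miller-Madow, shrinkage, jackknife) is applied: the downstream surrogate
permutation null is computed with the same estimator, so the estimator's bias
under independence cancels out of the significance decision.

Counts stay exact integers until the final log-sum, so results are
reproducible bit-for-bit at double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinaryJointDistribution",
    "MIResult",
    "binary_entropy",
    "joint_counts",
    "mutual_information",
    "mutual_information_from_counts",
    "pairwise_mi",
    "mi_bits_from_counts",
]

_LN2 = np.log(2.0)


def binary_entropy(p) -> float | np.ndarray:
    """Entropy of a Bernoulli(p) variable, in bits.

    ``H(p) = -p log2 p - (1-p) log2 (1-p)`` with ``0 log 0 = 0``; the result
    lies in [0, 1] and peaks at p = 0.5.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probability outside [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log2(p), 0.0)
              + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))
    h = np.maximum(h, 0.0)
    return float(h) if h.ndim == 0 else h


@dataclass(frozen=True)
class BinaryJointDistribution:
    """Exact 2x2 contingency counts over a pair of binary series.

    ``nxy`` counts patients with X = x and Y = y; the empirical joint
    probability is ``nxy / n_total`` and the marginals follow by row/column
    sums.
    """

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        for cell in (self.n00, self.n01, self.n10, self.n11):
            if cell < 0:
                raise ValueError("negative cell count")
        if self.n_total < 1:
            raise ValueError("empty contingency table")

    @property
    def n_total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def p_x(self) -> float:
        """Marginal probability P(X = 1)."""
        return (self.n10 + self.n11) / self.n_total

    @property
    def p_y(self) -> float:
        """Marginal probability P(Y = 1)."""
        return (self.n01 + self.n11) / self.n_total


@dataclass(frozen=True)
class MIResult:
    """Mutual information of a binary pair plus the entropies that bound it."""

    mi_bits: float
    entropy_x_bits: float
    entropy_y_bits: float
    cond_entropy_bits: float  # H(X|Y)


def joint_counts(x, y) -> BinaryJointDistribution:
    """Tabulate the exact 2x2 contingency counts of two equal-length binary series."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("empty series")
    x = x.astype(np.int64)
    y = y.astype(np.int64)
    n11 = int(np.dot(x, y))
    sx = int(x.sum())
    sy = int(y.sum())
    n = x.size
    return BinaryJointDistribution(
        n00=n - sx - sy + n11, n01=sy - n11, n10=sx - n11, n11=n11
    )


def mi_bits_from_counts(n00, n01, n10, n11) -> np.ndarray | float:
    """Plug-in MI in bits from 2x2 cell counts (vectorized over count arrays).

    Empty cells contribute zero (the 0*log 0 convention).  The value is
    clamped at 0 to absorb rounding at the 1e-16 level; the plug-in MI is
    mathematically nonnegative.
    """
    n00 = np.asarray(n00, dtype=np.float64)
    n01 = np.asarray(n01, dtype=np.float64)
    n10 = np.asarray(n10, dtype=np.float64)
    n11 = np.asarray(n11, dtype=np.float64)
    n = n00 + n01 + n10 + n11
    r0 = n00 + n01  # count X=0
    r1 = n10 + n11  # count X=1
    c0 = n00 + n10  # count Y=0
    c1 = n01 + n11  # count Y=1

    def term(nij, ri, cj):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = nij * np.log(nij * n / (ri * cj))
        return np.where(nij > 0, t, 0.0)

    terms = np.stack(
        [term(n00, r0, c0), term(n01, r0, c1), term(n10, r1, c0), term(n11, r1, c1)]
    )
    # summing in sorted order makes the result exactly invariant to swapping
    # x and y (which exchanges the two off-diagonal terms)
    total = np.sort(terms, axis=0).sum(axis=0)
    mi = np.maximum(total / (n * _LN2), 0.0)
    return float(mi) if mi.ndim == 0 else mi


def mutual_information_from_counts(counts: BinaryJointDistribution) -> MIResult:
    """MI and entropy bookkeeping for a 2x2 table.

    ``cond_entropy_bits`` is H(X|Y) = H(X,Y) - H(Y), computed from the joint
    entropy rather than via the MI itself, so the identity
    ``I = H(X) - H(X|Y)`` is an internal cross-check, not a tautology.
    """
    n = counts.n_total
    hx = binary_entropy(counts.p_x)
    hy = binary_entropy(counts.p_y)
    cells = np.array([counts.n00, counts.n01, counts.n10, counts.n11], dtype=float)
    probs = cells[cells > 0] / n
    h_joint = float(-(probs * np.log2(probs)).sum())
    mi = mi_bits_from_counts(counts.n00, counts.n01, counts.n10, counts.n11)
    return MIResult(
        mi_bits=mi,
        entropy_x_bits=hx,
        entropy_y_bits=hy,
        cond_entropy_bits=max(h_joint - hy, 0.0),
    )


def mutual_information(x, y) -> MIResult:
    """Plug-in mutual information of two equal-length binary series, in bits.

    Symmetric in its arguments; a constant series yields ``mi_bits = 0`` with
    a zero marginal entropy (MI is bounded by the smaller entropy, so zero
    variability forces zero shared information).
    """
    x = np.asarray(x)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return mutual_information_from_counts(joint_counts(x, y))


def pairwise_mi(m) -> np.ndarray:
    """Symmetric matrix of pairwise plug-in MI (bits) over a SymptomMatrix.

    The diagonal is set to zero by convention: self-links are never network
    edges, and downstream code treats the matrix as an adjacency candidate.
    """
    values = np.asarray(m.values, dtype=np.int64)
    n, k = values.shape
    if k < 2:
        raise ValueError("need at least 2 variables")
    ones = values.sum(axis=0)
    # all pairwise n11 in one product; remaining cells follow from marginals
    cross = values.T @ values  # k x k, entry (i, j) = n11
    n11 = cross.astype(np.float64)
    si = ones[:, None].astype(np.float64)
    sj = ones[None, :].astype(np.float64)
    mi = mi_bits_from_counts(n - si - sj + n11, sj - n11, si - n11, n11)
    np.fill_diagonal(mi, 0.0)
    return mi
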