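"""Synthetic binary symptom cohorts with controlled marginals and dependencies.

Patient-level symptom data of the kind this package analyzes typically cannot
be shared, so every pipeline stage is exercised on synthetic cohorts drawn
from a dichotomized-Gaussian (latent threshold) model: a zero-mean
multivariate normal Z with unit variances and a specified correlation matrix
is sampled per patient, and variable i is recorded present iff
Z_i exceeds the (1 - prevalence_i) standard-normal quantile.  This model
scales to dozens of correlated variables with arbitrary marginals, and
positive semidefiniteness of the latent correlation matrix is its only
consistency condition.

The mapping from a latent correlation rho to the mutual information of the
thresholded pair is computed exactly from the bivariate normal orthant
probability and inverted by bisection, so dependencies can be planted at a
target MI in bits.

Variables flagged degenerate (e.g. a 99.8%-prevalence indicator emulating a
near-universal symptom) are generated independently of the latent block with
an exact minority count, so threshold-based exclusion behaves reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

from .data import SymptomMatrix
from .information import binary_entropy

__all__ = [
    "VariableSpec",
    "CohortSpec",
    "CalibrationResult",
    "CohortError",
    "population_mi_bits",
    "calibrate_latent_rho",
    "generate_cohort",
    "planted_structure_spec",
]

#: eigenvalues above this (negative) floor are treated as rounding noise and
#: projected to zero; anything below is a genuinely inconsistent matrix
_PSD_TOL = -1e-8


class CohortError(ValueError):
    """Inconsistent cohort specification."""


@dataclass(frozen=True)
class VariableSpec:
    """One synthetic symptom: its name, marginal prevalence, degeneracy flag."""

    name: str
    prevalence: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise CohortError(
                f"{self.name}: prevalence must lie strictly in (0, 1), "
                f"got {self.prevalence}"
            )


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    Dependencies can be given either as a full latent correlation matrix
    (`latent_corr`, symmetric with unit diagonal and PSD) or as a list of
    (name_a, name_b, target_mi_bits) triples (`target_mi`), which are
    calibrated to latent correlations when the cohort is generated.  The two
    forms are mutually exclusive.
    """

    n_patients: int
    variables: list[VariableSpec]
    latent_corr: np.ndarray | None = None
    target_mi: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0
    cohort_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise CohortError("n_patients must be >= 2")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CohortError("variable names must be unique")
        if self.latent_corr is not None and self.target_mi:
            raise CohortError("give latent_corr or target_mi, not both")
        if self.latent_corr is not None:
            self.latent_corr = np.asarray(self.latent_corr, dtype=float)
            k = len(self.variables)
            if self.latent_corr.shape != (k, k):
                raise CohortError(
                    f"latent_corr must be {k}x{k}, got {self.latent_corr.shape}"
                )
            if not np.allclose(self.latent_corr, self.latent_corr.T):
                raise CohortError("latent_corr must be symmetric")
            if not np.allclose(np.diag(self.latent_corr), 1.0):
                raise CohortError("latent_corr must have unit diagonal")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def to_yaml(self, path) -> None:
        doc = {
            "n_patients": int(self.n_patients),
            "seed": int(self.seed),
            "cohort_label": self.cohort_label,
            "variables": [
                {
                    "name": v.name,
                    "prevalence": float(v.prevalence),
                    **({"degenerate": True} if v.degenerate else {}),
                }
                for v in self.variables
            ],
        }
        if self.target_mi:
            doc["target_mi"] = [
                {"pair": [a, b], "mi_bits": float(t)} for a, b, t in self.target_mi
            ]
        elif self.latent_corr is not None:
            doc["latent_corr"] = [
                [float(v) for v in row] for row in self.latent_corr
            ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        variables = [
            VariableSpec(
                name=str(v["name"]),
                prevalence=float(v["prevalence"]),
                degenerate=bool(v.get("degenerate", False)),
            )
            for v in doc["variables"]
        ]
        target_mi = [
            (str(t["pair"][0]), str(t["pair"][1]), float(t["mi_bits"]))
            for t in doc.get("target_mi", [])
        ]
        latent = doc.get("latent_corr")
        return cls(
            n_patients=int(doc["n_patients"]),
            variables=variables,
            latent_corr=None if latent is None else np.asarray(latent, dtype=float),
            target_mi=target_mi,
            seed=int(doc.get("seed", 0)),
            cohort_label=str(doc.get("cohort_label", "synthetic")),
        )


@dataclass(frozen=True)
class CalibrationResult:
    """Latent correlation matched to a target pairwise MI."""

    pair: tuple[str, str] | None
    latent_rho: float
    achieved_mi_bits: float
    target_mi_bits: float
    tolerance: float


def _mi_from_cell_probs(p00: float, p01: float, p10: float, p11: float) -> float:
    cells = np.array([p00, p01, p10, p11], dtype=float)
    cells = np.clip(cells, 0.0, 1.0)
    px = cells[2] + cells[3]
    py = cells[1] + cells[3]
    marg = np.array(
        [(1 - px) * (1 - py), (1 - px) * py, px * (1 - py), px * py]
    )
    mask = cells > 0
    return float(np.sum(cells[mask] * np.log2(cells[mask] / marg[mask])))


def population_mi_bits(rho: float, prev_x: float, prev_y: float) -> float:
    """Exact MI (bits) of a thresholded bivariate normal pair.

    The joint cell P(X=1, Y=1) is the bivariate normal orthant probability
    above the two thresholds; the remaining cells follow from the marginals.
    """
    if not (-1.0 < rho < 1.0):
        if rho in (-1.0, 1.0):  # comonotone limits handled exactly
            pass
        else:
            raise CohortError(f"latent rho must lie in [-1, 1], got {rho}")
    tx = stats.norm.ppf(1.0 - prev_x)
    ty = stats.norm.ppf(1.0 - prev_y)
    if rho >= 1.0:
        p11 = min(prev_x, prev_y)
    elif rho <= -1.0:
        p11 = max(0.0, prev_x + prev_y - 1.0)
    else:
        p11 = float(
            stats.multivariate_normal(
                mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
            ).cdf([-tx, -ty])
        )
    p11 = min(max(p11, 0.0), min(prev_x, prev_y))
    p10 = prev_x - p11
    p01 = prev_y - p11
    p00 = 1.0 - prev_x - prev_y + p11
    return _mi_from_cell_probs(p00, p01, p10, p11)


def calibrate_latent_rho(
    prev_x: float,
    prev_y: float,
    target_mi_bits: float,
    tol: float = 1e-4,
    pair: tuple[str, str] | None = None,
) -> CalibrationResult:
    """Find the latent rho >= 0 whose thresholded pair attains a target MI.

    Bisection on rho in [0, 1): the population MI is continuous and strictly
    increasing in rho on this interval, so the root is unique.  Targets above
    the entropy bound min(H(prev_x), H(prev_y)) are rejected; targets that
    exceed what rho -> 1 can deliver (the comonotone coupling) are rejected
    citing that bound.
    """
    if tol <= 0:
        raise CohortError("tolerance must be positive")
    if target_mi_bits < 0:
        raise CohortError("target MI must be nonnegative")
    bound = min(binary_entropy(prev_x), binary_entropy(prev_y))
    if target_mi_bits > bound:
        raise CohortError(
            f"target MI {target_mi_bits:.4f} bits exceeds the entropy bound "
            f"min(H(X), H(Y)) = {bound:.4f} bits"
        )
    if target_mi_bits == 0.0:
        return CalibrationResult(pair, 0.0, 0.0, 0.0, tol)
    hi = 1.0 - 1e-9
    mi_hi = population_mi_bits(hi, prev_x, prev_y)
    if mi_hi < target_mi_bits - tol:
        raise CohortError(
            f"target MI {target_mi_bits:.4f} bits is unattainable: the "
            f"comonotone limit of these marginals reaches only {mi_hi:.4f} bits"
        )
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mi_mid = population_mi_bits(mid, prev_x, prev_y)
        if abs(mi_mid - target_mi_bits) <= tol:
            return CalibrationResult(pair, mid, mi_mid, target_mi_bits, tol)
        if mi_mid < target_mi_bits:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return CalibrationResult(
        pair, mid, population_mi_bits(mid, prev_x, prev_y), target_mi_bits, tol
    )


def _resolve_latent(spec: CohortSpec) -> np.ndarray:
    """Latent correlation matrix from either spec form; degenerate rows identity."""
    k = len(spec.variables)
    if spec.latent_corr is not None:
        corr = spec.latent_corr.copy()
    else:
        corr = np.eye(k)
        index = {v.name: i for i, v in enumerate(spec.variables)}
        for a, b, target in spec.target_mi:
            if a not in index or b not in index:
                raise CohortError(f"target_mi names unknown variable in ({a}, {b})")
            i, j = index[a], index[b]
            cal = calibrate_latent_rho(
                spec.variables[i].prevalence,
                spec.variables[j].prevalence,
                target,
                pair=(a, b),
            )
            corr[i, j] = corr[j, i] = cal.latent_rho
    for i, v in enumerate(spec.variables):
        if v.degenerate:
            off = np.abs(np.delete(corr[i], i))
            if off.max(initial=0.0) > 0:
                raise CohortError(
                    f"degenerate variable {v.name!r} must be independent of "
                    "the latent block"
                )
    return corr


def generate_cohort(spec: CohortSpec) -> SymptomMatrix:
    """Draw a synthetic cohort from the dichotomized-Gaussian model.

    Deterministic for a fixed spec and seed.  A latent matrix whose smallest
    eigenvalue is below -1e-8 is rejected (naming the eigenvalue); tiny
    negative eigenvalues from rounding are projected to zero.  Degenerate
    variables get an exact minority count: round(prevalence * n) ones at
    uniformly random patient positions.
    """
    corr = _resolve_latent(spec)
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < _PSD_TOL:
        raise CohortError(
            f"latent correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {eigval.min():.3e})"
        )
    eigval = np.clip(eigval, 0.0, None)
    transform = eigvec * np.sqrt(eigval)  # rows map iid normals to latent Z
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    k = len(spec.variables)
    z = rng.standard_normal((n, k)) @ transform.T
    prev = np.array([v.prevalence for v in spec.variables])
    thresholds = stats.norm.ppf(1.0 - prev)
    values = (z > thresholds).astype(np.int8)
    for i, v in enumerate(spec.variables):
        if v.degenerate:
            n_ones = int(round(v.prevalence * n))
            col = np.zeros(n, dtype=np.int8)
            col[rng.permutation(n)[:n_ones]] = 1
            values[:, i] = col
    return SymptomMatrix(values, spec.names, cohort_label=spec.cohort_label)


def planted_structure_spec(
    kind: str,
    *,
    n_patients: int,
    seed: int = 0,
    effect_bits: float = 0.2,
    n_variables: int = 10,
    block_sizes: tuple[int, int] = (5, 5),
    n_core: int = 5,
    n_periphery: int = 8,
    prevalence: float = 0.5,
) -> CohortSpec:
    """Canonical test structures: ``global-null``, ``two-block``, ``core-periphery``.

    global-null:
        `n_variables` independent variables (identity latent matrix).
    two-block:
        two blocks of `block_sizes` variables; every within-block pair is
        planted at `effect_bits` of MI, between-block pairs are independent.
    core-periphery:
        `n_core` core variables pairwise dependent at `effect_bits`; each of
        the `n_periphery` periphery variables attaches to a single core
        variable (round-robin) at half the core effect; periphery-periphery
        pairs are independent.
    """
    if kind == "global-null":
        variables = [
            VariableSpec(f"v{i + 1:02d}", prevalence) for i in range(n_variables)
        ]
        return CohortSpec(
            n_patients=n_patients,
            variables=variables,
            latent_corr=np.eye(n_variables),
            seed=seed,
            cohort_label="global-null",
        )
    if kind == "two-block":
        ka, kb = block_sizes
        variables = [VariableSpec(f"a{i + 1:02d}", prevalence) for i in range(ka)]
        variables += [VariableSpec(f"b{i + 1:02d}", prevalence) for i in range(kb)]
        rho = calibrate_latent_rho(prevalence, prevalence, effect_bits).latent_rho
        corr = np.eye(ka + kb)
        corr[:ka, :ka] = rho
        corr[ka:, ka:] = rho
        np.fill_diagonal(corr, 1.0)
        return CohortSpec(
            n_patients=n_patients,
            variables=variables,
            latent_corr=corr,
            seed=seed,
            cohort_label="two-block",
        )
    if kind == "core-periphery":
        variables = [VariableSpec(f"core{i + 1:02d}", prevalence) for i in range(n_core)]
        variables += [
            VariableSpec(f"peri{i + 1:02d}", prevalence) for i in range(n_periphery)
        ]
        rho_cc = calibrate_latent_rho(prevalence, prevalence, effect_bits).latent_rho
        rho_cp = calibrate_latent_rho(
            prevalence, prevalence, effect_bits / 2.0
        ).latent_rho
        k = n_core + n_periphery
        corr = np.eye(k)
        corr[:n_core, :n_core] = rho_cc
        np.fill_diagonal(corr, 1.0)
        for p in range(n_periphery):
            c = p % n_core
            corr[n_core + p, c] = corr[c, n_core + p] = rho_cp
        # several pendants sharing a core variable can make the requested
        # attachment strength infeasible; shrink the core-periphery block to
        # the largest PSD-feasible scale rather than failing
        if np.linalg.eigvalsh(corr).min() < _PSD_TOL:
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                trial = corr.copy()
                trial[:n_core, n_core:] *= mid
                trial[n_core:, :n_core] *= mid
                if np.linalg.eigvalsh(trial).min() >= 1e-6:
                    lo = mid
                else:
                    hi = mid
            corr[:n_core, n_core:] *= lo
            corr[n_core:, :n_core] *= lo
        return CohortSpec(
            n_patients=n_patients,
            variables=variables,
            latent_corr=corr,
            seed=seed,
            cohort_label="core-periphery",
        )
    raise CohortError(
        f"unknown structure kind {kind!r}; expected global-null, two-block "
        "or core-periphery"
    )
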