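"""Binary symptom matrices: data model, delimited-text I/O, and pre-analysis filtering.

The central container is :class:`SymptomMatrix`, a patients x symptoms table of
lifetime indicators (1 = symptom ever present, 0 = absent).  Variables whose
minority class is too small to support a pairwise dependence analysis (in the
limit, constant columns with zero entropy) are dropped by
:func:`exclude_degenerate` before network inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SymptomMatrix",
    "PrevalenceSummary",
    "ExclusionReport",
    "SymptomDataError",
    "ParseError",
    "read_symptom_matrix",
    "write_symptom_matrix",
    "prevalence_summary",
    "exclude_degenerate",
    "round_half_up",
]


class SymptomDataError(ValueError):
    """Invalid symptom-matrix structure or contents."""


class ParseError(SymptomDataError):
    """A cell of the input file could not be interpreted as a binary indicator."""


_CELL_MAP = {
    "0": 0,
    "1": 1,
    "TRUE": 1,
    "FALSE": 0,
    "True": 1,
    "False": 0,
    "true": 1,
    "false": 0,
}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (half-up), as in printed prevalence tables.

    Python's built-in ``round`` is banker's rounding; prevalence percentages in
    clinical tables conventionally round 0.05 up, so 47.45 -> 47.5.
    """
    scale = 10.0**decimals
    return np.floor(np.asarray(x, dtype=float) * scale + 0.5) / scale


@dataclass
class SymptomMatrix:
    """Patients x variables binary indicator matrix.

    Parameters
    ----------
    values:
        Integer array of shape ``(n_patients, n_variables)`` with cells in {0, 1}.
    variable_names:
        Unique, nonempty column labels, in column order.
    cohort_label:
        Free-text label for the cohort (e.g. ``"young"``, ``"adult"``).
    """

    values: np.ndarray
    variable_names: list[str]
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.variable_names = list(self.variable_names)
        if self.values.ndim != 2:
            raise SymptomDataError("values must be a 2-D patients x variables array")
        n, k = self.values.shape
        if n < 2:
            raise SymptomDataError(f"need at least 2 patients, got {n}")
        if k < 2:
            raise SymptomDataError(f"need at least 2 variables, got {k}")
        if len(self.variable_names) != k:
            raise SymptomDataError(
                f"{len(self.variable_names)} names for {k} columns"
            )
        if len(set(self.variable_names)) != k:
            raise SymptomDataError("variable names must be unique")
        if any(not str(name) for name in self.variable_names):
            raise SymptomDataError("variable names must be nonempty")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise SymptomDataError(
                f"non-binary cell at patient row {bad[0]}, variable "
                f"{self.variable_names[bad[1]]!r}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.variable_names)


@dataclass
class PrevalenceSummary:
    """Per-variable lifetime prevalence: count present and percent present.

    Percentages are ``100 * count / n_patients`` rounded half-up to one
    decimal, matching the printed "No. (%)" convention of clinical tables.
    """

    variable_names: list[str]
    count_present: np.ndarray
    percent_present: np.ndarray
    n_patients: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable_names,
                "n": self.count_present,
                "percent": self.percent_present,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.1f")


@dataclass
class ExclusionReport:
    """Which variables were dropped before network inference, and why."""

    excluded_names: list[str] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)
    retained_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.excluded_names,
                "reason": [self.reasons[v] for v in self.excluded_names],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_symptom_matrix(
    path, delimiter: str = "\t", cohort_label: str = ""
) -> SymptomMatrix:
    """Read a delimited text file into a :class:`SymptomMatrix`.

    The file must have a header row of variable names and one row per patient;
    cells must parse as binary (``0``/``1``, or ``TRUE``/``FALSE`` mapped to
    1/0).  Column order is preserved.
    """
    # header=None keeps duplicate names intact (read_csv would mangle them)
    df = pd.read_csv(path, sep=delimiter, dtype=str, header=None, skip_blank_lines=True)
    names = [str(c).strip() for c in df.iloc[0]]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SymptomDataError(f"duplicate header names: {dupes}")
    if df.shape[0] < 2:
        raise SymptomDataError(f"{path}: no patient rows below the header")
    values = np.empty((df.shape[0] - 1, df.shape[1]), dtype=np.int8)
    raw = df.iloc[1:].to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            token = "" if cell is None or cell != cell else str(cell).strip()
            try:
                values[i, j] = _CELL_MAP[token]
            except KeyError:
                raise ParseError(
                    f"{path}: cell {cell!r} at patient row {i + 1}, column "
                    f"{names[j]!r} is not binary"
                ) from None
    return SymptomMatrix(values, names, cohort_label=cohort_label)


def write_symptom_matrix(m: SymptomMatrix, path, delimiter: str = "\t") -> None:
    """Write the matrix as delimited text with a header row (round-trips with
    :func:`read_symptom_matrix`)."""
    m.to_frame().to_csv(path, sep=delimiter, index=False)


def prevalence_summary(m: SymptomMatrix) -> PrevalenceSummary:
    """Per-variable present-count and percent, the "No. (%)" table column."""
    counts = m.values.sum(axis=0).astype(int)
    percents = round_half_up(100.0 * counts / m.n_patients, 1)
    return PrevalenceSummary(
        variable_names=list(m.variable_names),
        count_present=counts,
        percent_present=percents,
        n_patients=m.n_patients,
    )


def exclude_degenerate(
    m: SymptomMatrix, min_minority_count: int = 2
) -> tuple[SymptomMatrix, ExclusionReport]:
    """Drop near-constant variables before network inference.

    A variable is excluded when its minority class (the smaller of the ones
    count and the zeros count) is strictly below ``min_minority_count``.  A
    constant column carries zero entropy and hence zero mutual information
    with everything; columns with a single discordant patient are excluded for
    the same practical reason — they cannot support a stable dependence
    estimate.  Remaining column order is preserved.
    """
    if min_minority_count < 1:
        raise SymptomDataError("min_minority_count must be >= 1")
    n = m.n_patients
    ones = m.values.sum(axis=0).astype(int)
    minority = np.minimum(ones, n - ones)
    report = ExclusionReport()
    keep: list[int] = []
    for j, name in enumerate(m.variable_names):
        if minority[j] >= min_minority_count:
            keep.append(j)
            report.retained_names.append(name)
            continue
        if ones[j] == n:
            reason = "all-present"
        elif ones[j] == 0:
            reason = "all-absent"
        else:
            reason = "below-min-variability"
        report.excluded_names.append(name)
        report.reasons[name] = reason
    if len(keep) < 2:
        raise SymptomDataError(
            f"{len(keep)} variable(s) left after degeneracy filtering; "
            "nothing to analyze"
        )
    filtered = SymptomMatrix(
        m.values[:, keep],
        [m.variable_names[j] for j in keep],
        cohort_label=m.cohort_label,
    )
    return filtered, report
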