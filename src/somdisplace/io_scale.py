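"""Reading, validating and per-row scaling of condition tables.

A *condition table* holds one experimental condition: rows are biological
variables (transcripts, phenotypes, metabolites, ...), columns are ordered
measurements (developmental stages, tissues, species, ...). Column order is
semantically meaningful — the lagged cross-correlation step interprets it as
the measurement axis — so it is never reordered.

Before any map is trained, every row of every condition is scaled to zero
mean and unit variance, ``(x - mean(x)) / sd(x)`` with the sample (n-1)
standard deviation, so that all variables contribute equally to Euclidean
distance computations regardless of their native units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConditionTable",
    "ScaledConditionSet",
    "VariableMetadata",
    "AlignmentReport",
    "read_condition_csv",
    "read_metadata_csv",
    "scale_conditions",
    "check_alignment",
]

#: scaled rows must satisfy |mean| and |sd - 1| below this
SCALE_TOL = 1e-9


@dataclass
class ConditionTable:
    """One condition's variables-by-measurements value matrix.

    Parameters
    ----------
    condition_name
        Label of the condition (e.g. a species or treatment name).
    variable_ids
        Unique, case-sensitive row identifiers, length N.
    measurement_labels
        Ordered column labels, length M (M >= 3).
    values
        Real matrix of shape (N, M); all entries finite.
    """

    condition_name: str
    variable_ids: list[str]
    measurement_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.variable_ids = [str(v) for v in self.variable_ids]
        self.measurement_labels = [str(m) for m in self.measurement_labels]
        self.values = np.asarray(self.values, dtype=float)
        dupes = _duplicates(self.variable_ids)
        if dupes:
            raise ValueError(
                f"condition {self.condition_name!r}: duplicate variable ids: {sorted(dupes)}"
            )
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.variable_ids):
            raise ValueError("values row count does not match variable_ids")
        if m != len(self.measurement_labels):
            raise ValueError("values column count does not match measurement_labels")
        if m < 3:
            raise ValueError(
                f"condition {self.condition_name!r}: needs at least 3 measurement "
                f"columns (got {m}); lagged correlation requires a 3-point overlap"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"condition {self.condition_name!r}: non-finite value at "
                f"({self.variable_ids[bad[0]]}, {self.measurement_labels[bad[1]]})"
            )

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_measurements(self) -> int:
        return self.values.shape[1]

    def row(self, variable_id: str) -> np.ndarray:
        return self.values[self.variable_ids.index(variable_id)]

    def subset(self, variable_ids: list[str]) -> "ConditionTable":
        """New table restricted to ``variable_ids`` (given order)."""
        idx = [self.variable_ids.index(v) for v in variable_ids]
        return ConditionTable(
            self.condition_name,
            list(variable_ids),
            list(self.measurement_labels),
            self.values[idx].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.variable_ids, name="variable_id"),
            columns=self.measurement_labels,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass
class ScaledConditionSet:
    """Aligned, row-scaled conditions; the first one is the control.

    ``scaling_report`` records per variable and condition the mean and sd
    that were divided out, plus the action taken (``scaled`` or ``dropped``).
    """

    conditions: list[ConditionTable]
    scaling_report: pd.DataFrame

    @property
    def control(self) -> ConditionTable:
        return self.conditions[0]

    @property
    def test_conditions(self) -> list[ConditionTable]:
        return self.conditions[1:]

    @property
    def condition_names(self) -> list[str]:
        return [c.condition_name for c in self.conditions]

    def condition(self, name: str) -> ConditionTable:
        for c in self.conditions:
            if c.condition_name == name:
                return c
        raise KeyError(f"no condition named {name!r}")

    def write_report_csv(self, path) -> None:
        self.scaling_report.to_csv(path, index=False)


@dataclass
class VariableMetadata:
    """Categorical attributes per variable (kind, process, family, ...)."""

    frame: pd.DataFrame  # index = variable_id, columns = attributes

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate variable ids in metadata: {dupes}")
        self.frame.index = self.frame.index.astype(str)
        self.frame.index.name = "variable_id"

    @property
    def attribute_names(self) -> list[str]:
        return list(self.frame.columns)

    @classmethod
    def empty(cls) -> "VariableMetadata":
        return cls(pd.DataFrame(index=pd.Index([], name="variable_id")))


@dataclass
class AlignmentReport:
    """Outcome of a cross-condition consistency check (reporting only)."""

    passed: bool
    shared_ids: list[str]
    extras: dict[str, list[str]] = field(default_factory=dict)
    m_values: dict[str, int] = field(default_factory=dict)
    m_agrees: bool = True

    def raise_if_failed(self) -> None:
        if not self.passed:
            parts = []
            if any(self.extras.values()):
                parts.append(f"variable sets differ: extras per condition = {self.extras}")
            if not self.m_agrees:
                parts.append(f"measurement counts differ: {self.m_values}")
            raise ValueError("conditions are not aligned; " + "; ".join(parts))


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_condition_csv(
    path,
    condition_name: str,
    missing_policy: str = "error",
) -> ConditionTable:
    """Read one condition from CSV (first column = variable id, header row).

    Lines starting with ``#`` are treated as comments (the package's own
    writers put a parameter record there). ``missing_policy`` controls rows
    with missing/blank cells: ``"error"`` (default) rejects the file,
    ``"drop"`` removes the affected rows with a warning. Values are never
    imputed.
    """
    if missing_policy not in ("error", "drop"):
        raise ValueError("missing_policy must be 'error' or 'drop'")
    raw = pd.read_csv(path, index_col=0, comment="#")
    raw.index = raw.index.astype(str)

    dupes = _duplicates(list(raw.index))
    if dupes:
        raise ValueError(
            f"condition {condition_name!r} ({path}): duplicate variable ids: {sorted(dupes)}"
        )
    if raw.shape[1] < 3:
        raise ValueError(
            f"condition {condition_name!r} ({path}): fewer than 3 measurement columns"
        )

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    # cells that were present but not numbers → hard error with coordinates
    non_numeric = numeric.isna() & raw.notna()
    if non_numeric.any().any():
        r, c = np.argwhere(non_numeric.to_numpy())[0]
        raise ValueError(
            f"condition {condition_name!r} ({path}): non-numeric value "
            f"{raw.iat[r, c]!r} at ({raw.index[r]}, {raw.columns[c]})"
        )
    missing_rows = numeric.isna().any(axis=1)
    if missing_rows.any():
        names = numeric.index[missing_rows].tolist()
        if missing_policy == "error":
            raise ValueError(
                f"condition {condition_name!r} ({path}): missing values in rows {names}"
            )
        warnings.warn(
            f"condition {condition_name!r}: dropped {len(names)} row(s) with "
            f"missing values: {names}"
        )
        numeric = numeric.loc[~missing_rows]

    return ConditionTable(
        condition_name=condition_name,
        variable_ids=list(numeric.index),
        measurement_labels=[str(c) for c in numeric.columns],
        values=numeric.to_numpy(dtype=float),
    )


def read_metadata_csv(path) -> VariableMetadata:
    """Read the optional variable-metadata CSV (first column = variable id)."""
    frame = pd.read_csv(path, index_col=0, comment="#", dtype=str)
    return VariableMetadata(frame)


def check_alignment(tables: list[ConditionTable]) -> AlignmentReport:
    """Report whether conditions share the same variables and measurement count.

    Purely informative: never raises. Use :meth:`AlignmentReport.raise_if_failed`
    to escalate.
    """
    if len(tables) < 2:
        raise ValueError("alignment check needs at least 2 condition tables")
    id_sets = {t.condition_name: set(t.variable_ids) for t in tables}
    shared = set.intersection(*id_sets.values())
    extras = {
        name: sorted(ids - shared) for name, ids in id_sets.items() if ids - shared
    }
    m_values = {t.condition_name: t.n_measurements for t in tables}
    m_agrees = len(set(m_values.values())) == 1
    passed = not extras and m_agrees
    # preserve the control table's row order for the shared set
    shared_ordered = [v for v in tables[0].variable_ids if v in shared]
    return AlignmentReport(
        passed=passed,
        shared_ids=shared_ordered,
        extras=extras,
        m_values=m_values,
        m_agrees=m_agrees,
    )


def scale_row(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Z-score one row with the sample (n-1) standard deviation."""
    x = np.asarray(x, dtype=float)
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return x - mu, mu, sd
    return (x - mu) / sd, mu, sd


def scale_conditions(
    tables: list[ConditionTable],
    zero_variance_policy: str = "drop",
) -> ScaledConditionSet:
    """Row-scale every condition; first table is taken as the control.

    Each variable is scaled within each condition independently. A variable
    whose values are constant in ANY condition has no defined z-score there;
    under the default ``"drop"`` policy it is removed from EVERY condition
    (keeping the conditions aligned) and recorded in the scaling report,
    under ``"error"`` the call raises naming the variable.
    """
    if zero_variance_policy not in ("drop", "error"):
        raise ValueError("zero_variance_policy must be 'drop' or 'error'")
    if not tables:
        raise ValueError("no condition tables given")
    report_rows = []
    if len(tables) >= 2:
        check_alignment(tables).raise_if_failed()

    order = list(tables[0].variable_ids)
    # pass 1: find zero-variance offenders anywhere
    zero_var: set[str] = set()
    for t in tables:
        sds = t.values.std(axis=1, ddof=1)
        for vid, sd in zip(t.variable_ids, sds):
            if sd == 0.0:
                zero_var.add(vid)
    if zero_var and zero_variance_policy == "error":
        raise ValueError(
            f"zero-variance rows (cannot be scaled): {sorted(zero_var)}"
        )
    if zero_var:
        warnings.warn(
            f"dropped {len(zero_var)} zero-variance variable(s) from all "
            f"conditions: {sorted(zero_var)}"
        )

    keep = [v for v in order if v not in zero_var]
    if not keep:
        raise ValueError("all variables had zero variance; nothing left to scale")

    scaled_tables = []
    for t in tables:
        sub = t.subset(keep)
        vals = np.empty_like(sub.values)
        for i, vid in enumerate(sub.variable_ids):
            vals[i], mu, sd = scale_row(sub.values[i])
            report_rows.append(
                {"variable_id": vid, "condition": t.condition_name,
                 "mean": mu, "sd": sd, "action": "scaled"}
            )
        scaled_tables.append(
            ConditionTable(t.condition_name, sub.variable_ids,
                           sub.measurement_labels, vals)
        )
    for vid in sorted(zero_var):
        for t in tables:
            if vid in t.variable_ids:
                x = t.row(vid)
                report_rows.append(
                    {"variable_id": vid, "condition": t.condition_name,
                     "mean": float(x.mean()), "sd": float(x.std(ddof=1)),
                     "action": "dropped"}
                )
    report = pd.DataFrame(
        report_rows, columns=["variable_id", "condition", "mean", "sd", "action"]
    )
    return ScaledConditionSet(conditions=scaled_tables, scaling_report=report)
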