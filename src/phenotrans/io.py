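"""Observation tables and phenotype proportion matrices.

The experimental design behind this package is the pure-start multipotency
assay: FACS-purified subpopulations (one per state) are cultured and
re-phenotyped at later days.  Row ``i`` of the proportion matrix ``W(t)``
is the state composition observed at day ``t`` of the culture initiated as
pure state ``i``; ``W(0)`` is therefore the identity.

Input dialect: long-format CSV/TSV with header columns
``condition,initial_state,time_days,observed_state,value[,replicate]``.
Values are either raw cell counts or fractions in [0, 1]; percentages are
accepted only behind an explicit flag, never silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .states import StateSpace

__all__ = [
    "ObservationTable",
    "ProportionMatrix",
    "read_observation_table",
    "build_proportion_matrix",
    "proportions_to_table",
    "write_proportion_matrix",
    "read_proportion_matrix",
    "doubling_time",
]

REQUIRED_COLUMNS = ("condition", "initial_state", "time_days", "observed_state", "value")

_ROW_SUM_TOL = 1e-9
_FRACTION_SUM_TOL = 1e-6


@dataclass
class ObservationTable:
    """Long-format observations of state compositions over time.

    ``data`` holds one record per (condition, initial pure state, day,
    observed state[, replicate]) with a count or fraction in ``value``.
    """

    data: pd.DataFrame
    value_kind: str = "counts"  # "counts" | "fractions"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "fractions"):
            raise ValueError("value_kind must be 'counts' or 'fractions'")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = self.data
        if "replicate" not in df.columns:
            df = df.assign(replicate="r1")
        df = df.astype({"time_days": "int64", "value": "float64"})
        if (df["value"] < 0).any():
            raise ValueError("negative values in observation table")
        # The chain's time step is one day; fractional days are rejected
        # upstream in read_observation_table.
        if self.value_kind == "fractions":
            sums = df.groupby(
                ["condition", "initial_state", "time_days", "replicate"], sort=False
            )["value"].sum()
            bad = sums[(sums - 1.0).abs() > _FRACTION_SUM_TOL]
            if len(bad):
                key = bad.index[0]
                raise ValueError(
                    f"fractions for {key} sum to {bad.iloc[0]:.6g}, expected 1"
                )
        self.data = df

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.data["condition"]))

    @property
    def days(self) -> list[int]:
        return sorted(self.data["time_days"].unique().tolist())


def read_observation_table(
    path: str | Path,
    value_kind: str = "counts",
    percent: bool = False,
    sep: str | None = None,
) -> ObservationTable:
    """Read a long-format CSV/TSV observation table.

    Parameters
    ----------
    value_kind:
        ``"counts"`` or ``"fractions"``.
    percent:
        If true, values are percentages and are divided by 100 (only
        meaningful with ``value_kind="fractions"``).
    sep:
        Field separator; inferred from the file extension when ``None``
        (``.tsv`` → tab, otherwise comma).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    days = pd.to_numeric(df["time_days"])
    if not np.allclose(days, np.round(days)):
        raise ValueError(f"{path}: time_days must be integers (time step is 1 day)")
    df["time_days"] = np.round(days).astype("int64")
    if percent:
        if value_kind != "fractions":
            raise ValueError("percent=True requires value_kind='fractions'")
        df["value"] = df["value"] / 100.0
    return ObservationTable(data=df, value_kind=value_kind)


@dataclass
class ProportionMatrix:
    """Row-stochastic K x K phenotype proportion matrix at day ``t``.

    Row index = initial pure state, column index = observed phenotype,
    both in the state space's canonical order.
    """

    values: np.ndarray
    t: int
    space: StateSpace
    condition: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = self.space.n_states
        if v.shape != (k, k):
            raise ValueError(f"expected {k}x{k} matrix, got {v.shape}")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if (v < -_ROW_SUM_TOL).any() or (v > 1 + _ROW_SUM_TOL).any():
            raise ValueError("proportions must lie in [0, 1]")
        rs = v.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=_ROW_SUM_TOL):
            raise ValueError(f"rows must sum to 1 (got sums {rs})")
        self.values = v

    @property
    def labels(self) -> tuple[str, ...]:
        return self.space.labels


def build_proportion_matrix(
    table: ObservationTable,
    space: StateSpace,
    t: int,
    condition: str | None = None,
) -> ProportionMatrix:
    """Assemble ``W(t)`` from a long observation table.

    Counts are converted to fractions per (row, replicate); replicates are
    then averaged unweighted.  Observed states absent from a present row
    are treated as 0.  A request for ``t = 0`` with no day-0 records
    returns the identity (pure starts are pure by construction).

    Raises
    ------
    ValueError
        If an initial-state row is wholly missing, a row has zero total
        count, or the condition/day filter leaves ambiguous conditions.
    """
    df = table.data
    if condition is not None:
        df = df[df["condition"] == condition]
        if df.empty:
            raise ValueError(f"no records for condition {condition!r}")
    elif df["condition"].nunique() > 1:
        raise ValueError(
            f"table has multiple conditions {sorted(df['condition'].unique())}; "
            "pass condition="
        )
    sub = df[df["time_days"] == int(t)]
    k = space.n_states
    if sub.empty:
        if int(t) == 0:
            return ProportionMatrix(np.eye(k), t=0, space=space, condition=condition)
        raise ValueError(f"no records at day {t}")

    unknown = set(sub["observed_state"]) - set(space.labels)
    if unknown:
        raise ValueError(f"observed states not in state space: {sorted(unknown)}")

    w = np.zeros((k, k))
    for i, label in enumerate(space.labels):
        rows = sub[sub["initial_state"] == label]
        if rows.empty:
            raise ValueError(f"missing initial-state row {label!r} at day {t}")
        rep_fracs = []
        for _, rep in rows.groupby("replicate", sort=False):
            vec = np.zeros(k)
            for _, rec in rep.iterrows():
                vec[space.index(rec["observed_state"])] += rec["value"]
            total = vec.sum()
            if table.value_kind == "counts":
                if total <= 0:
                    raise ValueError(f"row {label!r} at day {t} has zero total count")
                vec = vec / total
            else:
                if total <= 0:
                    raise ValueError(f"row {label!r} at day {t} has zero total mass")
                vec = vec / total  # renormalize away rounding in stored fractions
            rep_fracs.append(vec)
        w[i] = np.mean(rep_fracs, axis=0)
    w = w / w.sum(axis=1, keepdims=True)
    return ProportionMatrix(w, t=int(t), space=space, condition=condition)


def proportions_to_table(
    matrix: ProportionMatrix, condition: str = "cond"
) -> ObservationTable:
    """Serialize a proportion matrix back into the long table dialect."""
    records = []
    cond = matrix.condition or condition
    for i, init in enumerate(matrix.labels):
        for j, obs in enumerate(matrix.labels):
            records.append(
                dict(
                    condition=cond,
                    initial_state=init,
                    time_days=matrix.t,
                    observed_state=obs,
                    value=matrix.values[i, j],
                )
            )
    return ObservationTable(pd.DataFrame.from_records(records), value_kind="fractions")


def write_proportion_matrix(matrix: ProportionMatrix, path: str | Path) -> None:
    """Write a labeled matrix CSV (state labels as row/column headers)."""
    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(
        Path(path), index_label="initial_state"
    )


def read_proportion_matrix(
    path: str | Path, space: StateSpace, t: int, condition: str | None = None
) -> ProportionMatrix:
    df = pd.read_csv(Path(path), index_col=0)
    if list(df.index) != list(space.labels) or list(df.columns) != list(space.labels):
        raise ValueError("matrix CSV labels do not match the state space order")
    return ProportionMatrix(df.to_numpy(float), t=t, space=space, condition=condition)


def doubling_time(t1: float, t2: float, n1: float, n2: float) -> float:
    """Population doubling time ``(t2 - t1) / log2(n2 / n1)`` in days.

    A negative result (shrinking population) is returned but flagged with
    a warning; equal counts make the formula undefined.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cell counts must be positive")
    if n2 == n1:
        raise ValueError("doubling time undefined for equal counts")
    dt = (t2 - t1) / math.log2(n2 / n1)
    if dt < 0:
        warnings.warn(
            f"negative doubling time {dt:.3g} d: population shrank", stacklevel=2
        )
    return dt
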