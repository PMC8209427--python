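"""Clustered-data containers, delimited-text I/O, group indexing, and
survey-weight-derived within-group sampling ratios.

The central container is :class:`ObservationTable`, a validated long-format
table of individuals nested in groups: an outcome ``y``, a predictor ``x``
(individual-level, or group-constant in the 2-1-1 design), an optional
mediator ``m``, and optional survey metadata (student/group weights, finite
group population sizes ``N_j``).  All downstream estimators consume this
container together with a :class:`ModelSpec` saying which two-level model is
being decomposed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("contextfpc")

__all__ = [
    "ConfigurationError",
    "DataError",
    "Model",
    "ModelSpec",
    "ObservationTable",
    "GroupIndex",
    "load_table",
    "write_table",
    "build_group_index",
    "school_size_from_weights",
    "within_group_sampling_ratio",
]


class ConfigurationError(ValueError):
    """Bad user configuration (missing column mapping, unknown design cell)."""


class DataError(ValueError):
    """Data violate a structural requirement (no usable groups, n_j > N_j, ...)."""


class Model(str, Enum):
    """Which two-level contextual model is decomposed."""

    MLM = "mlm"
    MED211 = "211"
    MED111 = "111"


@dataclass(frozen=True)
class ModelSpec:
    """Model form plus the roles of the data columns.

    ``MLM`` decomposes X into a group composition and an individual deviation
    in a single outcome equation.  ``MED211`` has a group-level treatment X, a
    decomposed individual-level mediator M, and outcome Y.  ``MED111``
    decomposes both X and M.
    """

    model: Model = Model.MLM

    @property
    def uses_mediator(self) -> bool:
        return self.model in (Model.MED211, Model.MED111)

    @property
    def x_is_group_level(self) -> bool:
        return self.model is Model.MED211

    @property
    def required_columns(self) -> tuple[str, ...]:
        return ("y", "x", "m") if self.uses_mediator else ("y", "x")

    @property
    def decomposed_variable(self) -> str:
        """Name of the focal decomposed predictor/mediator (x or m)."""
        return "m" if self.model is Model.MED211 else "x"


#: canonical internal column names, in storage order
_CANON = ["group", "y", "x", "m", "student_weight", "group_weight", "group_pop_size"]


@dataclass
class ObservationTable:
    """Validated long-format clustered observations.

    Wraps a pandas DataFrame with canonical columns (``group``, ``y``, ``x``,
    optional ``m``, ``student_weight``, ``group_weight``, ``group_pop_size``).
    Rows are sorted by first appearance of the group label; ``codes`` gives a
    dense 0..J-1 integer group id aligned with ``groups``.
    """

    df: pd.DataFrame
    n_dropped_rows: int = 0
    n_dropped_groups: int = 0
    codes: np.ndarray = field(init=False, repr=False)
    groups: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if "group" not in self.df.columns or "y" not in self.df.columns:
            raise ConfigurationError("table needs at least 'group' and 'y' columns")
        # dense codes in order of first appearance (deterministic output order)
        codes, groups = pd.factorize(self.df["group"], sort=False)
        self.codes = np.asarray(codes, dtype=np.int64)
        self.groups = np.asarray(groups)
        counts = np.bincount(self.codes)
        if len(counts) == 0:
            raise DataError("zero usable groups")
        if counts.min() < 2:
            raise DataError("every group must have at least 2 rows")
        first_idx = np.unique(self.codes, return_index=True)[1]
        for col in ("group_weight", "group_pop_size"):
            if col in self.df.columns:
                vals = self.df[col].to_numpy()
                if not np.array_equal(vals, vals[first_idx][self.codes]):
                    raise DataError(f"{col} must be constant within each group")
        if "group_pop_size" in self.df.columns:
            nj = counts[self.codes]
            if (self.df["group_pop_size"].to_numpy() < nj).any():
                raise DataError("observed n_j exceeds group_pop_size N_j")

    # -- convenience accessors -------------------------------------------------
    @property
    def J(self) -> int:
        return len(self.groups)

    @property
    def T(self) -> int:
        return len(self.df)

    @property
    def n_j(self) -> np.ndarray:
        return np.bincount(self.codes)

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(dtype=float)

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """T x k matrix of the named variables, in the given order."""
        return self.df[list(names)].to_numpy(dtype=float)

    def group_pop_sizes(self) -> Optional[np.ndarray]:
        """Per-group N_j aligned with ``groups``, or None if absent."""
        if "group_pop_size" not in self.df.columns:
            return None
        first_idx = np.unique(self.codes, return_index=True)[1]
        return self.df["group_pop_size"].to_numpy(dtype=float)[first_idx]


def load_table(
    source: Union[str, io.TextIOBase],
    column_map: Mapping[str, str],
    spec: Optional[ModelSpec] = None,
    sep: str = ",",
) -> ObservationTable:
    """Read a delimited text file into a validated :class:`ObservationTable`.

    ``column_map`` maps canonical names (``group``, ``y``, ``x``, ``m``,
    ``student_weight``, ``group_weight``, ``group_pop_size``) to the source
    header names.  Rows with missing values in the model variables are dropped
    (listwise deletion) and counted; groups reduced below two rows are dropped
    and counted.
    """
    if "group" not in column_map or "y" not in column_map:
        raise ConfigurationError("column_map must map at least 'group' and 'y'")
    raw = pd.read_csv(source, sep=sep, float_precision="round_trip")
    rename = {}
    for canon, src in column_map.items():
        if canon not in _CANON:
            raise ConfigurationError(f"unknown canonical column {canon!r}")
        if src not in raw.columns:
            raise ConfigurationError(f"mapped column {src!r} not in input header")
        rename[src] = canon
    df = raw[list(rename)].rename(columns=rename)

    spec = spec or ModelSpec()
    model_cols = [c for c in spec.required_columns if c in df.columns]
    n0 = len(df)
    df = df.dropna(subset=["group"] + model_cols)
    n_dropped_rows = n0 - len(df)

    counts = df.groupby("group", sort=False)["y"].transform("size")
    small = counts < 2
    n_dropped_groups = int(df.loc[small, "group"].nunique())
    df = df.loc[~small].reset_index(drop=True)
    if df.empty or df["group"].nunique() == 0:
        raise DataError("zero usable groups after filtering")
    if n_dropped_rows or n_dropped_groups:
        logger.info(
            "load_table: dropped %d incomplete rows and %d undersized groups",
            n_dropped_rows,
            n_dropped_groups,
        )
    return ObservationTable(df, n_dropped_rows, n_dropped_groups)


def write_table(table: ObservationTable, dest, sep: str = ",") -> None:
    """Write the table back to delimited text, round-trip exact for floats."""
    table.df.to_csv(dest, sep=sep, index=False, float_format="%.17g")


@dataclass
class GroupIndex:
    """Per-group counts and means plus the grand means.

    Group means are the plain arithmetic means of each group's rows; grand
    means are taken over all rows (so they equal the n_j-weighted mean of the
    group means).
    """

    variables: tuple[str, ...]
    n_j: np.ndarray          # (J,)
    group_means: np.ndarray  # (J, k) ordered as `variables`
    grand_means: np.ndarray  # (k,)
    N_j: Optional[np.ndarray] = None

    @property
    def J(self) -> int:
        return len(self.n_j)

    @property
    def T(self) -> int:
        return int(self.n_j.sum())

    def mean_of(self, var: str) -> np.ndarray:
        return self.group_means[:, self.variables.index(var)]


def build_group_index(table: ObservationTable, spec: ModelSpec) -> GroupIndex:
    """Compute n_j, the per-group mean vectors, and the grand means."""
    variables = tuple(spec.required_columns)
    for v in variables:
        if v not in table.df.columns:
            raise ConfigurationError(f"model variable {v!r} missing from table")
    Z = table.matrix(variables)
    J = table.J
    n_j = np.bincount(table.codes, minlength=J).astype(np.int64)
    sums = np.zeros((J, Z.shape[1]))
    np.add.at(sums, table.codes, Z)
    group_means = sums / n_j[:, None]
    grand_means = Z.mean(axis=0)
    return GroupIndex(variables, n_j, group_means, grand_means, table.group_pop_sizes())


def school_size_from_weights(
    student_weights: np.ndarray, group_weight: float
) -> float:
    """Estimated group (school) population size from survey weights.

    size_j = sum_i W_student_ij / W_group_j: the student weights say how many
    population members each sampled student represents, and dividing by the
    school weight removes the school-level selection probability.
    """
    w = np.asarray(student_weights, dtype=float)
    if w.size == 0 or (w <= 0).any():
        raise DataError("student weights must be positive")
    if not np.isfinite(group_weight) or group_weight <= 0:
        raise DataError("group weight must be positive")
    return float(w.sum() / group_weight)


def within_group_sampling_ratio(n_j: int, size_j: float) -> float:
    """Within-group sampling ratio r_j = n_j / size_j, clipped to 1.

    Weight noise in real surveys can push the raw ratio above 1; it is clipped
    so that the finite population correction 1 - r stays nonnegative, and the
    clip is logged.
    """
    if size_j <= 0:
        raise DataError("estimated group size must be positive")
    ratio = n_j / size_j
    if ratio > 1.0:
        logger.warning(
            "within-group sampling ratio %.4f > 1 clipped to 1 (n=%d, size=%.3f)",
            ratio, n_j, size_j,
        )
        ratio = 1.0
    return float(ratio)


def table_from_arrays(
    codes: np.ndarray,
    y: np.ndarray,
    x: np.ndarray,
    m: Optional[np.ndarray] = None,
    group_pop_size: Optional[np.ndarray] = None,
) -> ObservationTable:
    """Build an ObservationTable directly from aligned arrays (simulator path)."""
    data = {"group": codes, "y": y, "x": x}
    if m is not None:
        data["m"] = m
    if group_pop_size is not None:
        data["group_pop_size"] = group_pop_size
    return ObservationTable(pd.DataFrame(data))
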