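"""Between/within moment decomposition and its finite population correction.

For a k-vector Z observed on individuals i nested in groups j, the two
sample matrices that drive pseudo-balanced (MUML) estimation are

    S_PW = sum_j sum_i (Z_ij - Zbar_j)(Z_ij - Zbar_j)' / sum_j (n_j - 1)
    S_B  = sum_j n_j (Zbar_j - Zbar)(Zbar_j - Zbar)' / (J - 1)

together with the common (pseudo-balanced) cluster size

    n0 = (T^2 - sum_j n_j^2) / (T (J - 1)),   T = sum_j n_j.

Under two-stage sampling with a *finite* within-group population, a fraction
r = n/N of each group is observed and the group-mean sampling error shrinks
by the finite population correction fpc = 1 - n/N.  The method-of-moments
adjustment that restores the structure MUML expects is

    S_PW_fpc = ((n - 1) / (n - fpc)) * S_PW
    S_B_fpc  = S_B + ((n - 1) / (n - fpc)) * (1 - fpc) * S_PW.

fpc = 1 (negligible sampling fraction) leaves both matrices untouched, which
is the infinite-population limit assumed by latent aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_data import DataError, GroupIndex, ModelSpec, ObservationTable

__all__ = [
    "MomentSet",
    "FpcAdjustedMoments",
    "pooled_within_cov",
    "between_cov",
    "common_cluster_size",
    "finite_population_correction",
    "fpc_adjust",
    "compute_moments",
]


@dataclass
class MomentSet:
    """Sample moments entering the MUML fitting function."""

    S_PW: np.ndarray
    S_B: np.ndarray
    n0: float
    J: int
    T: int
    z_bar: np.ndarray
    variable_order: tuple[str, ...]

    def to_frame(self, which: str = "S_PW"):
        import pandas as pd

        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.variable_order, columns=self.variable_order)


@dataclass
class FpcAdjustedMoments:
    """fpc-corrected moment matrices plus how (n, fpc) were aggregated."""

    S_PW_fpc: np.ndarray
    S_B_fpc: np.ndarray
    fpc: float
    n_used: float
    provenance: str = ""


def _group_stats(table: ObservationTable, variables: Sequence[str]):
    Z = table.matrix(variables)
    J = table.J
    codes = table.codes
    n_j = np.bincount(codes, minlength=J).astype(float)
    sums = np.zeros((J, Z.shape[1]))
    np.add.at(sums, codes, Z)
    means = sums / n_j[:, None]
    return Z, codes, n_j, means


def pooled_within_cov(
    table: ObservationTable, index: GroupIndex, variables: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Pooled within-group covariance S_PW (denominator sum_j (n_j - 1))."""
    variables = tuple(variables or index.variables)
    Z, codes, n_j, means = _group_stats(table, variables)
    if (n_j < 2).any():
        raise DataError("pooled within covariance needs n_j >= 2 in every group")
    dev = Z - means[codes]
    return dev.T @ dev / (n_j.sum() - len(n_j))


def between_cov(
    table: ObservationTable, index: GroupIndex, variables: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Scaled between covariance S_B of group means (denominator J - 1)."""
    variables = tuple(variables or index.variables)
    Z, _, n_j, means = _group_stats(table, variables)
    if len(n_j) < 2:
        raise DataError("between covariance needs J >= 2 groups")
    d = means - Z.mean(axis=0)
    return (d * n_j[:, None]).T @ d / (len(n_j) - 1)


def common_cluster_size(n_list: Sequence[int]) -> float:
    """Pseudo-balanced common cluster size n0; equals n in balanced designs."""
    n = np.asarray(n_list, dtype=float)
    if n.size < 2:
        raise DataError("common cluster size needs J >= 2 groups")
    T = n.sum()
    return float((T**2 - (n**2).sum()) / (T * (n.size - 1)))


def finite_population_correction(n: float, N: float) -> float:
    """fpc = 1 - n/N for a sample of n from a finite group of N."""
    if not 0 < n <= N:
        raise DataError(f"need 0 < n <= N, got n={n}, N={N}")
    return 1.0 - n / N


def fpc_adjust(
    S_PW: np.ndarray, S_B: np.ndarray, n: float, fpc: float, provenance: str = ""
) -> FpcAdjustedMoments:
    """Method-of-moments fpc adjustment of (S_PW, S_B) at common size n.

    ``S_PW`` may be lower-dimensional than ``S_B`` when some variables (a
    group-level treatment) have no within-group variation; the S_PW term added
    to S_B is then embedded in the leading block, which is the convention used
    throughout this package (within-varying variables first).
    """
    if n <= 1:
        raise DataError("fpc adjustment needs n > 1")
    if not 0.0 <= fpc <= 1.0:
        raise DataError("fpc must lie in [0, 1]")
    S_PW = np.asarray(S_PW, dtype=float)
    S_B = np.asarray(S_B, dtype=float)
    shrink = (n - 1.0) / (n - fpc)
    S_PW_fpc = shrink * S_PW
    add = shrink * (1.0 - fpc) * S_PW
    S_B_fpc = S_B.copy()
    kw = S_PW.shape[0]
    S_B_fpc[:kw, :kw] += add
    return FpcAdjustedMoments(S_PW_fpc, S_B_fpc, float(fpc), float(n), provenance)


def compute_moments(
    table: ObservationTable,
    spec: ModelSpec,
    index: Optional[GroupIndex] = None,
    variables: Optional[Sequence[str]] = None,
) -> MomentSet:
    """S_PW, S_B, n0 and grand means for the model's variable vector.

    The variable order is (y, m, x) for mediation models and (y, x) for the
    MLM.  For the 2-1-1 design, S_PW is computed only over the within-varying
    variables (y, m); S_B covers the full vector including the group-level x.
    """
    from .core_data import build_group_index

    index = index or build_group_index(table, spec)
    order = ("y", "m", "x") if spec.uses_mediator else ("y", "x")
    order = tuple(v for v in order if v in index.variables)
    within_vars = tuple(v for v in order if not (v == "x" and spec.x_is_group_level))
    S_PW = pooled_within_cov(table, index, within_vars)
    S_B = between_cov(table, index, order)
    n0 = common_cluster_size(index.n_j)
    k = len(order)
    z_bar = np.array([index.grand_means[index.variables.index(v)] for v in order])
    return MomentSet(S_PW, S_B, n0, index.J, index.T, z_bar, order)


def aggregate_fpc(
    n_j: np.ndarray, N_j: Optional[np.ndarray] = None, ratio_j: Optional[np.ndarray] = None
) -> tuple[float, float, str]:
    """Single (n, fpc) pair for a possibly unbalanced design.

    The adjustment formulas are stated for one common n and one fpc; we use
    the pseudo-balanced size n0 and the pooled sampling fraction
    fpc = 1 - sum(n_j)/sum(N_j), both of which reduce to the exact quantities
    in balanced designs.  When only per-group ratios are known, N_j is
    reconstructed as n_j / r_j.
    """
    n_j = np.asarray(n_j, dtype=float)
    if N_j is None:
        if ratio_j is None:
            raise DataError("need group population sizes or sampling ratios")
        ratio_j = np.asarray(ratio_j, dtype=float)
        if (ratio_j <= 0).any() or (ratio_j > 1).any():
            raise DataError("sampling ratios must lie in (0, 1]")
        N_j = n_j / ratio_j
        prov = "n=n0; fpc=1-sum(n_j)/sum(n_j/r_j) from ratio column"
    else:
        N_j = np.asarray(N_j, dtype=float)
        if (n_j > N_j + 1e-9).any():
            raise DataError("n_j exceeds N_j")
        prov = "n=n0; fpc=1-sum(n_j)/sum(N_j) from group_pop_size"
    n0 = common_cluster_size(n_j)
    fpc = float(np.clip(1.0 - n_j.sum() / N_j.sum(), 0.0, 1.0))
    return n0, fpc, prov
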