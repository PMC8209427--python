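"""Finite-population two-stage data generator and Monte Carlo harness.

The generating process mirrors a two-stage cluster sample from a population
with *finite group rosters*: groups are drawn from an infinite population of
groups; each sampled group has a finite roster of N_j individuals whose
within-group components are generated from the model and then recentered so
the roster mean of the decomposed variable's within component is exactly
zero; finally n_j = round(N_j * r) individuals are drawn from each roster by
simple random sampling without replacement.  The within-group sampling ratio
r is what separates the three analysis approaches: manifest aggregation is
exact at r = 1, latent aggregation at r -> 0, and the fpc-MUML estimator
corrects for any r in between.

The design grid crosses balanced/unbalanced rosters, average roster size
N in {20, 100}, ICC of the decomposed variable in {0.05, 0.25},
between-to-within effect ratio R in {0.1, 10}, sampled group count
g in {50, 200}, and r in {0.1, 0.3, 0.5, 0.7, 0.9} — 160 cells per model.
Fits are evaluated by convergence rate, relative bias, RMSE, and observed
95% CI coverage, with a full-factorial eta-squared ANOVA to attribute
variance in the cell metrics to design factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    ConfigurationError,
    DataError,
    Model,
    ModelSpec,
    ObservationTable,
    table_from_arrays,
)
from .estimators import APPROACHES, fit, model_sigma
from .oracles import LevelMoments

logger = logging.getLogger("contextfpc")

__all__ = [
    "Condition",
    "GeneratorParams",
    "CellMetrics",
    "Rosters",
    "full_grid",
    "error_variances",
    "generate_groups",
    "sample_within",
    "generate_infinite_sample",
    "run_condition",
    "relative_bias",
    "rmse",
    "coverage",
    "convergence_rate",
    "eta_squared",
    "cells_to_frame",
    "true_sigmas",
    "implied_icc",
    "level_moments",
    "focal_params",
    "ETA_SQ_MEDIUM",
]

ETA_SQ_MEDIUM = 0.059

# ---------------------------------------------------------------------------
# design grid
# ---------------------------------------------------------------------------

_MODEL_ID = {Model.MLM: 0, Model.MED211: 1, Model.MED111: 2}


@dataclass(frozen=True)
class Condition:
    """One simulation design cell."""

    model: Model
    bal: bool
    N: int
    icc: float
    R: float
    g: int
    r: float

    def int_key(self) -> tuple[int, ...]:
        """Small-integer key used to derive per-cell random substreams."""
        return (
            _MODEL_ID[self.model], int(self.bal), self.N,
            int(round(self.icc * 100)), int(round(self.R * 10)),
            self.g, int(round(self.r * 10)),
        )


def full_grid(
    model: Model,
    bal: Sequence[bool] = (True, False),
    N: Sequence[int] = (20, 100),
    icc: Sequence[float] = (0.05, 0.25),
    R: Sequence[float] = (0.1, 10.0),
    g: Sequence[int] = (50, 200),
    r: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
) -> list[Condition]:
    """The factorial design (160 cells per model at the default levels)."""
    return [
        Condition(model, b, n, i, rr, gg, sr)
        for b in bal for n in N for i in icc for rr in R for gg in g for sr in r
    ]


# ---------------------------------------------------------------------------
# population parameters (structural values and error variances)
# ---------------------------------------------------------------------------

# group-level residual variances by (R, ICC); individual-level residual
# variances are 4.0 throughout and the 2-1-1 / 1-1-1 group residual of the
# mediator is 1.0 throughout
_VAR_U0 = {
    Model.MLM: {(0.1, 0.05): 1.35, (0.1, 0.25): 1.34, (10.0, 0.05): 1.15, (10.0, 0.25): 0.34},
    Model.MED211: {(0.1, 0.05): 1.36, (0.1, 0.25): 1.30, (10.0, 0.05): 0.24, (10.0, 0.25): 0.18},
    Model.MED111: {(0.1, 0.05): 1.34, (0.1, 0.25): 1.34, (10.0, 0.05): 0.89, (10.0, 0.25): 0.09},
}


def _cell_values(model: Model, R: float, icc: float) -> dict:
    """Full generating-parameter dictionary for one (model, R, ICC) cell."""
    try:
        var_u0 = _VAR_U0[model][(float(R), float(icc))]
    except KeyError:
        raise ConfigurationError(f"no error-variance cell for {model}, R={R}, ICC={icc}")
    v: dict[str, float] = {"var_u0": var_u0, "var_e": 4.0}
    if model is Model.MLM:
        v |= dict(beta_xw=0.2, beta_xb=R * 0.2, sigma2_xw=1.0 - icc, tau2_xb=icc)
    elif model is Model.MED211:
        # Var(M_W) chosen so that Var(M_B) = alpha_b^2 + var_w0 = 1.04 yields ICC_M
        v |= dict(
            beta_mw=0.1, beta_mb=R * 0.1, beta_xb=0.2, alpha_b=0.2,
            tau2_xb=1.0, var_w0=1.0, var_d=1.04 * (1.0 - icc) / icc,
        )
    else:
        v |= dict(
            beta_mw=0.05, beta_mb=R * 0.05, beta_xw=0.1, beta_xb=R * 0.1,
            alpha_w=0.2, alpha_b=R * 0.2, sigma2_xw=1.0 - icc, tau2_xb=icc,
            var_w0=1.0, var_d=4.0,
        )
    return v


@dataclass(frozen=True, eq=False)
class GeneratorParams:
    """Structural coefficients and error variances for one design cell."""

    model: Model
    R: float
    icc: float
    values: dict

    @classmethod
    def for_cell(cls, model: Model, R: float, icc: float) -> "GeneratorParams":
        return cls(model, R, icc, _cell_values(model, R, icc))

    def value(self, name: str) -> float:
        return self.values[name]


def error_variances(model: Model, R: float, icc: float) -> dict:
    """Residual variances of the generating model for one (R, ICC) cell.

    Returns the group-level residual variance of Y (``var_u0``), the
    individual-level residual variance of Y (``var_e``), and for mediation
    models the mediator residuals (``var_w0`` at group level; ``var_d`` at
    individual level).  Raises on an unknown cell and verifies that the
    implied ICC of Y is 0.25 within 0.01.
    """
    vals = _cell_values(model, R, icc)
    gp = GeneratorParams(model, R, icc, vals)
    icc_y = implied_icc(gp, "y")
    if abs(icc_y - 0.25) > 0.01:
        raise ConfigurationError(
            f"error-variance cell implies ICC_Y={icc_y:.4f}, expected 0.25"
        )
    return {k: v for k, v in vals.items() if k.startswith("var_")}


def true_sigmas(params: GeneratorParams) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Model-implied (Sigma_W, Sigma_B) at the generating parameter values.

    Sigma_W covers the within-varying variables only (so it is 2x2 for the
    2-1-1 design); the variable order is that of the fitted model.
    """
    from .estimators import ModelSigma

    struct = model_sigma(ModelSpec(params.model))
    wc = np.array([params.value(n) for *_, n in struct.within.a_entries])
    wp = np.array([params.value(n) for n in struct.within.psi_names])
    bc = np.array([params.value(n) for *_, n in struct.between.a_entries])
    bp = np.array([params.value(n) for n in struct.between.psi_names])
    Sw, _ = ModelSigma._build(struct.within, wc, wp)
    Sb, _ = ModelSigma._build(struct.between, bc, bp)
    return Sw, Sb, struct.names


def implied_icc(params: GeneratorParams, var: str) -> float:
    """Population ICC of a model variable implied by the generating values."""
    Sw, Sb, names = true_sigmas(params)
    struct = model_sigma(ModelSpec(params.model))
    i = names.index(var)
    if i not in struct.w_idx:
        return 1.0
    iw = struct.w_idx.index(i)
    return Sb[i, i] / (Sb[i, i] + Sw[iw, iw])


def level_moments(params: GeneratorParams, n: float) -> LevelMoments:
    """Group- and individual-level second moments for the analytic oracles."""
    Sw_small, Sb, names = true_sigmas(params)
    struct = model_sigma(ModelSpec(params.model))
    Sw = np.zeros_like(Sb)
    idx = np.asarray(struct.w_idx)
    Sw[np.ix_(idx, idx)] = Sw_small
    ii = {v: names.index(v) for v in names}
    y, x = ii["y"], ii["x"]
    m = ii.get("m", y)
    return LevelMoments(
        n=n,
        tau2_x=Sb[x, x], tau2_m=Sb[m, m], tau2_y=Sb[y, y],
        tau_xm=Sb[x, m], tau_xy=Sb[x, y], tau_my=Sb[m, y],
        sigma2_x=Sw[x, x], sigma2_m=Sw[m, m],
        sigma_xm=Sw[x, m], sigma_xy=Sw[x, y], sigma_my=Sw[m, y],
    )


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------


@dataclass
class Rosters:
    """Finite population rosters for g sampled groups."""

    N_j: np.ndarray   # (g,) roster sizes
    codes: np.ndarray  # (sum N_j,) group index per roster member
    y: np.ndarray
    x: np.ndarray
    m: Optional[np.ndarray] = None

    def to_table(self) -> ObservationTable:
        """Census table (r = 1)."""
        return table_from_arrays(self.codes, self.y, self.x, self.m,
                                 group_pop_size=self.N_j[self.codes])


def _roster_sizes(condition: Condition) -> np.ndarray:
    g, N = condition.g, condition.N
    if condition.bal:
        return np.full(g, N, dtype=np.int64)
    n_big = (g + 1) // 2
    if g % 2:
        logger.info("unbalanced design with odd g=%d: %d large groups", g, n_big)
    sizes = np.concatenate([
        np.full(n_big, (3 * N) // 2, dtype=np.int64),
        np.full(g - n_big, N // 2, dtype=np.int64),
    ])
    return sizes


def _recenter(v: np.ndarray, codes: np.ndarray, g: int) -> np.ndarray:
    cnt = np.bincount(codes, minlength=g)
    means = np.bincount(codes, weights=v, minlength=g) / cnt
    return v - means[codes]


def generate_groups(
    spec: ModelSpec, condition: Condition, params: GeneratorParams,
    rng: np.random.Generator,
) -> Rosters:
    """Draw g finite group rosters from the population model.

    Group-level and individual-level components are drawn from independent
    normals at the Table-of-variances values; the within component of the
    decomposed variable is recentered to an exact zero mean in every roster
    (so the roster group mean *is* the group composition), and M and Y are
    then built from the structural equations.
    """
    N_j = _roster_sizes(condition)
    g = len(N_j)
    codes = np.repeat(np.arange(g), N_j)
    Tot = int(N_j.sum())
    v = params.value
    u0 = rng.normal(0.0, np.sqrt(v("var_u0")), g)
    eps = rng.normal(0.0, np.sqrt(v("var_e")), Tot)

    if spec.model is Model.MLM:
        xb = rng.normal(0.0, np.sqrt(v("tau2_xb")), g)
        xw = rng.normal(0.0, np.sqrt(v("sigma2_xw")), Tot)
        xw = _recenter(xw, codes, g)
        y = v("beta_xw") * xw + v("beta_xb") * xb[codes] + u0[codes] + eps
        return Rosters(N_j, codes, y, xb[codes] + xw)

    om = rng.normal(0.0, np.sqrt(v("var_w0")), g)
    if spec.model is Model.MED211:
        xj = rng.normal(0.0, np.sqrt(v("tau2_xb")), g)
        mw = rng.normal(0.0, np.sqrt(v("var_d")), Tot)
        mw = _recenter(mw, codes, g)
        mb = v("alpha_b") * xj + om
        mvals = mb[codes] + mw
        y = (v("beta_mw") * mw + v("beta_mb") * mb[codes]
             + v("beta_xb") * xj[codes] + u0[codes] + eps)
        return Rosters(N_j, codes, y, xj[codes], mvals)

    xb = rng.normal(0.0, np.sqrt(v("tau2_xb")), g)
    xw = rng.normal(0.0, np.sqrt(v("sigma2_xw")), Tot)
    xw = _recenter(xw, codes, g)
    delta = rng.normal(0.0, np.sqrt(v("var_d")), Tot)
    mw = v("alpha_w") * xw + delta
    mb = v("alpha_b") * xb + om
    y = (v("beta_mw") * mw + v("beta_mb") * mb[codes]
         + v("beta_xw") * xw + v("beta_xb") * xb[codes] + u0[codes] + eps)
    return Rosters(N_j, codes, y, xb[codes] + xw, mb[codes] + mw)


def sample_within(rosters: Rosters, r: float, rng: np.random.Generator) -> ObservationTable:
    """SRS without replacement of n_j = round(N_j * r) per group (min 2)."""
    if not 0.0 < r <= 1.0:
        raise DataError("sampling ratio must lie in (0, 1]")
    N_j = rosters.N_j
    n_j = np.clip(np.rint(N_j * r).astype(np.int64), 2, N_j)
    keys = rng.random(len(rosters.codes))
    order = np.lexsort((keys, rosters.codes))
    starts = np.concatenate([[0], np.cumsum(N_j)[:-1]])
    rank = np.arange(len(order)) - starts[rosters.codes[order]]
    take = order[rank < n_j[rosters.codes[order]]]
    take.sort()
    codes = rosters.codes[take]
    m = rosters.m[take] if rosters.m is not None else None
    return table_from_arrays(codes, rosters.y[take], rosters.x[take], m,
                             group_pop_size=N_j[codes])


def generate_infinite_sample(
    spec: ModelSpec, params: GeneratorParams, g: int, n: int,
    rng: np.random.Generator,
) -> ObservationTable:
    """Draw n individuals per group straight from the model, with no finite
    roster and no recentering — the infinite-within-group-population setting
    assumed by the latent approach and by the analytic bias formulas."""
    N_j = np.full(g, n, dtype=np.int64)
    codes = np.repeat(np.arange(g), n)
    Tot = g * n
    v = params.value
    u0 = rng.normal(0.0, np.sqrt(v("var_u0")), g)
    eps = rng.normal(0.0, np.sqrt(v("var_e")), Tot)
    if spec.model is Model.MLM:
        xb = rng.normal(0.0, np.sqrt(v("tau2_xb")), g)
        xw = rng.normal(0.0, np.sqrt(v("sigma2_xw")), Tot)
        y = v("beta_xw") * xw + v("beta_xb") * xb[codes] + u0[codes] + eps
        return table_from_arrays(codes, y, xb[codes] + xw)
    om = rng.normal(0.0, np.sqrt(v("var_w0")), g)
    if spec.model is Model.MED211:
        xj = rng.normal(0.0, np.sqrt(v("tau2_xb")), g)
        mw = rng.normal(0.0, np.sqrt(v("var_d")), Tot)
        mb = v("alpha_b") * xj + om
        y = (v("beta_mw") * mw + v("beta_mb") * mb[codes]
             + v("beta_xb") * xj[codes] + u0[codes] + eps)
        return table_from_arrays(codes, y, xj[codes], mb[codes] + mw)
    xb = rng.normal(0.0, np.sqrt(v("tau2_xb")), g)
    xw = rng.normal(0.0, np.sqrt(v("sigma2_xw")), Tot)
    delta = rng.normal(0.0, np.sqrt(v("var_d")), Tot)
    mw = v("alpha_w") * xw + delta
    mb = v("alpha_b") * xb + om
    y = (v("beta_mw") * mw + v("beta_mb") * mb[codes]
         + v("beta_xw") * xw + v("beta_xb") * xb[codes] + u0[codes] + eps)
    return table_from_arrays(codes, y, xb[codes] + xw, mb[codes] + mw)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


def relative_bias(estimates: Sequence[float], theta: float) -> float:
    """Mean of (estimate - theta) / theta."""
    if theta == 0:
        raise ZeroDivisionError("relative bias undefined for theta = 0")
    e = np.asarray(estimates, dtype=float)
    return float(np.mean((e - theta) / theta))


def rmse(estimates: Sequence[float], theta: float) -> float:
    """Root mean squared deviation from theta."""
    e = np.asarray(estimates, dtype=float)
    return float(np.sqrt(np.mean((e - theta) ** 2)))


def coverage(intervals: Sequence[tuple[float, float]], theta: float) -> float:
    """Fraction of closed intervals containing theta."""
    iv = np.asarray(intervals, dtype=float)
    if iv.size == 0:
        return np.nan
    return float(np.mean((iv[:, 0] <= theta) & (theta <= iv[:, 1])))


def convergence_rate(flags: Sequence[bool]) -> float:
    return float(np.mean(np.asarray(flags, dtype=bool)))


def focal_params(model: Model) -> list[str]:
    """The decomposed within/between effects the harness tracks per model."""
    if model is Model.MLM:
        return ["beta_xw", "beta_xb"]
    if model is Model.MED211:
        return ["beta_mw", "beta_mb"]
    return ["beta_xw", "beta_xb", "beta_mw", "beta_mb", "alpha_w", "alpha_b"]


@dataclass
class CellMetrics:
    """Evaluated metrics for one design cell, per approach and parameter."""

    condition: Condition
    reps: int
    seed: int
    convergence: dict = field(default_factory=dict)           # approach -> rate
    metrics: dict = field(default_factory=dict)               # (approach, param) -> dict


def run_condition(
    condition: Condition,
    approaches: Sequence[str],
    reps: int,
    seed: int,
) -> CellMetrics:
    """Generate-sample-fit ``reps`` times and aggregate the cell's metrics.

    Each replication draws fresh rosters and one sample, which is shared by
    all requested approaches (paired comparisons).  Relative bias, RMSE and
    coverage are computed over converged replications only; the convergence
    rate over all replications.  Fully reproducible from (condition, seed).
    """
    for a in approaches:
        if a not in APPROACHES:
            raise ConfigurationError(f"unknown approach {a!r}")
    spec = ModelSpec(condition.model)
    params = GeneratorParams.for_cell(condition.model, condition.R, condition.icc)
    track = focal_params(condition.model)
    est: dict = {(a, p): [] for a in approaches for p in track}
    cis: dict = {(a, p): [] for a in approaches for p in track}
    conv: dict = {a: [] for a in approaches}
    key = condition.int_key()
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, *key, rep]))
        rosters = generate_groups(spec, condition, params, rng)
        table = sample_within(rosters, condition.r, rng)
        for a in approaches:
            res = fit(table, spec, a)
            conv[a].append(res.converged)
            if res.converged:
                for p in track:
                    est[(a, p)].append(res.params[p])
                    cis[(a, p)].append(res.ci95[p])
    out = CellMetrics(condition, reps, seed)
    for a in approaches:
        out.convergence[a] = convergence_rate(conv[a])
        for p in track:
            e = est[(a, p)]
            theta = params.value(p)
            if len(e) == 0:
                out.metrics[(a, p)] = dict(
                    relative_bias=np.nan, rmse=np.nan, coverage=np.nan,
                    mean_est=np.nan, sd_est=np.nan, n_converged=0,
                )
                continue
            iv = [c for c in cis[(a, p)] if np.isfinite(c[0])]
            out.metrics[(a, p)] = dict(
                relative_bias=relative_bias(e, theta),
                rmse=rmse(e, theta),
                coverage=coverage(iv, theta),
                mean_est=float(np.mean(e)),
                sd_est=float(np.std(e, ddof=1)) if len(e) > 1 else np.nan,
                n_converged=len(e),
            )
    return out


def cells_to_frame(cells: Iterable[CellMetrics]) -> pd.DataFrame:
    """Tidy long-format table: one row per cell x approach x parameter."""
    rows = []
    for c in cells:
        base = dict(
            model=c.condition.model.value, bal=c.condition.bal, N=c.condition.N,
            icc=c.condition.icc, R=c.condition.R, g=c.condition.g,
            r=c.condition.r, reps=c.reps, seed=c.seed,
        )
        for (a, p), m in c.metrics.items():
            rows.append(base | dict(approach=a, param=p,
                                    convergence_rate=c.convergence[a]) | m)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# factorial ANOVA effect sizes
# ---------------------------------------------------------------------------


def eta_squared(
    table: pd.DataFrame, factors: Sequence[str], response: str
) -> pd.DataFrame:
    """Full-factorial fixed-effects eta-squared decomposition.

    Fits the saturated ANOVA (all main effects and interactions of the given
    factors) on a complete, balanced factorial table of cell metrics and
    returns SS_effect / SS_total per effect, flagging effects above the
    conventional medium threshold of 0.059.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[list(factors) + [response]].dropna().copy()
    counts = df.groupby(list(factors), observed=True).size()
    expect = int(np.prod([df[f].nunique() for f in factors]))
    if len(counts) != expect or counts.nunique() != 1:
        raise ConfigurationError("eta_squared needs a complete balanced factorial grid")
    df = df.rename(columns={response: "_resp"})
    safe = {f: f"f{i}" for i, f in enumerate(factors)}
    df = df.rename(columns=safe)
    formula = "_resp ~ " + "*".join(f"C({safe[f]})" for f in factors)
    resp = df["_resp"].to_numpy(dtype=float)
    ss_about_mean = float(((resp - resp.mean()) ** 2).sum())
    degenerate = ss_about_mean <= 1e-12 * max(1.0, float(np.abs(resp).max()) ** 2)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = sm.stats.anova_lm(smf.ols(formula, data=df).fit(), typ=1)
    ss_total = 0.0 if degenerate else float(aov["sum_sq"].sum())
    inv = {v: k for k, v in safe.items()}
    rows = []
    for term, ss in aov["sum_sq"].items():
        if term == "Residual" and np.isclose(ss, 0.0, atol=1e-10):
            continue
        name = ":".join(
            inv.get(t[2:-1], t) if t.startswith("C(") else t
            for t in term.split(":")
        )
        eta = float(ss) / ss_total if ss_total > 0 else 0.0
        rows.append(dict(effect=name, ss=float(ss), eta_sq=eta,
                         medium=eta > ETA_SQ_MEDIUM))
    return pd.DataFrame(rows)
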