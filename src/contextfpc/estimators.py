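"""The three fitting approaches for contextual-effect decomposition.

Three estimators of the same two-level random-intercept path models
(MLM, 2-1-1 mediation, 1-1-1 mediation):

* **manifest** — ordinary random-intercept ML regressions on observed group
  means and group-mean-centered deviations (the traditional approach; group
  means carry sampling error).
* **latent** — full-information ML for the two-level SEM, modelling the
  group-level and individual-level covariance structure explicitly; assumes
  an effectively infinite within-group population.
* **muml / fpc_muml** — Muthen's pseudo-balanced limited-information
  estimator, minimizing

      F = J {log|S_W + n0 S_B(th)| + tr([.]^-1 [S_B + n0 (zbar-mu)(zbar-mu)'])}
        + (T-J) {log|S_W(th)| + tr(S_W(th)^-1 S_PW)}

  over the structural parameters; ``fpc_muml`` first applies the within-group
  finite-population correction to (S_PW, S_B), which is the package's reason
  to exist.  With fpc = 1 the two are identical; under a balanced design MUML
  coincides with full-information ML.

Statistical failure is never an exception: every fitter returns a
:class:`FitResult` with a ``converged`` flag and a ``failure_reason``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .core_data import DataError, Model, ModelSpec, ObservationTable, build_group_index
from .moments import MomentSet, aggregate_fpc, compute_moments, fpc_adjust

logger = logging.getLogger("contextfpc")

__all__ = [
    "Z95",
    "FitResult",
    "ModelSigma",
    "model_sigma",
    "fit",
    "fit_manifest",
    "fit_latent",
    "fit_muml",
    "fit_fpc_muml",
    "indirect_effect",
    "wald_ci",
]

#: two-sided 95% normal quantile, 6-digit convention
Z95 = 1.959964

_PSI_FLOOR = 1e-4
_MAXITER = 500
_GTOL = 1e-6
#: residual inf-norm of the gradient below which a line-search stall is still
#: accepted as converged (the objective is O(1e3); see docs/methods.md)
_GRAD_ACCEPT = 0.5


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Symmetric normal-theory interval estimate +/- z*se."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    if level == 0.95:
        z = Z95
    else:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2.0))
    return (estimate - z * se, estimate + z * se)


def indirect_effect(
    a: float, b: float, var_a: float, var_b: float, cov_ab: float = 0.0
) -> tuple[float, float]:
    """Product-of-coefficients indirect effect with a first-order delta SE.

    se^2 = b^2 var(a) + a^2 var(b) + 2ab cov(a,b); a negative radicand (only
    possible with a negative covariance estimate) is clamped to zero.
    """
    if var_a < 0 or var_b < 0:
        raise ValueError("variances must be nonnegative")
    est = a * b
    rad = b * b * var_a + a * a * var_b + 2.0 * a * b * cov_ab
    if rad < 0:
        logger.warning("negative delta-method radicand %.3g clamped to 0", rad)
        rad = 0.0
    return est, float(np.sqrt(rad))


# ---------------------------------------------------------------------------
# model-implied covariance structure (path form): Sigma = B Psi B', B=(I-A)^-1
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Level:
    dim: int
    a_entries: tuple[tuple[int, int, str], ...]  # (row, col, coefficient name)
    psi_names: tuple[str, ...]                   # residual/exogenous variances


@dataclass(frozen=True)
class ModelSigma:
    """Mapping from structural parameters to (Sigma_W, Sigma_B, mu).

    Variable order is (y, x) for the MLM and (y, m, x) for mediation models.
    ``w_idx`` indexes the within-varying variables (all of them except the
    group-level x of the 2-1-1 design).
    """

    model: Model
    names: tuple[str, ...]
    w_idx: tuple[int, ...]
    within: _Level
    between: _Level

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def kw(self) -> int:
        return len(self.w_idx)

    def param_names(self, with_mu: bool = False) -> list[str]:
        names = [n for _, _, n in self.within.a_entries]
        names += list(self.within.psi_names)
        names += [n for _, _, n in self.between.a_entries]
        names += list(self.between.psi_names)
        if with_mu:
            names += [f"mu_{v}" for v in self.names]
        return names

    @property
    def n_within(self) -> int:
        return len(self.within.a_entries) + len(self.within.psi_names)

    @property
    def n_between_free(self) -> int:
        """Free parameters of the unrestricted symmetric Sigma_B."""
        return self.k * (self.k + 1) // 2

    def vech_indices(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.tril_indices(self.k)
        return rows, cols

    # -- theta packing: [w_coefs, log w_psis, vech(Sigma_B), (mu)] ----------
    # The between level is parameterized directly by the free symmetric
    # Sigma_B: equivalent to the path form whenever Sigma_B is admissible,
    # but with a well-defined interior optimum in Heywood cases (where the
    # path coefficients would diverge along a likelihood ridge); see
    # docs/methods.md.
    def split(self, theta: np.ndarray, with_mu: bool = False):
        nwc = len(self.within.a_entries)
        nwp = len(self.within.psi_names)
        nb = self.n_between_free
        i = 0
        wc = theta[i : i + nwc]; i += nwc
        wp = np.exp(theta[i : i + nwp]); i += nwp
        bv = theta[i : i + nb]; i += nb
        mu = theta[i : i + self.k] if with_mu else None
        Sb = np.zeros((self.k, self.k))
        rows, cols = self.vech_indices()
        Sb[rows, cols] = bv
        Sb[cols, rows] = bv
        return wc, wp, Sb, mu

    @staticmethod
    def _build(level: _Level, coefs: np.ndarray, psis: np.ndarray):
        A = np.zeros((level.dim, level.dim))
        for (r, c, _), val in zip(level.a_entries, coefs):
            A[r, c] = val
        B = np.linalg.inv(np.eye(level.dim) - A)
        Sigma = (B * psis) @ B.T
        return Sigma, B

    def sigmas(self, theta: np.ndarray, with_mu: bool = False):
        wc, wp, Sb, mu = self.split(theta, with_mu)
        Sw, Bw = self._build(self.within, wc, wp)
        return Sw, Bw, wp, Sb, mu

    def between_grad(self, G: np.ndarray) -> np.ndarray:
        """tr(G dSigma_B/dvech) for symmetric G: diagonal entries once,
        off-diagonal entries twice."""
        rows, cols = self.vech_indices()
        g = G[rows, cols] * 2.0
        g[rows == cols] *= 0.5
        return g

    def embed_within(self, Sw: np.ndarray) -> np.ndarray:
        out = np.zeros((self.k, self.k))
        idx = np.asarray(self.w_idx)
        out[np.ix_(idx, idx)] = Sw
        return out

    @staticmethod
    def _level_grad(level: _Level, G: np.ndarray, Sigma: np.ndarray,
                    B: np.ndarray, psis: np.ndarray, log_scale: bool):
        """Gradient contributions tr(G dSigma/dtheta) for one level."""
        SGB = Sigma @ G @ B
        gc = np.array([2.0 * SGB[c, r] for r, c, _ in level.a_entries])
        M = B.T @ G @ B
        gp = np.diagonal(M).copy()
        if log_scale:
            gp = gp * psis
        return gc, gp


def model_sigma(spec: ModelSpec) -> ModelSigma:
    """Structure of the model-implied two-level covariance matrices."""
    m = spec.model
    if m is Model.MLM:
        # order (y, x)
        return ModelSigma(
            m, ("y", "x"), (0, 1),
            within=_Level(2, ((0, 1, "beta_xw"),), ("var_e", "sigma2_xw")),
            between=_Level(2, ((0, 1, "beta_xb"),), ("var_u0", "tau2_xb")),
        )
    if m is Model.MED211:
        # order (y, m, x); x has no within-group variation
        return ModelSigma(
            m, ("y", "m", "x"), (0, 1),
            within=_Level(2, ((0, 1, "beta_mw"),), ("var_e", "var_d")),
            between=_Level(
                3,
                ((0, 1, "beta_mb"), (0, 2, "beta_xb"), (1, 2, "alpha_b")),
                ("var_u0", "var_w0", "tau2_xb"),
            ),
        )
    if m is Model.MED111:
        return ModelSigma(
            m, ("y", "m", "x"), (0, 1, 2),
            within=_Level(
                3,
                ((0, 1, "beta_mw"), (0, 2, "beta_xw"), (1, 2, "alpha_w")),
                ("var_e", "var_d", "sigma2_xw"),
            ),
            between=_Level(
                3,
                ((0, 1, "beta_mb"), (0, 2, "beta_xb"), (1, 2, "alpha_b")),
                ("var_u0", "var_w0", "tau2_xb"),
            ),
        )
    raise DataError(f"unknown model {m}")


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------

_FAILURES = ("none", "optimizer", "npd_between", "singular_input", "max_iter")


@dataclass
class FitResult:
    """Estimates, standard errors, Wald intervals, and status of one fit."""

    approach: str
    model: Model
    params: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    indirect: dict = field(default_factory=dict)
    converged: bool = False
    failure_reason: str = "none"
    npd_between: bool = False
    objective: float = np.nan
    n_iter: int = 0

    def finish(self) -> "FitResult":
        assert self.failure_reason in _FAILURES
        self.converged = self.failure_reason == "none"
        for k, v in self.params.items():
            s = self.se.get(k, np.nan)
            self.ci95[k] = wald_ci(v, s) if np.isfinite(s) else (np.nan, np.nan)
        return self


def _failed(approach: str, spec: ModelSpec, reason: str, objective=np.nan) -> FitResult:
    return FitResult(
        approach=approach, model=spec.model, converged=False,
        failure_reason=reason, objective=objective,
    ).finish()


# ---------------------------------------------------------------------------
# manifest approach: exact concentrated-ML random-intercept regressions
# ---------------------------------------------------------------------------


def _ri_ml(y: np.ndarray, X: np.ndarray, codes: np.ndarray, J: int):
    """ML fit of y = X beta + u_group + e by profiling beta and sigma2.

    Concentrates the likelihood down to the scalar variance ratio
    lambda = var_u / var_e and solves the GLS normal equations from per-group
    sufficient statistics.  Returns (beta, se, var_e, var_u, m2ll).
    """
    T, p = X.shape
    n_j = np.bincount(codes, minlength=J).astype(float)
    Sx = np.zeros((J, p))
    np.add.at(Sx, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=J)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def profile(lam: float):
        w = lam / (1.0 + n_j * lam)
        A = XtX - (Sx * w[:, None]).T @ Sx
        b = Xty - (Sx * (w * Sy)[:, None]).sum(axis=0)
        c = yty - float(w @ (Sy * Sy))
        beta = np.linalg.solve(A, b)
        rss = max(c - float(beta @ b), 1e-300)
        s2 = rss / T
        m2ll = T * np.log(s2) + float(np.log1p(n_j * lam).sum()) + T * (1 + np.log(2 * np.pi))
        return m2ll, beta, s2, A

    def obj(t: float) -> float:
        return profile(np.exp(t))[0]

    res = minimize_scalar(obj, bounds=(-25.0, 12.0), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    # a boundary solution at the lower bracket is effectively var_u = 0
    if res.x < -24.0:
        lam = 0.0
    m2ll, beta, s2, A = profile(lam)
    cov = s2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    return beta, se, s2, lam * s2, m2ll


def fit_manifest(table: ObservationTable, spec: ModelSpec) -> FitResult:
    """Manifest aggregation: ML random-intercept regressions on observed
    group means and group-mean-centered deviations (equation by equation for
    the mediation models)."""
    out = FitResult(approach="manifest", model=spec.model)
    codes, J = table.codes, table.J
    y = table.column("y")
    x = table.column("x")
    n_j = np.bincount(codes, minlength=J).astype(float)
    xbar = np.bincount(codes, weights=x, minlength=J) / n_j
    xc, xm = x - xbar[codes], xbar[codes]

    try:
        if spec.model is Model.MLM:
            X = np.column_stack([np.ones_like(y), xc, xm])
            names = ["beta00", "beta_xw", "beta_xb"]
            beta, se, ve, vu, m2ll = _ri_ml(y, X, codes, J)
            out.params = dict(zip(names, beta), var_e=ve, var_u0=vu)
            out.se = dict(zip(names, se))
            out.objective = m2ll
        else:
            m = table.column("m")
            mbar = np.bincount(codes, weights=m, minlength=J) / n_j
            mc, mm = m - mbar[codes], mbar[codes]
            if spec.model is Model.MED211:
                Xy = np.column_stack([np.ones_like(y), mc, mm, x])
                ynames = ["beta00", "beta_mw", "beta_mb", "beta_xb"]
                Xm = np.column_stack([np.ones_like(y), x])
                mnames = ["alpha00", "alpha_b"]
            else:
                Xy = np.column_stack([np.ones_like(y), mc, mm, xc, xm])
                ynames = ["beta00", "beta_mw", "beta_mb", "beta_xw", "beta_xb"]
                Xm = np.column_stack([np.ones_like(y), xc, xm])
                mnames = ["alpha00", "alpha_w", "alpha_b"]
            by, sy, ve, vu, m2y = _ri_ml(y, Xy, codes, J)
            bm, sm, vd, vw, m2m = _ri_ml(m, Xm, codes, J)
            out.params = dict(zip(ynames, by)) | dict(zip(mnames, bm))
            out.params |= dict(var_e=ve, var_u0=vu, var_d=vd, var_w0=vw)
            out.se = dict(zip(ynames, sy)) | dict(zip(mnames, sm))
            out.objective = m2y + m2m
            # a and b come from different equations: cov(a, b) = 0
            _add_indirect(out, between=True, cov_ab=0.0)
            if spec.model is Model.MED111:
                _add_indirect(out, between=False, cov_ab=0.0)
    except np.linalg.LinAlgError:
        return _failed("manifest", spec, "singular_input")
    if not all(np.isfinite(v) for v in out.params.values()):
        return _failed("manifest", spec, "singular_input")
    return out.finish()


def _add_indirect(out: FitResult, between: bool, cov_ab: float) -> None:
    a_name, b_name = ("alpha_b", "beta_mb") if between else ("alpha_w", "beta_mw")
    if a_name not in out.params or b_name not in out.params:
        return
    a, b = out.params[a_name], out.params[b_name]
    sa, sb = out.se.get(a_name, np.nan), out.se.get(b_name, np.nan)
    if not (np.isfinite(sa) and np.isfinite(sb)):
        return
    est, se = indirect_effect(a, b, sa**2, sb**2, cov_ab)
    key = "indirect_b" if between else "indirect_w"
    out.indirect[key] = {"est": est, "se": se, "ci95": wald_ci(est, se)}


# ---------------------------------------------------------------------------
# shared machinery for the structured (latent / MUML) objectives
# ---------------------------------------------------------------------------


def _chol_inv_logdet(M: np.ndarray):
    """(inverse, logdet) via Cholesky; raises LinAlgError when not PD."""
    L = np.linalg.cholesky(M)
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv, 2.0 * float(np.log(np.diagonal(L)).sum())


def _regression_start(S: np.ndarray, level: _Level) -> tuple[np.ndarray, np.ndarray]:
    """Moment starting values: recursive regression solves on a target S."""
    coefs = np.zeros(len(level.a_entries))
    psis = np.zeros(level.dim)
    rows: dict[int, list[tuple[int, int]]] = {}
    for i, (r, c, _) in enumerate(level.a_entries):
        rows.setdefault(r, []).append((i, c))
    for p in range(level.dim):
        preds = rows.get(p, [])
        if not preds:
            psis[p] = max(S[p, p], _PSI_FLOOR)
            continue
        q = [c for _, c in preds]
        try:
            sol = np.linalg.solve(S[np.ix_(q, q)], S[q, p])
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(S[np.ix_(q, q)]) @ S[q, p]
        sol = np.clip(sol, -50.0, 50.0)
        for (i, _), v in zip(preds, sol):
            coefs[i] = v
        psis[p] = max(S[p, p] - float(sol @ S[q, p]), _PSI_FLOOR)
    return coefs, psis


def _path_from_sigma(S: np.ndarray, level: _Level) -> tuple[np.ndarray, np.ndarray]:
    """Exact recursive path solve on a symmetric S (no floors or clips).

    Inverts Sigma = B Psi B' for the recursive model: regression coefficients
    from the (possibly indefinite) predictor submatrix and residual variances
    as the Schur complements.  Residuals can come out negative — that is the
    Heywood-case signal, not an error.
    """
    coefs = np.zeros(len(level.a_entries))
    psis = np.zeros(level.dim)
    rows: dict[int, list[tuple[int, int]]] = {}
    for i, (r, c, _) in enumerate(level.a_entries):
        rows.setdefault(r, []).append((i, c))
    for p in range(level.dim):
        preds = rows.get(p, [])
        if not preds:
            psis[p] = S[p, p]
            continue
        q = [c for _, c in preds]
        sub = S[np.ix_(q, q)]
        try:
            sol = np.linalg.solve(sub, S[q, p])
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(sub) @ S[q, p]
        for (i, _), v in zip(preds, sol):
            coefs[i] = v
        psis[p] = S[p, p] - float(sol @ S[q, p])
    return coefs, psis


def _start_theta(struct: ModelSigma, S_W: np.ndarray, S_B: np.ndarray,
                 n0: float, zbar: Optional[np.ndarray]) -> np.ndarray:
    wc, wp = _regression_start(S_W, struct.within)
    SigB_mom = (S_B - struct.embed_within(S_W)) / n0
    SigB_mom = 0.5 * (SigB_mom + SigB_mom.T)
    d = np.diagonal(SigB_mom).copy()
    bad = d < _PSI_FLOOR
    if bad.any():
        SigB_mom = SigB_mom.copy()
        SigB_mom[np.diag_indices_from(SigB_mom)] = np.maximum(d, _PSI_FLOOR)
    rows, cols = struct.vech_indices()
    theta = np.concatenate([wc, np.log(wp), SigB_mom[rows, cols]])
    if zbar is not None:
        theta = np.concatenate([theta, zbar])
    return theta


def _damp_start(fun, theta: np.ndarray, struct: ModelSigma, with_mu: bool) -> np.ndarray:
    """Shrink the between start toward a small diagonal until F is finite."""
    if np.isfinite(fun(theta)[0]):
        return theta
    nw = struct.n_within
    nb = struct.n_between_free
    rows, cols = struct.vech_indices()
    diag_vech = np.where(rows == cols, 0.05, 0.0)
    for w in (0.5, 0.25, 0.1, 0.0):
        cand = theta.copy()
        cand[nw : nw + nb] = w * theta[nw : nw + nb] + (1 - w) * diag_vech
        if np.isfinite(fun(cand)[0]):
            return cand
    return theta


def _run_bfgs(fun, x0: np.ndarray):
    res = minimize(fun, x0, jac=True, method="BFGS",
                   options={"gtol": _GTOL, "maxiter": _MAXITER})
    gnorm = float(np.max(np.abs(res.jac)))
    if res.status == 1:
        reason = "max_iter"
    elif res.success or gnorm < _GRAD_ACCEPT:
        reason = "none"
    else:
        reason = "optimizer"
    return res, reason


def _hessian_cov(fun, theta: np.ndarray) -> np.ndarray:
    """Covariance of theta-hat: 2 * inverse curvature of the objective
    (the objective plays the role of -2 log likelihood)."""
    p = len(theta)
    H = np.zeros((p, p))
    for i in range(p):
        h = 1e-5 * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        gp = fun(tp)[1]
        gm = fun(tm)[1]
        H[i] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = 2.0 * np.linalg.pinv(H)
    return cov


def _package_structured(out: FitResult, struct: ModelSigma, theta: np.ndarray,
                        cov: np.ndarray, with_mu: bool) -> FitResult:
    """Translate (theta-hat, cov) into named path parameters with SEs.

    Within-level path parameters are read off directly (delta method back
    from the log scale for variances).  Between-level path parameters are
    recovered from the fitted Sigma_B by the exact recursive solve, with
    their covariance obtained by the delta method through the numerical
    Jacobian of that mapping.
    """
    names = struct.param_names(with_mu)
    wc, wp, Sb, mu = struct.split(theta, with_mu)
    bc, bp = _path_from_sigma(Sb, struct.between)
    values = np.concatenate([wc, wp, bc, bp] + ([mu] if with_mu else []))

    nwc = len(struct.within.a_entries)
    nwp = len(struct.within.psi_names)
    nw = struct.n_within
    nb = struct.n_between_free
    rows, cols = struct.vech_indices()

    # Jacobian of vech(Sigma_B) -> between path parameters
    nbp = len(struct.between.a_entries) + len(struct.between.psi_names)
    Jb = np.zeros((nbp, nb))
    base = np.concatenate([bc, bp])
    for j in range(nb):
        h = 1e-6 * (1.0 + abs(theta[nw + j]))
        Sp = Sb.copy()
        Sp[rows[j], cols[j]] += h
        Sp[cols[j], rows[j]] = Sp[rows[j], cols[j]]
        cp, pp = _path_from_sigma(Sp, struct.between)
        Jb[:, j] = (np.concatenate([cp, pp]) - base) / h
    cov_b_vech = cov[nw : nw + nb, nw : nw + nb]
    cov_bpath = Jb @ cov_b_vech @ Jb.T

    var_all = np.concatenate([
        np.diagonal(cov)[:nw],
        np.diagonal(cov_bpath),
        np.diagonal(cov)[nw + nb :] if with_mu else np.empty(0),
    ])
    ses = np.where(var_all >= 0, np.sqrt(np.abs(var_all)), np.nan)
    ses = ses.copy()
    ses[nwc : nwc + nwp] *= wp  # log-scale delta method

    out.params = dict(zip(names, values))
    out.se = dict(zip(names, ses))
    # Heywood flag: fitted between covariance matrix not positive semidefinite
    out.npd_between = bool(np.linalg.eigvalsh(Sb).min() < 0)
    if struct.model in (Model.MED211, Model.MED111):
        bnames = [n for *_, n in struct.between.a_entries] + list(struct.between.psi_names)
        bidx = {n: i for i, n in enumerate(bnames)}
        cab = float(cov_bpath[bidx["alpha_b"], bidx["beta_mb"]])
        _add_indirect(out, between=True, cov_ab=cab)
        if struct.model is Model.MED111:
            widx = {n: i for i, n in enumerate(names[:nw])}
            caw = float(cov[widx["alpha_w"], widx["beta_mw"]])
            _add_indirect(out, between=False, cov_ab=caw)
    return out.finish()


# ---------------------------------------------------------------------------
# MUML and fpc-MUML
# ---------------------------------------------------------------------------


def _muml_objective(struct: ModelSigma, S_PW: np.ndarray, S_Bhat: np.ndarray,
                    n0: float, J: int, T: int):
    """Pseudo-balanced fitting function F and its analytic gradient.

    The mean vector is concentrated out exactly (mu-hat = zbar), so the
    (zbar - mu) term of F vanishes identically.
    """
    def fun(theta: np.ndarray):
        Sw, Bw, wp, Sb, _ = struct.sigmas(theta, with_mu=False)
        SigT = struct.embed_within(Sw) + n0 * Sb
        try:
            Ti, Tld = _chol_inv_logdet(SigT)
            Wi, Wld = _chol_inv_logdet(Sw)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        f = J * (Tld + float(np.sum(Ti * S_Bhat))) \
            + (T - J) * (Wld + float(np.sum(Wi * S_PW)))
        G_T = J * (Ti - Ti @ S_Bhat @ Ti)
        G_Wp = (T - J) * (Wi - Wi @ S_PW @ Wi)
        idx = np.asarray(struct.w_idx)
        G_W = G_Wp + G_T[np.ix_(idx, idx)]
        gwc, gwp = ModelSigma._level_grad(struct.within, G_W, Sw, Bw, wp, True)
        gb = struct.between_grad(n0 * G_T)
        return f, np.concatenate([gwc, gwp, gb])

    return fun


def _fit_muml_core(approach: str, table: ObservationTable, spec: ModelSpec,
                   S_PW: np.ndarray, S_Bhat: np.ndarray, mom: MomentSet) -> FitResult:
    struct = model_sigma(spec)
    if np.linalg.matrix_rank(S_PW) < S_PW.shape[0]:
        return _failed(approach, spec, "singular_input")
    fun = _muml_objective(struct, S_PW, S_Bhat, mom.n0, mom.J, mom.T)
    x0 = _damp_start(fun, _start_theta(struct, S_PW, S_Bhat, mom.n0, None),
                     struct, with_mu=False)
    if not np.isfinite(fun(x0)[0]):
        return _failed(approach, spec, "singular_input")
    res, reason = _run_bfgs(fun, x0)
    out = FitResult(approach=approach, model=spec.model,
                    objective=float(res.fun), n_iter=int(res.nit))
    if reason != "none":
        out.failure_reason = reason
        return out.finish()
    cov = _hessian_cov(fun, res.x)
    return _package_structured(out, struct, res.x, cov, with_mu=False)


def fit_muml(table: ObservationTable, spec: ModelSpec) -> FitResult:
    """Pseudo-balanced (MUML) fit on the unadjusted moment matrices."""
    mom = compute_moments(table, spec)
    return _fit_muml_core("muml", table, spec, mom.S_PW, mom.S_B, mom)


def fit_fpc_muml(
    table: ObservationTable,
    spec: ModelSpec,
    pop_sizes: Optional[np.ndarray] = None,
    ratios: Optional[Union[float, np.ndarray]] = None,
) -> FitResult:
    """The within-group finite-population-corrected MUML estimator.

    ``pop_sizes`` (per-group N_j, aligned with ``table.groups``) wins over
    ``ratios`` when both are given; if neither argument is supplied the
    table's ``group_pop_size`` column is used.
    """
    mom = compute_moments(table, spec)
    index = build_group_index(table, spec)
    if pop_sizes is None and ratios is None:
        pop_sizes = table.group_pop_sizes()
        if pop_sizes is None:
            raise DataError("fpc_muml needs group population sizes or sampling ratios")
    if pop_sizes is not None and ratios is not None:
        logger.warning("both N_j and ratios supplied; using N_j")
        ratios = None
    if ratios is not None and np.isscalar(ratios):
        ratios = np.full(index.J, float(ratios))
    n_used, fpc, prov = aggregate_fpc(index.n_j, pop_sizes, ratios)
    adj = fpc_adjust(mom.S_PW, mom.S_B, n_used, fpc, prov)
    return _fit_muml_core("fpc_muml", table, spec, adj.S_PW_fpc, adj.S_B_fpc, mom)


# ---------------------------------------------------------------------------
# latent aggregation: full-information ML
# ---------------------------------------------------------------------------


def _latent_objective(struct: ModelSigma, W_pool: np.ndarray, sizes: np.ndarray,
                      J_s: np.ndarray, b_s: np.ndarray, M2_s: np.ndarray,
                      T: int, J: int, const: float):
    """Exact -2 log likelihood of the two-level model and its gradient.

    Each group's contribution splits into a mean component
    N(zbar_j; mu, Sigma_B + Sigma_W / n_j) and (n_j - 1) deviation
    components N(0, Sigma_W); groups are pre-aggregated by distinct size so
    one evaluation costs a handful of k x k operations.
    """
    def fun(theta: np.ndarray):
        Sw, Bw, wp, Sb, mu = struct.sigmas(theta, with_mu=True)
        SwE = struct.embed_within(Sw)
        try:
            Wi, Wld = _chol_inv_logdet(Sw)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        f = (T - J) * Wld + float(np.sum(Wi * W_pool)) + const
        G_W = (T - J) * Wi - Wi @ W_pool @ Wi
        G_B = np.zeros((struct.k, struct.k))
        g_mu = np.zeros(struct.k)
        widx = np.asarray(struct.w_idx)
        for s, js, bs, m2 in zip(sizes, J_s, b_s, M2_s):
            V = Sb + SwE / s
            try:
                Vi, Vld = _chol_inv_logdet(V)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros_like(theta)
            C = m2 - np.outer(mu, bs) - np.outer(bs, mu) + js * np.outer(mu, mu)
            f += js * Vld + float(np.sum(Vi * C))
            G = js * Vi - Vi @ C @ Vi
            G_B += G
            G_W += G[np.ix_(widx, widx)] / s
            g_mu += -2.0 * (Vi @ (bs - js * mu))
        gwc, gwp = ModelSigma._level_grad(struct.within, G_W, Sw, Bw, wp, True)
        gb = struct.between_grad(G_B)
        return f, np.concatenate([gwc, gwp, gb, g_mu])

    return fun


def _latent_stats(table: ObservationTable, spec: ModelSpec, struct: ModelSigma):
    order = struct.names
    Z = table.matrix(order)
    codes, J = table.codes, table.J
    n_j = np.bincount(codes, minlength=J).astype(float)
    sums = np.zeros((J, struct.k))
    np.add.at(sums, codes, Z)
    means = sums / n_j[:, None]
    widx = np.asarray(struct.w_idx)
    dev = Z[:, widx] - means[codes][:, widx]
    W_pool = dev.T @ dev
    sizes = np.unique(n_j)
    J_s, b_s, M2_s = [], [], []
    for s in sizes:
        sel = means[n_j == s]
        J_s.append(len(sel))
        b_s.append(sel.sum(axis=0))
        M2_s.append(sel.T @ sel)
    kw = struct.kw
    const = kw * float(np.log(n_j).sum()) \
        + (n_j.sum() * kw + J * (struct.k - kw)) * np.log(2 * np.pi)
    return (W_pool, np.asarray(sizes), np.asarray(J_s), np.asarray(b_s),
            np.asarray(M2_s), int(n_j.sum()), J, const, means, n_j)


def fit_latent(table: ObservationTable, spec: ModelSpec) -> FitResult:
    """Latent aggregation: full-information ML for the two-level path model."""
    struct = model_sigma(spec)
    (W_pool, sizes, J_s, b_s, M2_s, T, J, const, means, n_j) = _latent_stats(
        table, spec, struct
    )
    fun = _latent_objective(struct, W_pool, sizes, J_s, b_s, M2_s, T, J, const)
    S_PW = W_pool / (T - J)
    d = (means - means.mean(axis=0))
    S_B = (d * n_j[:, None]).T @ d / (J - 1)
    n0 = (T**2 - float((n_j**2).sum())) / (T * (J - 1))
    zbar = (means * n_j[:, None]).sum(axis=0) / T
    if np.linalg.matrix_rank(S_PW) < S_PW.shape[0]:
        return _failed("latent", spec, "singular_input")
    x0 = _damp_start(fun, _start_theta(struct, S_PW, S_B, n0, zbar),
                     struct, with_mu=True)
    if not np.isfinite(fun(x0)[0]):
        return _failed("latent", spec, "singular_input")
    res, reason = _run_bfgs(fun, x0)
    out = FitResult(approach="latent", model=spec.model,
                    objective=float(res.fun), n_iter=int(res.nit))
    if reason != "none":
        out.failure_reason = reason
        return out.finish()
    cov = _hessian_cov(fun, res.x)
    return _package_structured(out, struct, res.x, cov, with_mu=True)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

APPROACHES = ("manifest", "latent", "muml", "fpc_muml")


def fit(table: ObservationTable, spec: ModelSpec, approach: str, **kwargs) -> FitResult:
    """Fit ``table`` under ``spec`` with the named approach."""
    if spec.x_is_group_level:
        x = table.column("x")
        first = np.unique(table.codes, return_index=True)[1]
        if not np.array_equal(x, x[first][table.codes]):
            raise DataError("2-1-1 model requires x constant within each group")
    if approach == "manifest":
        return fit_manifest(table, spec)
    if approach == "latent":
        return fit_latent(table, spec)
    if approach == "muml":
        return fit_muml(table, spec)
    if approach in ("fpc_muml", "fpc"):
        return fit_fpc_muml(table, spec, **kwargs)
    raise DataError(f"unknown approach {approach!r}")
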