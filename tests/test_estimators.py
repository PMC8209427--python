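"""Correctness of the manifest, latent (FIML), MUML and fpc-MUML fitters."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import contextfpc as cf
from contextfpc.core_data import Model, ModelSpec, table_from_arrays
from contextfpc.estimators import (
    Z95,
    _latent_objective,
    _latent_stats,
    _muml_objective,
    _start_theta,
    indirect_effect,
    model_sigma,
    wald_ci,
)
from contextfpc.moments import compute_moments
from tests.conftest import make_table


class TestWaldCI:
    def test_unit_normal_interval(self):
        lo, hi = wald_ci(0.0, 1.0)
        assert (lo, hi) == (-Z95, Z95)

    def test_degenerate(self):
        assert wald_ci(1.5, 0.0) == (1.5, 1.5)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.0, -1.0)

    def test_mc_coverage_near_nominal(self, rng):
        theta, se = 0.3, 0.7
        draws = rng.normal(theta, se, size=100_000)
        covered = np.abs(draws - theta) <= Z95 * se
        assert abs(covered.mean() - 0.95) < 0.005


class TestIndirectEffect:
    def test_zero_path(self):
        est, se = indirect_effect(0.0, 2.0, 0.09, 0.04, 0.0)
        assert est == 0.0 and np.isclose(se, 2.0 * 0.3)

    def test_no_uncertainty(self):
        assert indirect_effect(0.5, 0.5, 0.0, 0.0, 0.0) == (0.25, 0.0)

    def test_delta_vs_parametric_bootstrap(self, rng):
        a, b, va, vb = 0.2, 1.0, 0.01, 0.01
        _, se = indirect_effect(a, b, va, vb, 0.0)
        draws = rng.normal(a, np.sqrt(va), 100_000) * rng.normal(b, np.sqrt(vb), 100_000)
        assert abs(se - draws.std(ddof=1)) / draws.std(ddof=1) < 0.02


class TestManifest:
    def test_exact_linear_dependence(self):
        rng = np.random.default_rng(0)
        codes = np.repeat(np.arange(30), 6)
        x = rng.normal(size=180)
        xbar = np.bincount(codes, weights=x) / 6
        y = 2.0 * (x - xbar[codes])
        res = cf.fit_manifest(table_from_arrays(codes, y, x), ModelSpec())
        assert res.converged
        assert abs(res.params["beta_xw"] - 2.0) < 1e-8
        assert res.params["var_e"] < 1e-10

    def test_matches_mixedlm_ml(self):
        import statsmodels.api as sm

        t, spec, _ = make_table(g=100, N=20, r=0.5, icc=0.25, R=0.1, seed=3)
        res = cf.fit_manifest(t, spec)
        df = t.df.copy()
        xbar = df.groupby("group")["x"].transform("mean")
        df["xc"], df["xm"] = df["x"] - xbar, xbar
        ref = sm.MixedLM.from_formula("y ~ xc + xm", groups="group", data=df).fit(
            reml=False
        )
        assert np.isclose(res.params["beta_xw"], ref.params["xc"], atol=1e-7)
        assert np.isclose(res.params["beta_xb"], ref.params["xm"], atol=1e-7)
        assert np.isclose(res.params["var_u0"], ref.cov_re.iloc[0, 0], atol=1e-5)
        assert np.isclose(res.se["beta_xb"], ref.bse["xm"], atol=1e-5)
        assert np.isclose(res.objective, -2 * ref.llf, atol=1e-6)

    def test_degenerate_design_flagged_not_raised(self):
        codes = np.repeat(np.arange(5), 4)
        y = np.random.default_rng(1).normal(size=20)
        res = cf.fit_manifest(table_from_arrays(codes, y, np.zeros(20)), ModelSpec())
        assert not res.converged and res.failure_reason == "singular_input"


class TestObjectivesAndGradients:
    @pytest.mark.parametrize("model", [Model.MLM, Model.MED211, Model.MED111])
    def test_analytic_gradients_match_finite_differences(self, model):
        t, spec, _ = make_table(model=model, g=25, N=20, icc=0.25, R=0.1, seed=5)
        struct = model_sigma(spec)
        stats = _latent_stats(t, spec, struct)
        fun = _latent_objective(struct, *stats[:8])
        mom = compute_moments(t, spec)
        x0 = _start_theta(struct, mom.S_PW, mom.S_B, mom.n0, mom.z_bar)
        theta = x0 + np.random.default_rng(2).normal(0, 0.05, len(x0))
        for f in (fun, _muml_objective(struct, mom.S_PW, mom.S_B, mom.n0,
                                       mom.J, mom.T)):
            th = theta[: len(x0) if f is fun else len(x0) - struct.k]
            val, g = f(th)
            assert np.isfinite(val)
            gfd = np.empty_like(th)
            for i in range(len(th)):
                h = 1e-6 * (1 + abs(th[i]))
                tp, tm = th.copy(), th.copy()
                tp[i] += h
                tm[i] -= h
                gfd[i] = (f(tp)[0] - f(tm)[0]) / (2 * h)
            assert np.max(np.abs(g - gfd) / (1 + np.abs(gfd))) < 1e-5

    @pytest.mark.parametrize("model", [Model.MLM, Model.MED211])
    def test_fiml_equals_brute_force_stacked_normal(self, model):
        """The two-block likelihood equals the full stacked-normal density."""
        t, spec, _ = make_table(model=model, g=6, N=20, icc=0.25, R=0.1, seed=7)
        struct = model_sigma(spec)
        stats = _latent_stats(t, spec, struct)
        fun = _latent_objective(struct, *stats[:8])
        mom = compute_moments(t, spec)
        theta = _start_theta(struct, mom.S_PW, mom.S_B, mom.n0, mom.z_bar)
        f0, _ = fun(theta)
        Sw, _, _, Sb, mu = struct.sigmas(theta, with_mu=True)
        Z = t.matrix(struct.names)
        ll = 0.0
        for j in range(t.J):
            zj = Z[t.codes == j]
            n = len(zj)
            if model is Model.MED211:
                d = 2 * n + 1
                C = np.zeros((d, d))
                for a in range(n):
                    for b in range(n):
                        C[2 * a:2 * a + 2, 2 * b:2 * b + 2] = (
                            Sb[:2, :2] + (Sw if a == b else 0)
                        )
                    C[2 * a:2 * a + 2, -1] = Sb[:2, 2]
                    C[-1, 2 * a:2 * a + 2] = Sb[2, :2]
                C[-1, -1] = Sb[2, 2]
                v = np.concatenate([zj[:, :2].ravel(), [zj[0, 2]]])
                m = np.concatenate([np.tile(mu[:2], n), [mu[2]]])
            else:
                C = np.kron(np.ones((n, n)), Sb) + np.kron(np.eye(n), Sw)
                v, m = zj.ravel(), np.tile(mu, n)
            ll += multivariate_normal.logpdf(v, m, C)
        assert np.isclose(f0, -2 * ll, rtol=1e-10)

    def test_latent_objective_invariant_to_relabeling_and_row_order(self):
        t, spec, _ = make_table(g=30, N=20, seed=9)
        res = cf.fit_latent(t, spec)
        rng = np.random.default_rng(4)
        perm = rng.permutation(t.T)
        df = t.df.iloc[perm].reset_index(drop=True)
        df["group"] = [f"relabel_{g}" for g in df["group"]]
        t2 = cf.ObservationTable(df)
        res2 = cf.fit_latent(t2, spec)
        assert np.isclose(res.objective, res2.objective, rtol=1e-10)


class TestApproachEquivalences:
    def test_balanced_muml_equals_fiml(self):
        """Pseudo-balanced and full-information ML coincide for balanced data
        (coefficients to ~1e-3; variance parameters to the J/(J-1) term)."""
        for seed in range(3):
            t, spec, _ = make_table(g=100, N=20, r=1.0, icc=0.25, R=0.1,
                                    seed=seed)
            rl, rm = cf.fit_latent(t, spec), cf.fit_muml(t, spec)
            assert rl.converged and rm.converged
            for p in ("beta_xw", "beta_xb"):
                tol = max(1e-3, 3.0 * abs(rl.params[p]) / t.J)
                assert abs(rl.params[p] - rm.params[p]) < tol
            for p in ("var_e", "sigma2_xw", "var_u0", "tau2_xb"):
                tol = 5.0 / t.J * (1 + abs(rl.params[p]))
                assert abs(rl.params[p] - rm.params[p]) < tol

    def test_fpc_one_reduces_to_muml_exactly(self):
        t, spec, _ = make_table(g=50, N=20, seed=11)
        rm = cf.fit_muml(t, spec)
        rf = cf.fit_fpc_muml(t, spec, ratios=1e-18)  # fpc rounds to exactly 1
        assert rf.objective == rm.objective
        for p in rm.params:
            assert rf.params[p] == rm.params[p]

    def test_census_fpc_agrees_with_manifest_in_expectation(self):
        """At r = 1 (fpc = 0) the group means are error-free and both the
        manifest and fpc-corrected between effects are consistent: the paired
        mean difference is within 3 MC SEs of zero."""
        diffs = []
        for seed in range(120):
            t, spec, _ = make_table(bal=True, g=60, N=20, icc=0.25, R=10.0,
                                    r=1.0, seed=1000 + seed)
            rm = cf.fit_manifest(t, spec)
            rf = cf.fit_fpc_muml(t, spec)
            if rm.converged and rf.converged:
                diffs.append(rf.params["beta_xb"] - rm.params["beta_xb"])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-4

    def test_within_effects_agree_across_approaches(self):
        """The within effect is essentially approach-invariant."""
        gaps = []
        for seed in range(12):
            t, spec, _ = make_table(g=200, N=20, icc=0.25, R=0.1, r=0.5,
                                    seed=200 + seed)
            ests = [cf.fit(t, spec, a).params["beta_xw"]
                    for a in ("manifest", "latent", "muml", "fpc_muml")]
            gaps.append(np.ptp(ests))
        assert np.mean(gaps) < 0.02


class TestFitResultContract:
    def test_statistical_failure_never_raises(self):
        # between-variance truth ~ 0: tiny ICC and within-dominated sampling
        t, spec, _ = make_table(g=30, N=20, icc=0.05, R=0.1, r=0.1, seed=42)
        for a in ("manifest", "latent", "muml", "fpc_muml"):
            res = cf.fit(t, spec, a)
            assert res.converged == (res.failure_reason == "none")
            for p, v in res.params.items():
                lo, hi = res.ci95[p]
                if np.isfinite(res.se.get(p, np.nan)):
                    assert np.isclose(hi - v, v - lo, rtol=1e-9)

    def test_npd_between_is_flagged_when_truth_is_zero_like(self):
        """Near-zero between variance produces frequent Heywood solutions."""
        flags = []
        for seed in range(15):
            t, spec, _ = make_table(g=30, N=20, icc=0.05, R=0.1, r=0.1,
                                    seed=300 + seed)
            res = cf.fit_latent(t, spec)
            if res.converged:
                flags.append(res.npd_between)
        assert any(flags)

    def test_indirect_effects_reported_for_mediation(self):
        t, spec, _ = make_table(model=Model.MED211, g=80, N=20, icc=0.25,
                                R=10.0, seed=8)
        for a in ("manifest", "latent", "fpc_muml"):
            res = cf.fit(t, spec, a)
            assert res.converged
            ind = res.indirect["indirect_b"]
            assert np.isclose(ind["est"],
                              res.params["alpha_b"] * res.params["beta_mb"],
                              rtol=1e-9)
            assert ind["se"] >= 0
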