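# Methods

## The problem

In contextual (compositional) studies — school effects on students, ward
effects on patients, firm effects on workers — the same variable X appears
twice in a two-level model: once as an individual characteristic and once as
its group composition. The random-intercept contextual model

    Y_ij = b00 + b_xw * X_Wij + b_xb * X_Bj + u_0j + e_ij

separates a within-group effect `b_xw` from a between-group effect `b_xb`.
The composition X_Bj is not observed; it must be estimated from the sampled
members of group j, and how that sampling error is handled is what
distinguishes the three estimators this package implements:

* **Manifest aggregation** substitutes the observed group mean for the
  composition and group-mean-centers the individual predictor. The group
  mean carries sampling error, so the between effect is pulled toward the
  within effect by the reliability of the mean:

      E[b_xb_hat] = [b_xb * ICC_X + b_xw * (1 - ICC_X)/n]
                    / [ICC_X + (1 - ICC_X)/n].

  This expectation (and its 2-1-1 and 1-1-1 indirect-effect analogues) is
  implemented in `contextfpc.oracles` and used as an independent Monte Carlo
  cross-check of the simulator and fitters.
* **Latent aggregation** fits the two-level SEM by full-information ML,
  modelling Sigma_W and Sigma_B explicitly. It removes the sampling error
  under the assumption that each group's population is effectively
  infinite, i.e. the within-group sampling ratio r = n_j/N_j is near 0.
* **fpc-MUML** (the estimator this package exists for) recognizes that real
  groups are finite: when a fraction r of a roster of size N_j is sampled,
  the group-mean error variance shrinks by the finite population correction
  fpc = 1 - n/N. The pooled-within and scaled-between moment matrices

      S_PW = sum_j sum_i (Z_ij - Zbar_j)(Z_ij - Zbar_j)' / sum_j (n_j - 1)
      S_B  = sum_j n_j (Zbar_j - Zbar)(Zbar_j - Zbar)' / (J - 1)

  are adjusted by the method of moments,

      S_PW_fpc = ((n - 1)/(n - fpc)) S_PW
      S_B_fpc  = S_B + ((n - 1)/(n - fpc)) (1 - fpc) S_PW,

  and the structural parameters are estimated by minimizing Muthen's
  pseudo-balanced (MUML) fitting function

      F = J {log|Sig_W + n0 Sig_B| + tr([Sig_W + n0 Sig_B]^-1
             [S_B_fpc + n0 (zbar - mu)(zbar - mu)'])}
        + (T - J) {log|Sig_W| + tr(Sig_W^-1 S_PW_fpc)}

  with the common cluster size n0 = (T^2 - sum n_j^2)/(T (J - 1)). At
  fpc = 1 the adjustment is the identity and fpc-MUML coincides bit-for-bit
  with plain MUML; at fpc = 0 (census) the group means are error-free and
  the estimator agrees with manifest aggregation in expectation.

The same machinery covers three model forms: the contextual MLM above, the
2-1-1 mediation model (group-level treatment X_j, decomposed mediator M,
outcome Y) and the 1-1-1 mediation model (X and M both decomposed), with
delta-method indirect effects a*b at each level.

## Estimation details

**Manifest.** Each equation is an ordinary random-intercept LMM fitted by
exact concentrated ML: for a fixed variance ratio lambda = var_u/var_e the
GLS coefficients and the profiled var_e are closed-form in per-group
sufficient statistics, and lambda is found by a bounded scalar search (the
boundary lambda = 0 is admissible). This is algebraically the same fit
statsmodels' MixedLM(reml=False) produces — the test suite verifies
agreement to ~1e-7 — but roughly an order of magnitude faster, which the
Monte Carlo harness (tens of thousands of fits) needs. Mediation models are
fitted equation by equation, so cov(a_hat, b_hat) = 0 in their
delta-method indirect effects.

**Latent (FIML).** Each group's likelihood contribution factorizes into a
mean block N(zbar_j; mu, Sigma_B + Sigma_W/n_j) and (n_j - 1) deviation
blocks N(0, Sigma_W); groups are pre-aggregated by distinct size, so an
objective evaluation costs a handful of k x k operations regardless of the
sample size. The test suite checks this two-block likelihood against a
brute-force stacked multivariate-normal density to 1e-10.

**Parameterization.** Within-level structure is parameterized by path
coefficients with residual variances on the log scale (Sigma_W is always
positive definite). The between level is parameterized by the free
symmetric matrix Sigma_B rather than by path coefficients. The two are
equivalent wherever Sigma_B is admissible, but in Heywood cells — where the
unconstrained optimum has a non-positive definite Sigma_B, which happens in
a third to a half of replications when the between variance of the
decomposed variable is near zero — the path coefficients have no finite
optimizer and diverge along a likelihood ridge, whereas the direct
parameterization has a well-defined interior optimum. Path coefficients are
recovered from the fitted Sigma_B by the exact recursive regression solve
(ML invariance), with standard errors via the delta method through the
numerical Jacobian of that mapping. A non-PSD fitted Sigma_B is reported as
`npd_between = True` on the `FitResult`; it is a Heywood flag, not a
failure, matching the near-100% convergence rates such models show in
practice. `converged` is False only when the optimizer itself fails
(`optimizer`, `max_iter`) or the input moments are singular
(`singular_input`).

**Optimization.** BFGS on the analytic gradient (matrix-calculus gradients
of both objectives are exact; verified against finite differences at 1e-8
relative error), gradient tolerance 1e-6, 500 iterations cap; moment-based
starting values (within regression solves on S_PW; between from
(S_B - S_PW)/n0 with a small diagonal floor). Non-PD intermediate
composites return +inf and the line search backtracks. A line-search stall
with residual gradient inf-norm below 0.5 (objective is O(1e3)) is accepted
as converged.

**Standard errors.** Inverse curvature of objective/2 at the optimum
(observed information for FIML; the same convention applied to the MUML F,
whose known approximateness under strong unbalance is accepted). 95%
intervals are estimate +/- 1.959964 se. MUML concentrates mu out exactly
(mu_hat = zbar; the cross-derivatives vanish at the optimum so dropping mu
from the curvature is exact); FIML keeps mu free.

## The synthetic-data generator

`simulation.generate_groups` draws finite rosters the way the evaluation
design prescribes: g groups from an infinite group population; roster sizes
all N (balanced) or half 3N/2 and half N/2 (unbalanced, ceil(g/2) large
when g is odd); group components (composition, intercept residuals) and
individual components from independent normals; the within component of the
decomposed variable recentered to an exact zero mean per roster — so the
roster mean *is* the composition — before M and Y are built structurally.
`sample_within` then draws n_j = round(N_j r) members (floor 2, so the
smallest design cell N = 20, r = 0.1 yields n_j = 2) by simple random
sampling without replacement, and the table carries N_j so the fpc is
computable. Residual variances per design cell are fixed constants chosen
so the outcome ICC is 0.25 in every cell; the module cross-checks this
analytically (to 0.01) whenever a cell is instantiated. "Recentering" is a
location shift only; rescaling to also restore the within variance exactly
would be an alternative reading of the design, and the calibration tests
(roster ICC of X within 0.01 of target) support the location-only choice.

A separate `generate_infinite_sample` draws individuals directly from the
model with no roster and no recentering — the regime the latent approach
and the closed-form manifest-bias formulas assume — and exists purely as
the oracle cross-check path.

What the generator does not emulate: non-normal components, unequal
selection probabilities (PPS first stage, weighting), random slopes,
measurement error in X, or more than two levels. Passing tests therefore
speak to the estimators' behavior under the stated normal two-stage design,
not to robustness beyond it.

## The evaluation harness

`run_condition` generates, samples, and fits each requested approach on the
same data (paired comparisons), with a dedicated substream
SeedSequence([seed, condition-key, rep]) per replication so any cell is
independently and exactly reproducible. Convergence rate is computed over
all replications; relative bias mean((est - theta)/theta), RMSE, and
closed-interval 95% coverage over converged replications only. Design-factor
attribution uses a saturated fixed-effects ANOVA over the complete factorial
of cell metrics (eta^2 = SS_effect/SS_total via statsmodels OLS/anova_lm,
0.059 flagged as medium).

### Aggregation choices for unbalanced designs

The fpc adjustment is stated for one common n and one fpc. For unbalanced
data the package uses n = n0 and fpc = 1 - sum(n_j)/sum(N_j), both of which
reduce to the exact quantities when the design is balanced; the choice is
recorded in `FpcAdjustedMoments.provenance`. Per-group population
information is accepted as N_j (preferred) or as per-group sampling ratios
(ratios above 1, which occur with noisy survey weights, are clipped to 1 so
the fpc stays nonnegative, with a logged warning). For survey data the
ratio inputs come from the weight identities size_j = sum_i W_student /
W_group and ratio_j = n_j/size_j.

## Known limitations

* The between-effect estimator is a ratio; in design cells where the
  between variance of the decomposed variable is near zero (ICC 0.05 with
  small rosters, or latent fits at sampling ratios near 1) its sampling
  distribution is heavy-tailed and per-cell mean relative bias does not
  stabilize at any replication count. Aggregates over such cells should be
  read with their Monte Carlo error, which the harness reports via per-cell
  estimate SDs.
* MUML standard errors from the F/2 curvature are approximate under strong
  unbalance, and published two-level results obtained with other software
  can embed more conservative SE conventions; the within-effect coverage of
  the fpc estimator here is near-nominal (~0.96) rather than 1.000.
* With the printed moment normalizations (S_B over J - 1, between weight J
  in F), balanced MUML matches FIML exactly in the coefficients only up to
  a J/(J-1) factor on the between moment; variance parameters differ
  O(1/J).
* No sampling-weighted (MPML) estimation, no Bayesian or EAP-based
  stepwise estimation, no random slopes or cross-level interactions, no
  multiple-indicator (doubly latent) measurement models.
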