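"""Closed-form expectations of the manifest-approach between-effect and
group-level indirect-effect estimators.

When group compositions are estimated by sample group means, the sampling
error of the mean attenuates the between effect toward the within effect.
For the MLM model the expected manifest between-effect estimator is the
reliability-weighted mix

    E[b_xb] = [beta_xb ICC_X + beta_xw (1/n)(1 - ICC_X)]
              / [ICC_X + (1/n)(1 - ICC_X)],

and analogous expressions hold for the group-level indirect effects of the
2-1-1 and 1-1-1 mediation designs in terms of the group-level (tau) and
individual-level (sigma) variances and covariances.  These formulas assume
an infinite within-group population and a common group sample size n; the
simulator's "infinite-population" mode exists to cross-check them by Monte
Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass


__all__ = [
    "LevelMoments",
    "expected_manifest_between_mlm",
    "expected_manifest_indirect_211",
    "expected_manifest_indirect_111",
]


@dataclass(frozen=True)
class LevelMoments:
    """Group-level (tau) and individual-level (sigma) second moments.

    Only the entries needed by the formula at hand must be meaningful; unused
    entries default to zero.  ``n`` is the common group sample size.
    """

    n: float
    tau2_x: float = 0.0
    tau2_m: float = 0.0
    tau2_y: float = 0.0
    tau_xm: float = 0.0
    tau_xy: float = 0.0
    tau_my: float = 0.0
    sigma2_x: float = 0.0
    sigma2_m: float = 0.0
    sigma_xm: float = 0.0
    sigma_xy: float = 0.0
    sigma_my: float = 0.0

    def __post_init__(self):
        if self.n <= 1:
            raise ValueError("need common group size n > 1")


def expected_manifest_between_mlm(
    beta_xb: float, beta_xw: float, icc_x: float, n: float
) -> float:
    """Expected manifest between-effect estimator in the MLM model."""
    if not 0.0 < icc_x < 1.0:
        raise ValueError("ICC_X must lie in (0, 1)")
    if n <= 1:
        raise ValueError("need n > 1")
    w = (1.0 - icc_x) / n
    return (beta_xb * icc_x + beta_xw * w) / (icc_x + w)


def expected_manifest_indirect_211(
    lm: LevelMoments, alpha_b: float, beta_mb: float, beta_mw: float
) -> float:
    """Expected manifest group-level indirect effect in the 2-1-1 design.

    The mediator's group-level variance net of the treatment,
    tau2_m - tau_xm^2 / tau2_x, is mixed with the individual-level mediator
    noise sigma2_m / n exactly as in the MLM attenuation formula.
    """
    if lm.tau2_x == 0:
        raise ZeroDivisionError("tau2_x must be nonzero")
    resid_b = lm.tau2_m - lm.tau_xm**2 / lm.tau2_x
    w = lm.sigma2_m / lm.n
    denom = resid_b + w
    if denom == 0:
        raise ZeroDivisionError("degenerate mediator variance")
    return alpha_b * (beta_mb * resid_b + beta_mw * w) / denom


def expected_manifest_indirect_111(
    lm: LevelMoments, alpha_b: float, alpha_w: float
) -> float:
    """Expected manifest group-level indirect effect in the 1-1-1 design.

    Product of (i) the expected between effect of X on M (attenuated toward
    alpha_w) and (ii) the expected partial between effect of M on Y given X,
    each formed from the n-mixed group-mean moments tau + sigma/n.
    """
    n = lm.n
    tx = lm.tau2_x + lm.sigma2_x / n
    if tx == 0:
        raise ZeroDivisionError("degenerate X group-mean variance")
    first = (alpha_b * lm.tau2_x + alpha_w * lm.sigma2_x / n) / tx
    xm = lm.tau_xm + lm.sigma_xm / n
    xy = lm.tau_xy + lm.sigma_xy / n
    my = lm.tau_my + lm.sigma_my / n
    mm = lm.tau2_m + lm.sigma2_m / n
    denom = mm - xm**2 / tx
    if denom == 0:
        raise ZeroDivisionError("degenerate partialled mediator variance")
    second = (my - xy * xm / tx) / denom
    return first * second
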