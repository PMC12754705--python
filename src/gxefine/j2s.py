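"""Conversion between joint and exposure-stratified summary statistics.

Under a fully exposure-interacted linear model with a binary exposure
coded 0/1, the genetic effect in the unexposed stratum is the main effect
beta_G and in the exposed stratum beta_G + beta_GxE.  The delta-method
variances are exact:

    var(beta_e0) = var_G
    var(beta_e1) = var_G + var_GxE + 2*cov(G, GxE)

and the map inverts exactly: beta_GxE = beta_e1 - beta_e0 with, for
independent strata, cov(G, GxE) = -var_e0 and var_GxE = var_e0 + var_e1.
When strata are exactly decoupled in this way the joint 2df chi-square
equals the sum of the two stratified 1df chi-squares.

Real meta-analysis covariances only approximately satisfy the decoupling
assumption (shared covariates couple the strata); the conversion is then
an approximation and is flagged as such in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import VariantKey

logger = logging.getLogger(__name__)

__all__ = ["StratifiedStat", "joint_to_stratified", "stratified_to_joint"]


@dataclass
class StratifiedStat:
    """Per-stratum genetic effect estimates for one variant."""

    key: VariantKey | None
    beta_e0: float
    se_e0: float
    p_e0: float
    beta_e1: float
    se_e1: float
    p_e1: float
    n_e0: float | None = None
    n_e1: float | None = None


def _two_sided_p(beta: float, se: float) -> float:
    return max(float(2.0 * stats.norm.sf(abs(beta / se))), 1e-300)


def joint_to_stratified(
    beta_g: float,
    beta_gxe: float,
    var_g: float,
    var_gxe: float,
    cov: float,
    key: VariantKey | None = None,
    n_e0: float | None = None,
    n_e1: float | None = None,
) -> StratifiedStat:
    """Convert joint (main, interaction) estimates to per-stratum effects.

    Raises if the implied exposed-stratum variance is not positive, which
    indicates an inconsistent covariance input.
    """
    if var_g <= 0 or var_gxe <= 0:
        raise ValueError("variances must be positive")
    var_e1 = var_g + var_gxe + 2.0 * cov
    if var_e1 <= 0:
        raise ValueError(
            f"implied exposed-stratum variance is non-positive ({var_e1:g}); "
            "covariance inconsistent with the variances"
        )
    beta_e0 = beta_g
    beta_e1 = beta_g + beta_gxe
    se_e0 = float(np.sqrt(var_g))
    se_e1 = float(np.sqrt(var_e1))
    return StratifiedStat(
        key=key,
        beta_e0=beta_e0,
        se_e0=se_e0,
        p_e0=_two_sided_p(beta_e0, se_e0),
        beta_e1=beta_e1,
        se_e1=se_e1,
        p_e1=_two_sided_p(beta_e1, se_e1),
        n_e0=n_e0,
        n_e1=n_e1,
    )


def stratified_to_joint(
    strat: StratifiedStat,
) -> tuple[float, float, float, float, float]:
    """Convert stratified estimates back to joint form.

    Treats the strata as independent samples, so the main/interaction
    covariance is -var_e0 exactly.  Returns
    ``(beta_g, beta_gxe, var_g, var_gxe, cov)``.
    """
    if strat.se_e0 is None or strat.se_e1 is None:
        raise ValueError("both strata must be present")
    if strat.se_e0 <= 0 or strat.se_e1 <= 0:
        raise ValueError("stratum standard errors must be positive")
    var_e0 = strat.se_e0**2
    var_e1 = strat.se_e1**2
    beta_g = strat.beta_e0
    beta_gxe = strat.beta_e1 - strat.beta_e0
    var_g = var_e0
    cov = -var_e0
    var_gxe = var_e0 + var_e1
    return beta_g, beta_gxe, var_g, var_gxe, cov
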