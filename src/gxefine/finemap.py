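"""Sum-of-single-effects fine mapping on bivariate 2df summary statistics.

Standard summary-statistic fine mapping asks which variant in a region
drives a marginal association signal.  Here each variant carries a
*bivariate* signal -- the genetic main effect and the variant-by-exposure
interaction, summarized as the z-vector

    z_j = (beta_g / se_g, beta_gxe / se_gxe)

with within-variant correlation rho_j = cov / (se_g * se_gxe).  The
working model is a sum of L single effects: a one-hot vector gamma_l picks
the causal variant of effect l and the observed z at variant j is, under
causal variant k, attenuated identically in both dimensions by the LD
correlation r_jk.  The within-variant null covariance C is 2x2 with unit
diagonal and off-diagonal the (region-averaged) rho.

Each single effect is a Bayesian model-averaging step over variants: with
prior effect covariance W, the per-variant evidence is

    logBF_j = log N(z_j; 0, C + W) - log N(z_j; 0, C)

and the inclusion probabilities alpha_j are the normalized prior-weighted
Bayes factors.  Effects are fit iteratively (iterative Bayesian stepwise
selection): each effect sees the z residualized through LD against the
expected contribution of all other effects.  The prior covariance of each
effect is estimated each sweep by maximizing the effect-level average
Bayes factor over a fixed scale grid; a scale of zero marks the effect
inactive.  Posterior inclusion probabilities aggregate over active
effects, and credible sets are smallest-prefix sets of cumulative
inclusion probability reaching the coverage target, filtered by LD purity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .sumstats import LDMatrix, JointStat

logger = logging.getLogger(__name__)

__all__ = [
    "FinemapInput",
    "SusieFit",
    "CredibleSet",
    "single_effect_2df",
    "fit_susiegxe",
    "credible_sets",
    "pip",
    "narrow_region",
]

#: scale grid over which each effect's prior covariance is estimated
PRIOR_SCALE_GRID = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class FinemapInput:
    """A region ready for fine mapping.

    ``z`` is p x 2 (main, interaction); ``rho`` the per-variant
    within-variant correlation between the two z components; ``ld`` the
    variant-aligned LD matrix; ``pi`` prior inclusion weights (uniform by
    default).
    """

    z: np.ndarray
    rho: np.ndarray
    ld: LDMatrix
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        p = self.z.shape[0]
        if self.z.ndim != 2 or self.z.shape[1] != 2:
            raise ValueError("z must be p x 2")
        if self.rho.shape != (p,):
            raise ValueError("rho must have one entry per variant")
        if np.any(np.abs(self.rho) >= 1):
            raise ValueError("|rho| must be < 1")
        if len(self.ld) != p:
            raise ValueError("LD matrix not aligned to records")
        if self.pi is None:
            self.pi = np.full(p, 1.0 / p)
        else:
            self.pi = np.asarray(self.pi, dtype=float)
            self.pi = self.pi / self.pi.sum()

    @property
    def p(self) -> int:
        return self.z.shape[0]

    @classmethod
    def from_joint_records(
        cls, records: list[JointStat], ld: LDMatrix, pi: np.ndarray | None = None
    ) -> "FinemapInput":
        """Assemble z-vectors and within-variant correlations from records."""
        z = np.array(
            [[r.beta_g / r.se_g, r.beta_gxe / r.se_gxe] for r in records]
        )
        rho = np.array(
            [r.cov_g_gxe / (r.se_g * r.se_gxe) for r in records]
        )
        rho = np.clip(rho, -0.999, 0.999)
        return cls(z=z, rho=rho, ld=ld, pi=pi)


@dataclass
class SusieFit:
    """Fitted sum-of-single-effects model for one region."""

    L: int
    alpha: np.ndarray               # L x p inclusion probabilities
    mu: np.ndarray                  # L x p x 2 posterior means (z units)
    post_cov: np.ndarray            # L x 2 x 2 posterior covariance per effect
    prior_scales: np.ndarray        # L, chosen prior scale per effect
    lbf_effect: np.ndarray          # L, effect-level log average Bayes factor
    pip: np.ndarray                 # p
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0
    C: np.ndarray | None = None

    @property
    def active_effects(self) -> np.ndarray:
        """Indices of effects with a non-zero estimated prior."""
        return np.flatnonzero(self.prior_scales > 0)


@dataclass
class CredibleSet:
    """A coverage-level credible set for one single effect."""

    effect: int
    members: list[int]              # variant indices, descending alpha
    coverage: float
    purity: float


def _mvn2_logpdf(z: np.ndarray, S: np.ndarray) -> np.ndarray:
    """log N(z; 0, S) for p x 2 z and a shared 2x2 covariance."""
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    if det <= 0 or S[0, 0] <= 0:
        raise ValueError("covariance must be positive definite")
    inv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
    quad = (
        inv[0, 0] * z[:, 0] ** 2
        + 2.0 * inv[0, 1] * z[:, 0] * z[:, 1]
        + inv[1, 1] * z[:, 1] ** 2
    )
    return -np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad


def single_effect_2df(
    z_resid: np.ndarray,
    C: np.ndarray,
    W: np.ndarray,
    pi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bayesian single-effect update on bivariate residual z-scores.

    Returns ``(alpha, mu, post_cov, logbf)``: normalized inclusion
    probabilities, per-variant posterior mean of the causal bivariate
    effect (z units), the shared 2x2 posterior covariance, and per-variant
    log Bayes factors.  ``W`` may be singular (PSD); the conjugate update
    uses the form W - W (C+W)^-1 W which never inverts W.
    """
    z_resid = np.asarray(z_resid, dtype=float)
    C = np.asarray(C, dtype=float)
    W = np.asarray(W, dtype=float)
    wdet = W[0, 0] * W[1, 1] - W[0, 1] * W[1, 0]
    if W[0, 0] < 0 or W[1, 1] < 0 or wdet < -1e-12 * max(W[0, 0] * W[1, 1], 1.0):
        raise ValueError("prior covariance W must be positive semidefinite")

    S = C + W
    sdet = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / sdet
    logbf = _mvn2_logpdf(z_resid, S) - _mvn2_logpdf(z_resid, C)

    log_w = np.log(pi) + logbf
    alpha = np.exp(log_w - logsumexp(log_w))
    alpha = alpha / alpha.sum()

    gain = W @ Sinv                       # posterior mean operator
    mu = z_resid @ gain.T
    post_cov = W - gain @ W
    return alpha, mu, post_cov, logbf


def _estimate_prior(
    z_resid: np.ndarray,
    C: np.ndarray,
    pi: np.ndarray,
    grid=PRIOR_SCALE_GRID,
    main_only: bool = False,
) -> tuple[float, float]:
    """Pick the prior scale maximizing the effect-level average BF.

    The objective is log sum_j pi_j BF_j(scale).  Scale 0 (log average BF
    exactly 0) marks the effect inactive.  Returns (scale, objective).
    """
    best_scale, best_obj = 0.0, 0.0
    for scale in grid:
        if scale == 0.0:
            continue
        W = _prior_matrix(scale, main_only)
        _, _, _, logbf = single_effect_2df(z_resid, C, W, pi)
        obj = float(logsumexp(np.log(pi) + logbf))
        if obj > best_obj:
            best_scale, best_obj = scale, obj
    return best_scale, best_obj


def _prior_matrix(scale: float, main_only: bool) -> np.ndarray:
    if main_only:
        return np.array([[scale, 0.0], [0.0, 0.0]])
    return scale * np.eye(2)


def _inv2(S: np.ndarray) -> np.ndarray:
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    return np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det


def _elbo(
    z: np.ndarray,
    R: np.ndarray,
    C: np.ndarray,
    alpha: np.ndarray,
    mu: np.ndarray,
    post_cov: np.ndarray,
    scales: np.ndarray,
    pi: np.ndarray,
    main_only: bool,
) -> float:
    """Evidence lower bound of the C-weighted summary-statistic model,
    up to an additive constant in z.

    The likelihood treats z as N(R*M, R kron C) with M the sum of one-hot
    single effects; the variational family factorizes over effects.  The
    z'R^-1 z constant is dropped, so only differences along the trace are
    meaningful.  Coordinate updates (including the grid prior step) can
    only increase this bound, which is what the monotonicity invariant
    checks.
    """
    L = alpha.shape[0]
    Cinv = _inv2(C)
    Abar = alpha[:, :, None] * mu                # L x p x 2 mean contributions
    Mbar = Abar.sum(axis=0)                      # p x 2

    fit_term = -2.0 * np.trace(Cinv @ (Mbar.T @ z))
    fit_term += np.trace(Cinv @ (Mbar.T @ R @ Mbar))
    for l in range(L):
        S_l = post_cov[l] * alpha[l].sum() + np.einsum(
            "j,jd,je->de", alpha[l], mu[l], mu[l]
        )
        fit_term += np.trace(Cinv @ S_l)
        fit_term -= np.trace(Cinv @ (Abar[l].T @ R @ Abar[l]))

    kl = 0.0
    for l in range(L):
        if scales[l] == 0.0:
            continue
        a = alpha[l]
        nz = a > 0
        kl += float(np.sum(a[nz] * (np.log(a[nz]) - np.log(pi[nz]))))
        if main_only:
            w = scales[l]
            var = post_cov[l][0, 0]
            m2 = mu[l][:, 0] ** 2
            kl_b = 0.5 * (var / w + m2 / w - 1.0 + np.log(w) - np.log(var))
        else:
            W = _prior_matrix(scales[l], False)
            Winv = _inv2(W)
            ld_w = np.log(W[0, 0] * W[1, 1] - W[0, 1] ** 2)
            det_s = (
                post_cov[l][0, 0] * post_cov[l][1, 1] - post_cov[l][0, 1] ** 2
            )
            ld_s = np.log(max(det_s, 1e-300))
            quad = np.einsum("jd,de,je->j", mu[l], Winv, mu[l])
            kl_b = 0.5 * (
                np.trace(Winv @ post_cov[l]) + quad - 2.0 + ld_w - ld_s
            )
        kl += float(np.sum(a * kl_b))
    return -0.5 * fit_term - kl


def fit_susiegxe(
    inputs: FinemapInput,
    L: int = 10,
    max_iter: int = 100,
    tol: float = 1e-3,
    prior_main_only: bool = False,
    per_variant_rho: bool = False,
) -> SusieFit:
    """Fit the sum-of-single-effects model to a 2df region.

    Iterates single-effect updates, residualizing each effect's z against
    the LD-propagated expected contribution of the others, until the
    largest absolute change in any inclusion probability falls below
    ``tol``.  ``prior_main_only`` constrains every effect's prior to the
    main-effect dimension (the scalar degenerate mode).
    """
    if inputs.p < 2:
        raise ValueError("need at least 2 variants to fine-map")
    ld = inputs.ld.repaired_psd()
    R = ld.r
    z = inputs.z
    p = inputs.p
    pi = inputs.pi

    if per_variant_rho:
        # conservative scalarization: use the average anyway but warn;
        # a fully per-variant C would break the shared-covariance update
        logger.warning("per-variant rho requested; using region average C")
    rho_bar = float(np.mean(inputs.rho))
    C = np.array([[1.0, rho_bar], [rho_bar, 1.0]])

    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p, 2))
    post_cov = np.zeros((L, 2, 2))
    scales = np.zeros(L)
    lbf_eff = np.zeros(L)
    trace: list[float] = []
    converged = False
    it = 0

    # per-dimension expected contribution of each effect to E[z]
    def contribution(l: int) -> np.ndarray:
        b = alpha[l][:, None] * mu[l]          # p x 2
        return R @ b

    total = np.zeros((p, 2))
    for l in range(L):
        total += contribution(l)

    for it in range(1, max_iter + 1):
        alpha_old = alpha.copy()
        for l in range(L):
            total -= contribution(l)
            z_resid = z - total
            scale, obj = _estimate_prior(z_resid, C, pi, main_only=prior_main_only)
            scales[l] = scale
            lbf_eff[l] = obj
            W = _prior_matrix(scale, prior_main_only)
            if scale == 0.0:
                alpha[l] = pi.copy()
                mu[l] = 0.0
                post_cov[l] = np.zeros((2, 2))
            else:
                alpha[l], mu[l], post_cov[l], _ = single_effect_2df(
                    z_resid, C, W, pi
                )
            total += contribution(l)
        trace.append(
            _elbo(z, R, C, alpha, mu, post_cov, scales, pi, prior_main_only)
        )
        if np.max(np.abs(alpha - alpha_old)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("fine mapping did not converge in %d iterations", max_iter)

    fit = SusieFit(
        L=L,
        alpha=alpha,
        mu=mu,
        post_cov=post_cov,
        prior_scales=scales,
        lbf_effect=lbf_eff,
        pip=np.zeros(p),
        objective_trace=trace,
        converged=converged,
        iterations=it,
        C=C,
    )
    fit.pip = pip(fit)
    return fit


def pip(fit: SusieFit) -> np.ndarray:
    """Posterior inclusion probabilities aggregated over active effects.

    pip_j = 1 - prod_l (1 - alpha_lj), the product running over effects
    with non-zero estimated prior; inactive effects carry no evidence and
    would only add their (uniform) prior weight.
    """
    active = fit.active_effects
    if active.size == 0:
        return np.zeros(fit.alpha.shape[1])
    return 1.0 - np.prod(1.0 - fit.alpha[active], axis=0)


def credible_sets(
    fit: SusieFit,
    ld: LDMatrix,
    coverage: float = 0.95,
    min_purity: float = 0.5,
) -> list[CredibleSet]:
    """Coverage-level credible sets with an LD purity filter.

    Per active effect: sort variants by descending inclusion probability
    and take the smallest prefix whose cumulative probability reaches the
    coverage target; discard sets whose minimum absolute pairwise LD falls
    below ``min_purity``; deduplicate identical member sets across
    effects, keeping the one with higher cumulative probability.
    """
    R = np.abs(ld.r)
    best: dict[frozenset, CredibleSet] = {}
    for l in fit.active_effects:
        a = fit.alpha[l]
        order = np.argsort(-a, kind="stable")
        cum = np.cumsum(a[order])
        k = int(np.searchsorted(cum, coverage) + 1)
        k = min(k, len(order))
        members = order[:k]
        cov_achieved = float(cum[k - 1])
        if cov_achieved < coverage:
            continue
        if len(members) == 1:
            purity = 1.0
        else:
            sub = R[np.ix_(members, members)]
            off = sub[~np.eye(len(members), dtype=bool)]
            purity = float(off.min())
        if purity < min_purity:
            continue
        cs = CredibleSet(
            effect=int(l),
            members=[int(j) for j in members],
            coverage=cov_achieved,
            purity=purity,
        )
        sig = frozenset(cs.members)
        if sig not in best or best[sig].coverage < cs.coverage:
            best[sig] = cs
    return sorted(best.values(), key=lambda s: s.effect)


def narrow_region(
    span: tuple[int, int],
    sets: list[CredibleSet],
    positions: np.ndarray,
) -> tuple[tuple[int, int], float, bool]:
    """Refine a locus span to the extent of its credible-set members.

    Returns ``(refined span, width ratio, narrowed)``.  With no surviving
    set the original span is returned and ``narrowed`` is False.  A
    single-variant set has width reported as 1 bp.
    """
    if not sets:
        return span, 1.0, False
    member_pos = np.array(
        sorted({positions[j] for s in sets for j in s.members}), dtype=int
    )
    refined = (int(member_pos.min()), int(member_pos.max()))
    orig_width = max(span[1] - span[0], 1)
    new_width = max(refined[1] - refined[0], 1)
    return refined, new_width / orig_width, True
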