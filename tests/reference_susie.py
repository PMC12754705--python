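"""Independent scalar sum-of-single-effects reference on marginal z-scores.

A from-scratch scalar implementation of summary-statistic SuSiE (RSS
parameterization with standardized z and correlation matrix R), written in
one dimension with no shared code with the package's bivariate
implementation.  Used as an oracle: when the bivariate fit is constrained
to the main-effect dimension it must reduce to this model.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

SCALE_GRID = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)


def _single_effect(z_resid: np.ndarray, w: float, pi: np.ndarray):
    """Scalar Bayesian single-effect update: returns (alpha, mu, logbf)."""
    logbf = norm.logpdf(z_resid, 0.0, np.sqrt(1.0 + w)) - norm.logpdf(
        z_resid, 0.0, 1.0
    )
    logw = np.log(pi) + logbf
    alpha = np.exp(logw - logsumexp(logw))
    alpha = alpha / alpha.sum()
    mu = (w / (1.0 + w)) * z_resid
    return alpha, mu, logbf


def scalar_susie_rss(
    z: np.ndarray,
    R: np.ndarray,
    L: int = 10,
    max_iter: int = 100,
    tol: float = 1e-3,
    grid=SCALE_GRID,
):
    """Iterative scalar single-effect regression on z-scores.

    Returns ``(alpha, mu, scales, converged)`` with alpha of shape L x p.
    The per-effect prior variance is selected from ``grid`` by maximizing
    the effect-level log average Bayes factor; zero marks the effect
    inactive (alpha reset to the prior weights).
    """
    p = len(z)
    pi = np.full(p, 1.0 / p)
    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p))
    scales = np.zeros(L)
    converged = False

    def contribution(l):
        return R @ (alpha[l] * mu[l])

    total = np.zeros(p)
    for l in range(L):
        total += contribution(l)

    for _ in range(max_iter):
        alpha_old = alpha.copy()
        for l in range(L):
            total -= contribution(l)
            resid = z - total
            best_w, best_obj = 0.0, 0.0
            for w in grid:
                if w == 0.0:
                    continue
                _, _, logbf = _single_effect(resid, w, pi)
                obj = float(logsumexp(np.log(pi) + logbf))
                if obj > best_obj:
                    best_w, best_obj = w, obj
            scales[l] = best_w
            if best_w == 0.0:
                alpha[l] = pi.copy()
                mu[l] = 0.0
            else:
                alpha[l], mu[l], _ = _single_effect(resid, best_w, pi)
            total += contribution(l)
        if np.max(np.abs(alpha - alpha_old)) < tol:
            converged = True
            break
    return alpha, mu, scales, converged
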