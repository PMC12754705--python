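"""Per-study association analysis for gene-environment interaction GWAS.

Two linear models are fit per variant by ordinary least squares:

Model 1 (joint):     E(Y) = b0 + bE*E + bG*SNP + bGE*E*SNP + bC*C
Model 2 (marginal):  E(Y) = b0 + bG*SNP + bC*C

where Y is the phenotype, E the (binary or quantitative) exposure, SNP the
allele dosage in [0, 2] and C covariates.  When age, age^2 or sex are among
the covariates, Model 1 also includes their products with E so that the
exposure strata are fully interacted.  The interaction coefficient is
tested with a 1df Wald test and (bG, bGE) jointly with a 2df Wald test.

Estimation uses the Frisch-Waugh-Lovell decomposition: the shared nuisance
design (intercept, E, covariates, covariate-by-E terms) is projected out of
the phenotype and all dosage columns once, after which each variant needs
only a 2x2 (Model 1) or scalar (Model 2) solve.  This is algebraically
identical to the full per-variant OLS fit, including standard errors, and
is what makes genome-wide per-study scans tractable.  Reported covariances
are model-based (homoskedastic OLS); an HC0 sandwich option exists behind
a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import JointStat, MarginalStat, VariantKey

logger = logging.getLogger(__name__)

__all__ = [
    "StudyCohort",
    "ModelSpec",
    "SkippedVariant",
    "fit_model1",
    "fit_model2",
    "wald_1df",
    "wald_2df",
]


@dataclass
class StudyCohort:
    """Individual-level rectangular data for one study.

    ``dosages`` is n x p in [0, 2]; ``covariates`` is n x c with
    ``covariate_names`` naming its columns.  Rows must be complete:
    subjects with missing phenotype, exposure or covariates are removed
    before construction (listwise deletion).
    """

    dosages: np.ndarray
    phenotype: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str]
    keys: list[VariantKey]
    info: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.phenotype)
        if self.dosages.shape[0] != n or len(self.exposure) != n:
            raise ValueError("row counts disagree across cohort arrays")
        if self.covariates.shape != (n, len(self.covariate_names)):
            raise ValueError("covariate matrix does not match names")
        if self.dosages.shape[1] != len(self.keys):
            raise ValueError("variant index does not match dosage columns")

    @property
    def n(self) -> int:
        return len(self.phenotype)

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def exposure_is_binary(self) -> bool:
        vals = np.unique(self.exposure)
        return len(vals) <= 2 and set(vals).issubset({0.0, 1.0})


@dataclass
class ModelSpec:
    """Which exposure and covariates enter the model."""

    exposure_name: str = "CURSMK"
    covariate_names: list[str] = field(default_factory=list)
    include_exposure_covariate_interactions: bool = True
    #: covariates whose E-interaction is added when present (combined-sex runs)
    interacted_covariates: tuple[str, ...] = ("age", "age2", "sex")
    robust: bool = False


@dataclass(frozen=True)
class SkippedVariant:
    """A variant excluded from fitting, with the reason."""

    index: int
    key: VariantKey
    reason: str


def wald_1df(beta_gxe: float, se_gxe: float) -> float:
    """Two-sided Wald p-value for a single coefficient.

    ``(beta/se)^2`` is referred to a 1df chi-square, equivalent to the
    two-sided normal tail of beta/se.
    """
    if se_gxe <= 0:
        raise ValueError("se must be positive")
    return float(stats.chi2.sf((beta_gxe / se_gxe) ** 2, df=1))


def wald_2df(b: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """Joint 2df Wald test of b = 0 given its 2x2 covariance V.

    Returns ``(chi2, p)`` with ``chi2 = b' V^-1 b`` referred to a 2df
    chi-square (survival function exp(-x/2)).
    """
    b = np.asarray(b, dtype=float).ravel()
    V = np.asarray(V, dtype=float)
    if b.shape != (2,) or V.shape != (2, 2):
        raise ValueError("b must be a 2-vector and V a 2x2 matrix")
    det = V[0, 0] * V[1, 1] - V[0, 1] * V[1, 0]
    if not np.isfinite(det) or det <= 0 or V[0, 0] <= 0:
        raise ValueError("V must be symmetric positive definite")
    Vinv = np.array([[V[1, 1], -V[0, 1]], [-V[1, 0], V[0, 0]]]) / det
    chi2 = float(b @ Vinv @ b)
    return chi2, float(stats.chi2.sf(chi2, df=2))


def _nuisance_design(cohort: StudyCohort, spec: ModelSpec, with_exposure: bool) -> np.ndarray:
    n = cohort.n
    cols = [np.ones(n)]
    names = cohort.covariate_names
    use = spec.covariate_names or names
    for name in use:
        if name not in names:
            raise ValueError(f"covariate {name!r} not in cohort")
        cols.append(cohort.covariates[:, names.index(name)])
    if with_exposure:
        e = cohort.exposure.astype(float)
        cols.append(e)
        if spec.include_exposure_covariate_interactions:
            for name in spec.interacted_covariates:
                if name in use:
                    cols.append(e * cohort.covariates[:, names.index(name)])
    return np.column_stack(cols)


def _residualize(Z: np.ndarray, *arrays: np.ndarray) -> tuple[list[np.ndarray], int]:
    """Project arrays onto the orthogonal complement of col(Z) via QR."""
    q, r = np.linalg.qr(Z)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag.max() * 1e-10).sum()) if diag.size else 0
    if rank < Z.shape[1]:
        raise ValueError(
            "nuisance design is rank deficient (constant exposure or "
            "collinear covariates)"
        )
    out = [a - q @ (q.T @ a) for a in arrays]
    return out, rank


def fit_model1(cohort: StudyCohort, spec: ModelSpec | None = None):
    """Fit the joint main/interaction model at every variant.

    Returns ``(records, skipped)``: one :class:`JointStat` per fitted
    variant plus :class:`SkippedVariant` entries for collinear or
    monomorphic variants.
    """
    spec = spec or ModelSpec()
    if np.ptp(cohort.exposure) == 0:
        raise ValueError("exposure is constant; interaction model undefined")
    y = cohort.phenotype.astype(float)
    e = cohort.exposure.astype(float)
    G = cohort.dosages.astype(float)
    GE = G * e[:, None]

    Z = _nuisance_design(cohort, spec, with_exposure=True)
    (y_r, G_r, GE_r), rank = _residualize(Z, y, G, GE)
    n = cohort.n
    dof = n - rank - 2
    if dof <= 0:
        raise ValueError("not enough subjects for the model")

    # per-variant 2x2 normal equations, fully vectorized
    a11 = np.einsum("ij,ij->j", G_r, G_r)
    a12 = np.einsum("ij,ij->j", G_r, GE_r)
    a22 = np.einsum("ij,ij->j", GE_r, GE_r)
    c1 = G_r.T @ y_r
    c2 = GE_r.T @ y_r
    det = a11 * a22 - a12**2
    yty = float(y_r @ y_r)

    scale = np.maximum(a11 * a22, 1e-300)
    ok = det > 1e-10 * scale

    b_g = np.where(ok, (a22 * c1 - a12 * c2) / np.where(ok, det, 1.0), np.nan)
    b_ge = np.where(ok, (a11 * c2 - a12 * c1) / np.where(ok, det, 1.0), np.nan)
    rss = yty - (b_g * c1 + b_ge * c2)
    sigma2 = np.maximum(rss, 0.0) / dof
    var_g = sigma2 * a22 / np.where(ok, det, 1.0)
    var_ge = sigma2 * a11 / np.where(ok, det, 1.0)
    cov = -sigma2 * a12 / np.where(ok, det, 1.0)

    if spec.robust:
        for j in np.flatnonzero(ok):
            X = np.column_stack([G_r[:, j], GE_r[:, j]])
            resid = y_r - X @ np.array([b_g[j], b_ge[j]])
            bread = np.linalg.inv(X.T @ X)
            meat = (X * resid[:, None] ** 2).T @ X
            Vr = bread @ meat @ bread
            var_g[j], var_ge[j], cov[j] = Vr[0, 0], Vr[1, 1], Vr[0, 1]

    eaf = G.mean(axis=0) / 2.0
    binary = cohort.exposure_is_binary
    n_e1 = float((e == 1).sum()) if binary else None
    n_e0 = float((e == 0).sum()) if binary else None

    records: list[JointStat] = []
    skipped: list[SkippedVariant] = []
    for j in range(cohort.p):
        if not ok[j] or var_g[j] <= 0 or var_ge[j] <= 0:
            reason = "monomorphic" if np.ptp(G[:, j]) == 0 else "collinear design"
            skipped.append(SkippedVariant(j, cohort.keys[j], reason))
            continue
        se_g = float(np.sqrt(var_g[j]))
        se_ge = float(np.sqrt(var_ge[j]))
        p1 = wald_1df(float(b_ge[j]), se_ge)
        V = np.array([[var_g[j], cov[j]], [cov[j], var_ge[j]]])
        _, p2 = wald_2df(np.array([b_g[j], b_ge[j]]), V)
        records.append(
            JointStat(
                key=cohort.keys[j],
                eaf=float(eaf[j]),
                n=float(n),
                n_e0=n_e0,
                n_e1=n_e1,
                info=float(cohort.info[j]) if cohort.info is not None else 1.0,
                beta_g=float(b_g[j]),
                se_g=se_g,
                beta_gxe=float(b_ge[j]),
                se_gxe=se_ge,
                cov_g_gxe=float(cov[j]),
                p_1df=max(p1, 1e-300),
                p_2df=max(p2, 1e-300),
            )
        )
    if skipped:
        logger.info("fit_model1 skipped %d variant(s)", len(skipped))
    return records, skipped


def fit_model2(cohort: StudyCohort, spec: ModelSpec | None = None):
    """Fit the marginal (exposure-free) model at every variant.

    Returns ``(records, skipped)`` with one :class:`MarginalStat` per
    fitted variant.
    """
    spec = spec or ModelSpec()
    y = cohort.phenotype.astype(float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; residual variance undefined")
    G = cohort.dosages.astype(float)
    Z = _nuisance_design(cohort, spec, with_exposure=False)
    (y_r, G_r), rank = _residualize(Z, y, G)
    n = cohort.n
    dof = n - rank - 1
    if dof <= 0:
        raise ValueError("not enough subjects for the model")

    gtg = np.einsum("ij,ij->j", G_r, G_r)
    gty = G_r.T @ y_r
    yty = float(y_r @ y_r)
    ok = gtg > 1e-10 * max(yty, 1.0)

    beta = np.where(ok, gty / np.where(ok, gtg, 1.0), np.nan)
    rss = yty - beta * gty
    sigma2 = np.maximum(rss, 0.0) / dof
    var = sigma2 / np.where(ok, gtg, 1.0)
    eaf = G.mean(axis=0) / 2.0

    records: list[MarginalStat] = []
    skipped: list[SkippedVariant] = []
    for j in range(cohort.p):
        if not ok[j] or var[j] <= 0:
            reason = "monomorphic" if np.ptp(G[:, j]) == 0 else "degenerate fit"
            skipped.append(SkippedVariant(j, cohort.keys[j], reason))
            continue
        se = float(np.sqrt(var[j]))
        z = beta[j] / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        records.append(
            MarginalStat(
                key=cohort.keys[j],
                eaf=float(eaf[j]),
                n=float(n),
                beta=float(beta[j]),
                se=se,
                p=max(p, 1e-300),
            )
        )
    return records, skipped
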