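"""Synthetic multi-study generator for gene-exposure interaction GWAS.

Genotypes come from a Gaussian copula with binomial (Hardy-Weinberg)
margins: two latent haplotype draws per subject share a block-diagonal
latent correlation (blocks of ``block_size`` variants at correlation
``rho``), and each latent value is thresholded at the allele-frequency
quantile, so dosages are 0/1/2 with the target MAF and block-structured
LD.  Realized dosage correlation is attenuated relative to the latent
``rho`` (a known property of threshold copulas) and is measured, not
assumed, in the test suite.

Phenotypes follow the joint interaction model: a binary (or quantitative)
exposure independent of genotype by default, additive covariate effects
(age, age^2, sex), configurable causal main and interaction effects, and
Gaussian residual noise.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .assoc import ModelSpec, StudyCohort, fit_model1
from .finemap import FinemapInput
from .sumstats import LDMatrix, VariantKey

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_multistudy",
    "simulate_finemap_region",
]


@dataclass
class SimConfig:
    """Study conditions for the generators.

    Defaults describe a mid-sized cohort contributing to a multi-study
    interaction analysis: a few thousand subjects, LD blocks of ten
    variants at latent correlation 0.8, common variants, roughly a quarter
    of subjects currently exposed, and BP-like residual noise around 10
    (mmHg) relative to per-allele effects given in the causal spec.
    """

    n_subjects: int = 4000
    n_studies: int = 1
    p_variants: int = 50
    block_size: int = 10
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_kind: str = "binary"       # "binary" or "quantitative"
    prevalence: float = 0.25
    beta_e: float = 2.0
    causal: list[tuple[int, float, float]] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.3, "age2": 0.002, "sex": 2.0}
    )
    residual_sd: float = 10.0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 5_000
    confounded_exposure: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0,1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0,1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        for idx, _, _ in self.causal:
            if idx >= self.p_variants:
                raise ValueError("causal index out of range")


def _block_correlation(p: int, block_size: int, rho: float) -> np.ndarray:
    r = np.eye(p)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        r[start:stop, start:stop] = rho
    np.fill_diagonal(r, 1.0)
    return r


def _phi2(h: np.ndarray, k: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized standard bivariate normal CDF via Owen's T function."""
    from scipy.special import owens_t

    h, k, r = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(r, float)
    )
    eps = 1e-12
    denom = np.sqrt(np.clip(1.0 - r**2, eps, 1.0))
    h_safe = np.where(np.abs(h) < eps, eps, h)
    k_safe = np.where(np.abs(k) < eps, eps, k)
    a_h = (k - r * h) / (h_safe * denom)
    a_k = (h - r * k) / (k_safe * denom)
    out = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - owens_t(h, a_h)
        - owens_t(k, a_k)
    )
    # quadrant correction: subtract 1/2 when h and k have opposite signs
    neg = (h * k < 0) | ((np.abs(h * k) < eps) & (h + k < 0))
    out = out - np.where(neg, 0.5, 0.0)
    both_zero = (np.abs(h) < eps) & (np.abs(k) < eps)
    out = np.where(both_zero, 0.25 + np.arcsin(np.clip(r, -1, 1)) / (2 * np.pi), out)
    return out


def _latent_pair_rho(
    target: float, maf_i: np.ndarray, maf_j: np.ndarray
) -> np.ndarray:
    """Latent Gaussian correlations whose thresholded-indicator correlation
    equals ``target`` at each pair of allele frequencies.

    Thresholding attenuates correlation (the tetrachoric effect), so the
    latent value must exceed the target; solved by vectorized bisection on
    the bivariate normal orthant probability.  Pairs for which the target
    is unreachable (very different MAFs) saturate near 1.
    """
    maf_i = np.asarray(maf_i, float)
    maf_j = np.asarray(maf_j, float)
    if target <= 0.0:
        return np.full(np.broadcast(maf_i, maf_j).shape, target)
    t_i = stats.norm.ppf(maf_i)
    t_j = stats.norm.ppf(maf_j)
    sd = np.sqrt(maf_i * (1 - maf_i) * maf_j * (1 - maf_j))

    def realized(r):
        return (_phi2(t_i, t_j, r) - maf_i * maf_j) / sd

    lo = np.full_like(sd, target)
    hi = np.full_like(sd, 0.9999)
    unreachable = realized(hi) < target
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        too_low = realized(mid) < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    out = 0.5 * (lo + hi)
    return np.where(unreachable, 0.9999, out)


def _calibrated_latent_corr(
    mafs: np.ndarray, block_size: int, rho: float
) -> np.ndarray:
    """Block latent correlation matrix calibrated pairwise so realized
    dosage LD matches ``rho``; repaired to PSD by eigenvalue clipping."""
    p = len(mafs)
    corr = np.eye(p)
    if rho > 0.0:
        for start in range(0, p, block_size):
            stop = min(start + block_size, p)
            idx = np.arange(start, stop)
            ii, jj = np.meshgrid(idx, idx, indexing="ij")
            upper = ii < jj
            lat = _latent_pair_rho(rho, mafs[ii[upper]], mafs[jj[upper]])
            corr[ii[upper], jj[upper]] = lat
            corr[jj[upper], ii[upper]] = lat
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        corr = (v * w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


def _variant_keys(config: SimConfig) -> list[VariantKey]:
    return [
        VariantKey(
            chrom=config.chrom,
            pos=config.pos_start + j * config.pos_step,
            ea="A",
            oa="G",
            rsid=f"sim{j}",
        )
        for j in range(config.p_variants)
    ]


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[VariantKey], LDMatrix]:
    """Draw block-LD dosages via a Gaussian copula with binomial margins.

    Returns ``(dosages, keys, true latent LDMatrix)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    p = config.p_variants
    # variant properties depend on the config seed only, so every study in
    # a multi-study run sees the same MAF spectrum (homogeneous cohorts).
    # MAFs are drawn per LD block and shared within it: variants in strong
    # LD necessarily have similar allele frequencies (the maximal
    # correlation between binary variables shrinks as frequencies diverge)
    maf_rng = np.random.default_rng([config.seed, 7919])
    n_blocks = -(-p // config.block_size)
    block_mafs = maf_rng.uniform(*config.maf_range, size=n_blocks)
    mafs = np.repeat(block_mafs, config.block_size)[:p]
    thresh = stats.norm.ppf(mafs)
    # calibrate the latent correlation pairwise so realized dosage LD
    # matches rho despite threshold attenuation
    corr = _calibrated_latent_corr(mafs, config.block_size, config.rho)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(p))

    n = config.n_subjects
    dosage = np.zeros((n, p))
    for _hap in range(2):
        latent = rng.standard_normal((n, p)) @ chol.T
        dosage += (latent < thresh).astype(float)
    keys = _variant_keys(config)
    # the truth LD is reported on the dosage scale (the calibration target)
    target_corr = _block_correlation(p, config.block_size, config.rho)
    return dosage, keys, LDMatrix(keys, target_corr)


def _covariates(n: int, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    age = rng.uniform(30, 75, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    cov = np.column_stack([age, age**2, sex])
    return cov, ["age", "age2", "sex"]


def simulate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> StudyCohort:
    """Simulate one study's individual-level data under the joint model."""
    rng = rng or np.random.default_rng(config.seed)
    dosage, keys, _ = simulate_genotypes(config, rng)
    n = config.n_subjects
    cov, cov_names = _covariates(n, rng)

    if config.exposure_kind == "binary":
        if config.confounded_exposure and config.causal:
            j0 = config.causal[0][0]
            logits = stats.norm.ppf(config.prevalence) + 0.3 * (
                dosage[:, j0] - dosage[:, j0].mean()
            )
            exposure = (rng.standard_normal(n) < logits).astype(float)
        else:
            exposure = (rng.random(n) < config.prevalence).astype(float)
    elif config.exposure_kind == "quantitative":
        # CPD-like: log-normal cigarettes/day among the exposed
        exposed = rng.random(n) < config.prevalence
        exposure = np.where(exposed, rng.lognormal(2.5, 0.5, size=n), 0.0)
    else:
        raise ValueError(f"unknown exposure kind {config.exposure_kind!r}")

    y = np.zeros(n)
    eff = config.covariate_effects
    y += eff.get("age", 0.0) * cov[:, 0]
    y += eff.get("age2", 0.0) * cov[:, 1]
    y += eff.get("sex", 0.0) * cov[:, 2]
    y += config.beta_e * exposure
    for idx, beta_g, beta_gxe in config.causal:
        y += beta_g * dosage[:, idx]
        y += beta_gxe * dosage[:, idx] * exposure
    y += rng.normal(0.0, config.residual_sd, size=n)

    return StudyCohort(
        dosages=dosage,
        phenotype=y,
        exposure=exposure,
        covariates=cov,
        covariate_names=cov_names,
        keys=keys,
    )


def simulate_multistudy(
    config: SimConfig,
) -> tuple[list[StudyCohort], dict]:
    """Independent cohorts sharing the causal specification.

    Returns the cohorts and a truth record carrying every generative
    parameter, for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    cohorts = []
    for _ in range(config.n_studies):
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        cohorts.append(simulate_cohort(config, child))
    truth = {
        "causal": list(config.causal),
        "beta_e": config.beta_e,
        "residual_sd": config.residual_sd,
        "n_total": config.n_subjects * config.n_studies,
        "config": config,
    }
    return cohorts, truth


def simulate_finemap_region(
    config: SimConfig, spec: ModelSpec | None = None
) -> tuple[FinemapInput, dict]:
    """Simulate a region and assemble its fine-mapping input.

    Simulates a cohort, fits the joint model at every variant, and builds
    z-vectors, within-variant correlations, and the empirical dosage LD.
    The truth record carries the causal index set.
    """
    cohort = simulate_cohort(config)
    records, skipped = fit_model1(cohort, spec)
    if skipped:
        raise RuntimeError(
            f"{len(skipped)} variant(s) unfittable in simulated region"
        )
    emp_r = np.corrcoef(cohort.dosages, rowvar=False)
    ld = LDMatrix(cohort.keys, emp_r)
    fm = FinemapInput.from_joint_records(records, ld)
    truth = {
        "causal_indices": [idx for idx, _, _ in config.causal],
        "records": records,
        "cohort_n": cohort.n,
    }
    return fm, truth
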