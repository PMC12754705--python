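"""Quality control and fixed-effects meta-analysis of summary statistics.

The 1df interaction (and marginal) effects are combined by inverse-variance
weighting; the bivariate (main, interaction) effects are combined by
inverse-covariance-matrix weighting:

    V* = (sum_i V_i^-1)^-1,    b* = V* * sum_i V_i^-1 b_i

followed by 1df and 2df Wald tests on the combined estimates.  Genomic
control deflates test statistics by the ratio of the observed to expected
median chi-square when that ratio exceeds 1 (inflation is corrected,
deflation is left alone).

Study-level QC mirrors common GWAS-consortium practice: drop monomorphic
variants, low imputation quality (INFO < 0.6 generally, < 0.8 for rare
variants with EAF outside [0.01, 0.99]), and exposure strata with minor
allele count below 10.  Meta-level inclusion requires a minimum combined
sample size, more than one contributing population for cross-population
results, and exclusion of the extended MHC region.

For small strata a t-distribution option replaces the normal/chi-square
reference using approximate degrees of freedom df = 2*MAF*(1-MAF)*N, the
expected minor-allele-informative sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .assoc import wald_2df
from .sumstats import JointStat, VariantKey

logger = logging.getLogger(__name__)

__all__ = [
    "QCRules",
    "MetaResult",
    "approximate_df",
    "study_qc_filter",
    "meta_1df",
    "meta_2df_joint",
    "genomic_control",
    "meta_inclusion_filter",
    "small_sample_pvalues",
    "sex_heterogeneity",
    "meta_joint_records",
    "apply_genomic_control",
]

# medians of central chi-square distributions, used by genomic control
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549...
CHI2_MEDIAN_2DF = float(stats.chi2.ppf(0.5, 2))  # 1.3863...

# hg38 MHC consensus interval on chromosome 6
DEFAULT_MHC = ("6", 28_477_797, 33_448_354)


@dataclass
class QCRules:
    """Thresholds for study- and meta-level variant filters."""

    min_maf_total: float = 0.001
    min_info_genotype: float = 0.3
    min_info_study: float = 0.6
    info_if_rare: float = 0.8
    rare_eaf_low: float = 0.01
    rare_eaf_high: float = 0.99
    min_mac_stratum: float = 10.0
    min_df_all: float = 20.0
    min_df_stratum: float = 10.0
    min_info_meta: float = 0.5
    min_n_study: float = 100.0
    min_n_meta: float = 20_000.0
    mhc_interval: tuple[str, int, int] = DEFAULT_MHC
    mhc_exclusion_bp: int = 1_000_000
    #: when df fields are present and df_all < t_df_cutoff, use t/F references
    t_df_cutoff: float = 100.0


@dataclass
class MetaResult:
    """Combined bivariate estimate for one variant."""

    key: VariantKey
    beta_g: float
    beta_gxe: float
    cov: np.ndarray
    chi2_1df: float
    chi2_2df: float
    p_1df: float
    p_2df: float
    n: float
    n_studies: int
    n_populations: int = 1
    eaf: float = float("nan")
    info: float = float("nan")
    p_1df_gc: float | None = None
    p_2df_gc: float | None = None

    @property
    def se_g(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def se_gxe(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))


def approximate_df(n_stratum: float, maf: float) -> float:
    """Approximate degrees of freedom for a stratum.

    df = 2*MAF*(1-MAF)*N: the expected genotype variance times the sample
    size, i.e. the effective number of minor-allele-informative
    observations.  Monotone in both arguments on MAF in [0, 0.5].
    """
    if n_stratum < 0:
        raise ValueError("n must be non-negative")
    if not (0.0 <= maf <= 0.5):
        raise ValueError("MAF must lie in [0, 0.5]")
    return 2.0 * maf * (1.0 - maf) * n_stratum


@dataclass(frozen=True)
class DroppedRecord:
    key: VariantKey
    reason: str


def study_qc_filter(
    records: list[JointStat], rules: QCRules | None = None
) -> tuple[list[JointStat], list[DroppedRecord]]:
    """Apply study-level variant filters.

    Each dropped record carries the first failing rule, so the filter
    cascade is auditable.
    """
    rules = rules or QCRules()
    kept: list[JointStat] = []
    dropped: list[DroppedRecord] = []
    for r in records:
        reason = _first_failing_rule(r, rules)
        if reason is None:
            kept.append(r)
        else:
            dropped.append(DroppedRecord(r.key, reason))
    if dropped:
        logger.info("study QC dropped %d of %d variants", len(dropped), len(records))
    return kept, dropped


def _first_failing_rule(r: JointStat, rules: QCRules) -> str | None:
    if r.maf <= 0:
        return "monomorphic"
    if r.maf < rules.min_maf_total:
        return f"MAF<{rules.min_maf_total}"
    if r.info < rules.min_info_study:
        return f"INFO<{rules.min_info_study}"
    rare = not (rules.rare_eaf_low <= r.eaf <= rules.rare_eaf_high)
    if rare and r.info < rules.info_if_rare:
        return f"rare-band INFO<{rules.info_if_rare}"
    if r.n_e0 is not None and r.n_e1 is not None:
        mac_e0 = 2.0 * r.n_e0 * r.maf
        mac_e1 = 2.0 * r.n_e1 * r.maf
        if min(mac_e0, mac_e1) < rules.min_mac_stratum:
            return f"stratum MAC<{rules.min_mac_stratum}"
    if r.n < rules.min_n_study:
        return f"N<{rules.min_n_study}"
    if r.df_all is not None and r.df_all < rules.min_df_all:
        return f"DF_ALL<{rules.min_df_all}"
    for df, label in ((r.df_e0, "DF_E0"), (r.df_e1, "DF_E1")):
        if df is not None and df < rules.min_df_stratum:
            return f"{label}<{rules.min_df_stratum}"
    if r.info < rules.min_info_meta:
        return f"INFO<{rules.min_info_meta}"
    return None


def meta_1df(estimates: list[tuple[float, float]]) -> tuple[float, float, float]:
    """Inverse-variance-weighted fixed-effects combination of (beta, se).

    Returns ``(beta, se, p)`` with a two-sided normal p-value.
    """
    if not estimates:
        raise ValueError("no estimates to combine")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, max(p, 1e-300)


def meta_2df_joint(
    estimates: list[tuple[np.ndarray, np.ndarray]],
    key: VariantKey | None = None,
    ns: list[float] | None = None,
    n_populations: int = 1,
) -> MetaResult:
    """Inverse-covariance-matrix weighted combination of bivariate effects.

    Studies whose covariance matrix is singular are excluded for this
    variant and logged rather than failing the whole combination.
    """
    if not estimates:
        raise ValueError("no estimates to combine")
    precision = np.zeros((2, 2))
    weighted = np.zeros(2)
    used = 0
    total_n = 0.0
    for i, (b, V) in enumerate(estimates):
        b = np.asarray(b, dtype=float).ravel()
        V = np.asarray(V, dtype=float)
        det = V[0, 0] * V[1, 1] - V[0, 1] * V[1, 0]
        if det <= 0 or V[0, 0] <= 0 or not np.isfinite(det):
            logger.warning("study %d excluded: singular covariance", i)
            continue
        Vinv = np.array([[V[1, 1], -V[0, 1]], [-V[1, 0], V[0, 0]]]) / det
        precision += Vinv
        weighted += Vinv @ b
        used += 1
        if ns is not None:
            total_n += ns[i]
    if used == 0:
        raise ValueError("no usable studies after excluding singular covariances")
    Vstar = np.linalg.inv(precision)
    bstar = Vstar @ weighted
    chi2_2, p_2 = wald_2df(bstar, Vstar)
    z1 = bstar[1] / np.sqrt(Vstar[1, 1])
    chi2_1 = float(z1**2)
    p_1 = float(stats.chi2.sf(chi2_1, 1))
    return MetaResult(
        key=key if key is not None else _dummy_key(),
        beta_g=float(bstar[0]),
        beta_gxe=float(bstar[1]),
        cov=Vstar,
        chi2_1df=chi2_1,
        chi2_2df=chi2_2,
        p_1df=max(p_1, 1e-300),
        p_2df=max(p_2, 1e-300),
        n=total_n,
        n_studies=used,
        n_populations=n_populations,
    )


def _dummy_key() -> VariantKey:
    return VariantKey(chrom="1", pos=1, ea="A", oa="G")


def meta_joint_records(
    studies: list[list[JointStat]], n_populations: int = 1
) -> list[MetaResult]:
    """Combine per-study :class:`JointStat` lists variant by variant.

    Variants are matched on (chrom, pos, ea, oa); a variant present in a
    single study passes through as its own combination.
    """
    by_key: dict[tuple, list[JointStat]] = {}
    order: list[tuple] = []
    for recs in studies:
        for r in recs:
            k = (r.key.chrom, r.key.pos, r.key.ea, r.key.oa)
            if k not in by_key:
                by_key[k] = []
                order.append(k)
            by_key[k].append(r)
    results = []
    for k in order:
        group = by_key[k]
        est = [(np.array([r.beta_g, r.beta_gxe]), r.covariance()) for r in group]
        res = meta_2df_joint(
            est,
            key=group[0].key,
            ns=[r.n for r in group],
            n_populations=n_populations,
        )
        w = np.array([r.n for r in group], dtype=float)
        res.eaf = float(np.average([r.eaf for r in group], weights=w))
        res.info = float(np.average([r.info for r in group], weights=w))
        results.append(res)
    return results


def genomic_control(
    chi2: np.ndarray, df: int = 1
) -> tuple[float, np.ndarray, np.ndarray]:
    """Median-based genomic-control correction.

    lambda = median(chi2) / median of the central chi-square(df).  When
    lambda > 1 all statistics are divided by it; deflation (lambda < 1) is
    never "corrected" upward.  Returns ``(lambda, corrected chi2,
    corrected p)``.
    """
    chi2 = np.asarray(chi2, dtype=float)
    if df == 1:
        ref = CHI2_MEDIAN_1DF
    elif df == 2:
        ref = CHI2_MEDIAN_2DF
    else:
        ref = float(stats.chi2.ppf(0.5, df))
    if len(chi2) < 1000:
        logger.warning(
            "genomic control on %d statistics; median is noisy below 1000",
            len(chi2),
        )
    lam = float(np.median(chi2) / ref)
    corrected = chi2 / lam if lam > 1.0 else chi2.copy()
    p = stats.chi2.sf(corrected, df)
    return lam, corrected, p


def apply_genomic_control(
    results: list[MetaResult], min_variants: int = 1000
) -> tuple[float, float]:
    """Apply GC separately to the 1df and 2df statistics of meta results.

    Stores corrected p-values on each record and returns both lambdas.
    Below ``min_variants`` the median is dominated by true signal rather
    than the null, so no correction is applied (lambda reported as 1).
    """
    if not results:
        return 1.0, 1.0
    if len(results) < min_variants:
        logger.warning(
            "skipping genomic control: %d variants < %d (median not "
            "null-dominated)", len(results), min_variants,
        )
        for r in results:
            r.p_1df_gc = r.p_1df
            r.p_2df_gc = r.p_2df
        return 1.0, 1.0
    lam1, _, p1 = genomic_control(np.array([r.chi2_1df for r in results]), df=1)
    lam2, _, p2 = genomic_control(np.array([r.chi2_2df for r in results]), df=2)
    for r, a, b in zip(results, p1, p2):
        r.p_1df_gc = max(float(a), 1e-300)
        r.p_2df_gc = max(float(b), 1e-300)
    return lam1, lam2


def meta_inclusion_filter(
    results: list[MetaResult],
    rules: QCRules | None = None,
    cpma: bool = False,
) -> tuple[list[MetaResult], list[DroppedRecord]]:
    """Meta-level inclusion filters.

    Drops variants with combined N below the minimum, cross-population
    variants with a single contributing population, and variants within
    the padded MHC exclusion zone.
    """
    rules = rules or QCRules()
    mhc_chrom, mhc_start, mhc_end = rules.mhc_interval
    pad = rules.mhc_exclusion_bp
    kept, dropped = [], []
    for r in results:
        if r.n < rules.min_n_meta:
            dropped.append(DroppedRecord(r.key, f"N<{rules.min_n_meta:g}"))
        elif cpma and r.n_populations <= 1:
            dropped.append(DroppedRecord(r.key, "single population in CPMA"))
        elif (
            str(r.key.chrom) == str(mhc_chrom)
            and mhc_start - pad <= r.key.pos <= mhc_end + pad
        ):
            dropped.append(DroppedRecord(r.key, "MHC region"))
        else:
            kept.append(r)
    return kept, dropped


def small_sample_pvalues(
    rec: JointStat, rules: QCRules | None = None
) -> tuple[float, float]:
    """t/F-based p-values for small strata.

    When approximate degrees of freedom are available and df_all falls
    below the cutoff, the 1df Wald statistic is referred to a t
    distribution with df_all degrees of freedom and the 2df statistic to
    F(2, df_all); otherwise the standard normal/chi-square p-values on the
    record are returned unchanged.
    """
    rules = rules or QCRules()
    if rec.df_all is None or rec.df_all >= rules.t_df_cutoff:
        return rec.p_1df, rec.p_2df
    df = max(rec.df_all, 1.0)
    t = rec.beta_gxe / rec.se_gxe
    p1 = float(2.0 * stats.t.sf(abs(t), df))
    chi2, _ = wald_2df(np.array([rec.beta_g, rec.beta_gxe]), rec.covariance())
    p2 = float(stats.f.sf(chi2 / 2.0, 2, df))
    return max(p1, 1e-300), max(p2, 1e-300)


def sex_heterogeneity(
    beta_m: float, se_m: float, beta_f: float, se_f: float,
    threshold: float = 1e-6,
) -> tuple[float, float, bool]:
    """Two-sample Z-test for a sex difference in effect size.

    Returns ``(z, p, heterogeneous)`` where the flag is set when the
    two-sided p falls below ``threshold``.
    """
    if se_m <= 0 or se_f <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_m - beta_f) / np.sqrt(se_m**2 + se_f**2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p, p < threshold
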