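# Methods

## Phenotype and exposure derivation

Blood-pressure outcomes are systolic (SBP), diastolic (DBP) and pulse
pressure (PP = SBP − DBP), all in mmHg. Subjects on antihypertensive
medication have a fixed offset added (+15 mmHg SBP, +10 mmHg DBP) to
approximate untreated pressure; PP is derived from the *adjusted* values.
Outcomes are winsorized at mean ± k·SD with k = 6, with the mean and SD
computed once on the input vector — the bounds are not re-estimated after
clamping, so the operation is idempotent and rank-preserving. Whether
winsorization should precede or follow medication adjustment is genuinely
open; the default adjusts first (`PhenoConfig.adjust_before_winsorize`),
because the adjustment is a deterministic shift that would otherwise leak
into the outlier bounds asymmetrically between treated and untreated
subjects.

Smoking exposures: CURSMK (current smoker, 0/1), CPD (cigarettes/day,
current smokers only) and pack-years PY = (CPD/20) × years smoked. Current
smokers with CPD or PY zero or missing are excluded from the quantitative
analyses, and CPD/PY are winsorized separately by sex. Strata with fewer
than 100 current smokers after exclusions analyze CURSMK only — below that
the interaction design is too thin for a stable quantitative-exposure fit.

## Per-study association

Model 1 regresses the phenotype on exposure, dosage, dosage×exposure and
covariates (age, age², sex plus their products with the exposure, so the
exposure strata are fully interacted); Model 2 drops all exposure terms.
Estimation uses the Frisch–Waugh–Lovell decomposition: the shared nuisance
design is projected out once by QR, after which each variant requires only
a 2×2 (or scalar) solve. This is algebraically identical to per-variant
OLS — estimates, standard errors and the (β_G, β_GE) covariance all match
`statsmodels.OLS` to 1e-8 relative in the test suite — and is what makes a
genome-wide scan tractable in one pass. Covariances are model-based
(homoskedastic); an HC0 sandwich option exists behind `ModelSpec.robust`
but is off by default, matching the reported-p-value convention for
linear-model GWAS. Dosage-level missingness is handled by listwise
deletion per variant; covariate missingness excludes the subject globally.
Related-subject designs are supported only through a pre-residualized
phenotype supplied as the outcome column; no kinship model is fit here.

The 1df interaction test refers (β_GE/se)² to χ²₁; the 2df joint test
refers b′V⁻¹b to χ²₂. For small strata, `small_sample_pvalues` substitutes
t and F(2, df) references using approximate degrees of freedom
df = 2·MAF·(1−MAF)·N (the expected count of minor-allele-informative
observations), applied when df < 100.

## Quality control and meta-analysis

Study-level filters: monomorphic variants, MAF < 0.001, INFO < 0.6
(0.8 for rare variants with EAF outside [0.01, 0.99]), minor allele count
< 10 in either exposure stratum, N < 100, and approximate-df floors
(df_all ≥ 20, stratum df ≥ 10). Each dropped variant records its first
failing rule so the filter cascade is auditable. Meta-level inclusion
requires combined N ≥ 20,000, more than one contributing population for
cross-population results, and exclusion of the MHC region
(chr6:28,477,797–33,448,354, hg38 consensus) padded by 1 Mb. All
thresholds live in `QCRules` and are configuration, not code.

1df statistics combine by inverse-variance weighting; the bivariate
(main, interaction) vector combines by inverse-covariance-matrix
weighting, V* = (ΣVᵢ⁻¹)⁻¹, b* = V*ΣVᵢ⁻¹bᵢ. The combination is
order-invariant, pairwise-associative, and each study's covariance
dominates the combined one (Vᵢ − V* is PSD) — all property-tested. A
study with a singular covariance at some variant is excluded for that
variant and logged rather than failing the combination.

Genomic control divides both the 1df and 2df chi-squares by
λ = median(χ²)/median(χ²_ref) (0.4549 for 1 df, 1.3863 for 2 df) when
λ > 1; deflation is never "corrected" upward. λ is estimated per
statistic and both values are recorded. Below 1000 variants the median is
not null-dominated and correction is skipped with a warning — a
median-based λ on a signal-dense region would erase true associations.

Sex heterogeneity uses the two-sample Z-test
z = (β_m − β_f)/√(se_m² + se_f²), flagged below p = 1×10⁻⁶.

## Locus discovery

A variant is significant if (1a) its interaction p ≤ 5×10⁻⁹ with
genome-wide BH FDR < 0.05, or (1b) its interaction p ≤ 0.05/m_G with
FDR < 0.05 over the m_G variants whose marginal p ≤ 10⁻⁵, or (2) its 2df
p ≤ 5×10⁻⁹ with genome-wide 2df FDR < 0.05. BH step-up q-values are used
for all FDR quantities (the procedure is substitutable). Clumping is
greedy: the most significant unassigned variant leads a locus and absorbs
variants within ±500 kb of the lead or with r² ≥ 0.1 to the lead; ties on
p break by chromosome then position, so output is invariant to input
order. Absorption measures distance/LD to the lead, not transitively
through members; a transitive mode exists behind a flag. Non-significant
variants may be absorbed as members (the `background` argument) but never
lead. A locus is "known" if any member lies within 1 Mb of a catalog
entry on the same chromosome.

## Joint ↔ stratified conversion

With a binary exposure and a fully interacted model, the unexposed-stratum
genetic effect is β_G and the exposed-stratum effect β_G + β_GE, with
var(β_e1) = var_G + var_GE + 2cov. The inverse map (independent strata)
gives cov = −var_e0 and var_GE = var_e0 + var_e1; forward and backward are
exact inverses, and on exactly decoupled inputs the joint 2df chi-square
equals the sum of the two stratified 1df chi-squares. Real meta-analysis
covariances satisfy the decoupling only approximately (shared covariates
couple strata), so the conversion of real data is an approximation.

## 2df fine mapping

Each variant j carries z_j = (β_G/se_G, β_GE/se_GE) with within-variant
correlation ρ_j = cov/(se_G·se_GE). The working model: the p×2 matrix of
true effects is a sum of L single effects, each a one-hot row vector with
a bivariate effect; under causal variant k the expected z at variant j is
r_jk·ζ_k in both dimensions, which assumes the exposure is independent of
genotype so LD attenuation acts identically on main and interaction
components. The null covariance C is 2×2 with unit diagonal and
off-diagonal the region-average ρ̂ (a per-variant-ρ entry point exists but
falls back to the average: a per-variant C would break the shared-posterior
update).

Each single effect is a Bayesian model-averaging step:
logBF_j = log N(z_j; 0, C+W) − log N(z_j; 0, C), α_j ∝ π_j·BF_j, with
conjugate posterior mean W(C+W)⁻¹z_j and covariance W − W(C+W)⁻¹W (forms
valid for singular W, needed for the main-effect-only mode). Effects are
fit by iterative Bayesian stepwise selection: each effect sees z
residualized through LD against the expected contribution of the others,
R·Σ_{l′≠l} α_{l′}∘μ_{l′,d} per dimension d. The prior covariance of each
effect is re-estimated every sweep over the grid
{0, 0.01, 0.1, 1, 10, 100}·I₂ by maximizing the effect-level log average
Bayes factor; scale 0 marks the effect inactive (α reset to the prior,
excluded from PIPs and credible sets). Convergence: max |Δα| < 1e-3, at
most 100 iterations; defaults L = 10, coverage 0.95, minimum purity 0.5.

The tracked objective is the evidence lower bound of the variational
model with likelihood z ~ N(R·M, R ⊗ C) (the z′R⁻¹z constant dropped).
The coordinate updates — including the grid prior step — can only
increase this bound, and the test suite asserts monotonicity along the
trace. A naive sum of per-effect Bayes factors is *not* monotone and is
not used.

Credible sets take, per active effect, the smallest prefix of variants by
descending α reaching cumulative 0.95; sets whose minimum absolute
pairwise LD is below 0.5 are discarded as diffuse, and identical sets
across effects are deduplicated keeping the higher-coverage copy. PIPs
aggregate as 1 − Π_l(1 − α_lj) over active effects. `narrow_region`
reports the positional span of all surviving credible-set members against
the original locus span.

LD matrices are repaired to PSD by eigenvalue clipping at zero, rescaling
to unit diagonal, and shrinking off-diagonals by 1e-4 to guard exactly
singular blocks. Multi-ancestry fine mapping uses combined z from the
inverse-covariance meta-analysis against an element-wise
minimum-|r| merged LD panel; the test suite checks that combined-panel
credible sets are, on average, no larger than single-population sets.

## Synthetic data

Genotypes come from a Gaussian copula with binomial margins: two latent
haplotype draws per subject with block-diagonal latent correlation,
thresholded at the allele-frequency quantile, giving Hardy–Weinberg 0/1/2
dosages. Two deliberate choices make the blocks realistic: (a) MAFs are
drawn per LD block and shared within it, because the maximal correlation
between binary variables shrinks as their frequencies diverge — strongly
linked variants necessarily have similar frequencies; (b) the latent
pairwise correlation is calibrated by bisection on the bivariate-normal
orthant probability so the *realized dosage* correlation matches the
target ρ (thresholding otherwise attenuates 0.8 to roughly 0.5). At the
default target 0.8 the realized within-block mean is ≈ 0.799. Variant
properties (MAFs) depend only on the configuration seed, so multi-study
runs produce genuinely homogeneous cohorts; subject-level draws use
per-study child seeds.

Phenotypes follow Model 1 generatively: covariate effects (age 0.3
mmHg/yr, age² 0.002, sex 2.0), exposure main effect 2.0 mmHg, configurable
causal (β_G, β_GE) pairs, Gaussian residual SD 10 mmHg (BP-like). The
default exposure is binary with 25% prevalence, independent of genotype; a
confounded mode ties exposure probability to the first causal variant for
robustness checks. Everything is a pure function of (config, seed).

What the simulator does **not** emulate: recombination-map LD decay (blocks
are exchangeable within and independent between), imputation error (INFO
is a constant 1 stub), population stratification, relatedness, and
phenotype non-normality. Passing tests therefore demonstrate correctness
of the estimators and calibration under idealized sampling, not robustness
to those real-data complications.

## Problem sizes used in checks

The recovery suite uses 200-variant regions (blocks of 10 at ρ = 0.8) with
3,000 subjects and a strong causal signal (β_G = 2.5, β_GE = 2.0 against
residual SD 10, i.e. joint z around 8–12): 200 regions in the test suite
and 100 in the acceptance script, plus 50 null regions. Null calibration
uses 5,000 independent variants in two 1,000-subject studies. The
meta-vs-pooled oracle uses four 1,000-subject studies at 200 variants.
These sizes give stable Monte Carlo estimates (binomial 99% band of
±0.008 at 5,000 draws) while each run stays in the minutes range on one
CPU.

## Known limitations

- The fine-mapping model assumes one shared LD attenuation per variant
  pair across both z dimensions; exposure-genotype dependence violates
  this and is only available in the simulator as a stress mode.
- The region-average ρ̂ in C mis-weights variants whose within-variant
  correlation deviates strongly from the average (e.g. highly variable
  exposure prevalence across contributing studies).
- The joint↔stratified conversion is exact only for fully interacted
  models with independent strata.
- Genomic control, clumping and novelty classification operate on whatever
  variant set they are given; no liftover or allele-frequency matching
  against external panels is performed beyond the harmonization rules in
  `gxefine.sumstats` (swapped alleles fixed, strand-ambiguous records
  dropped with a logged count).
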