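# gxefine

A toolkit for gene–environment interaction GWAS of quantitative traits,
built around blood-pressure-by-smoking analyses: per-study joint
main-effect/interaction models, 1df and 2df fixed-effects meta-analysis of
summary statistics, FDR/LD-based locus discovery, conversion between joint
and exposure-stratified summary statistics, and **2df fine mapping** — a
sum-of-single-effects model operating on bivariate (main, interaction)
z-scores. A built-in multi-study simulator generates LD-block genotypes,
smoking-like exposures and BP-like phenotypes for testing every stage.

## Who it is for

Statistical geneticists running interaction GWAS across cohorts: each study
fits, per variant, the joint model

```
Model 1:  E(Y) = β₀ + β_E E + β_G SNP + β_GE (E×SNP) + β_C C
Model 2:  E(Y) = β₀ + β_G SNP + β_C C
```

with Y the phenotype (e.g. SBP in mmHg), E the exposure (e.g. current
smoking 0/1), SNP the allele dosage, and C covariates (age, age², sex, plus
their products with E). The interaction is tested with a 1df Wald test of
β_GE and the pair (β_G, β_GE) jointly with a 2df Wald test
χ² = b′V⁻¹b. Per-study estimates are combined by inverse-variance (1df)
and inverse-covariance-matrix (2df) fixed-effects meta-analysis:

```
V* = (Σᵢ Vᵢ⁻¹)⁻¹ ,   b* = V* Σᵢ Vᵢ⁻¹ bᵢ
```

Fine mapping treats each variant's bivariate z-vector
z_j = (β_G/se_G, β_GE/se_GE) as a noisy, LD-attenuated observation of L
one-hot single effects; per-variant Bayes factors
BF_j = N(z_j; 0, C+W)/N(z_j; 0, C) drive posterior inclusion
probabilities and 95% coverage credible sets with an LD-purity filter.

## Worked example

Simulate two 1,500-subject studies sharing one causal variant with both a
main effect (2.5 mmHg/allele) and a smoking interaction (2.0 mmHg/allele in
smokers), then run the whole pipeline:

```python
from gxefine.cli import RunConfig, run_pipeline

cfg = RunConfig(
    trait="SBP", exposure="CURSMK", seed=7, out_dir="run",
    simulate={
        "n_subjects": 1500, "n_studies": 2, "p_variants": 60,
        "block_size": 10, "rho": 0.8,
        "causal": [[25, 2.5, 2.0]], "residual_sd": 10.0,
    },
)
out = run_pipeline(cfg)
```

`run/manifest.json` then records (numbers from this exact run):

```json
"stages": {
  "simulate": {"studies": 2, "subjects": 3000, "variants": 60},
  "assoc_qc": {"kept": 120},
  "meta":     {"variants": 60, "dropped": 0,
               "lambda_1df": 1.0, "lambda_2df": 1.0},
  "loci":     {"significant_variants": 7, "loci": 1},
  "j2s":      {"variants": 7},
  "finemap":  {"loci": 1, "credible_sets": 1}
}
```

Reading: 60 variants were fit per study and survived QC (120 study-level
records); the 2df meta-analysis flagged the causal variant and six of its
LD-block neighbors at genome-wide significance; clumping groups all seven
into one locus led by the smallest p-value; the significant joint estimates
were converted to smoker/non-smoker stratified effects; and fine mapping of
the locus emitted one 95% credible set containing the causal variant. Genomic
control is skipped (λ reported as 1) because 60 variants cannot estimate a
null median.

The same stages are available on files from the shell:

```
gxefine simulate --out-dir fx --seed 42
gxefine assoc --pheno fx/pheno.tsv --dosages fx/dosages.tsv --model joint --out s1.tsv
gxefine meta --inputs s1.tsv --no-gc --out meta.tsv
gxefine finemap --sumstats s1.tsv --ld fx/ld.txt --ld-index fx/ld.idx --out cs.tsv
```

## Layout

| module | contents |
| --- | --- |
| `gxefine.sumstats` | data model, TSV/LD readers and writers, allele harmonization |
| `gxefine.pheno` | BP medication adjustment, winsorization, smoking exposures |
| `gxefine.assoc` | per-study Model 1 / Model 2 fits, 1df and 2df Wald tests |
| `gxefine.meta` | QC filters, IVW and inverse-covariance meta, genomic control |
| `gxefine.loci` | BH FDR, significance rules, LD clumping, novelty labels |
| `gxefine.j2s` | joint ↔ exposure-stratified summary-statistic conversion |
| `gxefine.finemap` | 2df sum-of-single-effects fine mapping, credible sets |
| `gxefine.simulate` | multi-study genotype/phenotype generator |
| `gxefine.cli` | `gxefine` command-line interface and pipeline driver |

See `docs/methods.md` for the statistical model, defaults and limitations.
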