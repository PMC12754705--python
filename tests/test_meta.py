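import numpy as np
import pytest
from scipy import stats

from gxefine.assoc import fit_model1
from gxefine.meta import (
    QCRules,
    apply_genomic_control,
    approximate_df,
    genomic_control,
    meta_1df,
    meta_2df_joint,
    meta_inclusion_filter,
    meta_joint_records,
    sex_heterogeneity,
    small_sample_pvalues,
    study_qc_filter,
)
from gxefine.simulate import SimConfig, simulate_cohort, simulate_multistudy
from gxefine.sumstats import JointStat, VariantKey


def _spd(rng, scale=1.0):
    a = rng.standard_normal((2, 2))
    return scale * (a @ a.T + 0.2 * np.eye(2))


class TestApproximateDF:
    def test_expected_genotype_variance_formula(self):
        assert approximate_df(100, 0.5) == pytest.approx(50.0)

    def test_monomorphic_gives_zero(self):
        assert approximate_df(1000, 0.0) == 0.0

    def test_monotone_in_both_arguments(self):
        mafs = np.linspace(0.01, 0.5, 20)
        dfs = [approximate_df(500, m) for m in mafs]
        assert np.all(np.diff(dfs) > 0)
        ns = np.arange(100, 1000, 100)
        assert np.all(np.diff([approximate_df(n, 0.2) for n in ns]) > 0)


def _rec(eaf=0.3, info=0.9, n_e0=5000.0, n_e1=2000.0, n=None, **kw):
    n = n or (n_e0 + n_e1)
    defaults = dict(
        key=VariantKey(chrom="1", pos=100, ea="A", oa="G"),
        eaf=eaf, n=n, n_e0=n_e0, n_e1=n_e1, info=info,
        beta_g=0.1, se_g=0.05, beta_gxe=0.02, se_gxe=0.08,
        cov_g_gxe=-0.001, p_1df=0.5, p_2df=0.5,
    )
    defaults.update(kw)
    return JointStat(**defaults)


class TestStudyQC:
    def test_low_info_dropped(self):
        kept, dropped = study_qc_filter([_rec(info=0.55)])
        assert not kept and "INFO<0.6" in dropped[0].reason

    def test_rare_band_needs_higher_info(self):
        kept, dropped = study_qc_filter([_rec(eaf=0.005, info=0.75)])
        assert not kept and "rare-band" in dropped[0].reason

    def test_all_rules_pass(self):
        kept, dropped = study_qc_filter(
            [_rec(eaf=0.5, info=0.9, n_e0=5000, n_e1=15.0 / (2 * 0.5))]
        )
        assert len(kept) == 1 and not dropped

    def test_stratum_mac_rule(self):
        # MAC_e1 = 2 * 10 * 0.3 = 6 < 10
        kept, dropped = study_qc_filter([_rec(n_e1=10.0, n_e0=7000.0)])
        assert not kept and "MAC" in dropped[0].reason

    def test_monomorphic_dropped_first(self):
        kept, dropped = study_qc_filter([_rec(eaf=0.0, info=0.2)])
        assert dropped[0].reason == "monomorphic"

    def test_df_thresholds(self):
        kept, dropped = study_qc_filter([_rec(df_all=15.0)])
        assert "DF_ALL" in dropped[0].reason


class TestMeta1df:
    def test_single_study_identity(self):
        beta, se, _ = meta_1df([(0.3, 0.1)])
        assert (beta, se) == (pytest.approx(0.3), pytest.approx(0.1))

    def test_two_identical_studies_halve_variance(self):
        beta, se, _ = meta_1df([(0.3, 0.1), (0.3, 0.1)])
        assert beta == pytest.approx(0.3)
        assert se == pytest.approx(0.1 / np.sqrt(2))

    def test_matches_gls_normal_equations(self, rng):
        """IVW equals weighted least squares solved explicitly."""
        est = [(rng.normal(), rng.uniform(0.05, 0.5)) for _ in range(5)]
        beta, se, _ = meta_1df(est)
        y = np.array([b for b, _ in est])
        W = np.diag([1 / s**2 for _, s in est])
        X = np.ones((5, 1))
        gls_var = np.linalg.inv(X.T @ W @ X)
        gls_beta = gls_var @ X.T @ W @ y
        assert beta == pytest.approx(float(gls_beta[0]), rel=1e-12)
        assert se == pytest.approx(float(np.sqrt(gls_var[0, 0])), rel=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            meta_1df([])


class TestMeta2df:
    def test_single_study_identity(self, rng):
        b, V = rng.standard_normal(2), _spd(rng)
        res = meta_2df_joint([(b, V)])
        assert np.allclose(res.cov, V)
        assert res.beta_g == pytest.approx(b[0])

    def test_two_identical_studies_halve_covariance(self, rng):
        b, V = rng.standard_normal(2), _spd(rng)
        res = meta_2df_joint([(b, V), (b, V)])
        assert np.allclose(res.cov, V / 2)
        assert np.allclose([res.beta_g, res.beta_gxe], b)

    def test_order_invariance_and_pairwise_associativity(self, rng):
        ests = [(rng.standard_normal(2), _spd(rng)) for _ in range(4)]
        full = meta_2df_joint(ests)
        shuffled = meta_2df_joint(ests[::-1])
        assert np.allclose(full.cov, shuffled.cov)
        assert full.beta_g == pytest.approx(shuffled.beta_g)
        # pairwise: combine (1,2) then (3,4), then the two combinations
        a = meta_2df_joint(ests[:2])
        b = meta_2df_joint(ests[2:])
        paired = meta_2df_joint(
            [
                (np.array([a.beta_g, a.beta_gxe]), a.cov),
                (np.array([b.beta_g, b.beta_gxe]), b.cov),
            ]
        )
        assert np.allclose(paired.cov, full.cov)
        assert paired.beta_gxe == pytest.approx(full.beta_gxe)

    def test_combined_covariance_dominated_by_each_study(self, rng):
        ests = [(rng.standard_normal(2), _spd(rng)) for _ in range(3)]
        res = meta_2df_joint(ests)
        for _, V in ests:
            assert np.linalg.eigvalsh(V - res.cov).min() > -1e-10

    def test_singular_study_excluded_not_fatal(self, rng):
        good = (np.zeros(2), np.eye(2))
        bad = (np.ones(2), np.ones((2, 2)))
        res = meta_2df_joint([good, bad])
        assert res.n_studies == 1

    def test_matches_pooled_individual_level_fit(self):
        """IVW of homogeneous per-study fits agrees with the pooled fit."""
        cfg = SimConfig(
            n_subjects=1000, n_studies=4, p_variants=12,
            causal=[(4, 0.4, 0.3)], residual_sd=1.0, seed=77,
        )
        cohorts, _ = simulate_multistudy(cfg)
        per_study = [fit_model1(c)[0] for c in cohorts]
        combined = meta_joint_records(per_study)

        import numpy as _np
        from gxefine.assoc import StudyCohort
        stacked = StudyCohort(
            dosages=_np.vstack([c.dosages for c in cohorts]),
            phenotype=_np.concatenate([c.phenotype for c in cohorts]),
            exposure=_np.concatenate([c.exposure for c in cohorts]),
            covariates=_np.vstack([c.covariates for c in cohorts]),
            covariate_names=cohorts[0].covariate_names,
            keys=cohorts[0].keys,
        )
        pooled, _ = fit_model1(stacked)
        for res, pool in zip(combined, pooled):
            se_g = np.sqrt(res.cov[0, 0])
            se_ge = np.sqrt(res.cov[1, 1])
            assert abs(res.beta_g - pool.beta_g) < 3 * se_g
            assert abs(res.beta_gxe - pool.beta_gxe) < 3 * se_ge


class TestGenomicControl:
    def test_well_calibrated_statistics_lambda_one(self, rng):
        chi2 = rng.chisquare(1, size=100_000)
        lam, _, _ = genomic_control(chi2, df=1)
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_inflated_statistics_deflated_to_reference_median(self, rng):
        chi2 = 1.2 * rng.chisquare(1, size=100_000)
        lam, corrected, _ = genomic_control(chi2, df=1)
        assert lam == pytest.approx(1.2, abs=0.03)
        assert np.median(corrected) == pytest.approx(
            stats.chi2.ppf(0.5, 1), abs=0.01
        )

    def test_deflation_left_alone(self, rng):
        chi2 = 0.9 * rng.chisquare(1, size=10_000)
        lam, corrected, _ = genomic_control(chi2, df=1)
        assert lam < 1
        assert np.array_equal(corrected, chi2)

    def test_df2_reference_median(self, rng):
        chi2 = rng.chisquare(2, size=100_000)
        lam, _, _ = genomic_control(chi2, df=2)
        assert lam == pytest.approx(1.0, abs=0.02)


class TestInclusionFilter:
    def _res(self, n=50_000, pops=3, chrom="1", pos=1000):
        from gxefine.meta import MetaResult
        return MetaResult(
            key=VariantKey(chrom=chrom, pos=pos, ea="A", oa="G"),
            beta_g=0.0, beta_gxe=0.0, cov=np.eye(2),
            chi2_1df=0.0, chi2_2df=0.0, p_1df=1.0, p_2df=1.0,
            n=n, n_studies=3, n_populations=pops,
        )

    def test_small_n_dropped(self):
        kept, dropped = meta_inclusion_filter([self._res(n=19_999)])
        assert not kept and "N<" in dropped[0].reason

    def test_single_population_cpma_dropped(self):
        kept, dropped = meta_inclusion_filter([self._res(pops=1)], cpma=True)
        assert not kept and "population" in dropped[0].reason

    def test_mhc_padding(self):
        inside = self._res(chrom="6", pos=28_477_797 - 500_000)
        outside = self._res(chrom="6", pos=28_477_797 - 1_500_000)
        kept, dropped = meta_inclusion_filter([inside, outside])
        assert len(kept) == 1 and kept[0].key.pos == outside.key.pos


class TestSexHeterogeneity:
    def test_equal_effects_null(self):
        z, p, flag = sex_heterogeneity(0.5, 0.1, 0.5, 0.2)
        assert z == 0.0 and p == pytest.approx(1.0) and not flag

    def test_z_formula(self):
        z, p, flag = sex_heterogeneity(1.0, 0.5, 0.0, 0.5)
        assert z == pytest.approx(np.sqrt(2), rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(np.sqrt(2)), rel=1e-10)
        assert not flag

    def test_flag_only_below_threshold(self):
        _, p, flag = sex_heterogeneity(1.0, 0.1, 0.0, 0.1)
        assert (p < 1e-6) == flag


class TestSmallSample:
    def test_large_df_passthrough(self):
        rec = _rec(df_all=500.0)
        assert small_sample_pvalues(rec) == (rec.p_1df, rec.p_2df)

    def test_small_df_uses_heavier_tails(self):
        rec = _rec(beta_gxe=0.24, se_gxe=0.08, df_all=10.0)
        p1, p2 = small_sample_pvalues(rec)
        z = rec.beta_gxe / rec.se_gxe
        assert p1 > 2 * stats.norm.sf(abs(z))  # t has heavier tails


def test_null_meta_2df_pvalues_uniform():
    """Two-study null meta-analysis yields uniform 1df and 2df p-values."""
    cfg = SimConfig(
        n_subjects=1000, n_studies=2, p_variants=800, block_size=1,
        rho=0.0, causal=[], residual_sd=1.0, seed=99,
    )
    cohorts, _ = simulate_multistudy(cfg)
    combined = meta_joint_records([fit_model1(c)[0] for c in cohorts])
    p1 = np.array([r.p_1df for r in combined])
    p2 = np.array([r.p_2df for r in combined])
    assert stats.kstest(p1, "uniform").pvalue > 0.01
    assert stats.kstest(p2, "uniform").pvalue > 0.01
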