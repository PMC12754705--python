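import numpy as np
import pytest

from gxefine.finemap import (
    CredibleSet,
    FinemapInput,
    SusieFit,
    credible_sets,
    fit_susiegxe,
    narrow_region,
    pip,
    single_effect_2df,
)
from gxefine.simulate import SimConfig, simulate_finemap_region
from gxefine.sumstats import LDMatrix, VariantKey

from reference_susie import scalar_susie_rss


def _keys(p):
    return [VariantKey(chrom="1", pos=1000 + i, ea="A", oa="G") for i in range(p)]


def _uniform_pi(p):
    return np.full(p, 1.0 / p)


class TestSingleEffect:
    def test_null_z_gives_uniform_alpha(self):
        p = 10
        alpha, mu, cov, logbf = single_effect_2df(
            np.zeros((p, 2)), np.eye(2), 10 * np.eye(2), _uniform_pi(p)
        )
        assert np.allclose(alpha, 1.0 / p)
        assert np.allclose(mu, 0.0)

    def test_strong_variant_dominates(self):
        p = 50
        z = np.zeros((p, 2))
        z[17] = [10.0, 0.0]
        alpha, *_ = single_effect_2df(
            z, np.eye(2), np.diag([100.0, 100.0]), _uniform_pi(p)
        )
        assert alpha[17] > 0.99
        # cross-check with direct Bayes-factor computation
        from scipy.stats import multivariate_normal as mvn
        bf = np.array(
            [
                mvn.pdf(z[j], cov=np.eye(2) + np.diag([100, 100.0]))
                / mvn.pdf(z[j], cov=np.eye(2))
                for j in range(p)
            ]
        )
        direct = bf / bf.sum()
        assert np.allclose(alpha, direct, atol=1e-10)

    def test_alpha_always_normalized(self, rng):
        for _ in range(10):
            z = rng.standard_normal((20, 2)) * 3
            alpha, *_ = single_effect_2df(
                z, np.eye(2), rng.uniform(0.1, 5) * np.eye(2), _uniform_pi(20)
            )
            assert alpha.sum() == pytest.approx(1.0)
            assert np.all(alpha >= 0)

    def test_singular_prior_allowed(self):
        """W constrained to the main-effect dimension must not fail."""
        z = np.array([[3.0, 0.0], [0.0, 0.0]])
        W = np.array([[4.0, 0.0], [0.0, 0.0]])
        alpha, mu, cov, _ = single_effect_2df(z, np.eye(2), W, _uniform_pi(2))
        assert alpha[0] > alpha[1]
        assert mu[0, 1] == 0.0  # no interaction-dimension update

    def test_non_psd_prior_rejected(self):
        with pytest.raises(ValueError, match="semidefinite"):
            single_effect_2df(
                np.zeros((3, 2)), np.eye(2),
                np.array([[1.0, 2.0], [2.0, 1.0]]), _uniform_pi(3),
            )


class TestPip:
    def test_single_effect_pip_is_alpha(self):
        alpha = np.array([[0.7, 0.2, 0.1]])
        fit = _fit_stub(alpha, scales=np.array([1.0]))
        assert np.allclose(pip(fit), alpha[0])

    def test_certain_effects_give_pip_one(self):
        alpha = np.array([[1.0, 0.0], [1.0, 0.0]])
        fit = _fit_stub(alpha, scales=np.array([1.0, 1.0]))
        assert pip(fit)[0] == pytest.approx(1.0)

    def test_matches_product_formula(self, rng):
        alpha = rng.dirichlet(np.ones(6), size=4)
        fit = _fit_stub(alpha, scales=np.ones(4))
        expected = 1 - np.prod(1 - alpha, axis=0)
        assert np.allclose(pip(fit), expected)

    def test_inactive_effects_excluded(self, rng):
        alpha = np.vstack([np.array([0.9, 0.05, 0.05]), np.full(3, 1 / 3)])
        fit = _fit_stub(alpha, scales=np.array([1.0, 0.0]))
        assert np.allclose(pip(fit), alpha[0])


def _fit_stub(alpha, scales):
    L, p = alpha.shape
    return SusieFit(
        L=L, alpha=alpha, mu=np.zeros((L, p, 2)),
        post_cov=np.zeros((L, 2, 2)), prior_scales=scales,
        lbf_effect=np.zeros(L), pip=np.zeros(p),
    )


class TestCredibleSets:
    def _ld(self, p, r=0.9):
        m = np.full((p, p), r)
        np.fill_diagonal(m, 1.0)
        return LDMatrix(_keys(p), m)

    def test_dominant_variant_singleton_set(self):
        fit = _fit_stub(np.array([[0.97, 0.02, 0.01]]), np.array([1.0]))
        (cs,) = credible_sets(fit, self._ld(3))
        assert cs.members == [0] and cs.purity == 1.0

    def test_prefix_rule_two_members(self):
        fit = _fit_stub(np.array([[0.50, 0.46, 0.04]]), np.array([1.0]))
        (cs,) = credible_sets(fit, self._ld(3))
        assert cs.members == [0, 1]
        assert cs.coverage == pytest.approx(0.96)

    def test_diffuse_set_discarded_by_purity(self):
        p = 100
        fit = _fit_stub(np.full((1, p), 1.0 / p), np.array([1.0]))
        assert credible_sets(fit, self._ld(p, r=0.01)) == []

    def test_duplicate_sets_deduplicated(self):
        alpha = np.array([[0.97, 0.02, 0.01], [0.98, 0.01, 0.01]])
        fit = _fit_stub(alpha, np.array([1.0, 1.0]))
        sets = credible_sets(fit, self._ld(3))
        assert len(sets) == 1
        assert sets[0].coverage == pytest.approx(0.98)


class TestFitSusiegxe:
    def test_strong_single_causal_recovered(self):
        cfg = SimConfig(
            n_subjects=3000, p_variants=200, block_size=10, rho=0.8,
            causal=[(47, 2.5, 2.0)], residual_sd=10.0, seed=7,
        )
        fm, truth = simulate_finemap_region(cfg)
        fit = fit_susiegxe(fm)
        assert fit.converged
        assert fit.pip[47] > 0.9
        sets = credible_sets(fit, fm.ld)
        assert len(sets) == 1 and 47 in sets[0].members

    def test_alpha_rows_sum_to_one(self):
        cfg = SimConfig(
            n_subjects=1500, p_variants=60, causal=[(11, 2.0, 1.5)],
            residual_sd=10.0, seed=13,
        )
        fm, _ = simulate_finemap_region(cfg)
        fit = fit_susiegxe(fm)
        assert np.allclose(fit.alpha.sum(axis=1), 1.0)

    def test_objective_trace_non_decreasing(self):
        cfg = SimConfig(
            n_subjects=2000, p_variants=100, causal=[(30, 2.5, 2.0)],
            residual_sd=10.0, seed=17,
        )
        fm, _ = simulate_finemap_region(cfg)
        fit = fit_susiegxe(fm)
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_null_region_rarely_emits_sets(self):
        with_sets = 0
        for seed in range(15):
            cfg = SimConfig(
                n_subjects=1500, p_variants=100, block_size=10, rho=0.8,
                causal=[], residual_sd=10.0, seed=300 + seed,
            )
            fm, _ = simulate_finemap_region(cfg)
            fit = fit_susiegxe(fm)
            if credible_sets(fit, fm.ld):
                with_sets += 1
        assert with_sets <= 2

    def test_L1_reduces_to_single_effect(self):
        cfg = SimConfig(
            n_subjects=2000, p_variants=50, causal=[(9, 2.5, 2.0)],
            residual_sd=10.0, seed=23,
        )
        fm, _ = simulate_finemap_region(cfg)
        fit = fit_susiegxe(fm, L=1)
        rho_bar = float(np.mean(fm.rho))
        C = np.array([[1.0, rho_bar], [rho_bar, 1.0]])
        from gxefine.finemap import _estimate_prior, _prior_matrix
        scale, _ = _estimate_prior(fm.z, C, fm.pi)
        alpha, *_ = single_effect_2df(fm.z, C, _prior_matrix(scale, False), fm.pi)
        assert np.allclose(fit.alpha[0], alpha, atol=1e-10)

    def test_too_few_variants_rejected(self):
        z = np.zeros((1, 2))
        ld = LDMatrix(_keys(1), np.eye(1))
        with pytest.raises(ValueError, match="at least 2"):
            fit_susiegxe(FinemapInput(z=z, rho=np.zeros(1), ld=ld))


class TestDegenerateScalarReduction:
    def test_matches_scalar_susie_rss_reference(self):
        """With the interaction dimension removed, the bivariate fit reduces
        to an independently written scalar summary-statistic model."""
        cfg = SimConfig(
            n_subjects=2500, p_variants=80, block_size=10, rho=0.8,
            causal=[(25, 2.5, 0.0)], residual_sd=10.0, seed=29,
        )
        fm, _ = simulate_finemap_region(cfg)
        z2 = np.column_stack([fm.z[:, 0], np.zeros(fm.p)])
        degenerate = FinemapInput(
            z=z2, rho=np.zeros(fm.p), ld=fm.ld, pi=fm.pi
        )
        fit = fit_susiegxe(degenerate, prior_main_only=True)
        R = fm.ld.repaired_psd().r
        ref_alpha, _, ref_scales, ref_conv = scalar_susie_rss(fm.z[:, 0], R)
        assert fit.converged == ref_conv
        assert np.max(np.abs(fit.alpha - ref_alpha)) < 1e-4


class TestMultiAncestry:
    def test_combined_populations_narrow_sets(self):
        """Pooling two populations (stricter LD, combined z) should not give
        larger credible sets on average."""
        from gxefine.meta import meta_2df_joint

        sizes_single, sizes_multi = [], []
        for seed in range(12):
            cfgs = [
                SimConfig(
                    n_subjects=1500, p_variants=100, block_size=10, rho=0.8,
                    causal=[(33, 2.2, 1.8)], residual_sd=10.0, seed=500 + seed,
                ),
                SimConfig(
                    n_subjects=1500, p_variants=100, block_size=10, rho=0.6,
                    causal=[(33, 2.2, 1.8)], residual_sd=10.0, seed=700 + seed,
                ),
            ]
            fms = []
            recs = []
            for cfg in cfgs:
                fm, truth = simulate_finemap_region(cfg)
                fms.append(fm)
                recs.append(truth["records"])
            fit_a = fit_susiegxe(fms[0])
            sets_a = credible_sets(fit_a, fms[0].ld)
            if sets_a:
                sizes_single.append(np.mean([len(s.members) for s in sets_a]))

            combined = []
            for ra, rb in zip(*recs):
                res = meta_2df_joint(
                    [
                        (np.array([ra.beta_g, ra.beta_gxe]), ra.covariance()),
                        (np.array([rb.beta_g, rb.beta_gxe]), rb.covariance()),
                    ]
                )
                combined.append(res)
            z = np.array(
                [
                    [r.beta_g / r.se_g, r.beta_gxe / r.se_gxe]
                    for r in combined
                ]
            )
            rho = np.array(
                [r.cov[0, 1] / (r.se_g * r.se_gxe) for r in combined]
            )
            r_multi = np.where(
                np.abs(fms[0].ld.r) < np.abs(fms[1].ld.r),
                fms[0].ld.r, fms[1].ld.r,
            )
            ld_multi = LDMatrix(fms[0].ld.keys, r_multi)
            fm_multi = FinemapInput(z=z, rho=np.clip(rho, -0.99, 0.99), ld=ld_multi)
            fit_m = fit_susiegxe(fm_multi)
            sets_m = credible_sets(fit_m, fm_multi.ld)
            if sets_m:
                sizes_multi.append(np.mean([len(s.members) for s in sets_m]))
        assert np.mean(sizes_multi) <= np.mean(sizes_single) + 0.5


class TestNarrowRegion:
    def _positions(self):
        return np.array([26_681_997, 26_690_000, 26_700_000, 26_710_019])

    def test_refined_span_from_members(self):
        cs = CredibleSet(effect=0, members=[1, 2], coverage=0.96, purity=0.9)
        span, ratio, narrowed = narrow_region(
            (26_681_997, 26_710_019), [cs], self._positions()
        )
        assert span == (26_690_000, 26_700_000)
        assert narrowed and ratio < 1

    def test_single_variant_set_reports_1bp(self):
        cs = CredibleSet(effect=0, members=[2], coverage=0.97, purity=1.0)
        span, ratio, narrowed = narrow_region(
            (26_681_997, 26_710_019), [cs], self._positions()
        )
        assert span == (26_700_000, 26_700_000)
        assert ratio == pytest.approx(1 / 28_022)

    def test_no_sets_returns_original(self):
        span, ratio, narrowed = narrow_region(
            (100, 200), [], self._positions()
        )
        assert span == (100, 200) and not narrowed and ratio == 1.0
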