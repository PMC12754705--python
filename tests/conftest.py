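import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from gxefine import simulate
from gxefine.sumstats import JointStat, VariantKey


@pytest.fixture
def small_cohort():
    """A 2000-subject cohort with one causal variant (main 0.5, gxe 0.3)."""
    cfg = simulate.SimConfig(
        n_subjects=2000,
        p_variants=20,
        block_size=5,
        rho=0.5,
        causal=[(7, 0.5, 0.3)],
        residual_sd=1.0,
        seed=11,
    )
    return simulate.simulate_cohort(cfg), cfg


@pytest.fixture
def joint_records():
    """Three hand-built valid joint records."""
    recs = []
    for i, (chrom, pos) in enumerate([("1", 1000), ("2", 5000), ("2", 9000)]):
        recs.append(
            JointStat(
                key=VariantKey(chrom=chrom, pos=pos, ea="A", oa="G", rsid=f"rs{i}"),
                eaf=0.3 + 0.1 * i,
                n=10000,
                n_e0=7500,
                n_e1=2500,
                info=0.95,
                beta_g=0.1 * (i + 1),
                se_g=0.05,
                beta_gxe=-0.02 * i,
                se_gxe=0.08,
                cov_g_gxe=-0.001,
                p_1df=0.5,
                p_2df=0.05,
            )
        )
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
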