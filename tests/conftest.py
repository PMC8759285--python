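import numpy as np
import pytest

from ptrs_kit.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-population cohort shared by read-only tests."""
    cfg = SimConfig(
        n_per_population=400,
        n_variants=200,
        n_genes=50,
        cis_variants_per_gene=3,
        fst_like_divergence=0.1,
        mediated_h2=0.35,
        direct_h2=0.15,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
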