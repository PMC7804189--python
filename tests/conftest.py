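import numpy as np
import pytest

from grexdissect.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with moderate heritability and no phenotype effects."""
    cfg = SimulationConfig(
        n_samples=200, n_cases=100, n_genes=15, snps_per_gene=10,
        n_causal_weights_per_gene=4, h2_per_gene=0.3,
        maf_range=(0.1, 0.4), n_covariates=2, n_genotype_pcs=2, seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
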