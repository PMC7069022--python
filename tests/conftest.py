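import numpy as np
import pytest

from mycnfunnel import synthetic_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A 300-gene, 20-sample cohort with 20 planted targets at log2fc 1.5."""
    cfg = synthetic_data.CohortSimConfig(
        n_genes=300,
        n_samples=20,
        amplified_fraction=0.5,
        n_target_genes=20,
        target_log2fc=1.5,
        seed=3,
    )
    matrix, annotations, truth = synthetic_data.simulate_cohort(cfg)
    return cfg, matrix, annotations, truth


@pytest.fixture
def small_genome():
    cfg = synthetic_data.GenomeSimConfig(
        n_genes=50, chrom_length=100_000, promoter_len=200,
        ebox_plant_probability=0.5, seed=11,
    )
    return cfg, synthetic_data.simulate_genome(cfg)
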