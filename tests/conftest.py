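import numpy as np
import pytest

from polyte.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic genome shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        chrom_lengths={"chr1A": 400_000, "chr1B": 400_000, "chr1D": 400_000},
        n_genes_per_subgenome=40,
        n_flltr=15,
        ltr_length_range=(300, 500),
        internal_length_range=(1_000, 1_500),
        age_distribution=("uniform", 0.0, 1.5e6),
        module_sizes=(40, 30),
        spacing_conservation=0.8,
    )
    return simulate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
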