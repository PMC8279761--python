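import numpy as np
import pytest

from calchip import SimConfig, make_genomes, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale experiment: 4 experimental chromosomes with anchored peaks."""
    return SimConfig(
        seed=7,
        n_chroms_exp=4,
        chrom_len_exp=10_000,
        n_chroms_cal=2,
        chrom_len_cal=8_000,
        peak_width=600,
        peak_amplitude=6.0,
        read_len=40,
        n_ip_reads=8_000,
        n_wce_reads=8_000,
    )


@pytest.fixture(scope="session")
def small_genomes(small_config):
    return make_genomes(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_config, small_genomes):
    return simulate_experiment(small_genomes, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_917)
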