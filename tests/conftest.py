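import numpy as np
import pytest

from centrotrace import SimConfig, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down generator config for unit tests (one small chromosome)."""
    return SimConfig(
        n_chroms=1, chrom_len=400_000, cen_len=120_000, cen_position=0.4,
        n_families=3, planted_cr_copies_cen=8, planted_cr_copies_noncen=2,
        background_copies=8, element_len=3000, ltr_len=500,
        extra_ltr_solo_copies_cen=5, tr_copy_number=30, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return generate_genome(small_config)
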