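import numpy as np
import pytest

from cerna_screen.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A down-scaled synthetic cohort used by fast integration tests."""
    return SyntheticConfig(
        n_lncrna=30, n_mirna=15, n_planted_pairs=5, n_probes_per_lncrna=3,
        n_decoy_coding_overlaps=4, n_ig_region_lncrna=3,
        group_sizes={"MM": 20, "PCL": 8, "normal": 4},
        transcript_length=(300, 500), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
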