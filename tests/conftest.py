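import numpy as np
import pytest

from eggcomp import synthdata


@pytest.fixture(scope="session")
def default_design():
    """The full study-sized design: 39 clutches, 114 eggs."""
    return synthdata.generate_design(synthdata.StudyConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A down-scaled study for fast end-to-end runs."""
    return synthdata.StudyConfig(
        seed=5, n_clutches=14, n_full_clutches=4, target_n_eggs=44,
        n_albumen_proteins=24, n_yolk_proteins=20)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthdata.generate_dataset(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140)
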