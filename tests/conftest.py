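import numpy as np
import pytest

from tausynth import PhantomConfig, generate_cohort, make_atlas


@pytest.fixture(scope="session")
def small_config():
    """Cheap 16^3 phantom conditions used by most unit tests."""
    return PhantomConfig(grid_shape=(16, 16, 16), n_subjects=12, scans_per_subject=2, seed=7)


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return make_atlas(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_atlas):
    return generate_cohort(small_config, small_atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
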