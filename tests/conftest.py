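import numpy as np
import pytest

from petcad import PhantomConfig, simulate_cohort
from petcad.preprocess import Volume


@pytest.fixture(scope="session")
def small_config():
    """A fast 22-subject phantom with a strong, well-localized group effect."""
    return PhantomConfig(
        grid_shape=(20, 20, 20),
        n_pd=10,
        n_aps=12,
        effect_size=30.0,
        noise_sd=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_volume(data, voxel_size=(2.0, 2.0, 2.0), subject_id="test"):
    return Volume(data=np.asarray(data, dtype=float), voxel_size=voxel_size,
                  subject_id=subject_id)
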