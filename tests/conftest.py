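import numpy as np
import pytest

from handsym.imggeom import ImageGrid
from handsym.synthdata import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid():
    return ImageGrid((10, 8, 6), (3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def small_cohort_config():
    """A desk-scale cohort: same generative structure as the defaults,
    smaller groups and grid so pipeline tests stay fast."""
    return CohortConfig(
        n_patients=5,
        n_controls=6,
        shape=(20, 20, 16),
        T=128,
        n_flip_patients=2,
        n_flip_controls=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return generate_cohort(small_cohort_config)
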