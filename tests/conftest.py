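import numpy as np
import pytest

from painstn.labeling import AUCoding
from painstn.synthetic import NuisanceConfig, generate_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """120 frames of 24x24 synthetic faces, 10 subjects, mild nuisance."""
    return generate_arrays(
        120,
        distribution=(0.4, 0.3, 0.2, 0.1),
        n_subjects=10,
        nuisance=NuisanceConfig().scaled(0.5),
        image_size=24,
        seed=7,
    )


@pytest.fixture
def neutral_au():
    return AUCoding(0, 0, 0, 0, 0, 0)


@pytest.fixture
def extreme_au():
    return AUCoding(5, 5, 5, 5, 5, 1)
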