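import numpy as np
import pytest
from hypothesis import settings

from accelhar import DatasetConfig, generate_dataset, segment_recordings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """Two subjects x one trial of the default protocol."""
    return generate_dataset(2, 1, DatasetConfig(), seed=11)


@pytest.fixture(scope="session")
def small_tensor(small_dataset):
    """Windowed tensor over the small dataset (transition-free, pure)."""
    return segment_recordings(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
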