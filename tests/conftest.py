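import numpy as np
import pytest

from grasshopper_fs import SplitSpec, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 samples, 8 features (3 informative, separation 4): exhaustively searchable."""
    return generate_dataset(
        SyntheticSpec(n_samples=60, n_informative=3, n_noise=5,
                      class_separation=4.0, seed=1))


@pytest.fixture(scope="session")
def recovery_dataset():
    """200 samples, 10 features (3 informative, separation 4)."""
    return generate_dataset(
        SyntheticSpec(n_samples=200, n_informative=3, n_noise=7,
                      class_separation=4.0, seed=11))


@pytest.fixture()
def fixed_split():
    return SplitSpec(seed=7)
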