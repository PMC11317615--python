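import numpy as np
import pytest

import chd


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fput_dataset():
    """One FPUT benchmark realization shared by the acceptance tests."""
    return chd.simulate_fput(seed=2024)


@pytest.fixture(scope="session")
def fput_normalized(fput_dataset):
    return chd.normalize(fput_dataset.data)
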