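import numpy as np
import pytest

from photospawn.model import default_model, sample_fc_ensemble


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def fc300(model):
    """The standard 300-member thermal ensemble at 300 K."""
    return sample_fc_ensemble(model, 300, 300.0, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
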