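import numpy as np
import pytest

from gmhcrf.gradcheck import random_model, random_sequence, random_spd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model(rng):
    return random_model(rng, n_classes=3, Q=2, M=2, D=2)


@pytest.fixture
def small_sequence(rng):
    return random_sequence(rng, T=4, D=2)


def make_instance(rng, n_classes=2, Q=2, M=2, D=2, T=4):
    """(model, sequence) pair with a label drawn from the model."""
    model = random_model(rng, n_classes, Q, M, D)
    label = model.labels[int(rng.integers(n_classes))]
    seq = random_sequence(rng, T, D, label=label)
    return model, seq
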