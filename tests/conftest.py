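import numpy as np
import pytest

from idpmeta.types import DISORDERED, ORDERED, DisorderLabels


def random_instance(rng, n_max=200, n_min=4):
    """Random (scores, states) with both classes present."""
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        states = rng.choice([ORDERED, DISORDERED], size=n).astype(np.int8)
        if 0 < states.sum() < n:
            break
    scores = np.round(rng.random(n), 3)  # rounded -> frequent ties
    return scores, states


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labels_ab():
    """Two small label records used across io/metric tests."""
    return [
        DisorderLabels.from_string("t1", "DDOOO"),
        DisorderLabels.from_string("t2", "OODD.O"),
    ]
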