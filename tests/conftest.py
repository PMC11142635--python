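import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from esses.network import BrainNetwork


def make_net(weights, labels=None):
    w = np.asarray(weights, dtype=float)
    labels = labels or tuple(f"r{i}" for i in range(w.shape[0]))
    return BrainNetwork(labels, w)


@pytest.fixture
def path3():
    """3-node path a-b-c, w(a,b)=0.5, w(b,c)=0.25."""
    return make_net([[0, 0.5, 0], [0.5, 0, 0.25], [0, 0.25, 0]])


@pytest.fixture
def star3():
    """3-node star: centre 0, spokes 1 and 2, both weights 0.5."""
    return make_net([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]])


@pytest.fixture
def complete4():
    """4-node complete graph with distinct weights."""
    w = np.zeros((4, 4))
    vals = iter([0.9, 0.8, 0.7, 0.6, 0.55, 0.52])
    for i in range(4):
        for j in range(i + 1, 4):
            w[i, j] = w[j, i] = next(vals)
    return make_net(w)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
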