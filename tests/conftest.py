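import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_two_clusters():
    """Two tight, far-separated 2-D clusters of 10 points each."""
    g = np.random.default_rng(7)
    a = g.normal(0.0, 1.0, size=(10, 2))
    b = g.normal(100.0, 1.0, size=(10, 2))
    X = np.vstack([a, b])
    labels = np.repeat([1, 2], 10)
    return X, labels
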