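import numpy as np
import pytest

from netstab.network import LayeredNetworkSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_layered_spec(rng, n_min=2, n_max=8, signed=True):
    """Random layered spec with a nonempty random set of feedback distances."""
    n = int(rng.integers(n_min, n_max + 1))
    n_dist = int(rng.integers(1, min(3, n) + 1))
    distances = rng.choice(n, size=n_dist, replace=False)
    lo = -1.5 if signed else 0.0
    w = {}
    for l in range(1, n):
        w[(l, l + 1)] = float(rng.uniform(lo, 1.5))
    for q in distances:
        q = int(q)
        for l in range(1, n - q + 1):
            w[(l + q, l)] = float(rng.uniform(lo, 1.5))
    return LayeredNetworkSpec(n_layers=n, weights=w)
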