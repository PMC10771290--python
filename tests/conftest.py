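import numpy as np
import pytest

from scdnet.atlas import load_default_atlas
from scdnet.connectivity import ConnectivityMatrix


@pytest.fixture(scope="session")
def atlas():
    return load_default_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_adjacency(rng, n=10, density=0.5, band="delta", roi_order=None):
    """Random valid ConnectivityMatrix for structural tests."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    mask = rng.random(iu.size) < density
    w[iu[mask], ju[mask]] = rng.uniform(0.05, 1.0, mask.sum())
    w = w + w.T
    if roi_order is None:
        roi_order = [f"r{i}" for i in range(n)]
    return ConnectivityMatrix(band=band, values=w, roi_order=roi_order)
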