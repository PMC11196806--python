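import numpy as np
import pytest

from eegperm import cluster as _cluster
from eegperm import montage as _montage


@pytest.fixture(scope="session")
def montage62():
    return _montage.default_montage()


@pytest.fixture(scope="session")
def adjacency62(montage62):
    return _cluster.build_adjacency(montage62)


@pytest.fixture(scope="session")
def montage_small(montage62):
    """First 8 electrodes of the template: a small connected sub-montage."""
    labels = montage62.labels[:8]
    return _montage.Montage(labels=labels, coords=montage62.coords[:8])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240611)
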