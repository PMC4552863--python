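import numpy as np
import pytest

from bdnevo.topology import Connectome, build_ring_of_clusters


@pytest.fixture(scope="session")
def ring18():
    """3 small-world clusters of 6 neurons in a chemical ring."""
    return build_ring_of_clusters(3, 6, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def ring60():
    """The 6x10 ring-of-small-world-clusters starting topology."""
    return build_ring_of_clusters(6, 10, rng=np.random.default_rng(1))


@pytest.fixture(scope="session")
def single_neuron():
    z = np.zeros((1, 1), dtype=np.int8)
    return Connectome(z, z.copy())


@pytest.fixture(scope="session")
def ws12():
    """12-neuron electrically coupled small-world net (no chemical layer)."""
    from bdnevo.topology import generate_small_world_cluster

    adj = generate_small_world_cluster(12, 4, 0.1, rng=np.random.default_rng(3))
    return Connectome(adj, np.zeros_like(adj))
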