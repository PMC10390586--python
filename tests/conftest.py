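import numpy as np
import pytest

import criticonn as cc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ws():
    """50-node small-world network with exponential weights."""
    return cc.generate_ws_network(50, 6, 0.3, lam=12.5, seed=7)


@pytest.fixture(scope="session")
def tiny_connectome():
    """60-node 3-module connectome with RSN-style labels."""
    return cc.generate_modular_connectome(
        60, [30, 18, 12], mean_degree_in=8.0, mean_degree_out=2.0,
        seed=11, module_names=["visual", "motor", "auditory"],
    )


@pytest.fixture(scope="session")
def lattice_4x4():
    return cc.build_lattice(cc.LatticeSpec(4, 4))


def random_network(rng, n, p=0.4, directed=False, unit=False):
    """Helper for oracle tests: random weighted network without self-loops."""
    w = (rng.random((n, n)) < p) * (1.0 if unit else rng.random((n, n)))
    np.fill_diagonal(w, 0.0)
    if not directed:
        w = np.triu(w, 1)
        w = w + w.T
    return cc.WeightedNetwork(w, directed=directed)
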