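import itertools

import numpy as np
import pytest

from netwalk import DataVector, Edge, InteractionNetwork, synthetic


def random_network(seed: int, n: int = 50, p: float = 0.08, frac_directed: float = 0.3):
    """Mixed directed/undirected Erdos-Renyi-style network for solver tests."""
    rng = np.random.default_rng(seed)
    names = [f"N{i:03d}" for i in range(n)]
    edges = []
    for a, b in itertools.combinations(range(n), 2):
        if rng.random() < p:
            directed = rng.random() < frac_directed
            if directed and rng.random() < 0.5:
                a, b = b, a
            edges.append(Edge(names[a], names[b], directed=directed))
    return InteractionNetwork(edges, extra_nodes=names)


def random_data(net: InteractionNetwork, seed: int) -> DataVector:
    rng = np.random.default_rng(seed)
    vals = np.exp(rng.normal(0, 1, size=net.n))
    return DataVector("rand", dict(zip(net.nodes, map(float, vals))))


@pytest.fixture(scope="session")
def toy():
    return synthetic.make_toy_network()


@pytest.fixture(scope="session")
def planted():
    return synthetic.make_planted_fixture()


@pytest.fixture(scope="session")
def small_planted():
    return synthetic.make_planted_fixture(n=200, module_size=10, seed=11)
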