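import networkx as nx
import numpy as np
import pytest

from netprio.network import new_network
from netprio.synthetic import generate_scale_free_network


@pytest.fixture
def triangle():
    return new_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star6():
    """Star with center S and 5 leaves."""
    return new_network([("S", f"L{i}") for i in range(1, 6)])


@pytest.fixture
def path4():
    return new_network([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture(scope="session")
def ba2000():
    """A 2000-node preferential-attachment network, frozen by seed."""
    return generate_scale_free_network(2000, 2, rng_seed=1)


def random_connected_graph(rng: np.random.Generator, n_nodes: int, extra_edge_p: float = 0.05):
    """Connected simple graph: random spanning tree plus random extra edges.

    Independent helper used by several oracle-based tests.
    """
    nodes = [f"N{i:03d}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        edges.append((nodes[i], nodes[int(rng.integers(0, i))]))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < extra_edge_p:
                edges.append((nodes[i], nodes[j]))
    g = new_network(edges)
    assert nx.is_connected(g)
    return g
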