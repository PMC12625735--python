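import networkx as nx
import numpy as np
import pytest

from tknet import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study, shared across tests (read-only)."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_graph(rng, n_max=30, p=None):
    """Random labelled graph for oracle comparisons."""
    n = int(rng.integers(5, n_max + 1))
    p = p if p is not None else float(rng.uniform(0.1, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


def random_disjoint_sets(rng, graph):
    nodes = sorted(graph.nodes)
    rng.shuffle(nodes)
    k1 = int(rng.integers(1, max(2, len(nodes) // 3)))
    k2 = int(rng.integers(1, max(2, len(nodes) // 3)))
    return set(nodes[:k1]), set(nodes[k1 : k1 + k2])
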