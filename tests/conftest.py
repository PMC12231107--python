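import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_cliques():
    """Two 6-cliques joined by a single bridge edge."""
    g = nx.Graph()
    for base in (0, 6):
        members = [f"n{base + i:02d}" for i in range(6)]
        g.add_edges_from((a, b) for i, a in enumerate(members)
                         for b in members[i + 1:])
    g.add_edge("n00", "n06")
    return g


def random_graph(n_nodes: int, edge_p: float, seed: int) -> nx.Graph:
    """Labelled Erdős–Rényi graph with string node ids."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    nodes = [f"v{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if rng.random() < edge_p:
                g.add_edge(u, v)
    return g
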