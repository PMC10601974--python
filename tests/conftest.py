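import networkx as nx
import numpy as np
import pytest


def weighted_graph(node_weights: dict, edges: list[tuple]) -> nx.Graph:
    """Build a search-ready graph with explicit edge weights."""
    g = nx.Graph()
    for node, w in node_weights.items():
        g.add_node(node, weight=w)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


@pytest.fixture
def weighted_path_graph():
    """A -- B -- C with edge weights 0.9 and 0.1."""
    return weighted_graph(
        {"A": 0.9, "B": 0.9, "C": 0.1},
        [("A", "B", 0.9), ("B", "C", 0.1)],
    )


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(42)
    return rng.integers(1, 500, size=(4, 3))
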