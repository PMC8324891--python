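import numpy as np
import pytest

from igamnet.graphio import Graph


@pytest.fixture
def p4():
    """Path a-b-c-d."""
    return Graph.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def star10():
    """Star K_{1,9} with centre 'hub'."""
    return Graph.from_edges([("hub", f"leaf{i}") for i in range(9)])


@pytest.fixture
def toy_likelihood():
    """4 nodes at heights [0,1,1,1], single root-child edge; c = 2."""
    graph = Graph.from_edges([("a", "b")], extra_nodes=["c", "d"])
    heights = {"a": 0, "b": 1, "c": 1, "d": 1}
    return graph, heights


def random_graph(n: int, p: float, rng: np.random.Generator) -> Graph:
    """Erdos-Renyi helper with string labels (deterministic given rng state)."""
    labels = [f"n{i:02d}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((labels[i], labels[j]))
    return Graph(nodes=set(labels), edges=edges)
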