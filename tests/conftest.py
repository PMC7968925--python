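import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bioidnet import FunctionalNetwork, NetworkTruth, PsmMatrix, SeedSet, simulate_network


@pytest.fixture
def toy_psm() -> PsmMatrix:
    """3 proteins x 4 samples (2 bait + 2 control), hand-written counts."""
    counts = pd.DataFrame(
        {
            "b1": [10.0, 3.0, 0.0],
            "b2": [12.0, 4.0, 1.0],
            "c1": [1.0, 3.0, 0.0],
            "c2": [2.0, 5.0, 0.0],
        },
        index=["P1", "P2", "P3"],
    )
    condition = pd.Series(["bait", "bait", "control", "control"], index=counts.columns)
    replicate = pd.Series([1, 2, 1, 2], index=counts.columns)
    return PsmMatrix(counts=counts, condition=condition, replicate=replicate)


@pytest.fixture
def path_graph() -> FunctionalNetwork:
    g = nx.Graph()
    g.add_edge("A", "B", weight=1.0)
    g.add_edge("B", "C", weight=1.0)
    return FunctionalNetwork(graph=g)


@pytest.fixture
def two_triangles() -> FunctionalNetwork:
    g = nx.Graph()
    for u, v in [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")]:
        g.add_edge(u, v, weight=1.0)
    return FunctionalNetwork(graph=g)


@pytest.fixture
def planted_network():
    """Default 4x15 planted-partition fixture with seeds and labels."""
    return simulate_network(NetworkTruth(seed=42))


def random_weighted_graph(n: int, p: float, rng: np.random.Generator) -> FunctionalNetwork:
    """Connected-ish random graph with weights in (0.4, 1]."""
    g = nx.Graph()
    g.add_nodes_from(f"N{i:03d}" for i in range(n))
    names = sorted(g.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j], weight=rng.uniform(0.41, 1.0))
    for i in range(1, n):  # spanning chain guarantees one component
        if not g.has_edge(names[i - 1], names[i]):
            g.add_edge(names[i - 1], names[i], weight=rng.uniform(0.41, 1.0))
    return FunctionalNetwork(graph=g)


@pytest.fixture
def unit_seed():
    return SeedSet(heat={"N000": 1.0})
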