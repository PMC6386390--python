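import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netsmooth.datatypes import (
    BINARY,
    CONTINUOUS,
    GeneMatrix,
    GeneSet,
    WeightedNetwork,
)
from netsmooth.synthetic_data import SimConfig, generate_bundle


def make_network(edges) -> WeightedNetwork:
    """Build a WeightedNetwork from (u, v, w) triples."""
    graph = nx.Graph()
    for u, v, w in edges:
        graph.add_edge(u, v, weight=w)
    return WeightedNetwork(graph)


def random_weighted_graph(n: int, p: float, rng: np.random.Generator) -> WeightedNetwork:
    """Random Erdos-Renyi graph with uniform weights; at least one edge."""
    while True:
        graph = nx.erdos_renyi_graph(n, p, seed=int(rng.integers(2**31)))
        if graph.number_of_edges() > 0:
            break
    for _, _, attrs in graph.edges(data=True):
        attrs["weight"] = float(rng.uniform(0.1, 1.0))
    graph = nx.relabel_nodes(graph, {i: f"N{i:03d}" for i in graph.nodes})
    return WeightedNetwork(graph)


@pytest.fixture
def path_network() -> WeightedNetwork:
    """Unit-weight path A - B - C."""
    return make_network([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def binary_matrix() -> GeneMatrix:
    data = pd.DataFrame(
        [[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]],
        index=["S1", "S2"],
        columns=["A", "B", "C"],
    )
    return GeneMatrix(data, dtype_flag=BINARY)


@pytest.fixture(scope="session")
def tiny_bundle():
    """One small synthetic study shared by the slower integration tests."""
    return generate_bundle(SimConfig(n_genes=80, n_samples=50, module_size=4, seed=7))
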