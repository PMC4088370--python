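import networkx as nx
import numpy as np
import pytest

from pinzones import synthetic_data


def random_graph(rng: np.random.Generator, max_nodes: int = 15) -> nx.Graph:
    """A small random simple graph with string node labels (may be disconnected)."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.1, 0.6))
    net = nx.Graph()
    net.add_nodes_from(f"n{i:02d}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(f"n{i:02d}", f"n{j:02d}")
    return net


@pytest.fixture
def path5() -> nx.Graph:
    return nx.path_graph(["A", "B", "C", "D", "E"])


@pytest.fixture
def star5() -> nx.Graph:
    net = nx.Graph()
    net.add_edges_from(("hub", f"leaf{i}") for i in range(5))
    return net


@pytest.fixture(scope="session")
def preset_network():
    """The shipped ~500-node core-periphery preset (seed 1) with its truth."""
    return synthetic_data.generate_core_periphery(synthetic_data.hfpin_like_params(seed=1))


@pytest.fixture(scope="session")
def preset_decomposition(preset_network):
    from pinzones import metric_space

    net, _ = preset_network
    return metric_space.decompose(net)
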