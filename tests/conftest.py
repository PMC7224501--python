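import networkx as nx
import pytest

from livestocknet.graph_build import TradeNetwork
from livestocknet.synthetic import SyntheticConfig, build_movement_table


def make_network(edges, year_label="test", nodes=()):
    """TradeNetwork from (u, v) or (u, v, count, volume) tuples."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 2:
            u, v = e
            cnt, vol = 1, 1.0
        else:
            u, v, cnt, vol = e
        if g.has_edge(u, v):
            g[u][v]["movement_count"] += cnt
            g[u][v]["animal_volume"] += vol
        else:
            g.add_edge(u, v, movement_count=cnt, animal_volume=vol)
    return TradeNetwork(g, year_label)


#: 5-node directed fixture with known metric values
PROBE_EDGES = [(1, 2), (1, 3), (2, 3), (3, 4), (4, 5), (5, 1), (2, 5)]


@pytest.fixture
def probe_network():
    return make_network(PROBE_EDGES)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down generator settings for fast unit tests."""
    return SyntheticConfig(seed=7, n_markets=60, n_hubs=6, n_survey_points=12,
                           monthly_volume=60.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return build_movement_table(small_config)
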