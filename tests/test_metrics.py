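import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import PROBE_EDGES, make_network
from livestocknet.graph_build import build_yearly_networks
from livestocknet.metrics import (
    UndefinedMetric, average_path_length, average_quantities, centralization,
    connected_components, degree_assortativity, diameter, key_market_table,
    link_density, metric_report, node_metrics, transitivity,
)


class TestAgainstReferenceToolchain:
    """Frozen values computed independently with the R igraph toolchain on
    the 5-node probe digraph."""

    def test_degree_centralizations(self, probe_network):
        assert centralization(probe_network, "degree") \
            == pytest.approx(0.04166667)
        assert centralization(probe_network, "in-degree") \
            == pytest.approx(0.1875)
        assert centralization(probe_network, "out-degree") \
            == pytest.approx(0.1875)

    def test_betweenness_centralization(self, probe_network):
        assert centralization(probe_network, "betweenness") \
            == pytest.approx(0.2291667)

    def test_closeness_centralization(self, probe_network):
        assert centralization(probe_network, "closeness") \
            == pytest.approx(0.07777778)

    def test_assortativity_conventions(self, probe_network):
        assert degree_assortativity(probe_network, "directed-out-in") \
            == pytest.approx(0.4166667)
        assert degree_assortativity(probe_network, "undirected-total") \
            == pytest.approx(-0.1666667)

    def test_transitivity(self, probe_network):
        assert transitivity(probe_network, "average-local") \
            == pytest.approx(0.4)
        assert transitivity(probe_network, "global") \
            == pytest.approx(0.4615385)

    def test_geodesics(self, probe_network):
        assert diameter(probe_network, respect_direction=True) == 4
        assert diameter(probe_network, respect_direction=False) == 2
        assert average_path_length(probe_network, True) == pytest.approx(1.95)
        assert average_path_length(probe_network, False) == pytest.approx(1.3)


class TestSmallExamples:
    def test_directed_three_cycle_diameters(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "A")])
        assert diameter(net, True) == 2
        assert diameter(net, False) == 1

    def test_single_link_diameter(self):
        net = make_network([("A", "B")])
        assert diameter(net, True) == 1

    def test_directed_path_average_length(self):
        net = make_network([("A", "B"), ("B", "C")])
        assert average_path_length(net, True) == pytest.approx(4 / 3)

    def test_complete_graph_density_and_path_length(self):
        nodes = list("ABCD")
        net = make_network([(u, v) for u in nodes for v in nodes if u != v])
        assert link_density(net) == 1.0
        assert average_path_length(net, True) == 1.0

    def test_star_density(self):
        net = make_network([("H", f"S{i}") for i in range(9)])
        assert link_density(net) == pytest.approx(0.1)
        assert link_density(net, doubled=True) == pytest.approx(0.05)

    def test_average_quantities(self):
        net = make_network([("A", "B")])
        assert average_quantities(net) == (0.5, 0.5)

    def test_triangle_and_star_transitivity(self):
        tri = make_network([("A", "B"), ("B", "C"), ("C", "A")])
        assert transitivity(tri, "average-local") == 1.0
        assert transitivity(tri, "global") == 1.0
        star = make_network([("H", f"S{i}") for i in range(4)])
        assert transitivity(star, "average-local") == 0.0
        assert transitivity(star, "global") == 0.0

    def test_triangle_plus_pendant_transitivity(self):
        # local coefficients: attachment node 1/3, other two 1, pendant n/a
        net = make_network([("A", "B"), ("B", "C"), ("C", "A"), ("A", "P")])
        assert transitivity(net, "global") == pytest.approx(0.6)
        assert transitivity(net, "average-local") == pytest.approx(7 / 9)
        assert transitivity(net, "average-local", include_low_degree=True) \
            == pytest.approx(7 / 12)

    def test_reciprocal_star_degree_centralization_is_one(self):
        edges = [("H", f"S{i}") for i in range(6)]
        edges += [(v, u) for u, v in edges]
        net = make_network(edges)
        assert centralization(net, "degree") == pytest.approx(1.0)

    def test_cycle_degree_centralization_is_zero(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        assert centralization(net, "degree") == 0.0

    def test_undirected_star_is_perfectly_disassortative(self):
        net = make_network([("H", f"S{i}") for i in range(5)])
        assert degree_assortativity(net, "undirected-total") \
            == pytest.approx(-1.0)

    def test_disjoint_equal_links_assortativity_undefined(self):
        net = make_network([("A", "B"), ("C", "D")])
        with pytest.raises(UndefinedMetric):
            degree_assortativity(net, "directed-out-in")

    def test_directed_four_cycle_components(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        assert connected_components(net, "strong") == [4]

    def test_closeness_on_disconnected_graph_undefined(self):
        net = make_network([("A", "B"), ("C", "D"), ("E", "A")])
        with pytest.raises(UndefinedMetric):
            centralization(net, "closeness")

    def test_edgeless_network_metrics_undefined(self):
        net = make_network([], nodes=["A", "B", "C"])
        for fn in (lambda: diameter(net), lambda: average_path_length(net),
                   lambda: transitivity(net)):
            with pytest.raises(UndefinedMetric):
                fn()


def random_digraph(rng, n, p):
    nodes = list(range(n))
    edges = [(u, v) for u in nodes for v in nodes
             if u != v and rng.random() < p]
    return nodes, edges


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 12),
       p=st.floats(0.1, 0.7))
def test_metrics_match_brute_force_oracle(seed, n, p):
    """All geodesic, clustering, correlation and component metrics agree
    with from-first-principles enumeration on random digraphs (n <= 12)."""
    rng = np.random.default_rng(seed)
    nodes, edges = random_digraph(rng, n, p)
    net = make_network(edges, nodes=nodes)
    if edges:
        for directed in (True, False):
            assert diameter(net, directed) \
                == oracles.diameter(nodes, edges, directed)
            assert average_path_length(net, directed) \
                == pytest.approx(oracles.avg_path_length(nodes, edges, directed))
    assert connected_components(net, "strong") \
        == oracles.strong_components(nodes, edges)
    assert connected_components(net, "weak") \
        == oracles.weak_components(nodes, edges)
    if n >= 2 and edges:
        assert link_density(net) == len(set(edges)) / (n * (n - 1))
    oracle_t = oracles.transitivity_avg_local(nodes, edges)
    if oracle_t is not None:
        assert transitivity(net, "average-local") == pytest.approx(oracle_t)
        assert transitivity(net, "global") \
            == pytest.approx(oracles.transitivity_global(nodes, edges))
    oracle_a = oracles.assortativity_out_in(nodes, edges)
    if oracle_a is not None and len(edges) >= 2:
        assert degree_assortativity(net, "directed-out-in") \
            == pytest.approx(oracle_a)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_metrics_invariant_under_relabeling(seed):
    rng = np.random.default_rng(seed)
    nodes, edges = random_digraph(rng, 9, 0.3)
    if len(edges) < 2:
        return
    mapping = {v: f"node-{v * 7 % 9}-{v}" for v in nodes}
    relabeled = [(mapping[u], mapping[v]) for u, v in edges]
    a = make_network(edges, nodes=nodes)
    b = make_network(relabeled, nodes=[mapping[v] for v in nodes])
    ra, rb = metric_report(a).as_dict(), metric_report(b).as_dict()
    ra.pop("year_label")
    rb.pop("year_label")
    for key in ra:
        assert ra[key] == pytest.approx(rb[key], nan_ok=True), key


class TestBounds:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_metric_ranges(self, seed):
        rng = np.random.default_rng(seed)
        nodes, edges = random_digraph(rng, 10, 0.3)
        net = make_network(edges, nodes=nodes)
        rep = metric_report(net)
        for name in ("link_density", "transitivity_avg_local",
                     "transitivity_global", "centralization_degree",
                     "centralization_in_degree", "centralization_out_degree",
                     "centralization_betweenness", "centralization_closeness"):
            val = rep.as_dict()[name]
            assert math.isnan(val) or 0.0 <= val <= 1.0 + 1e-12, name
        a = rep.degree_assortativity
        assert math.isnan(a) or -1.0 - 1e-12 <= a <= 1.0 + 1e-12

    def test_undirected_diameter_bound_when_strongly_connected(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "A"), ("A", "C")])
        assert diameter(net, False) <= diameter(net, True)


class TestNodeMetrics:
    def test_volume_sums_in_and_out(self):
        net = make_network([("A", "B", 1, 10.0), ("B", "C", 1, 5.0)])
        nm = node_metrics(net)
        assert nm.loc["B", "volume"] == 15.0

    def test_hub_link_and_shipment_degrees(self):
        net = make_network([(f"P{i}", "H", 2, 2.0) for i in range(3)])
        nm = node_metrics(net)
        assert nm.loc["H", "links_in"] == 3
        assert nm.loc["H", "shipments_in"] == 6

    def test_reciprocal_partner_counted_once_in_links_all(self):
        net = make_network([("A", "B"), ("B", "A")])
        nm = node_metrics(net)
        assert nm.loc["A", "links_all"] == 1
        assert nm.loc["A", "links_in"] + nm.loc["A", "links_out"] == 2


class TestKeyMarkets:
    def test_two_node_network_leader(self):
        nets = {2013: make_network([("A", "B", 2, 7.0)])}
        t = key_market_table(nets)
        vol = t[(t.metric == "volume")].iloc[0]
        assert vol.market in ("A", "B")
        assert vol.value == 7.0

    def test_lexicographic_tie_break(self):
        nets = {2015: make_network([("B", "Z", 1, 1.0), ("A", "Y", 1, 1.0)])}
        t = key_market_table(nets)
        out = t[t.metric == "links_out"].iloc[0]
        assert out.market == "A"  # tie between A and B -> lexicographic


def test_metric_report_on_yearly_network(small_dataset):
    table, markets = small_dataset
    yearly = build_yearly_networks(table)
    rep = metric_report(yearly[2014], markets)
    assert rep.n == yearly[2014].n
    assert rep.avg_link_degree == pytest.approx(rep.l / rep.n)
    assert rep.avg_shipments == pytest.approx(rep.m / rep.n)
    assert rep.gscc_size <= rep.gwcc_size <= rep.n
    assert rep.survey_markets <= markets["is_survey_point"].sum()
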