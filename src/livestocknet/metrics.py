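"""Network- and node-level statistics for market trade networks.

All topological metrics are computed on the unweighted topology; volumes and
shipment counts enter only the node-level rankings. Conventions follow the
common graph-library defaults of the field's toolchain:

* geodesics ignore unreachable pairs (the yearly networks are not strongly
  connected, yet diameter and mean path length are reported finite);
* directed degree assortativity is the Pearson correlation, over directed
  links, of source out-degree with target in-degree;
* Freeman centralization divides by the theoretical maximum attained by a
  star of the same size: ``2(n-1)(n-2)`` for directed total degree,
  ``(n-1)^2`` for in-/out-degree, ``(n-1)^2(n-2)`` for directed betweenness
  and ``(n-1)(n-2)/(2n-3)`` for normalized undirected closeness.

A metric that is mathematically undefined on the given network (edgeless
diameter, assortativity with zero degree variance, closeness on a
disconnected graph) raises :class:`UndefinedMetric`; the report assembly
records it as missing rather than guessing a value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from livestocknet.graph_build import TradeNetwork

logger = logging.getLogger(__name__)


class UndefinedMetric(ValueError):
    """The requested metric is not defined on this network."""


def _distance_matrix(network: TradeNetwork, directed: bool) -> np.ndarray:
    g = network.graph
    if g.number_of_nodes() == 0:
        raise UndefinedMetric("empty network")
    adj = nx.to_scipy_sparse_array(g, weight=None, format="csr")
    return shortest_path(adj, method="D", directed=directed, unweighted=True)


def _finite_offdiag(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    mask = np.isfinite(dist) & ~np.eye(n, dtype=bool)
    return dist[mask]


def diameter(network: TradeNetwork, respect_direction: bool = True) -> int:
    """Longest finite geodesic (in links); unreachable pairs are ignored."""
    if network.l < 1:
        raise UndefinedMetric("diameter undefined on an edgeless network")
    vals = _finite_offdiag(_distance_matrix(network, respect_direction))
    if vals.size == 0:
        raise UndefinedMetric("no reachable pair")
    return int(vals.max())


def link_density(network: TradeNetwork, doubled: bool = False) -> float:
    """Ratio of directed links to possible ordered pairs, l / (n(n-1)).

    ``doubled=True`` uses the divisor 2n(n-1) instead (an alternative
    normalisation that treats reciprocal links as distinct of a doubled
    maximum); the default matches the usual directed-density definition.
    """
    n = network.n
    if n < 2:
        raise UndefinedMetric("density undefined for n < 2")
    denom = n * (n - 1) * (2 if doubled else 1)
    return network.l / denom


def average_quantities(network: TradeNetwork) -> tuple[float, float]:
    """(average link degree l/n, average shipments m/n), unrounded."""
    if network.n < 1:
        raise UndefinedMetric("averages undefined on an empty network")
    return network.l / network.n, network.m / network.n


def transitivity(network: TradeNetwork, variant: str = "average-local",
                 include_low_degree: bool = False) -> float:
    """Clustering coefficient of the undirected simplification.

    ``average-local`` averages local clustering coefficients over nodes of
    degree >= 2 (nodes of lower degree are included as zeros when
    ``include_low_degree``); ``global`` is 3 x triangles / connected triples.
    """
    und = network.undirected()
    if variant == "global":
        trans = nx.transitivity(und)
        if und.number_of_edges() == 0 or max(
                (d for _, d in und.degree()), default=0) < 2:
            raise UndefinedMetric("no connected triple")
        return trans
    if variant != "average-local":
        raise ValueError(f"unknown variant {variant!r}")
    clustering = nx.clustering(und)
    eligible = [v for v, d in und.degree() if d >= 2]
    if not eligible:
        raise UndefinedMetric("no node with degree >= 2")
    if include_low_degree:
        return float(np.mean(list(clustering.values())))
    return float(np.mean([clustering[v] for v in eligible]))


def average_path_length(network: TradeNetwork,
                        respect_direction: bool = True) -> float:
    """Mean geodesic over ordered reachable pairs (unreachable excluded)."""
    if network.l < 1:
        raise UndefinedMetric("path length undefined on an edgeless network")
    vals = _finite_offdiag(_distance_matrix(network, respect_direction))
    if vals.size == 0:
        raise UndefinedMetric("no reachable pair")
    return float(vals.mean())


def degree_assortativity(network: TradeNetwork,
                         convention: str = "directed-out-in") -> float:
    """Pearson correlation between the degrees at the two ends of links.

    ``directed-out-in`` correlates source out-degree with target in-degree
    over directed links; ``undirected-total`` correlates total degrees over
    both orientations of each undirected link.
    """
    g = network.graph
    if network.l < 2:
        raise UndefinedMetric("assortativity needs at least two links")
    if convention == "directed-out-in":
        x = np.array([g.out_degree(u) for u, _ in g.edges()], dtype=float)
        y = np.array([g.in_degree(v) for _, v in g.edges()], dtype=float)
    elif convention == "undirected-total":
        und = network.undirected()
        deg = dict(und.degree())
        pairs = [(deg[u], deg[v]) for u, v in und.edges()]
        pairs += [(b, a) for a, b in pairs]
        x, y = map(np.asarray, zip(*pairs))
        x = x.astype(float)
        y = y.astype(float)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetric("zero degree variance on one endpoint vector")
    return float(np.corrcoef(x, y)[0, 1])


def _to_igraph(g: nx.DiGraph) -> tuple[ig.Graph, list]:
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    return ig.Graph(n=len(nodes), edges=edges, directed=True), nodes


_CENTRALIZATION_MEASURES = ("degree", "in-degree", "out-degree",
                            "betweenness", "closeness")


def centralization(network: TradeNetwork, measure: str) -> float:
    """Freeman centralization: sum of (C_max - C_i) over the star maximum."""
    if measure not in _CENTRALIZATION_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; "
                         f"choose from {_CENTRALIZATION_MEASURES}")
    g = network.graph
    n = network.n
    if n < 3:
        raise UndefinedMetric("centralization needs n >= 3")

    if measure in ("degree", "in-degree", "out-degree"):
        if measure == "degree":
            c = np.array([g.degree(v) for v in g.nodes], dtype=float)
            tmax = 2 * (n - 1) * (n - 2)
        elif measure == "in-degree":
            c = np.array([g.in_degree(v) for v in g.nodes], dtype=float)
            tmax = (n - 1) ** 2
        else:
            c = np.array([g.out_degree(v) for v in g.nodes], dtype=float)
            tmax = (n - 1) ** 2
    elif measure == "betweenness":
        graph, _ = _to_igraph(g)
        c = np.asarray(graph.betweenness(directed=True), dtype=float)
        tmax = (n - 1) ** 2 * (n - 2)
    else:  # closeness, on the undirected simplification
        und = network.undirected()
        if not nx.is_connected(und):
            raise UndefinedMetric("closeness centralization is not "
                                  "well-defined for disconnected graphs")
        c = np.array([nx.closeness_centrality(und, v) for v in und.nodes],
                     dtype=float)
        tmax = (n - 1) * (n - 2) / (2 * n - 3)
    return float((c.max() - c).sum() / tmax)


def connected_components(network: TradeNetwork, mode: str = "strong") -> list[int]:
    """Component sizes, largest first; strong respects link direction."""
    if mode == "strong":
        comps = nx.strongly_connected_components(network.graph)
    elif mode == "weak":
        comps = nx.weakly_connected_components(network.graph)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sizes = sorted((len(c) for c in comps), reverse=True)
    return sizes


def node_metrics(network: TradeNetwork) -> pd.DataFrame:
    """Per-market volume and degree table.

    ``volume`` sums incident animal volume (in + out); ``links_*`` count
    distinct trading partners (``links_all`` counts a reciprocal partner
    once); ``shipments_*`` count movements.
    """
    g = network.graph
    und = network.undirected()
    rows = []
    for v in g.nodes:
        rows.append({
            "market": v,
            "volume": g.in_degree(v, weight="animal_volume")
                      + g.out_degree(v, weight="animal_volume"),
            "links_all": und.degree(v),
            "links_in": g.in_degree(v),
            "links_out": g.out_degree(v),
            "shipments_all": g.degree(v, weight="movement_count"),
            "shipments_in": g.in_degree(v, weight="movement_count"),
            "shipments_out": g.out_degree(v, weight="movement_count"),
        })
    return pd.DataFrame(rows).set_index("market") if rows else pd.DataFrame(
        columns=["volume", "links_all", "links_in", "links_out",
                 "shipments_all", "shipments_in", "shipments_out"])


KEY_METRICS = ("volume", "links_all", "links_in", "links_out",
               "shipments_all", "shipments_in", "shipments_out")


def key_market_table(networks: Mapping[int, TradeNetwork],
                     annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Top market per year and metric, with border/urban tags.

    Ties are broken lexicographically by market code so runs are
    deterministic. ``annotations`` is a node list indexed by market code
    with ``border_within_50km`` and ``is_urban`` columns; an unannotated
    leader is reported untagged with a warning.
    """
    rows = []
    for year, net in networks.items():
        nm = node_metrics(net)
        if nm.empty:
            continue
        for metric in KEY_METRICS:
            # lexicographic pre-sort + stable sort = deterministic tie-break
            ordered = nm.loc[sorted(nm.index)].sort_values(
                metric, ascending=False, kind="stable")
            leader = ordered.index[0]
            row = {"year": year, "metric": metric, "market": leader,
                   "value": ordered.iloc[0][metric],
                   "border_within_50km": None, "is_urban": None}
            if annotations is not None and leader in annotations.index:
                row["border_within_50km"] = bool(
                    annotations.loc[leader, "border_within_50km"])
                row["is_urban"] = bool(annotations.loc[leader, "is_urban"])
            elif annotations is not None:
                logger.warning("no annotation for key market %r", leader)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MetricReport:
    """The network-level statistics vector for one network (one year)."""

    year_label: str
    survey_markets: float = np.nan
    n: int = 0
    m: int = 0
    l: int = 0
    diameter_directed: float = np.nan
    diameter_undirected: float = np.nan
    link_density: float = np.nan
    avg_link_degree: float = np.nan
    avg_shipments: float = np.nan
    transitivity_avg_local: float = np.nan
    transitivity_global: float = np.nan
    avg_path_length: float = np.nan
    degree_assortativity: float = np.nan
    centralization_degree: float = np.nan
    centralization_in_degree: float = np.nan
    centralization_out_degree: float = np.nan
    centralization_betweenness: float = np.nan
    centralization_closeness: float = np.nan
    gscc_size: float = np.nan
    gwcc_size: float = np.nan
    propinquity_p: float = np.nan

    def as_dict(self) -> dict:
        return asdict(self)


def metric_report(network: TradeNetwork,
                  markets: pd.DataFrame | None = None,
                  density_doubled: bool = False,
                  assortativity_convention: str = "directed-out-in"
                  ) -> MetricReport:
    """Assemble the full statistics vector, recording undefined metrics as
    missing. The propinquity p-value is attached separately by the spatial
    module (it needs coordinates)."""
    rep = MetricReport(year_label=network.year_label,
                       n=network.n, m=network.m, l=network.l)
    if markets is not None and "is_survey_point" in markets.columns:
        rep.survey_markets = int(markets.loc[
            markets.index.intersection(list(network.graph.nodes)),
            "is_survey_point"].sum())

    def attempt(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except UndefinedMetric:
            return np.nan

    rep.diameter_directed = attempt(diameter, network, True)
    rep.diameter_undirected = attempt(diameter, network, False)
    rep.link_density = attempt(link_density, network, density_doubled)
    try:
        rep.avg_link_degree, rep.avg_shipments = average_quantities(network)
    except UndefinedMetric:
        pass
    rep.transitivity_avg_local = attempt(transitivity, network, "average-local")
    rep.transitivity_global = attempt(transitivity, network, "global")
    rep.avg_path_length = attempt(average_path_length, network, True)
    rep.degree_assortativity = attempt(degree_assortativity, network,
                                       assortativity_convention)
    rep.centralization_degree = attempt(centralization, network, "degree")
    rep.centralization_in_degree = attempt(centralization, network, "in-degree")
    rep.centralization_out_degree = attempt(centralization, network, "out-degree")
    rep.centralization_betweenness = attempt(centralization, network, "betweenness")
    rep.centralization_closeness = attempt(centralization, network, "closeness")
    if network.n:
        rep.gscc_size = connected_components(network, "strong")[0]
        rep.gwcc_size = connected_components(network, "weak")[0]
    return rep


def report_frame(reports: Mapping[int | str, MetricReport]) -> pd.DataFrame:
    """Metrics as rows, years as columns (the usual summary-table layout)."""
    cols = {}
    for label, rep in reports.items():
        d = rep.as_dict()
        d.pop("year_label")
        cols[label] = d
    return pd.DataFrame(cols)
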