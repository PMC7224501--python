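"""Aggregate movement records into directed weighted market networks.

Movements are aggregated per calendar year (and over the whole study period)
into directed simple graphs: nodes are markets that appear as endpoints,
links are ordered market pairs carrying the number of movements
(``movement_count``) and the scaled animal volume (``animal_volume``).
The symbols follow field convention: n markets, m shipments, l directed
links (pairs of trading markets).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from livestocknet.data_io import MovementTable

STUDY_YEARS = (2013, 2014, 2015, 2016, 2017)


@dataclass
class TradeNetwork:
    """A directed simple market graph for one year (or the whole period)."""

    graph: nx.DiGraph
    year_label: str

    @property
    def n(self) -> int:
        """Number of markets (nodes)."""
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        """Number of shipments (sum of per-link movement counts)."""
        return int(sum(d["movement_count"] for _, _, d in self.graph.edges(data=True)))

    @property
    def l(self) -> int:
        """Number of directed links (ordered pairs of trading markets)."""
        return self.graph.number_of_edges()

    def undirected(self) -> nx.Graph:
        """Collapse to an undirected simple graph, summing link weights of
        reciprocal pairs."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, d in self.graph.edges(data=True):
            if g.has_edge(u, v):
                g[u][v]["movement_count"] += d["movement_count"]
                g[u][v]["animal_volume"] += d["animal_volume"]
            else:
                g.add_edge(u, v, movement_count=d["movement_count"],
                           animal_volume=d["animal_volume"])
        return g


@dataclass
class DegreeSequence:
    """Per-market degree values under one counting mode and direction."""

    values: np.ndarray
    mode: str        # "movements" (shipment counts) or "neighbors" (links)
    direction: str   # "all", "in" or "out"


def build_network(table: MovementTable, year_label: str = "overall") -> TradeNetwork:
    """Aggregate all records of ``table`` into one directed simple graph,
    merging parallel movements per ordered pair."""
    df = table.records
    g = nx.DiGraph()
    if not df.empty:
        agg = (df.groupby(["from_market", "to_market"], observed=True)
                 .agg(movement_count=("heads", "size"),
                      animal_volume=("heads", "sum"))
                 .reset_index())
        for row in agg.itertuples(index=False):
            g.add_edge(row.from_market, row.to_market,
                       movement_count=int(row.movement_count),
                       animal_volume=float(row.animal_volume))
    return TradeNetwork(g, year_label)


def build_yearly_networks(table: MovementTable,
                          years: tuple[int, ...] = STUDY_YEARS
                          ) -> dict[int, TradeNetwork]:
    """One directed network per study year.

    A record outside ``years`` raises, naming the offending record.
    """
    df = table.records
    record_years = df["month"].map(lambda p: p.year) if not df.empty \
        else pd.Series(dtype=int)
    outside = ~record_years.isin(years) if not df.empty else pd.Series(dtype=bool)
    if not df.empty and outside.any():
        bad = df[outside].iloc[0]
        raise ValueError(
            f"record outside study years {years}: "
            f"{bad['from_market']} -> {bad['to_market']} in {bad['month']}")
    out = {}
    for year in years:
        sub = MovementTable(df[record_years == year] if not df.empty else df)
        out[year] = build_network(sub, year_label=str(year))
    return out


def build_overall_network(table: MovementTable) -> TradeNetwork:
    """Single network over the whole period (parallel yearly links merged)."""
    return build_network(table, year_label="overall")


def degree_sequences(network: TradeNetwork, mode: str = "neighbors",
                     direction: str = "all") -> DegreeSequence:
    """Degree sequence of a network.

    mode="movements" counts shipments (per-link movement_count summed over
    incident links); mode="neighbors" counts distinct trading partners. For
    direction="all", neighbors are the undirected union of in/out partners
    (a reciprocal partner counts once), while movements sum in + out.
    """
    if mode not in ("movements", "neighbors"):
        raise ValueError(f"unknown mode {mode!r}")
    if direction not in ("all", "in", "out"):
        raise ValueError(f"unknown direction {direction!r}")
    g = network.graph
    nodes = list(g.nodes)
    if mode == "movements":
        if direction == "in":
            vals = [g.in_degree(v, weight="movement_count") for v in nodes]
        elif direction == "out":
            vals = [g.out_degree(v, weight="movement_count") for v in nodes]
        else:
            vals = [g.degree(v, weight="movement_count") for v in nodes]
    else:
        if direction == "in":
            vals = [g.in_degree(v) for v in nodes]
        elif direction == "out":
            vals = [g.out_degree(v) for v in nodes]
        else:
            und = network.undirected()
            vals = [und.degree(v) for v in nodes]
    return DegreeSequence(np.asarray(vals, dtype=int), mode, direction)


def to_edge_csv(network: TradeNetwork, path: str | Path) -> None:
    rows = [(u, v, d["movement_count"], d["animal_volume"])
            for u, v, d in network.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["from", "to", "movement_count",
                                "animal_volume"]).to_csv(path, index=False)


def from_edge_csv(path: str | Path, year_label: str = "overall") -> TradeNetwork:
    df = pd.read_csv(path, dtype={"from": str, "to": str})
    g = nx.DiGraph()
    for u, v, cnt, vol in df[["from", "to", "movement_count",
                              "animal_volume"]].itertuples(index=False, name=None):
        g.add_edge(u, v, movement_count=int(cnt), animal_volume=float(vol))
    return TradeNetwork(g, year_label)


def to_graphml(network: TradeNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, path)


def from_graphml(path: str | Path, year_label: str = "overall") -> TradeNetwork:
    return TradeNetwork(nx.DiGraph(nx.read_graphml(path)), year_label)
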