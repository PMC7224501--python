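"""Configuration-model null ensembles and observed-vs-null z-scores.

The null model preserves every market's in- and out-degree while randomising
who trades with whom, realised by repeated double-edge swaps on the directed
simple graph (swaps that would create a self-loop or a parallel link are
rejected and re-drawn). Metrics that are fixed by construction (n, m, l,
density, degree centralizations) are excluded; for the rest, the observed
value is normalised as z = (observed - ensemble mean) / ensemble sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from livestocknet.graph_build import TradeNetwork
from livestocknet.metrics import (
    UndefinedMetric, diameter, transitivity, average_path_length,
    degree_assortativity, centralization,
)
from livestocknet.spatial import propinquity_test

logger = logging.getLogger(__name__)

#: metrics recomputed per replicate (the ones not fixed by degree preservation)
ENSEMBLE_METRICS = (
    "diameter_directed",
    "diameter_undirected",
    "transitivity_avg_local",
    "avg_path_length",
    "degree_assortativity",
    "centralization_betweenness",
)

#: attempted double-edge swaps per link (the rewiring budget per replicate)
DEFAULT_SWAPS_PER_LINK = 10


def _metric_vector(network: TradeNetwork) -> dict[str, float]:
    fns = {
        "diameter_directed": lambda n: diameter(n, True),
        "diameter_undirected": lambda n: diameter(n, False),
        "transitivity_avg_local": lambda n: transitivity(n, "average-local"),
        "avg_path_length": lambda n: average_path_length(n, True),
        "degree_assortativity": degree_assortativity,
        "centralization_betweenness": lambda n: centralization(n, "betweenness"),
    }
    out = {}
    for name in ENSEMBLE_METRICS:
        try:
            out[name] = float(fns[name](network))
        except UndefinedMetric:
            out[name] = np.nan
    return out


def rewire_configuration(network: TradeNetwork, n_swaps: int | None = None,
                         seed: int | np.random.Generator = 0) -> TradeNetwork:
    """Degree-preserving randomisation by rejected double-edge swaps.

    A swap picks two directed links (u1,v1), (u2,v2) and proposes
    (u1,v2), (u2,v1); proposals creating self-loops or parallel links are
    discarded. In- and out-degree sequences are preserved exactly. The
    default budget is ``10 * l`` attempted swaps.
    """
    if network.l < 2:
        raise ValueError("rewiring needs at least two links")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if n_swaps is None:
        n_swaps = DEFAULT_SWAPS_PER_LINK * network.l

    edges = list(network.graph.edges())
    edge_set = set(edges)
    l = len(edges)
    accepted = 0
    picks = rng.integers(0, l, size=(n_swaps, 2))
    for a, b in picks:
        if a == b:
            continue
        u1, v1 = edges[a]
        u2, v2 = edges[b]
        if u1 == v2 or u2 == v1:
            continue  # would create a self-loop
        e1, e2 = (u1, v2), (u2, v1)
        if e1 in edge_set or e2 in edge_set:
            continue  # would create a parallel link
        edge_set.discard((u1, v1))
        edge_set.discard((u2, v2))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[a] = e1
        edges[b] = e2
        accepted += 1
    if accepted == 0 and n_swaps > 0:
        logger.warning("no swap accepted in %d attempts; degree sequence may "
                       "admit a unique simple realisation", n_swaps)

    g = nx.DiGraph()
    g.add_nodes_from(network.graph.nodes)
    # unit weights: the null model randomises topology, not volumes
    g.add_edges_from((u, v, {"movement_count": 1, "animal_volume": 1.0})
                     for u, v in edges)
    return TradeNetwork(g, f"{network.year_label}-rewired")


def _replicate_rng(seed: int, i: int) -> np.random.Generator:
    # independent, order-insensitive substream per replicate
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))


def generate_ensemble(network: TradeNetwork, size: int = 1000,
                      seed: int = 0,
                      swaps_per_link: int = DEFAULT_SWAPS_PER_LINK
                      ) -> pd.DataFrame:
    """Metric vectors for ``size`` independent rewired replicates."""
    if size < 1:
        raise ValueError("ensemble size must be >= 1")
    rows = []
    n_swaps = swaps_per_link * network.l
    for i in range(size):
        rep = rewire_configuration(network, n_swaps, _replicate_rng(seed, i))
        rows.append(_metric_vector(rep))
    return pd.DataFrame(rows, columns=list(ENSEMBLE_METRICS))


@dataclass
class EnsembleReport:
    """Observed-vs-null comparison for one network."""

    ensemble_size: int
    seed: int
    metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: columns: observed, ensemble_mean, ensemble_sd, z (NaN where sd == 0)
    min_ensemble_propinquity_p: float = np.nan


def z_scores(observed: dict[str, float] | "pd.Series",
             ensemble: pd.DataFrame, seed: int = 0) -> EnsembleReport:
    """z = (observed - ensemble mean) / ensemble sd (sample sd, ddof=1).

    Metrics with zero ensemble sd are flagged with z = NaN.
    """
    if len(ensemble) < 2:
        raise ValueError("need an ensemble of size >= 2 for z-scores")
    obs = pd.Series(observed)
    rows = {}
    for name in ensemble.columns:
        if name not in obs.index:
            continue
        vals = ensemble[name].to_numpy(dtype=float)
        mean = float(np.nanmean(vals))
        sd = float(np.nanstd(vals, ddof=1))
        z = (obs[name] - mean) / sd if sd > 0 else np.nan
        if sd == 0:
            logger.warning("zero ensemble sd for %s; z undefined", name)
        rows[name] = {"observed": obs[name], "ensemble_mean": mean,
                      "ensemble_sd": sd, "z": z}
    report = EnsembleReport(ensemble_size=len(ensemble), seed=seed,
                            metrics=pd.DataFrame(rows).T)
    return report


def ensemble_propinquity(network: TradeNetwork, coords: pd.DataFrame,
                         size: int = 1000, seed: int = 0,
                         swaps_per_link: int = DEFAULT_SWAPS_PER_LINK) -> float:
    """Minimum propinquity p-value over rewired replicates (same coordinates).

    A minimum near 1 means no replicate shows the observed spatial signal.
    """
    if size < 1:
        raise ValueError("ensemble size must be >= 1")
    n_swaps = swaps_per_link * network.l
    min_p = np.inf
    for i in range(size):
        rep = rewire_configuration(network, n_swaps, _replicate_rng(seed, i))
        min_p = min(min_p, propinquity_test(rep, coords).p_value)
    return float(min_p)
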