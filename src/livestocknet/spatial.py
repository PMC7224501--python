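"""Spatial propinquity: are trading markets closer than non-trading ones?

Great-circle (Haversine) distances between all unordered market pairs are
split into linked pairs (at least one directed link in either direction) and
unlinked pairs, and compared with a one-sided Mann-Whitney test under the
alternative that unlinked distances are stochastically larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from livestocknet.graph_build import TradeNetwork

#: IUGG mean Earth radius, km
EARTH_RADIUS_KM = 6371.0088

#: both groups at or below this size (and tie-free) use exact enumeration
EXACT_THRESHOLD = 10


@dataclass
class PropinquityResult:
    u_statistic: float
    p_value: float
    n_linked_pairs: int
    n_unlinked_pairs: int
    median_linked_km: float
    median_unlinked_km: float


def haversine_km(a, b, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance between (lat, lon) points in degrees.

    Accepts scalars or aligned arrays; symmetric, zero iff identical points.
    """
    lat1, lon1 = np.radians(np.asarray(a, dtype=float).T)
    lat2, lon2 = np.radians(np.asarray(b, dtype=float).T)
    if np.any(np.abs(np.degrees(lat1)) > 90) or np.any(np.abs(np.degrees(lat2)) > 90):
        raise ValueError("latitude out of [-90, 90]")
    if np.any(np.abs(np.degrees(lon1)) > 180) or np.any(np.abs(np.degrees(lon2)) > 180):
        raise ValueError("longitude out of [-180, 180]")
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def mann_whitney_one_sided(group_x, group_y) -> tuple[float, float]:
    """One-sided Mann-Whitney test of H1: ``group_y`` shifted above ``group_x``.

    Uses exact enumeration when both groups have at most
    :data:`EXACT_THRESHOLD` observations and no cross-group ties; otherwise
    the normal approximation with continuity and tie correction. Returns
    (U of y over x, one-sided p).
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = ("exact" if (x.size <= EXACT_THRESHOLD
                          and y.size <= EXACT_THRESHOLD and not has_ties)
              else "asymptotic")
    res = stats.mannwhitneyu(y, x, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def propinquity_test(network: TradeNetwork, coords: pd.DataFrame,
                     radius_km: float = EARTH_RADIUS_KM) -> PropinquityResult:
    """Propinquity statistic for one network.

    ``coords`` is a node table indexed by market code with ``latitude`` and
    ``longitude`` columns. All n(n-1)/2 unordered node pairs are partitioned
    into linked (trading in either direction) and unlinked; a node without
    coordinates raises, naming it. A network with no unlinked pair (complete
    graph) is degenerate and raises.
    """
    nodes = list(network.graph.nodes)
    missing = [v for v in nodes if v not in coords.index]
    if missing:
        raise ValueError(f"no coordinates for market(s): {missing[:5]}")
    lat = coords.loc[nodes, "latitude"].to_numpy(dtype=float)
    lon = coords.loc[nodes, "longitude"].to_numpy(dtype=float)
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    dists = haversine_km(np.column_stack([lat[iu], lon[iu]]),
                         np.column_stack([lat[ju], lon[ju]]),
                         radius_km=radius_km)

    index = {v: i for i, v in enumerate(nodes)}
    linked = np.zeros((n, n), dtype=bool)
    for u, v in network.graph.edges():
        linked[index[u], index[v]] = True
    linked |= linked.T
    linked_mask = linked[iu, ju]

    linked_d = dists[linked_mask]
    unlinked_d = dists[~linked_mask]
    if linked_d.size == 0 or unlinked_d.size == 0:
        raise ValueError("propinquity needs both linked and unlinked pairs")
    u_stat, p = mann_whitney_one_sided(linked_d, unlinked_d)
    return PropinquityResult(
        u_statistic=u_stat, p_value=p,
        n_linked_pairs=int(linked_d.size), n_unlinked_pairs=int(unlinked_d.size),
        median_linked_km=float(np.median(linked_d)),
        median_unlinked_km=float(np.median(unlinked_d)))
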