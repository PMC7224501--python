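"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (plain BFS, enumeration,
direct formulas) and deliberately avoids the graph/stats libraries the
package itself uses for the corresponding computation.
"""

from __future__ import annotations

import itertools
import math


def bfs_distances(adj: dict, source):
    """adj: node -> iterable of successors. Unit-weight BFS distances."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _adj_from_edges(nodes, edges, directed):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        if not directed:
            adj[v].add(u)
    return adj


def all_pairs_finite(nodes, edges, directed):
    """List of finite geodesic lengths over ordered pairs i != j."""
    adj = _adj_from_edges(nodes, edges, directed)
    out = []
    for s in nodes:
        dist = bfs_distances(adj, s)
        out.extend(d for v, d in dist.items() if v != s)
    return out


def diameter(nodes, edges, directed):
    vals = all_pairs_finite(nodes, edges, directed)
    return max(vals) if vals else None


def avg_path_length(nodes, edges, directed):
    vals = all_pairs_finite(nodes, edges, directed)
    return sum(vals) / len(vals) if vals else None


def undirected_simple_edges(edges):
    return {frozenset((u, v)) for u, v in edges if u != v}


def local_clustering(nodes, edges):
    """node -> local clustering coefficient on the undirected simplification."""
    und = undirected_simple_edges(edges)
    nbrs = {v: set() for v in nodes}
    for e in und:
        u, v = tuple(e)
        nbrs[u].add(v)
        nbrs[v].add(u)
    coeffs = {}
    for v in nodes:
        k = len(nbrs[v])
        if k < 2:
            coeffs[v] = None
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs[v], 2)
                    if frozenset((a, b)) in und)
        coeffs[v] = 2 * links / (k * (k - 1))
    return coeffs


def transitivity_avg_local(nodes, edges):
    coeffs = [c for c in local_clustering(nodes, edges).values()
              if c is not None]
    return sum(coeffs) / len(coeffs) if coeffs else None


def transitivity_global(nodes, edges):
    und = undirected_simple_edges(edges)
    nbrs = {v: set() for v in nodes}
    for e in und:
        u, v = tuple(e)
        nbrs[u].add(v)
        nbrs[v].add(u)
    triples = 0
    closed = 0
    for v in nodes:
        k = len(nbrs[v])
        triples += k * (k - 1) // 2
        closed += sum(1 for a, b in itertools.combinations(nbrs[v], 2)
                      if frozenset((a, b)) in und)
    return closed / triples if triples else None


def pearson(xs, ys):
    n = len(xs)
    if n == 0:
        return None
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    if vx == 0 or vy == 0:
        return None
    return cov / math.sqrt(vx * vy)


def assortativity_out_in(nodes, edges):
    out_deg = {v: 0 for v in nodes}
    in_deg = {v: 0 for v in nodes}
    for u, v in edges:
        out_deg[u] += 1
        in_deg[v] += 1
    xs = [out_deg[u] for u, _ in edges]
    ys = [in_deg[v] for _, v in edges]
    return pearson(xs, ys)


def weak_components(nodes, edges):
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in edges:
        parent[find(u)] = find(v)
    sizes = {}
    for v in nodes:
        sizes[find(v)] = sizes.get(find(v), 0) + 1
    return sorted(sizes.values(), reverse=True)


def strong_components(nodes, edges):
    """Kosaraju: sizes of strongly connected components, descending."""
    adj = _adj_from_edges(nodes, edges, directed=True)
    radj = {v: set() for v in nodes}
    for u, v in edges:
        radj[v].add(u)
    visited = set()
    order = []
    for s in nodes:
        if s in visited:
            continue
        stack = [(s, iter(adj[s]))]
        visited.add(s)
        while stack:
            v, it = stack[-1]
            advanced = False
            for w in it:
                if w not in visited:
                    visited.add(w)
                    stack.append((w, iter(adj[w])))
                    advanced = True
                    break
            if not advanced:
                order.append(v)
                stack.pop()
    assigned = set()
    sizes = []
    for s in reversed(order):
        if s in assigned:
            continue
        size = 0
        frontier = [s]
        assigned.add(s)
        while frontier:
            v = frontier.pop()
            size += 1
            for w in radj[v]:
                if w not in assigned:
                    assigned.add(w)
                    frontier.append(w)
        sizes.append(size)
    return sorted(sizes, reverse=True)


def mann_whitney_exact(x, y):
    """Exact one-sided p (H1: y > x) by enumerating all label assignments."""
    pooled = list(x) + list(y)
    n_x = len(x)

    def u_of(x_idx):
        xs = [pooled[i] for i in x_idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in x_idx]
        # U for y over x: pairs where y > x (+0.5 for ties)
        u = 0.0
        for yy in ys:
            for xx in xs:
                if yy > xx:
                    u += 1
                elif yy == xx:
                    u += 0.5
        return u

    observed = u_of(set(range(n_x)))
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        total += 1
        if u_of(set(combo)) >= observed:
            count += 1
    return observed, count / total


def modularity_hand(nodes, und_edges, membership):
    """Q = sum_c (e_c/m - (d_c/2m)^2) on an undirected simple graph."""
    m = len(und_edges)
    if m == 0:
        return 0.0
    deg = {v: 0 for v in nodes}
    internal = {}
    for e in und_edges:
        u, v = tuple(e) if len(tuple(e)) == 2 else (tuple(e)[0], tuple(e)[0])
        deg[u] += 1
        deg[v] += 1
        if membership[u] == membership[v]:
            internal[membership[u]] = internal.get(membership[u], 0) + 1
    q = 0.0
    communities = set(membership.values())
    for c in communities:
        d_c = sum(deg[v] for v in nodes if membership[v] == c)
        q += internal.get(c, 0) / m - (d_c / (2 * m)) ** 2
    return q


def haversine_law_of_cosines(a, b, radius_km=6371.0088):
    """Spherical law of cosines great-circle distance (independent route)."""
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    c = (math.sin(lat1) * math.sin(lat2)
         + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1))
    return radius_km * math.acos(max(-1.0, min(1.0, c)))


def zeta_inverse_cdf_sampler(alpha, size, rng, x_max=100000, x_min=1):
    """Exact discrete power-law draws via a CDF table."""
    ks = list(range(x_min, x_max + 1))
    weights = [k ** -alpha for k in ks]
    total = sum(weights)
    cdf = []
    acc = 0.0
    for w in weights:
        acc += w
        cdf.append(acc / total)
    us = rng.random(size)
    import bisect
    return [ks[bisect.bisect_left(cdf, u)] for u in us]
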