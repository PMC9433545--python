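"""Independent brute-force graph-measure implementations for cross-checks.

Everything here is written from the measure definitions with naive
enumeration (BFS layers, explicit path enumeration, Floyd-Warshall, direct
neighbour-pair counting) and shares no code with the package internals.
Intended for graphs of at most ~10 nodes.
"""

from __future__ import annotations

import math
from itertools import combinations


def edges_of(adj) -> list[tuple[int, int]]:
    n = len(adj)
    return [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i][j]]


def bfs_distances(adj, source: int) -> list[float]:
    n = len(adj)
    dist = [math.inf] * n
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u][v] and dist[v] == math.inf:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def floyd_warshall(adj) -> list[list[float]]:
    n = len(adj)
    d = [[0 if i == j else (1 if adj[i][j] else math.inf)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def brute_degree(adj) -> list[int]:
    return [sum(1 for j in range(len(adj)) if adj[i][j])
            for i in range(len(adj))]


def brute_clustering(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            out.append(0.0)
            continue
        links = sum(1 for a, b in combinations(nb, 2) if adj[a][b])
        out.append(links / (len(nb) * (len(nb) - 1) / 2))
    return out


def brute_char_path_length(adj) -> tuple[float, int]:
    n = len(adj)
    finite, excluded = [], 0
    for i in range(n):
        di = bfs_distances(adj, i)
        for j in range(i + 1, n):
            if math.isinf(di[j]):
                excluded += 1
            else:
                finite.append(di[j])
    if not finite:
        raise ValueError("no reachable pairs")
    return sum(finite) / len(finite), excluded


def brute_nodal_path_length(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        di = [d for j, d in enumerate(bfs_distances(adj, i))
              if j != i and not math.isinf(d)]
        out.append(sum(di) / len(di) if di else math.nan)
    return out


def brute_global_efficiency(adj) -> float:
    n = len(adj)
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        di = bfs_distances(adj, i)
        for j in range(n):
            if j != i and not math.isinf(di[j]):
                total += 1.0 / di[j]
    return total / (n * (n - 1))


def brute_nodal_efficiency(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        di = bfs_distances(adj, i)
        out.append(sum(1.0 / d for j, d in enumerate(di)
                       if j != i and not math.isinf(d)) / (n - 1))
    return out


def brute_local_efficiency(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            out.append(0.0)
            continue
        sub = [[1 if adj[a][b] else 0 for b in nb] for a in nb]
        out.append(brute_global_efficiency(sub))
    return out


def _all_shortest_paths(adj, s: int, t: int, dist) -> list[list[int]]:
    """Enumerate every geodesic from s to t by layered DFS."""
    if math.isinf(dist[t]):
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(path)
            return
        for v in range(len(adj)):
            if adj[u][v] and dist[v] == dist[u] + 1:
                extend(path + [v])

    extend([s])
    return paths


def brute_betweenness(adj) -> list[float]:
    """Unnormalized betweenness by explicit geodesic enumeration."""
    n = len(adj)
    bc = [0.0] * n
    for s in range(n):
        dist = bfs_distances(adj, s)
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t, dist)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def brute_assortativity(adj) -> float:
    k = brute_degree(adj)
    xs, ys = [], []
    for i, j in edges_of(adj):
        xs.extend([k[i], k[j]])
        ys.extend([k[j], k[i]])
    if len(xs) < 2:
        return math.nan
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    sx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    sy = math.sqrt(sum((y - my) ** 2 for y in ys))
    if sx == 0 or sy == 0:
        return math.nan
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    return cov / (sx * sy)


def brute_hierarchy(adj) -> float:
    """Least-squares slope of log C on log k, by the closed-form formula."""
    k = brute_degree(adj)
    c = brute_clustering(adj)
    pts = [(math.log(ki), math.log(ci))
           for ki, ci in zip(k, c) if ki >= 2 and ci > 0]
    if len(pts) < 2 or len({x for x, _ in pts}) < 2:
        return math.nan
    mx = sum(x for x, _ in pts) / len(pts)
    my = sum(y for _, y in pts) / len(pts)
    num = sum((x - mx) * (y - my) for x, y in pts)
    den = sum((x - mx) ** 2 for x, _ in pts)
    return -num / den


def brute_synchronization(adj) -> float:
    import numpy as np
    a = np.asarray(adj, dtype=float)
    lap = np.diag(a.sum(axis=1)) - a
    ev = np.sort(np.linalg.eigvalsh(lap))
    if ev[-1] <= 0:
        return math.nan
    return 0.0 if ev[1] < 1e-10 else float(ev[1] / ev[-1])
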