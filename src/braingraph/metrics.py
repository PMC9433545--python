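"""Nodal and global graph measures for binary brain networks.

Measures follow the common binary-graph conventions of connectome toolboxes:

* clustering coefficient: triangles around a node over possible neighbour
  pairs (0 for degree < 2); network Cp is the unweighted node mean;
* characteristic path length Lp: mean shortest-path hop count over *reachable*
  node pairs only (sparse brain networks are often disconnected; the number
  of excluded pairs is reported alongside);
* global/nodal efficiency: mean of 1/d with 1/inf = 0, so disconnection is
  handled natively;
* local efficiency: global efficiency of each node's neighbour-induced
  subgraph;
* betweenness: unnormalized shortest-path betweenness (undirected pairs);
* assortativity: Pearson correlation of end-point degrees over all edges,
  both orientations (Newman's degree-degree correlation);
* hierarchy: the exponent beta of C(k) ~ k^(-beta), fitted by least squares
  on log-log over nodes with degree >= 2 and positive clustering;
* synchronization: ratio of the second-smallest to the largest Laplacian
  eigenvalue (0 for disconnected graphs).

Small-world coefficients gamma = Cp/C_rand, lambda = Lp/L_rand and
sigma = gamma/lambda are normalized by an ensemble of degree-preserving
(double-edge-swap / Markov-chain) random networks, 100 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectome import BinaryNetwork

__all__ = [
    "degree_centrality",
    "clustering_coefficient",
    "shortest_path_lengths",
    "characteristic_path_length",
    "nodal_path_length",
    "betweenness_centrality",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "assortativity",
    "hierarchy",
    "synchronization",
    "rewire_degree_preserving",
    "small_world_coefficients",
    "auc_over_sparsity",
    "MetricTable",
    "compute_metric_table",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

GLOBAL_METRICS = ("Cp", "Lp", "global_efficiency", "local_efficiency",
                  "assortativity", "hierarchy", "synchronization",
                  "gamma", "lambda", "sigma")
NODAL_METRICS = ("degree", "betweenness", "clustering", "nodal_path_length",
                 "nodal_efficiency", "nodal_local_efficiency")


def _as_adj(net) -> np.ndarray:
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return a.astype(bool)


def degree_centrality(net) -> np.ndarray:
    """Node degrees (adjacency row sums)."""
    return _as_adj(net).sum(axis=1).astype(int)


def clustering_coefficient(net) -> tuple[np.ndarray, float]:
    """Per-node clustering and its unweighted mean Cp."""
    a = _as_adj(net).astype(np.int32)
    k = a.sum(axis=1)
    # (A^2 * A) row sums count 2x triangles through each node
    tri2 = ((a @ a) * a).sum(axis=1)
    denom = k * (k - 1)
    c = np.zeros(a.shape[0], dtype=float)
    ok = denom > 0
    c[ok] = tri2[ok] / denom[ok]
    return c, float(c.mean())


def shortest_path_lengths(net) -> np.ndarray:
    """All-pairs hop distances (breadth-first); unreachable pairs are inf."""
    a = _as_adj(net)
    return shortest_path(csr_matrix(a), method="D", unweighted=True)


def characteristic_path_length(distances: np.ndarray) -> tuple[float, int]:
    """Mean over finite off-diagonal distances; returns (Lp, excluded pairs).

    ``excluded`` counts unordered unreachable pairs.  Raises if no pair is
    reachable.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = d[iu, ju]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no reachable node pairs; path length undefined")
    return float(vals[finite].mean()), int((~finite).sum())


def nodal_path_length(distances: np.ndarray) -> np.ndarray:
    """Per-node mean hop distance to the reachable others (nan if isolated)."""
    d = np.asarray(distances, dtype=float).copy()
    np.fill_diagonal(d, np.nan)
    d[np.isinf(d)] = np.nan
    valid = ~np.isnan(d)
    cnt = valid.sum(axis=1)
    total = np.nansum(d, axis=1)
    out = np.full(d.shape[0], np.nan)
    ok = cnt > 0
    out[ok] = total[ok] / cnt[ok]
    return out


def betweenness_centrality(net, normalized: bool = False) -> np.ndarray:
    """Unnormalized (default) shortest-path betweenness per node."""
    a = _as_adj(net)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return np.array([bc[i] for i in range(a.shape[0])])


def global_efficiency(distances: np.ndarray) -> float:
    """Mean of 1/d over ordered off-diagonal pairs (1/inf = 0)."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(distances: np.ndarray) -> np.ndarray:
    """Per-node mean of 1/d to all other nodes."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(net) -> tuple[np.ndarray, float]:
    """Per-node neighbour-subgraph efficiency and the network mean."""
    a = _as_adj(net)
    n = a.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        vals[i] = global_efficiency(shortest_path_lengths(sub))
    return vals, float(vals.mean())


def assortativity(net) -> float:
    """Degree-degree Pearson correlation over edge end points (nan if the
    degree variance is zero, e.g. regular graphs)."""
    a = _as_adj(net)
    k = a.sum(axis=1)
    iu, ju = np.nonzero(np.triu(a, 1))
    if iu.size < 2:
        return float("nan")
    x = np.concatenate([k[iu], k[ju]]).astype(float)
    y = np.concatenate([k[ju], k[iu]]).astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def hierarchy(net) -> float:
    """Exponent beta of the clustering-degree power law C(k) ~ k^(-beta)."""
    a = _as_adj(net)
    c, _ = clustering_coefficient(a)
    k = a.sum(axis=1)
    ok = (k >= 2) & (c > 0)
    if ok.sum() < 2 or np.unique(k[ok]).size < 2:
        return float("nan")
    slope = np.polyfit(np.log(k[ok].astype(float)), np.log(c[ok]), 1)[0]
    return float(-slope)


def synchronization(net) -> float:
    """Laplacian eigenratio lambda_2 / lambda_max (0 when disconnected)."""
    a = _as_adj(net).astype(float)
    lap = np.diag(a.sum(axis=1)) - a
    ev = np.linalg.eigvalsh(lap)
    lam_max = ev[-1]
    if lam_max <= 0:
        return float("nan")
    lam2 = ev[1]
    if lam2 < 1e-10:
        return 0.0
    return float(lam2 / lam_max)


# ---------------------------------------------------------------------------
# degree-preserving null models

def rewire_degree_preserving(net, n_swaps: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Randomize a network by repeated double-edge swaps.

    ``n_swaps`` attempted swaps: pick two disjoint edges (a,b), (c,d) and
    replace them with (a,d), (c,b) unless that creates a self-loop or
    duplicate edge.  The degree sequence is invariant.
    """
    a = _as_adj(net)
    iu, ju = np.nonzero(np.triu(a, 1))
    edges = [(int(u), int(v)) for u, v in zip(iu, ju)]
    m = len(edges)
    if m < 2:
        return a.copy()
    edge_set = {frozenset(e) for e in edges}
    idx = rng.integers(0, m, size=(n_swaps, 2))
    flips = rng.random(n_swaps) < 0.5
    for s in range(n_swaps):
        i, j = idx[s]
        if i == j:
            continue
        u1, v1 = edges[i]
        u2, v2 = edges[j]
        if flips[s]:
            u2, v2 = v2, u2
        if len({u1, v1, u2, v2}) < 4:
            continue
        e1, e2 = frozenset((u1, v2)), frozenset((u2, v1))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((u1, v1)))
        edge_set.discard(frozenset((u2, v2)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (u1, v2)
        edges[j] = (u2, v1)
    out = np.zeros_like(a)
    for u, v in edges:
        out[u, v] = out[v, u] = True
    return out


def _largest_component(a: np.ndarray) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(a), directed=False)
    if n_comp == 1:
        return a
    counts = np.bincount(labels)
    keep = np.flatnonzero(labels == counts.argmax())
    return a[np.ix_(keep, keep)]


def _cp_lp(a: np.ndarray) -> tuple[float, float]:
    _, cp = clustering_coefficient(a)
    lp, _ = characteristic_path_length(shortest_path_lengths(a))
    return cp, lp


def small_world_coefficients(net, n_random: int = 100,
                             rng: np.random.Generator | None = None,
                             swaps_per_edge: int = 10) -> dict:
    """Small-world coefficients against a degree-preserving null ensemble.

    Returns a dict with Cp, Lp, their null-ensemble means, and gamma, lambda
    and sigma.  Computed on the largest connected component when the input is
    disconnected (component coverage is returned).
    """
    if n_random < 1:
        raise ValueError("need at least one null network")
    rng = rng if rng is not None else np.random.default_rng()
    a = _as_adj(net)
    lcc = _largest_component(a)
    coverage = lcc.shape[0] / a.shape[0]
    cp, lp = _cp_lp(lcc)
    m = int(lcc.sum()) // 2
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for r in range(n_random):
        null = rewire_degree_preserving(lcc, swaps_per_edge * m, rng)
        null_lcc = _largest_component(null)
        c_rand[r], l_rand[r] = _cp_lp(null_lcc)
    mean_c, mean_l = float(c_rand.mean()), float(l_rand.mean())
    if mean_c == 0:
        raise ValueError("null-ensemble clustering is zero; gamma undefined")
    gamma = cp / mean_c
    lam = lp / mean_l
    return {
        "Cp": cp, "Lp": lp, "C_rand": mean_c, "L_rand": mean_l,
        "gamma": gamma, "lambda": lam, "sigma": gamma / lam,
        "component_coverage": coverage, "n_random": n_random,
    }


def auc_over_sparsity(values, densities) -> float:
    """Trapezoidal average of a per-density series over the density range.

    Normalized by the range so a constant series maps to itself.  A
    single-density series returns its own value.  NaNs propagate.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(densities, dtype=float)
    if v.shape != d.shape:
        raise ValueError("series and density grid lengths differ")
    if np.isnan(v).any():
        return float("nan")
    if d.size == 1:
        return float(v[0])
    return float(np.trapezoid(v, d) / (d[-1] - d[0]))


# ---------------------------------------------------------------------------
# per-subject metric tables

@dataclass
class MetricTable:
    """All measures of one subject across the density sweep, plus AUCs."""

    subject_id: str
    densities: np.ndarray
    global_metrics: pd.DataFrame          # densities x GLOBAL_METRICS
    nodal_metrics: dict                   # metric -> densities x n_roi frame
    auc_global: pd.Series = field(init=False)
    auc_nodal: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.auc_global = pd.Series({
            m: auc_over_sparsity(self.global_metrics[m].values, self.densities)
            for m in self.global_metrics.columns})
        self.auc_nodal = pd.DataFrame({
            m: [auc_over_sparsity(df[c].values, self.densities)
                for c in df.columns]
            for m, df in self.nodal_metrics.items()
        }).T
        if self.nodal_metrics:
            first = next(iter(self.nodal_metrics.values()))
            self.auc_nodal.columns = first.columns

    def to_long(self) -> pd.DataFrame:
        """Long-format table (subject_id, density, metric, node, value)."""
        rows = []
        for d_i, d in enumerate(self.densities):
            for m in self.global_metrics.columns:
                rows.append((self.subject_id, d, m, "global",
                             self.global_metrics.iloc[d_i][m]))
            for m, df in self.nodal_metrics.items():
                for node in df.columns:
                    rows.append((self.subject_id, d, m, node,
                                 df.iloc[d_i][node]))
        return pd.DataFrame(rows, columns=["subject_id", "density", "metric",
                                           "node_or_global", "value"])


def compute_metric_table(networks: list[BinaryNetwork], densities,
                         subject_id: str = "", n_random: int = 100,
                         rng: np.random.Generator | None = None,
                         roi_labels: list[str] | None = None,
                         global_metrics=GLOBAL_METRICS,
                         nodal_metrics=NODAL_METRICS) -> MetricTable:
    """Compute the selected measures at every density of a subject's sweep.

    ``n_random = 0`` skips the null-normalized coefficients (gamma, lambda,
    sigma become NaN), which is much faster; a metric subset can be selected
    explicitly for scaled-down experiments.
    """
    densities = np.asarray(densities, dtype=float)
    if len(networks) != densities.size:
        raise ValueError("one network per density required")
    rng = rng if rng is not None else np.random.default_rng()
    n = networks[0].adjacency.shape[0]
    if roi_labels is None:
        roi_labels = [f"ROI_{i + 1}" for i in range(n)]
    want_g = set(global_metrics)
    want_n = set(nodal_metrics)
    g_rows = []
    n_frames: dict[str, list[np.ndarray]] = {m: [] for m in nodal_metrics}
    for net in networks:
        a = net.adjacency
        row: dict[str, float] = {}
        need_dist = want_g & {"Lp", "global_efficiency"} or \
            want_n & {"nodal_path_length", "nodal_efficiency"}
        dist = shortest_path_lengths(a) if need_dist else None
        if "degree" in want_n:
            n_frames["degree"].append(degree_centrality(a).astype(float))
        if "betweenness" in want_n:
            n_frames["betweenness"].append(betweenness_centrality(a))
        if want_n & {"clustering"} or want_g & {"Cp"}:
            c, cp = clustering_coefficient(a)
            if "clustering" in want_n:
                n_frames["clustering"].append(c)
            if "Cp" in want_g:
                row["Cp"] = cp
        if "Lp" in want_g:
            row["Lp"], _ = characteristic_path_length(dist)
        if "nodal_path_length" in want_n:
            n_frames["nodal_path_length"].append(nodal_path_length(dist))
        if "global_efficiency" in want_g:
            row["global_efficiency"] = global_efficiency(dist)
        if "nodal_efficiency" in want_n:
            n_frames["nodal_efficiency"].append(nodal_efficiency(dist))
        if want_n & {"nodal_local_efficiency"} or want_g & {"local_efficiency"}:
            le, le_mean = local_efficiency(a)
            if "nodal_local_efficiency" in want_n:
                n_frames["nodal_local_efficiency"].append(le)
            if "local_efficiency" in want_g:
                row["local_efficiency"] = le_mean
        if "assortativity" in want_g:
            row["assortativity"] = assortativity(a)
        if "hierarchy" in want_g:
            row["hierarchy"] = hierarchy(a)
        if "synchronization" in want_g:
            row["synchronization"] = synchronization(a)
        if want_g & {"gamma", "lambda", "sigma"}:
            if n_random > 0:
                sw = small_world_coefficients(a, n_random, rng)
                row.update({k: sw[k] for k in ("gamma", "lambda", "sigma")
                            if k in want_g})
            else:
                row.update({k: float("nan")
                            for k in ("gamma", "lambda", "sigma")
                            if k in want_g})
        g_rows.append(row)
    global_df = pd.DataFrame(g_rows, index=densities,
                             columns=[m for m in global_metrics])
    nodal = {m: pd.DataFrame(np.vstack(v), index=densities, columns=roi_labels)
             for m, v in n_frames.items() if v}
    return MetricTable(subject_id, densities, global_df, nodal)
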