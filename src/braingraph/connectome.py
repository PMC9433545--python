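"""Pearson connectivity matrices and fixed-density binarization.

Binarization ranks the ``n(n-1)/2`` upper-triangle correlations and keeps the
strongest ``floor(density * n(n-1)/2)`` as undirected edges, so every subject's
network has the same wiring cost at a given density.  Ranking is by signed
value by default (strongest positive correlations first); absolute-value
ranking is available.  Ties at the cutoff break by (row, column) order so the
result is deterministic.  A density sweep produces nested edge sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "SparsitySweep",
    "pearson_connectivity",
    "threshold_by_density",
    "sweep_networks",
]


@dataclass
class ConnectivityMatrix:
    values: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("connectivity matrix has non-finite entries")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")


@dataclass
class BinaryNetwork:
    adjacency: np.ndarray      # boolean, symmetric, hollow diagonal
    density: float
    edge_count: int


def default_densities() -> np.ndarray:
    """The 10-50% cost sweep in 1% steps (41 values)."""
    return np.round(np.arange(10, 51) / 100.0, 2)


@dataclass
class SparsitySweep:
    densities: np.ndarray = field(default_factory=default_densities)

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if d.size == 0 or not (np.diff(d) > 0).all():
            raise ValueError("densities must be strictly increasing")
        if not ((d > 0) & (d < 1)).all():
            raise ValueError("densities must lie in (0, 1)")
        self.densities = d


def pearson_connectivity(timeseries: np.ndarray,
                         roi_labels: list[str] | None = None
                         ) -> ConnectivityMatrix:
    """Sample Pearson correlation between every pair of ROI columns."""
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a T x n matrix with T >= 3")
    if not np.isfinite(x).all():
        raise ValueError("time series contain non-finite values")
    if roi_labels is None:
        roi_labels = [f"ROI_{i + 1}" for i in range(x.shape[1])]
    spread = x.max(axis=0) - x.min(axis=0)
    if (spread == 0).any():
        bad = [roi_labels[i] for i in np.flatnonzero(spread == 0)]
        raise ValueError(f"constant time series for ROI(s): {', '.join(bad)}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, list(roi_labels))


def threshold_by_density(R: ConnectivityMatrix, density: float,
                         use_absolute: bool = False) -> BinaryNetwork:
    """Keep the top ``floor(density * n(n-1)/2)`` correlations as edges."""
    if not 0.0 < density < 1.0:
        raise ValueError(f"density {density} outside (0, 1)")
    v = np.abs(R.values) if use_absolute else R.values
    n = v.shape[0]
    iu, ju = np.triu_indices(n, 1)
    n_pairs = iu.size
    m = int(np.floor(density * n_pairs))
    if m == 0:
        raise ValueError(f"density {density} keeps zero edges at n={n}")
    vals = v[iu, ju]
    # primary key: value descending; ties broken by (row, col) ascending
    order = np.lexsort((ju, iu, -vals))
    keep = order[:m]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return BinaryNetwork(adj, float(density), m)


def sweep_networks(R: ConnectivityMatrix, sweep: SparsitySweep | None = None,
                   use_absolute: bool = False) -> list[BinaryNetwork]:
    """Binarize at every density of the sweep (nested edge sets)."""
    sweep = sweep or SparsitySweep()
    return [threshold_by_density(R, d, use_absolute) for d in sweep.densities]


def write_network(net: BinaryNetwork, path, roi_labels: list[str]) -> None:
    """Edge-list TSV (roi_a, roi_b) with a JSON sidecar (density, edges)."""
    import json
    from pathlib import Path

    path = Path(path)
    iu, ju = np.nonzero(np.triu(net.adjacency, 1))
    with open(path, "w") as fh:
        fh.write("roi_a\troi_b\n")
        for i, j in zip(iu, ju):
            fh.write(f"{roi_labels[i]}\t{roi_labels[j]}\n")
    path.with_suffix(".json").write_text(json.dumps(
        {"density": net.density, "edge_count": net.edge_count,
         "n_roi": int(net.adjacency.shape[0])}))


def read_network(path, roi_labels: list[str]) -> BinaryNetwork:
    """Read a network written by :func:`write_network`."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    index = {lab: i for i, lab in enumerate(roi_labels)}
    adj = np.zeros((meta["n_roi"], meta["n_roi"]), dtype=bool)
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            adj[index[a], index[b]] = adj[index[b], index[a]] = True
    return BinaryNetwork(adj, meta["density"], meta["edge_count"])
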