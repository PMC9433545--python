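"""Synthetic two-group rs-fMRI cohort generator with known network ground truth.

Each group (TD-like and ADHD-like) is given a Watts-Strogatz small-world
"group graph" on the 116 AAL nodes; the two groups differ only in the
rewiring probability, so the less-rewired group has a longer characteristic
path length and lower global efficiency -- the topological signature the
downstream stages are meant to recover.  Per-subject graphs are small,
edge-count-preserving perturbations of the group graph.  ROI time series are
drawn from a zero-mean multivariate normal with covariance ``I + c*A`` so
the population correlation of every connected ROI pair is exactly the
coupling ``c`` and zero otherwise, which keeps recovery tests analytic.

Covariates mirror the demographic structure of a two-site ADHD/TD study:
age matched between groups, all three IQs lower in the ADHD-like group,
gender majority-male, and mean frame-wise displacement near 0.15 mm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import roi_labels

__all__ = [
    "CovariateParams",
    "SimulationConfig",
    "GroundTruth",
    "make_group_graph",
    "simulate_timeseries",
    "simulate_motion",
    "simulate_cohort",
    "Subject",
]

#: group-wise covariate distributions: (TD mean, TD sd, ADHD mean, ADHD sd)
_DEFAULT_COVARIATES = {
    "age": (11.51, 1.77, 11.86, 2.21),
    "verbal_iq": (120.9, 13.26, 107.48, 15.25),
    "performance_iq": (110.93, 15.03, 98.43, 11.86),
    "full_iq": (118.2, 13.46, 103.55, 12.63),
    "mean_fd": (0.1434, 0.058, 0.152, 0.046),
}
#: group-wise probability that a subject is male (TD, ADHD)
_DEFAULT_MALE_PROP = (44 / 56, 49 / 56)


@dataclass
class CovariateParams:
    """Group-wise covariate distributions (mean/SD per group, male proportion)."""

    means: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))
    male_proportion: tuple = _DEFAULT_MALE_PROP


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions: two groups of 56 subjects,
    116 ROIs, 226 retained volumes at TR = 2 s, small-world base graphs of
    lattice degree 10 with the TD-like group rewired at 0.2 and the
    ADHD-like group at 0.02 (hence longer paths in the latter).
    """

    n_per_group: int = 56
    n_roi: int = 116
    n_timepoints: int = 226
    tr_seconds: float = 2.0
    ws_neighbors: int = 10
    ws_rewire_td: float = 0.2
    ws_rewire_adhd: float = 0.02
    edge_coupling: float = 0.09
    subject_edge_jitter: float = 0.02
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    motion_spike_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("ws_rewire_td", "ws_rewire_adhd", "subject_edge_jitter",
                     "motion_spike_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")
        if self.ws_neighbors % 2 != 0:
            raise ValueError("ws_neighbors must be even (ring-lattice degree)")
        if self.n_roi < self.ws_neighbors + 1:
            raise ValueError("n_roi must exceed ws_neighbors")
        # sufficient positive-definiteness condition for I + c*A: the spectral
        # radius of A is at most the maximum degree, which jitter/rewiring can
        # push somewhat above the lattice degree; checked exactly per subject
        # in simulate_timeseries, and conservatively here.
        if self.edge_coupling < 0:
            raise ValueError("edge_coupling must be non-negative")
        if self.edge_coupling * self.ws_neighbors >= 1.0:
            raise ValueError(
                "edge_coupling x lattice degree must be < 1 for a valid covariance"
            )


@dataclass
class Subject:
    """One simulated subject: identifiers, data arrays, covariates."""

    subject_id: str
    group: str                      # "TD" or "ADHD"
    timeseries: np.ndarray          # T x n_roi
    motion: np.ndarray              # T x 6
    covariates: dict                # age, gender, IQs, mean_fd
    graph: np.ndarray               # n_roi x n_roi boolean adjacency


@dataclass
class GroundTruth:
    """What was injected: group/subject graphs, spikes, covariate effects."""

    group_graphs: dict              # group -> boolean adjacency
    subject_graphs: dict            # subject_id -> boolean adjacency
    spike_volumes: dict             # subject_id -> sorted list of volumes
    covariate_effects: dict
    seed: int = 0


def make_group_graph(n_roi: int, k: int, p_rewire: float,
                     rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
    """Connected Watts-Strogatz graph as a boolean adjacency matrix.

    Exactly ``n_roi * k / 2`` edges regardless of rewiring (rewiring moves
    edges, it never adds or removes them).  Redraws up to ``max_tries`` times
    until the graph is connected.
    """
    if k >= n_roi:
        raise ValueError("lattice degree k must be below the node count")
    for _ in range(max_tries):
        g = nx.watts_strogatz_graph(n_roi, k, p_rewire, seed=rng)
        if nx.is_connected(g):
            a = nx.to_numpy_array(g, nodelist=range(n_roi), dtype=bool)
            return a
    raise RuntimeError(
        f"could not draw a connected Watts-Strogatz graph in {max_tries} tries "
        f"(n={n_roi}, k={k}, p={p_rewire})"
    )


def _jitter_graph(adj: np.ndarray, fraction: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Move a random ``fraction`` of edges to random vacant pairs.

    Edge count is preserved exactly; degrees may change slightly.  This is the
    per-subject heterogeneity model.
    """
    a = adj.copy()
    n = a.shape[0]
    iu, ju = np.triu_indices(n, 1)
    present = a[iu, ju]
    edge_idx = np.flatnonzero(present)
    n_move = int(round(fraction * edge_idx.size))
    if n_move == 0:
        return a
    drop = rng.choice(edge_idx, size=n_move, replace=False)
    vacant = np.flatnonzero(~present)
    add = rng.choice(vacant, size=n_move, replace=False)
    for idx in drop:
        a[iu[idx], ju[idx]] = a[ju[idx], iu[idx]] = False
    for idx in add:
        a[iu[idx], ju[idx]] = a[ju[idx], iu[idx]] = True
    return a


def simulate_timeseries(subject_graph: np.ndarray, c: float, T: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw a T x n ROI time-series matrix with covariance ``I + c*A``.

    Population correlation is ``c`` for adjacent ROI pairs and 0 otherwise.
    Columns are rescaled to unit sample variance.  Raises if the covariance
    is not positive definite (coupling too strong for the graph's degrees).
    """
    a = subject_graph.astype(float)
    n = a.shape[0]
    cov = np.eye(n) + c * a
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        lam_min = float(np.linalg.eigvalsh(cov)[0])
        raise ValueError(
            f"covariance I + c*A not positive definite "
            f"(c={c}, min eigenvalue {lam_min:.4g}); reduce the coupling"
        ) from exc
    z = rng.standard_normal((T, n))
    x = z @ chol.T
    sd = x.std(axis=0, ddof=1)
    return x / sd


def simulate_motion(T: int, spike_rate: float, rng: np.random.Generator,
                    head_radius_mm: float = 50.0) -> tuple[np.ndarray, list[int]]:
    """Six-parameter motion trace: slow drift plus isolated large spikes.

    Returns ``(trace, spike_volumes)``.  The baseline is a small-step random
    walk (framewise displacement well under 0.5 mm); at each spike volume a
    transient translation offset is added whose FD exceeds 0.5 mm at the spike
    (and at the return to baseline).
    """
    trans = np.cumsum(rng.normal(0.0, 0.008, size=(T, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, 8e-5, size=(T, 3)), axis=0)
    motion = np.hstack([trans, rot])
    spikes = [t for t in range(1, T - 1) if rng.random() < spike_rate]
    for t in spikes:
        # one-volume offset: +0.3 mm on each translation axis -> FD = 0.9 mm
        motion[t, :3] += 0.3
    return motion, spikes


def _draw_covariates(group: str, params: CovariateParams,
                     rng: np.random.Generator) -> dict:
    gi = 0 if group == "TD" else 1
    cov = {}
    for name, (m_td, s_td, m_ad, s_ad) in params.means.items():
        m, s = (m_td, s_td) if gi == 0 else (m_ad, s_ad)
        v = rng.normal(m, s)
        if name == "mean_fd":
            v = max(v, 0.01)
        cov[name] = round(float(v), 4)
    cov["gender"] = int(rng.random() < params.male_proportion[gi])
    return cov


def simulate_cohort(config: SimulationConfig,
                    out_dir: str | Path | None = None
                    ) -> tuple[list[Subject], GroundTruth]:
    """Generate the full two-group cohort; optionally write it to disk.

    One global seed is split into independent substreams (group graphs first,
    then one per subject) so any single subject is reproducible on its own.
    When ``out_dir`` is given, writes per-subject time-series TSVs (ROI-label
    header), SPM-dialect motion text files, a phenotype CSV and a
    ground-truth JSON.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    graph_ss, *subject_ss = ss.spawn(1 + 2 * config.n_per_group)

    # Common random numbers: both group graphs are drawn from the same
    # substream, so the groups differ only through their rewiring
    # probability.  With equal probabilities the group graphs are identical
    # (a genuinely null cohort, no graph-level cluster effect); with
    # different probabilities the shared randomness reduces between-group
    # simulation noise.
    group_graphs = {
        "TD": make_group_graph(config.n_roi, config.ws_neighbors,
                               config.ws_rewire_td,
                               np.random.default_rng(graph_ss)),
        "ADHD": make_group_graph(config.n_roi, config.ws_neighbors,
                                 config.ws_rewire_adhd,
                                 np.random.default_rng(graph_ss)),
    }

    labels = roi_labels(config.n_roi)
    subjects: list[Subject] = []
    subject_graphs: dict[str, np.ndarray] = {}
    spike_volumes: dict[str, list[int]] = {}
    i_ss = 0
    for group in ("TD", "ADHD"):
        for i in range(config.n_per_group):
            rng = np.random.default_rng(subject_ss[i_ss])
            i_ss += 1
            sid = f"sub-{group.lower()}{i + 1:03d}"
            g_subj = _jitter_graph(group_graphs[group],
                                   config.subject_edge_jitter, rng)
            ts = simulate_timeseries(g_subj, config.edge_coupling,
                                     config.n_timepoints, rng)
            motion, spikes = simulate_motion(config.n_timepoints,
                                             config.motion_spike_rate, rng)
            cov = _draw_covariates(group, config.covariate_params, rng)
            subjects.append(Subject(sid, group, ts, motion, cov, g_subj))
            subject_graphs[sid] = g_subj
            spike_volumes[sid] = spikes

    truth = GroundTruth(
        group_graphs=group_graphs,
        subject_graphs=subject_graphs,
        spike_volumes=spike_volumes,
        covariate_effects={
            "ws_rewire": {"TD": config.ws_rewire_td, "ADHD": config.ws_rewire_adhd},
            "covariate_means": config.covariate_params.means,
            "male_proportion": list(config.covariate_params.male_proportion),
        },
        seed=config.seed,
    )
    if out_dir is not None:
        write_cohort(subjects, truth, config, Path(out_dir), labels)
    return subjects, truth


# ---------------------------------------------------------------------------
# on-disk formats

def _edge_list(adj: np.ndarray) -> list[list[int]]:
    iu, ju = np.nonzero(np.triu(adj, 1))
    return [[int(i), int(j)] for i, j in zip(iu, ju)]


def write_cohort(subjects: list[Subject], truth: GroundTruth,
                 config: SimulationConfig, out_dir: Path,
                 labels: list[str] | None = None) -> None:
    """Write time-series TSVs, motion traces, phenotype CSV and truth JSON."""
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    mo_dir = out_dir / "motion"
    ts_dir.mkdir(parents=True, exist_ok=True)
    mo_dir.mkdir(parents=True, exist_ok=True)
    if labels is None:
        labels = roi_labels(subjects[0].timeseries.shape[1])

    pheno_rows = []
    for s in subjects:
        df = pd.DataFrame(s.timeseries, columns=labels)
        df.to_csv(ts_dir / f"{s.subject_id}.tsv", sep="\t", index=False,
                  float_format="%.6f")
        np.savetxt(mo_dir / f"{s.subject_id}.txt", s.motion, fmt="%.6f")
        pheno_rows.append({
            "subject_id": s.subject_id,
            "dx": 0 if s.group == "TD" else 1,
            "age": s.covariates["age"],
            "gender": s.covariates["gender"],
            "verbal_iq": s.covariates["verbal_iq"],
            "performance_iq": s.covariates["performance_iq"],
            "full_iq": s.covariates["full_iq"],
            "mean_fd": s.covariates["mean_fd"],
        })
    pd.DataFrame(pheno_rows).to_csv(out_dir / "phenotype.csv", index=False)

    truth_json = {
        "seed": truth.seed,
        "group_graphs": {g: _edge_list(a) for g, a in truth.group_graphs.items()},
        "subject_graphs": {s: _edge_list(a)
                           for s, a in truth.subject_graphs.items()},
        "spike_volumes": truth.spike_volumes,
        "covariate_effects": truth.covariate_effects,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "covariate_params"},
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)


def read_cohort(in_dir: str | Path) -> list[Subject]:
    """Read a cohort written by :func:`write_cohort` (or real ROI extracts
    in the same TSV/CSV dialect) back into :class:`Subject` records."""
    in_dir = Path(in_dir)
    pheno = pd.read_csv(in_dir / "phenotype.csv")
    subjects = []
    for _, row in pheno.iterrows():
        sid = row["subject_id"]
        ts = pd.read_csv(in_dir / "timeseries" / f"{sid}.tsv", sep="\t").values
        mo_path = in_dir / "motion" / f"{sid}.txt"
        motion = np.loadtxt(mo_path) if mo_path.exists() else None
        cov = {k: row[k] for k in ("age", "gender", "verbal_iq",
                                   "performance_iq", "full_iq", "mean_fd")}
        group = "ADHD" if int(row["dx"]) == 1 else "TD"
        subjects.append(Subject(sid, group, ts, motion, cov, None))
    return subjects
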