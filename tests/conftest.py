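import networkx as nx
import numpy as np
import pytest


def random_connected_graphs(n_graphs: int = 60, seed: int = 2024):
    """Seeded fixture set: connected simple graphs with 4-9 nodes."""
    rng = np.random.default_rng(seed)
    graphs = []
    while len(graphs) < n_graphs:
        n = int(rng.integers(4, 10))
        p = float(rng.uniform(0.25, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        if nx.is_connected(g) and g.number_of_edges() >= 2:
            graphs.append(nx.to_numpy_array(g, dtype=bool))
    return graphs


@pytest.fixture(scope="session")
def small_graphs():
    return random_connected_graphs()


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but non-trivial simulated cohort shared across tests."""
    from braingraph.cohort import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(n_per_group=8, n_roi=40, n_timepoints=120,
                           ws_neighbors=6, seed=11)
    return simulate_cohort(cfg)
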