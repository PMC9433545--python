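"""Graph measures: closed forms, oracle spot checks, nulls, AUC, tables."""

import numpy as np
import networkx as nx
import pytest

import braingraph.metrics as gm
from braingraph.connectome import BinaryNetwork

from oracles import floyd_warshall


def adj(g: nx.Graph) -> np.ndarray:
    return nx.to_numpy_array(g, dtype=bool)


K5 = adj(nx.complete_graph(5))
STAR5 = adj(nx.star_graph(4))          # center + 4 leaves
P4 = adj(nx.path_graph(4))
C4 = adj(nx.cycle_graph(4))


class TestClosedForms:
    def test_complete_graph_unit_measures(self):
        d = gm.shortest_path_lengths(K5)
        assert gm.characteristic_path_length(d) == (1.0, 0)
        assert gm.global_efficiency(d) == pytest.approx(1.0)
        c, cp = gm.clustering_coefficient(K5)
        assert cp == pytest.approx(1.0) and np.allclose(c, 1.0)
        le, le_mean = gm.local_efficiency(K5)
        assert le_mean == pytest.approx(1.0)
        assert gm.synchronization(K5) == pytest.approx(1.0)
        assert np.isnan(gm.assortativity(K5))   # zero degree variance
        assert (gm.degree_centrality(K5) == 4).all()

    def test_star_graph(self):
        bc = gm.betweenness_centrality(STAR5)
        assert bc[0] == pytest.approx(6.0)       # C(4,2) leaf pairs
        assert np.allclose(bc[1:], 0.0)
        _, cp = gm.clustering_coefficient(STAR5)
        assert cp == 0.0
        assert gm.assortativity(STAR5) == pytest.approx(-1.0)
        le, le_mean = gm.local_efficiency(STAR5)
        assert le_mean == 0.0
        assert (gm.degree_centrality(STAR5) == [4, 1, 1, 1, 1]).all()

    def test_path_graph_distances_and_lp(self):
        d = gm.shortest_path_lengths(P4)
        iu, ju = np.triu_indices(4, 1)
        assert sorted(d[iu, ju]) == [1, 1, 1, 2, 2, 3]
        lp, excluded = gm.characteristic_path_length(d)
        assert lp == pytest.approx(10 / 6)
        assert excluded == 0

    def test_cycle_c4(self):
        assert gm.synchronization(C4) == pytest.approx(0.5)  # {0,2,2,4}
        bc = gm.betweenness_centrality(C4)
        assert np.allclose(bc, 0.5)

    def test_p3_efficiency(self):
        p3 = adj(nx.path_graph(3))
        assert gm.global_efficiency(gm.shortest_path_lengths(p3)) == \
            pytest.approx(5 / 6)

    def test_disconnected_conventions(self):
        two_triangles = np.zeros((6, 6), dtype=bool)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            two_triangles[a, b] = two_triangles[b, a] = True
        d = gm.shortest_path_lengths(two_triangles)
        lp, excluded = gm.characteristic_path_length(d)
        assert lp == pytest.approx(1.0) and excluded == 9
        assert gm.synchronization(two_triangles) == 0.0

        pair_of_edges = np.zeros((4, 4), dtype=bool)
        pair_of_edges[0, 1] = pair_of_edges[1, 0] = True
        pair_of_edges[2, 3] = pair_of_edges[3, 2] = True
        d = gm.shortest_path_lengths(pair_of_edges)
        assert gm.global_efficiency(d) == pytest.approx(1 / 3)

    def test_bowtie_hierarchy_exact(self):
        """Two triangles sharing a node: C(2)=1, C(4)=1/3 -> beta=log3/log2."""
        bowtie = np.zeros((5, 5), dtype=bool)
        for a, b in [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (2, 4)]:
            bowtie[a, b] = bowtie[b, a] = True
        assert gm.hierarchy(bowtie) == pytest.approx(np.log(3) / np.log(2))

    def test_hierarchy_undefined_on_regular_graph(self):
        assert np.isnan(gm.hierarchy(K5))


class TestDistancesOracle:
    def test_matches_floyd_warshall(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2 ** 31)))
            a = adj(g)
            d = gm.shortest_path_lengths(a)
            fw = np.array(floyd_warshall(a.tolist()))
            assert np.array_equal(np.isinf(d), np.isinf(fw))
            assert np.allclose(d[np.isfinite(d)], fw[np.isfinite(fw)])


class TestRewiring:
    def test_degree_sequence_invariant(self, small_graphs):
        rng = np.random.default_rng(0)
        for a in small_graphs[:15]:
            null = gm.rewire_degree_preserving(a, 200, rng)
            assert (null.sum(axis=1) == a.sum(axis=1)).all()
            assert not null.diagonal().any()
            assert np.array_equal(null, null.T)

    def test_zero_swaps_is_identity(self):
        a = adj(nx.cycle_graph(8))
        out = gm.rewire_degree_preserving(a, 0, np.random.default_rng(1))
        assert np.array_equal(out, a)

    def test_randomization_destroys_lattice_clustering(self):
        lattice = adj(nx.watts_strogatz_graph(60, 6, 0.0))
        _, c0 = gm.clustering_coefficient(lattice)
        m = int(lattice.sum()) // 2
        for seed in range(20):
            null = gm.rewire_degree_preserving(
                lattice, 10 * m, np.random.default_rng(seed))
            _, c = gm.clustering_coefficient(null)
            assert c < 0.5 * c0


class TestSmallWorld:
    def test_self_null_gives_unit_coefficients(self, monkeypatch):
        monkeypatch.setattr(gm, "rewire_degree_preserving",
                            lambda a, n, rng: a.copy())
        ws = adj(nx.connected_watts_strogatz_graph(40, 6, 0.1, seed=3))
        sw = gm.small_world_coefficients(ws, n_random=5,
                                        rng=np.random.default_rng(0))
        assert sw["gamma"] == pytest.approx(1.0)
        assert sw["lambda"] == pytest.approx(1.0)
        assert sw["sigma"] == pytest.approx(1.0)

    def test_random_graph_is_its_own_null(self):
        """An Erdos-Renyi graph should show gamma ~ 1, sigma ~ 1."""
        gammas, sigmas = [], []
        for seed in range(20):
            g = nx.gnm_random_graph(60, 240, seed=seed)
            g = g.subgraph(max(nx.connected_components(g), key=len))
            a = nx.to_numpy_array(g, dtype=bool)
            sw = gm.small_world_coefficients(
                a, n_random=10, rng=np.random.default_rng(seed))
            gammas.append(sw["gamma"])
            sigmas.append(sw["sigma"])
        assert np.mean(gammas) == pytest.approx(1.0, abs=0.1)
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.1)


class TestAUC:
    DENS = np.array([0.1, 0.2, 0.3, 0.4, 0.5])

    def test_constant_series_maps_to_itself(self):
        assert gm.auc_over_sparsity(np.full(5, 3.7), self.DENS) == \
            pytest.approx(3.7)

    def test_linear_series_gives_midpoint(self):
        v = np.linspace(2.0, 6.0, 5)
        assert gm.auc_over_sparsity(v, self.DENS) == pytest.approx(4.0)

    def test_matches_manual_trapezoid(self):
        rng = np.random.default_rng(9)
        v = rng.standard_normal(5)
        manual = sum((v[i] + v[i + 1]) / 2 * (self.DENS[i + 1] - self.DENS[i])
                     for i in range(4)) / (self.DENS[-1] - self.DENS[0])
        assert gm.auc_over_sparsity(v, self.DENS) == pytest.approx(manual)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gm.auc_over_sparsity(np.ones(3), self.DENS)


class TestMetricTable:
    def _nets(self, a, densities):
        m = int(a.sum()) // 2
        n = a.shape[0]
        return [BinaryNetwork(a, d, m) for d in densities]

    def test_complete_graph_rows_are_unit(self):
        dens = [0.2, 0.4]
        kn = adj(nx.complete_graph(10))
        mt = gm.compute_metric_table(self._nets(kn, dens), dens, "kn",
                                     n_random=0)
        for d in dens:
            row = mt.global_metrics.loc[d]
            assert row["Cp"] == pytest.approx(1.0)
            assert row["Lp"] == pytest.approx(1.0)
            assert row["global_efficiency"] == pytest.approx(1.0)
            assert row["local_efficiency"] == pytest.approx(1.0)

    def test_lattice_like_subject_has_longer_paths_than_random_like(self):
        dens = [0.2, 0.3]
        lattice = adj(nx.watts_strogatz_graph(50, 8, 0.02, seed=1))
        random_g = adj(nx.watts_strogatz_graph(50, 8, 0.5, seed=1))
        mts = [gm.compute_metric_table(self._nets(a, dens), dens, n_random=0)
               for a in (lattice, random_g)]
        assert mts[0].auc_global["Lp"] > mts[1].auc_global["Lp"]

    def test_seeded_tables_identical(self):
        dens = [0.3]
        ws = adj(nx.connected_watts_strogatz_graph(30, 4, 0.2, seed=5))
        mts = [gm.compute_metric_table(
            self._nets(ws, dens), dens, n_random=3,
            rng=np.random.default_rng(7)) for _ in range(2)]
        assert mts[0].global_metrics.equals(mts[1].global_metrics)
        assert mts[0].auc_global.equals(mts[1].auc_global)

    def test_long_format_export(self):
        dens = [0.2]
        ws = adj(nx.connected_watts_strogatz_graph(12, 4, 0.2, seed=6))
        mt = gm.compute_metric_table(self._nets(ws, dens), dens, "s1",
                                     n_random=0)
        long = mt.to_long()
        assert set(long.columns) == {"subject_id", "density", "metric",
                                     "node_or_global", "value"}
        assert (long.subject_id == "s1").all()
        assert len(long[long.node_or_global == "global"]) == len(
            gm.GLOBAL_METRICS)
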