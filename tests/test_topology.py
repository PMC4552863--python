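import warnings

import networkx as nx
import numpy as np
import pytest
from scipy.stats import binomtest

from bdnevo.topology import (Connectome, build_ring_of_clusters,
                             generate_alt_cluster, generate_small_world_cluster,
                             load_connectome, save_cluster_labels,
                             save_connectome)


class TestSmallWorldCluster:
    def test_ring_lattice_without_rewiring(self):
        adj = generate_small_world_cluster(10, 4, 0.0, rng=0)
        assert (adj.sum(axis=1) == 4).all()
        assert adj.sum() // 2 == 20

    @pytest.mark.parametrize("p_rewire", [0.0, 0.1, 0.5, 1.0])
    def test_edge_count_conserved_under_rewiring(self, p_rewire):
        adj = generate_small_world_cluster(10, 4, p_rewire, rng=42)
        assert adj.sum() // 2 == 20

    def test_always_connected(self):
        for seed in range(30):
            adj = generate_small_world_cluster(20, 4, 0.3, rng=seed)
            assert nx.is_connected(nx.from_numpy_array(adj))

    @pytest.mark.parametrize("n,k", [(10, 3), (10, 1), (4, 4), (4, 6)])
    def test_rejects_bad_ring_parameters(self, n, k):
        with pytest.raises(ValueError):
            generate_small_world_cluster(n, k, 0.1, rng=0)


class TestAltClusters:
    def test_pure_star_degrees(self):
        adj = generate_alt_cluster("perturbed_star", 8, {"f": 0.0}, rng=0)
        degs = np.sort(adj.sum(axis=1))
        assert degs[-1] == 7
        assert (degs[:-1] == 1).all()

    def test_perturbed_star_conserves_edges(self):
        for seed in range(20):
            adj = generate_alt_cluster("perturbed_star", 10, {"f": 0.2}, rng=seed)
            assert adj.sum() // 2 == 9
            assert nx.is_connected(nx.from_numpy_array(adj))

    def test_barabasi_albert_edge_count(self):
        adj = generate_alt_cluster("barabasi_albert", 20, {"m": 3}, rng=1)
        assert adj.sum() // 2 == (20 - 3) * 3

    def test_complete_graph_limit(self):
        adj = generate_alt_cluster("erdos_renyi", 7, {"p": 1.0}, rng=0)
        assert adj.sum() // 2 == 21

    def test_er_edge_count_in_distribution(self):
        # connectivity conditioning is negligible at n=30, p=0.3
        n, p, reps = 30, 0.3, 40
        total = sum(int(generate_alt_cluster("erdos_renyi", n, {"p": p},
                                             rng=s).sum() // 2)
                    for s in range(reps))
        res = binomtest(total, reps * n * (n - 1) // 2, p)
        assert res.pvalue > 0.01

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown cluster kind"):
            generate_alt_cluster("regular", 10, rng=0)


class TestRingOfClusters:
    def test_sixty_neuron_six_cluster_model(self, ring60):
        assert ring60.n_neurons == 60
        assert len(np.unique(ring60.cluster_labels)) == 6
        assert ring60.is_connected()

    @pytest.mark.parametrize("seed", range(100))
    def test_invariants_over_seeds(self, seed):
        net = build_ring_of_clusters(3, 5, rng=np.random.default_rng(seed))
        A, B, labels = net.electrical_adj, net.chemical_adj, net.cluster_labels
        same_cluster = labels[:, None] == labels[None, :]
        # electrical strictly intra-cluster, chemical strictly inter-cluster
        assert not A[~same_cluster].any()
        assert not B[same_cluster].any()
        # chemical ring: N_c links forming a single cycle over hubs
        assert B.sum() // 2 == 3
        deg_b = B.sum(axis=1)
        assert set(deg_b[deg_b > 0]) == {2}
        assert net.is_connected()

    def test_hub_is_max_degree_smallest_index(self):
        net = build_ring_of_clusters(3, 8, rng=np.random.default_rng(5))
        for c in range(3):
            nodes = np.nonzero(net.cluster_labels == c)[0]
            hub = nodes[net.chemical_adj[nodes].sum(axis=1) > 0]
            degs = net.electrical_adj[np.ix_(nodes, nodes)].sum(axis=1)
            candidates = nodes[degs == degs.max()]
            assert hub[0] == candidates.min()

    @pytest.mark.parametrize("kind", ["erdos_renyi", "barabasi_albert",
                                      "perturbed_star"])
    def test_alternative_cluster_kinds(self, kind):
        net = build_ring_of_clusters(3, 6, cluster_kind=kind,
                                     rng=np.random.default_rng(2))
        assert net.n_neurons == 18
        assert net.is_connected()


class TestConnectomeType:
    def test_rejects_asymmetric(self):
        M = np.zeros((3, 3), dtype=np.int8)
        M[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            Connectome(M, np.zeros_like(M))

    def test_rejects_self_loops(self):
        M = np.eye(3, dtype=np.int8)
        with pytest.raises(ValueError, match="diagonal"):
            Connectome(M, np.zeros_like(M))

    def test_combined_is_binary_union(self, ring18):
        C = ring18.combined
        assert np.array_equal(
            C, (ring18.electrical_adj | ring18.chemical_adj))


class TestIO:
    @pytest.mark.parametrize("fmt", ["edge_list", "csv_matrix", "graphml"])
    def test_round_trip(self, tmp_path, ring18, fmt):
        ext = {"edge_list": "edges", "csv_matrix": "csv", "graphml": "graphml"}[fmt]
        path = str(tmp_path / f"net.{ext}")
        save_connectome(ring18, path, format=fmt, layer="combined")
        back = load_connectome(path, format=fmt)
        assert np.array_equal(back.electrical_adj, ring18.combined)

    def test_isolated_node_removed(self, tmp_path):
        M = np.zeros((4, 4), dtype=int)
        M[0, 1] = M[1, 0] = M[1, 2] = M[2, 1] = 1  # node 3 isolated
        path = tmp_path / "m.csv"
        np.savetxt(path, M, delimiter=",", fmt="%d")
        net = load_connectome(str(path), format="csv_matrix")
        assert net.n_neurons == 3

    def test_directed_edge_list_symmetrized(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("a b\nb c\n# comment\nc a\n")
        net = load_connectome(str(path), format="edge_list")
        assert net.n_neurons == 3
        assert net.electrical_adj.sum() // 2 == 3

    def test_self_loop_dropped_with_warning(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("a a\na b\n")
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            net = load_connectome(str(path), format="edge_list")
        assert any("self-loop" in str(w.message) for w in rec)
        assert net.n_neurons == 2

    def test_malformed_line_names_location(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("a b\nbroken\n")
        with pytest.raises(ValueError, match=":2:"):
            load_connectome(str(path), format="edge_list")

    def test_cluster_label_export(self, tmp_path, ring18):
        path = tmp_path / "labels.csv"
        save_cluster_labels(ring18, str(path))
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "node,label"
        assert len(lines) == ring18.n_neurons + 1
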