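import numpy as np
import pytest

import criticonn as cc
from criticonn.networks import DEFAULT_MODULE_SIZES


class TestWeightedNetwork:
    def test_rejects_negative_weights(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="non-negative"):
            cc.WeightedNetwork(w)

    def test_rejects_nonzero_diagonal(self):
        w = np.eye(3)
        with pytest.raises(ValueError, match="diagonal"):
            cc.WeightedNetwork(w)

    def test_rejects_asymmetric_undirected(self):
        w = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cc.WeightedNetwork(w, directed=False)
        assert cc.WeightedNetwork(w, directed=True).n_nodes == 2


class TestWattsStrogatz:
    def test_ring_without_rewiring_is_regular(self):
        net = cc.generate_ws_network(10, 2, 0.0, seed=0)
        degrees = (net.weights > 0).sum(axis=0)
        assert (degrees == 2).all()
        assert (net.weights > 0).sum() // 2 == 10

    @pytest.mark.parametrize("k", [2, 10])
    def test_edge_count_preserved_under_rewiring(self, k):
        net = cc.generate_ws_network(400, k, 0.5, seed=1)
        assert (net.weights > 0).sum() // 2 == 400 * k // 2

    def test_exponential_weight_mean(self):
        net = cc.generate_ws_network(2000, 10, 0.5, lam=12.5, seed=2)
        weights = net.weights[np.triu_indices(2000, 1)]
        weights = weights[weights > 0]
        assert weights.size == 10_000
        # exponential mean 1/lambda = 0.08, sampling error ~ 3 sd of the mean
        assert abs(weights.mean() - 0.08) < 3 * 0.08 / np.sqrt(weights.size)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            cc.generate_ws_network(10, 3, 0.5)  # odd k
        with pytest.raises(ValueError):
            cc.generate_ws_network(10, 10, 0.5)  # k >= n
        with pytest.raises(ValueError):
            cc.generate_ws_network(2, 2, 0.5)  # n too small

    def test_seed_determinism(self):
        a = cc.generate_ws_network(50, 4, 0.5, seed=3)
        b = cc.generate_ws_network(50, 4, 0.5, seed=3)
        assert np.array_equal(a.weights, b.weights)


class TestModularConnectome:
    def test_sizes_labels_and_auditory_module(self):
        net, parc = cc.generate_modular_connectome(
            998, list(DEFAULT_MODULE_SIZES), 24.0, 10.0, seed=4,
            module_names=list(cc.networks.DEFAULT_RSN_NAMES),
        )
        assert net.n_nodes == 998
        assert parc.nodes_of("auditory").size == 119

    def test_modules_internally_connected_and_denser_inside(self, tiny_connectome):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        net, parc = tiny_connectome
        labels = np.asarray(parc.labels, dtype=object)
        for lab in parc.label_set:
            idx = parc.nodes_of(lab)
            sub = net.weights[np.ix_(idx, idx)] > 0
            n_comp, _ = connected_components(csr_matrix(sub), directed=False)
            assert n_comp == 1
        same = labels[:, None] == labels[None, :]
        density_in = (net.weights > 0)[same].mean()
        density_out = (net.weights > 0)[~same].mean()
        assert density_in > density_out

    def test_seeded_determinism(self):
        a, _ = cc.generate_modular_connectome(20, [12, 8], 5.0, 1.0, seed=5)
        b, _ = cc.generate_modular_connectome(20, [12, 8], 5.0, 1.0, seed=5)
        assert np.array_equal(a.weights, b.weights)

    def test_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            cc.generate_modular_connectome(20, [12, 9], 5.0, 1.0, seed=0)


class TestNormalizeInStrength:
    def test_unit_in_strength(self, small_ws):
        norm = cc.normalize_in_strength(small_ws)
        np.testing.assert_allclose(norm.weights.sum(axis=1), 1.0, atol=1e-12)
        assert ((norm.weights > 0) == (small_ws.weights > 0)).all()

    def test_symmetric_input_becomes_directed(self):
        w = np.array([[0, 1, 2], [1, 0, 0], [2, 0, 0]], dtype=float)
        net = cc.WeightedNetwork(w)
        norm = cc.normalize_in_strength(net)
        assert norm.directed
        # w~_01 = 1/3 but w~_10 = 1: normalization breaks symmetry
        assert norm.weights[0, 1] == pytest.approx(1 / 3)
        assert norm.weights[1, 0] == pytest.approx(1.0)

    def test_idempotent(self, small_ws):
        once = cc.normalize_in_strength(small_ws)
        twice = cc.normalize_in_strength(once)
        np.testing.assert_allclose(once.weights, twice.weights, atol=1e-15)

    def test_zero_in_strength_names_node(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            cc.normalize_in_strength(cc.WeightedNetwork(w))


class TestLattice:
    @pytest.mark.parametrize(
        "spec,expected_edges",
        [
            (cc.LatticeSpec(2, 2), 4),
            (cc.LatticeSpec(100, 100), 19_800),
            (cc.LatticeSpec(100, 100, "equal_halves"), 19_700),
        ],
    )
    def test_edge_counts(self, spec, expected_edges):
        net, _ = cc.build_lattice(spec)
        assert (net.weights > 0).sum() // 2 == expected_edges

    def test_equal_halves_components(self):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        net, parc = cc.build_lattice(cc.LatticeSpec(100, 100, "equal_halves"))
        n_comp, comp = connected_components(csr_matrix(net.support()), directed=False)
        assert n_comp == 2
        assert sorted(np.bincount(comp)) == [5000, 5000]
        labels = np.asarray(parc.labels)
        assert (labels == "A").sum() == 5000 and (labels == "B").sum() == 5000

    def test_central_patch_sizes(self):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        net, parc = cc.build_lattice(cc.LatticeSpec(100, 100, "central_patch", patch_side=50))
        n_comp, comp = connected_components(csr_matrix(net.support()), directed=False)
        assert n_comp == 2
        assert sorted(np.bincount(comp)) == [2500, 7500]
        assert (np.asarray(parc.labels) == "B").sum() == 2500

    def test_patch_must_be_interior(self):
        with pytest.raises(ValueError):
            cc.LatticeSpec(10, 10, "central_patch", patch_side=9)
        with pytest.raises(ValueError):
            cc.LatticeSpec(10, 10, "central_patch", patch_side=0)


class TestIO:
    @pytest.mark.parametrize("fmt", ["matrix", "edgelist"])
    def test_round_trip(self, tmp_path, rng, fmt):
        from conftest import random_network

        net = random_network(rng, 5)
        path = tmp_path / "net.txt"
        cc.write_network(net, path, fmt=fmt)
        back = cc.read_network(path)
        np.testing.assert_array_equal(back.weights, net.weights)

    def test_directed_round_trip(self, tmp_path, rng):
        from conftest import random_network

        net = random_network(rng, 6, directed=True)
        path = tmp_path / "net.tsv"
        cc.write_network(net, path, fmt="edgelist")
        back = cc.read_network(path)
        np.testing.assert_array_equal(back.weights, net.weights)
        assert back.directed

    def test_comma_separated_matrix(self, tmp_path):
        path = tmp_path / "net.csv"
        path.write_text("0,0.5\n0.5,0\n")
        net = cc.read_network(path)
        assert net.weights[0, 1] == 0.5

    def test_rejects_self_loop_edge(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("0\t1\t0.5\n2\t2\t0.25\n")
        with pytest.raises(ValueError, match="self-loop"):
            cc.read_network(path)

    def test_rejects_negative_weight_with_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 1\n-1 0\n")
        with pytest.raises(ValueError, match="negative"):
            cc.read_network(path)

    def test_rejects_non_square(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 1.5 2.5\n1.5 0 1.5\n")
        with pytest.raises(ValueError, match="ragged|square"):
            cc.read_network(path)

    def test_parcellation_round_trip(self, tmp_path, tiny_connectome):
        _, parc = tiny_connectome
        path = tmp_path / "parc.tsv"
        cc.write_parcellation(parc, path)
        assert cc.read_parcellation(path).labels == parc.labels

    def test_parcellation_rejects_gaps(self, tmp_path):
        path = tmp_path / "parc.tsv"
        path.write_text("0\tA\n2\tB\n")
        with pytest.raises(ValueError, match="gaps"):
            cc.read_parcellation(path)
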