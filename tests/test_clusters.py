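import numpy as np
import pytest

import criticonn as cc
from conftest import random_network


def brute_force_sizes(state, net, mode):
    """Independent oracle: exhaustive BFS over the undirected support."""
    n = net.n_nodes
    sup = net.support()
    if mode == "active_only":
        eligible = np.asarray(state) == 1
    else:
        eligible = np.ones(n, dtype=bool)
    seen = np.zeros(n, dtype=bool)
    sizes = []
    for start in range(n):
        if not eligible[start] or seen[start]:
            continue
        queue = [start]
        seen[start] = True
        size = 0
        while queue:
            u = queue.pop()
            size += 1
            for v in range(n):
                if sup[u, v] and eligible[v] and not seen[v] and state[v] == state[u]:
                    seen[v] = True
                    queue.append(v)
        sizes.append(size)
    return sorted(sizes, reverse=True)


class TestFindClusters:
    def test_all_active_connected(self, small_ws):
        sizes = cc.find_clusters(np.ones(50), small_ws, mode="active_only")
        assert list(sizes) == [50]

    def test_checkerboard_spins_fragment(self):
        net, _ = cc.build_lattice(cc.LatticeSpec(2, 2))
        spins = np.array([1, -1, -1, 1])  # checkerboard: no same-spin bond
        sizes = cc.find_clusters(spins, net, mode="same_value")
        assert list(sizes) == [1, 1, 1, 1]

    def test_no_active_nodes(self, small_ws):
        sizes = cc.find_clusters(np.zeros(50), small_ws, mode="active_only")
        assert sizes.size == 0

    @pytest.mark.parametrize("mode", ["active_only", "same_value"])
    def test_matches_brute_force_oracle(self, rng, mode):
        for _ in range(200):
            n = int(rng.integers(2, 21))
            net = random_network(rng, n, p=0.3)
            state = rng.choice([0, 1] if mode == "active_only" else [-1, 1], size=n)
            got = list(cc.find_clusters(state, net, mode=mode))
            assert got == brute_force_sizes(state, net, mode)


class TestLargestTwo:
    @pytest.mark.parametrize(
        "sizes,expected",
        [([7, 3, 3, 1], (7, 3)), ([5], (5, 0)), ([], (0, 0))],
    )
    def test_padding_convention(self, sizes, expected):
        assert cc.largest_two(sizes) == expected


class TestClusterSeries:
    def test_series_kernel_matches_find_clusters(self, rng, small_ws):
        """The compiled per-step kernel agrees with the scipy-based single
        snapshot labelling for both modes."""
        raster = rng.choice([0, 1], size=(50, 40))
        series = cc.cluster_series(raster, small_ws, mode="active_only")
        for t in range(40):
            s1, s2 = cc.largest_two(cc.find_clusters(raster[:, t], small_ws, "active_only"))
            assert (series.s1[t], series.s2[t]) == (s1, s2)

        spins = rng.choice([-1, 1], size=(50, 20))
        series = cc.cluster_series(spins, small_ws, mode="same_value")
        for t in range(20):
            s1, s2 = cc.largest_two(cc.find_clusters(spins[:, t], small_ws, "same_value"))
            assert (series.s1[t], series.s2[t]) == (s1, s2)

    def test_sum_of_same_value_clusters_is_n(self, rng):
        net = random_network(rng, 15, p=0.3)
        spins = rng.choice([-1, 1], size=15)
        assert cc.find_clusters(spins, net, mode="same_value").sum() == 15

    def test_sum_of_active_clusters_is_active_count(self, rng):
        net = random_network(rng, 15, p=0.3)
        state = rng.choice([0, 1], size=15)
        assert cc.find_clusters(state, net, mode="active_only").sum() == state.sum()


class TestTimeAverage:
    def test_constant_series(self):
        series = cc.ClusterSeries(np.full(10, 4), np.full(10, 2))
        assert cc.time_average(series) == (4.0, 2.0)

    def test_two_point_mean(self):
        series = cc.ClusterSeries(np.array([2, 4]), np.array([0, 0]))
        assert cc.time_average(series)[0] == 3.0

    def test_matches_independent_recomputation(self, small_ws):
        params = cc.GHParams(threshold=0.02, r1=0.02, r2=0.3, t_max=100, t_init=20, seed=0)
        raster = cc.run_gh(small_ws, params)
        series = cc.cluster_series(raster.states, small_ws, mode="active_only")
        s1_bar, s2_bar = cc.time_average(series)
        manual = [
            cc.largest_two(cc.find_clusters(raster.states[:, t], small_ws, "active_only"))
            for t in range(raster.t_sim)
        ]
        assert s1_bar == pytest.approx(np.mean([m[0] for m in manual]))
        assert s2_bar == pytest.approx(np.mean([m[1] for m in manual]))


class TestSubsystemSeries:
    def test_label_covering_all_nodes_equals_whole(self, rng, small_ws):
        parc = cc.Parcellation(["X"] * 50)
        raster = rng.choice([0, 1], size=(50, 10))
        whole = cc.cluster_series(raster, small_ws, mode="active_only")
        sub = cc.subsystem_series(raster, small_ws, parc, "X")
        assert np.array_equal(whole.s1, sub.s1) and np.array_equal(whole.s2, sub.s2)

    def test_unknown_label_rejected(self, rng, small_ws):
        parc = cc.Parcellation(["X"] * 50)
        with pytest.raises(ValueError, match="unknown"):
            cc.subsystem_series(rng.choice([0, 1], size=(50, 5)), small_ws, parc, "Y")

    def test_disconnected_subsystem_clusters_are_restrictions(self, rng):
        net, parc = cc.build_lattice(cc.LatticeSpec(6, 6, "equal_halves"))
        spins = rng.choice([-1, 1], size=(36, 15))
        mask_b = parc.mask_of("B")
        sub = cc.subsystem_series(spins, net, parc, "B", mode="same_value")
        # no cross edges: subsystem clusters are whole-system clusters
        # intersected with the subsystem
        for t in range(15):
            masked_state = np.where(mask_b, spins[:, t], 99)
            sizes = [
                s for s in _masked_sizes(masked_state, net) if s > 0
            ]
            top = sorted(sizes, reverse=True) + [0, 0]
            assert (sub.s1[t], sub.s2[t]) == (top[0], top[1])


def _masked_sizes(state, net):
    sup = net.support()
    n = net.n_nodes
    eligible = state != 99
    seen = np.zeros(n, dtype=bool)
    sizes = []
    for start in range(n):
        if not eligible[start] or seen[start]:
            continue
        queue = [start]
        seen[start] = True
        size = 0
        while queue:
            u = queue.pop()
            size += 1
            for v in range(n):
                if sup[u, v] and eligible[v] and not seen[v] and state[v] == state[u]:
                    seen[v] = True
                    queue.append(v)
        sizes.append(size)
    return sizes


class TestOrderingDecomposition:
    def test_direct_selection(self):
        a = cc.ClusterSeries(np.array([10]), np.array([4]))
        b = cc.ClusterSeries(np.array([6]), np.array([3]))
        pred = cc.ordering_decomposition(a, b)
        assert (pred.s1[0], pred.s2[0]) == (10, 6)

    def test_competition_won_by_second_cluster_of_a(self):
        # S2^A = 7 beats S1^B = 6 for the whole-system runner-up slot
        a = cc.ClusterSeries(np.array([10]), np.array([7]))
        b = cc.ClusterSeries(np.array([6]), np.array([3]))
        pred = cc.ordering_decomposition(a, b)
        assert (pred.s1[0], pred.s2[0]) == (10, 7)

    def test_misaligned_series_rejected(self):
        a = cc.ClusterSeries(np.array([5, 5]), np.array([1, 1]))
        b = cc.ClusterSeries(np.array([5]), np.array([1]))
        with pytest.raises(ValueError):
            cc.ordering_decomposition(a, b)

    def test_exact_identity_on_divided_ising_run(self):
        """For a fully divided lattice the whole-system (S1, S2) equals the
        rank-1/rank-2 selection from the subsystem clusters at every step."""
        net, parc = cc.build_lattice(cc.LatticeSpec(10, 10, "central_patch", patch_side=4))
        params = cc.IsingParams(temperature=2.3, t_max=150, t_init=50, seed=7)
        raster = cc.run_ising(net, params)
        whole = cc.cluster_series(raster.spins, net, mode="same_value")
        sub_a = cc.subsystem_series(raster.spins, net, parc, "A", mode="same_value")
        sub_b = cc.subsystem_series(raster.spins, net, parc, "B", mode="same_value")
        pred = cc.ordering_decomposition(sub_a, sub_b)
        assert np.array_equal(whole.s1, pred.s1)
        assert np.array_equal(whole.s2, pred.s2)
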