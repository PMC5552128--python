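"""Network generators and weighted-directed measures vs brute-force oracles."""

import itertools

import numpy as np
import pytest

from neurosnake import wirednet as wn

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def clustering_oracle(W):
    """Triple-loop triad-product clustering coefficient (Fagiolo form)."""
    A = (np.abs(W) > 0).astype(float)
    n = W.shape[0]
    wmax = np.abs(W).max()
    if wmax == 0:
        return np.zeros(n)
    What = np.abs(W) / wmax
    C = np.zeros(n)
    for i in range(n):
        num = 0.0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) < 3:
                    continue
                # all 8 directed closed triads through i, as cube roots
                num += (
                    (What[i, j] ** (1 / 3) + What[j, i] ** (1 / 3))
                    * (What[j, k] ** (1 / 3) + What[k, j] ** (1 / 3))
                    * (What[k, i] ** (1 / 3) + What[i, k] ** (1 / 3))
                )
        k_tot = A[:, i].sum() + A[i, :].sum()
        k_bi = (A[i, :] * A[:, i]).sum()
        den = 2.0 * (k_tot * (k_tot - 1) - 2 * k_bi)
        C[i] = num / den if den > 0 else 0.0
    return C


def floyd_warshall_oracle(W):
    """Average inverse-|w| shortest path over reachable ordered pairs."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for j in range(n):
        for i in range(n):
            if i != j and W[j, i] != 0:
                D[j, i] = 1.0 / abs(W[j, i])
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    return D[finite].mean(), int(off.sum() - finite.sum())


def random_digraph(n, rng, p_edge=0.35):
    W = rng.uniform(-1, 1, (n, n)) * (rng.random((n, n)) < p_edge)
    np.fill_diagonal(W, 0)
    return W


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


class TestRegular:
    def test_ring_degree_and_edges(self, rng):
        net = wn.build_regular(6, 1, n_interface=2, rng=rng)
        A = net.adjacency
        assert A.sum() == 12
        assert (A.sum(axis=0) == 2).all() and (A.sum(axis=1) == 2).all()

    def test_edge_count_formula(self, rng):
        net = wn.build_regular(200, 2, rng=rng)
        assert net.adjacency.sum() == 2 * 200 * 2

    def test_ring_clustering_closed_form(self, rng):
        # k=4 ring lattice: every node's unweighted clustering is 1/2
        net = wn.build_regular(200, 2, rng=rng)
        C, cbar = wn.clustering_coefficient(net.weight_matrix)
        assert np.allclose(C, 0.5)
        assert cbar == pytest.approx(0.5)

    def test_invalid_parameters(self, rng):
        with pytest.raises(wn.InvalidParameterError):
            wn.build_regular(4, 2, n_interface=2, rng=rng)


class TestWattsStrogatz:
    def test_p_zero_is_regular(self, rng):
        reg = wn.build_regular(50, 2, n_interface=5, rng=np.random.default_rng(7))
        ws = wn.build_ws(50, 2, 0.0, np.random.default_rng(7), n_interface=5)
        assert np.array_equal(reg.weight_matrix, ws.weight_matrix)

    @pytest.mark.parametrize("p", [0.05, 0.5, 1.0])
    def test_edge_count_conserved(self, p, rng_factory):
        for seed in range(5):
            net = wn.build_ws(60, 2, p, rng_factory(seed), n_interface=6)
            assert net.adjacency.sum() == 2 * 60 * 2
            assert np.array_equal(net.weight_matrix, net.weight_matrix.T)

    def test_small_world_regime(self, rng_factory):
        """p=0.05 sits between lattice clustering and random-graph paths."""
        stats = {p: {"C": [], "L": []} for p in (0.0, 0.05, 1.0)}
        for p in stats:
            for seed in range(25):
                net = wn.build_ws(200, 2, p, rng_factory(seed), n_interface=26)
                _, cbar = wn.clustering_coefficient(net.weight_matrix)
                spl, _ = wn.shortest_path_length(net.weight_matrix)
                stats[p]["C"].append(cbar)
                stats[p]["L"].append(spl)
        mean = {p: {k: np.mean(v) for k, v in d.items()} for p, d in stats.items()}
        assert mean[1.0]["C"] < mean[0.05]["C"] < mean[0.0]["C"]
        # small-world regime: path length collapses most of the way toward
        # the random graph (empirically ~2.05x the p=1 mean for n=200, m=2)
        assert mean[0.05]["L"] < 2.5 * mean[1.0]["L"]
        assert mean[0.05]["L"] < 0.5 * mean[0.0]["L"]


class TestBarabasiAlbert:
    def test_edge_count(self, rng):
        net = wn.build_ba(200, 2, 1, rng)
        # undirected attachment edges, symmetrised: (n - m0) * m each way
        assert net.adjacency.sum() == 2 * (200 - 2) * 1

    def test_heavy_tail(self, rng_factory):
        ratios = []
        for seed in range(50):
            net = wn.build_ba(500, 2, 1, rng_factory(seed), n_interface=26)
            deg = net.adjacency.sum(axis=0)
            ratios.append(deg.max() / max(np.median(deg), 1))
        assert np.mean(np.array(ratios) > 5) > 0.8

    def test_smallest_instance(self, rng):
        net = wn.build_ba(3, 2, 1, rng, n_interface=1)
        assert net.adjacency.sum() == 2  # one undirected edge
        assert net.adjacency[2].sum() + net.adjacency[:, 2].sum() == 2

    def test_invalid_parameters(self, rng):
        with pytest.raises(wn.InvalidParameterError):
            wn.build_ba(10, 2, 2, rng, n_interface=2)


class TestAssignWeights:
    def test_uniform_equals_adjacency(self, rng):
        net = wn.build_ws(40, 2, 0.3, rng, n_interface=4)
        out = wn.assign_weights(net, "uniform")
        assert np.array_equal(out.weight_matrix, net.adjacency.astype(float))

    def test_random_normalisation(self, rng):
        net = wn.build_ws(40, 2, 0.3, rng, n_interface=4)
        out = wn.assign_weights(net, "random", rng)
        sums = np.abs(out.weight_matrix).sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_normalisation_example(self):
        # raw (1.0, -3.0) -> (0.25, -0.75)
        raw = np.array([1.0, -3.0])
        normalised = raw / np.abs(raw).sum()
        assert np.allclose(normalised, [0.25, -0.75])

    def test_idempotent(self, rng):
        net = wn.build_ws(40, 2, 0.3, rng, n_interface=4)
        out = wn.assign_weights(net, "random", rng)
        sums = np.abs(out.weight_matrix).sum(axis=0)
        renorm = out.weight_matrix / sums
        assert np.allclose(renorm, out.weight_matrix, atol=1e-12)

    def test_roles_count(self, rng):
        net = wn.build_ws(200, 2, 0.05, rng)
        assert (net.roles == "interface").sum() == 26
        assert (net.roles == "hidden").sum() == 174


# ---------------------------------------------------------------------------
# Measures vs oracles
# ---------------------------------------------------------------------------


class TestClustering:
    def test_reciprocal_three_cycle(self):
        W = np.ones((3, 3)) - np.eye(3)
        C, cbar = wn.clustering_coefficient(W)
        assert np.allclose(C, 1.0)

    def test_edgeless(self):
        C, cbar = wn.clustering_coefficient(np.zeros((5, 5)))
        assert cbar == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_random_digraphs_vs_oracle(self, seed):
        W = random_digraph(12, np.random.default_rng(seed))
        C, _ = wn.clustering_coefficient(W)
        assert np.allclose(C, clustering_oracle(W), atol=1e-9)

    def test_small_digraphs_exhaustive_support(self):
        """All adjacency patterns on 3 nodes, random weights on the support."""
        rng = np.random.default_rng(0)
        offdiag = [(i, j) for i in range(3) for j in range(3) if i != j]
        for bits in range(2 ** 6):
            W = np.zeros((3, 3))
            for b, (i, j) in enumerate(offdiag):
                if bits >> b & 1:
                    W[i, j] = rng.uniform(0.2, 1.0) * rng.choice([-1, 1])
            C, _ = wn.clustering_coefficient(W)
            assert np.allclose(C, clustering_oracle(W), atol=1e-9)


class TestShortestPath:
    def test_single_edge(self):
        W = np.zeros((2, 2))
        W[0, 1] = 0.5
        spl, unreachable = wn.shortest_path_length(W)
        assert spl == pytest.approx(2.0)
        assert unreachable == 1

    def test_two_hop_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = 1.0
        W[1, 2] = 1.0
        spl, _ = wn.shortest_path_length(W)
        # distances: a->b 1, b->c 1, a->c 2; average over 3 reachable pairs
        assert spl == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(30))
    def test_random_digraphs_vs_oracle(self, seed):
        W = random_digraph(12, np.random.default_rng(seed))
        expected, exp_unreach = floyd_warshall_oracle(W)
        spl, unreach = wn.shortest_path_length(W)
        assert spl == pytest.approx(expected, abs=1e-9)
        assert unreach == exp_unreach

    def test_disconnected_raises(self):
        with pytest.raises(wn.DegenerateNetworkError):
            wn.shortest_path_length(np.zeros((4, 4)))


class TestDegrees:
    def test_uniform_in_degree(self, rng):
        net = wn.build_regular(20, 2, n_interface=2, rng=rng)
        deg, dmax = wn.node_degrees(net.weight_matrix)
        assert np.allclose(deg, 4.0)
        assert dmax == pytest.approx(4.0)

    def test_random_scheme_degree_is_one(self, rng):
        net = wn.assign_weights(wn.build_ws(40, 2, 0.2, rng, n_interface=4),
                                "random", rng)
        deg, _ = wn.node_degrees(net.weight_matrix)
        assert np.allclose(deg, 1.0, atol=1e-9)

    def test_ba_hubs_dominate_regular(self, rng_factory):
        wins = 0
        for seed in range(100):
            rng = rng_factory(seed)
            ba = wn.build_ba(100, 2, 1, rng, n_interface=10)
            reg = wn.build_regular(100, 2, n_interface=10, rng=rng)
            _, ba_max = wn.node_degrees(ba.weight_matrix)
            _, reg_max = wn.node_degrees(reg.weight_matrix)
            wins += ba_max > reg_max
        assert wins >= 95


class TestInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        W = random_digraph(10, rng)
        perm = rng.permutation(10)
        Wp = W[np.ix_(perm, perm)]
        C, cbar = wn.clustering_coefficient(W)
        Cp, cbarp = wn.clustering_coefficient(Wp)
        assert np.allclose(C[perm], Cp, atol=1e-12)
        spl, _ = wn.shortest_path_length(np.abs(W) + np.eye(10) * 0)
        splp, _ = wn.shortest_path_length(np.abs(Wp))
        assert spl == pytest.approx(splp, abs=1e-12)

    def test_save_load_roundtrip(self, rng, tmp_path):
        net = wn.assign_weights(wn.build_ws(30, 2, 0.1, rng, n_interface=4),
                                "random", rng)
        path = tmp_path / "net.edgelist"
        wn.save_network(net, str(path))
        back = wn.load_network(str(path))
        assert np.array_equal(back.weight_matrix, net.weight_matrix)
        assert np.array_equal(back.roles, net.roles)
        assert back.topology_tag == net.topology_tag
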