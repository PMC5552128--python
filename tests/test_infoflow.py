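"""KSG estimators vs Gaussian closed forms; IRM; information-network measures."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from neurosnake import infoflow as inf
from neurosnake import synthvalid as sv
from neurosnake import wirednet as wn


class TestKSGMutualInformation:
    def test_independent_gaussians_near_zero(self, rng):
        mi = inf.ksg_mutual_information(rng.normal(size=5000),
                                        rng.normal(size=5000))
        assert abs(mi) < 0.03

    def test_correlated_gaussians_closed_form(self, rng):
        rho = 0.8
        z = rng.normal(size=(5000, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
        mi = inf.ksg_mutual_information(x, y)
        assert mi == pytest.approx(sv.analytic_gaussian_mi(rho), abs=0.05)

    def test_independent_cross_check_sklearn(self, rng):
        """sklearn's kNN MI estimator agrees as an independent implementation."""
        from sklearn.feature_selection import mutual_info_regression

        rho = 0.6
        z = rng.normal(size=(4000, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
        ours = inf.ksg_mutual_information(x, y)
        theirs = mutual_info_regression(x[:, None], y, n_neighbors=4,
                                        random_state=0)[0]
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_identical_series_finite(self, rng):
        x = rng.normal(size=1000)
        mi = inf.ksg_mutual_information(x, x)
        assert np.isfinite(mi) and mi > 1.0

    def test_constant_series_zero(self, rng):
        assert inf.ksg_mutual_information(np.ones(500), rng.normal(size=500)) == 0.0

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            inf.ksg_mutual_information(rng.normal(size=50), rng.normal(size=50))


class TestKSGTransferEntropy:
    def test_independent_ar_pairs_near_zero(self, rng):
        x1 = sv.gaussian_var_pair(0.5, 0.0, 10_000, rng).data["x"]
        x2 = sv.gaussian_var_pair(0.5, 0.0, 10_000, rng).data["x"]
        assert abs(inf.ksg_transfer_entropy(x1, x2)) < 0.02

    def test_driven_pair_closed_form(self, rng):
        fx = sv.gaussian_var_pair(0.5, 0.5, 10_000, rng)
        te = inf.ksg_transfer_entropy(fx.data["y"], fx.data["x"])
        assert te == pytest.approx(fx.ground_truth["te_y_to_x"], abs=0.05)

    def test_no_feedback_direction(self, rng):
        fx = sv.gaussian_var_pair(0.5, 0.5, 10_000, rng)
        te_rev = inf.ksg_transfer_entropy(fx.data["x"], fx.data["y"])
        assert abs(te_rev) < 0.02

    def test_estimator_accuracy_across_seeds(self):
        """Mean |error| against the closed form stays within 0.05 nats."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fx = sv.gaussian_var_pair(0.5, 0.5, 10_000, rng)
            te = inf.ksg_transfer_entropy(fx.data["y"], fx.data["x"])
            errs.append(abs(te - fx.ground_truth["te_y_to_x"]))
        assert np.mean(errs) < 0.05

    def test_shuffled_source_loses_information(self, rng):
        fx = sv.gaussian_var_pair(0.5, 0.5, 4000, rng)
        te_coupled = inf.ksg_transfer_entropy(fx.data["y"], fx.data["x"])
        below = 0
        for _ in range(20):
            y_shuf = rng.permutation(fx.data["y"])
            below += inf.ksg_transfer_entropy(y_shuf, fx.data["x"]) < te_coupled
        assert below >= 19

    def test_higher_history_not_implemented(self, rng):
        with pytest.raises(NotImplementedError):
            inf.ksg_transfer_entropy(rng.normal(size=1000),
                                     rng.normal(size=1000), l_hist=2)


class TestEstimateInfoNetwork:
    def test_driver_has_top_outgoing_te(self, rng):
        fx = sv.driven_panel(10, driver=0, driven=[1, 2, 3], n=3000,
                             rng=rng, coupling=0.8)
        roles = np.array(["hidden"] * 10, dtype=object)
        net = inf.estimate_info_network(fx.data["x"], np.ones(3000, dtype=bool),
                                        roles, min_samples=500)
        te = net.te_matrix
        top3 = np.argsort(te[0])[::-1][:3]
        assert set(top3.tolist()) == {1, 2, 3}

    def test_iid_panel_below_null(self, rng):
        X = rng.normal(size=(2000, 6))
        roles = np.array(["hidden"] * 6, dtype=object)
        net = inf.estimate_info_network(X, np.ones(2000, dtype=bool), roles)
        off = ~np.eye(6, dtype=bool)
        assert np.abs(net.te_matrix[off]).max() < 0.03

    def test_deterministic(self, rng):
        X = rng.normal(size=(800, 4)).cumsum(axis=0)
        roles = np.array(["hidden"] * 4, dtype=object)
        nets = [inf.estimate_info_network(X, np.ones(800, dtype=bool), roles)
                for _ in range(2)]
        assert np.array_equal(nets[0].te_matrix, nets[1].te_matrix)
        assert np.array_equal(nets[0].mi_matrix, nets[1].mi_matrix)

    def test_short_segment_skipped(self, rng):
        X = rng.normal(size=(400, 4))
        roles = np.array(["hidden"] * 4, dtype=object)
        out = inf.estimate_info_network(X, np.ones(400, dtype=bool), roles,
                                        min_samples=500)
        assert out is None


class TestBinarizeOtsu:
    def test_two_valued_exact_split(self):
        M = np.full((5, 5), 0.1)
        M[0, 1] = M[2, 3] = M[4, 0] = 0.9
        np.fill_diagonal(M, 0)
        B = inf.binarize_otsu_matrix(M)
        assert B.sum() == 3
        assert B[0, 1] == B[2, 3] == B[4, 0] == 1

    def test_blockmodel_recovery(self, rng):
        fx = sv.planted_blockmodel(30, 3, 0.9, 0.05, rng)
        A = fx.data["adjacency"].astype(float)
        noisy = A * rng.uniform(0.6, 1.0, A.shape) + (1 - A) * rng.uniform(0, 0.25, A.shape)
        np.fill_diagonal(noisy, 0)
        B = inf.binarize_otsu_matrix(noisy)
        off = ~np.eye(30, dtype=bool)
        agreement = (B[off] == A[off]).mean()
        assert agreement >= 0.95

    def test_constant_offdiagonal_rejected(self):
        M = np.ones((4, 4)) * 0.3
        np.fill_diagonal(M, 0)
        with pytest.raises(inf.DegenerateInputError):
            inf.binarize_otsu_matrix(M)


class TestIRM:
    def test_all_ones_single_block(self):
        R = np.ones((8, 8), dtype=int) - np.eye(8, dtype=int)
        part = inf.irm_fit(R, rng=np.random.default_rng(0))
        assert np.unique(part).size == 1

    def test_empty_single_block(self):
        part = inf.irm_fit(np.zeros((8, 8), dtype=int),
                           rng=np.random.default_rng(0))
        assert np.unique(part).size == 1

    def test_planted_blocks_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fx = sv.planted_blockmodel(30, 3, 0.9, 0.05, rng)
            part = inf.irm_fit(fx.data["adjacency"], 1.0, 7.0, n_sweeps=30,
                               rng=rng)
            hits += adjusted_rand_score(fx.ground_truth["partition"], part) >= 0.9
        assert hits >= 18

    def test_partition_exhaustive_and_relabelled(self, rng):
        fx = sv.planted_blockmodel(20, 2, 0.8, 0.1, rng)
        part = inf.irm_fit(fx.data["adjacency"], rng=rng)
        assert part.size == 20
        labs = np.unique(part)
        assert labs[0] == 0 and (np.diff(labs) == 1).all()

    def test_greedy_final_sweep_non_decreasing(self, rng):
        """The returned partition scores at least as well as a random one."""
        fx = sv.planted_blockmodel(24, 3, 0.85, 0.1, rng)
        R = fx.data["adjacency"]
        part = inf.irm_fit(R, rng=np.random.default_rng(1))
        lp = inf.irm_log_posterior(R, part)
        for seed in range(5):
            random_part = np.random.default_rng(seed).integers(0, 3, 24)
            assert lp >= inf.irm_log_posterior(R, random_part)

    def test_non_binary_rejected(self, rng):
        M = rng.uniform(size=(6, 6))
        np.fill_diagonal(M, 0)
        with pytest.raises(inf.DegenerateInputError):
            inf.irm_fit(M)

    def test_block_order_and_overlay(self):
        part = np.array([1, 0, 1, 0, 2])
        order = inf.block_order(part)
        assert (np.sort(part[order]) == part[order]).all()
        te = np.arange(25, dtype=float).reshape(5, 5)
        np.fill_diagonal(te, 0)
        overlay = inf.block_te_overlay(te, part)
        assert overlay.shape == (3, 3)
        # block 0 = nodes {1,3}: mean of te[1,3], te[3,1]
        assert overlay[0, 0] == pytest.approx((te[1, 3] + te[3, 1]) / 2)


class TestMeasuresAndInfluence:
    def test_zero_te_degenerate(self):
        roles = np.array(["hidden"] * 4, dtype=object)
        net = inf.InfoNetwork(np.zeros((4, 4)), np.zeros((4, 4)), 0, 10.0, roles)
        m = inf.info_network_measures(net)
        assert m.avg_clustering == 0.0
        assert np.isnan(m.avg_shortest_path)

    def test_hand_built_matrix_vs_oracle(self):
        te = np.array([[0, 0.2, 0.0, 0.1],
                       [0.3, 0, 0.4, 0.0],
                       [0.0, 0.1, 0, 0.2],
                       [0.2, 0.0, 0.3, 0]])
        roles = np.array(["hidden"] * 4, dtype=object)
        net = inf.InfoNetwork(te, te, 0, 10.0, roles)
        m = inf.info_network_measures(net)
        from test_wirednet import clustering_oracle, floyd_warshall_oracle

        assert np.allclose(m.clustering_per_node, clustering_oracle(te), atol=1e-9)
        spl, _ = floyd_warshall_oracle(te)
        assert m.avg_shortest_path == pytest.approx(spl, abs=1e-9)

    def test_te_scaling_property(self):
        rng = np.random.default_rng(0)
        te = rng.uniform(0, 0.5, (6, 6))
        np.fill_diagonal(te, 0)
        roles = np.array(["hidden"] * 6, dtype=object)
        m1 = inf.info_network_measures(inf.InfoNetwork(te, te, 0, 1.0, roles))
        m2 = inf.info_network_measures(inf.InfoNetwork(2 * te, te, 0, 1.0, roles))
        assert m2.avg_shortest_path == pytest.approx(m1.avg_shortest_path / 2)
        assert m2.avg_clustering == pytest.approx(m1.avg_clustering, abs=1e-12)

    def test_influence_uniform(self):
        roles = np.array(["hidden", "hidden", "interface", "interface"],
                         dtype=object)
        te = np.full((4, 4), 0.3)
        np.fill_diagonal(te, 0)
        net = inf.InfoNetwork(te, te, 0, 5.0, roles)
        s = inf.body_influence(net)
        assert s.te_hidden_to_interface == pytest.approx(0.3)
        assert s.te_interface_to_hidden == pytest.approx(0.3)

    def test_influence_elevated_block(self):
        roles = np.array(["hidden"] * 3 + ["interface"] * 3, dtype=object)
        te = np.full((6, 6), 0.1)
        te[np.ix_([0, 1, 2], [3, 4, 5])] = 0.5  # hidden -> interface elevated
        np.fill_diagonal(te, 0)
        net = inf.InfoNetwork(te, te, 0, 5.0, roles)
        s = inf.body_influence(net)
        assert s.te_hidden_to_interface > s.te_interface_to_hidden

    def test_influence_zero(self):
        roles = np.array(["hidden", "interface"], dtype=object)
        net = inf.InfoNetwork(np.zeros((2, 2)), np.zeros((2, 2)), 0, 1.0, roles)
        s = inf.body_influence(net)
        assert s.te_hidden_to_interface == 0.0 and s.te_interface_to_hidden == 0.0
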