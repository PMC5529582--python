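import numpy as np
import pytest

from contextconn import independence as ind
from contextconn._utils import correlation_distance


class TestContextualCentroids:
    def test_single_state_is_global_mean(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((20, 6))
        cents = ind.contextual_centroids(z, np.zeros(20, dtype=int))
        np.testing.assert_allclose(cents[0], z.mean(axis=0))

    def test_disjoint_states_give_submeans(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((10, 4))
        assign = np.array([0] * 4 + [1] * 6)
        cents = ind.contextual_centroids(z, assign)
        np.testing.assert_allclose(cents[0], z[:4].mean(axis=0))
        np.testing.assert_allclose(cents[1], z[4:].mean(axis=0))

    def test_empty_state_rejected(self):
        with pytest.raises(ValueError, match="state 1"):
            ind.contextual_centroids(np.zeros((5, 3)), np.array([0, 0, 2, 2, 2]))


class TestWcssError:
    def test_centroids_containing_every_window_give_zero(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((8, 5))
        assert ind.wcss_error(z, z) == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_centroid_gives_w(self):
        # window rows and the centroid are zero-mean and exactly orthogonal,
        # so every correlation distance is 1 and the WCSS is W * 1^2
        rng = np.random.default_rng(3)
        w = 12
        a, b = rng.standard_normal((2, w))
        z = np.column_stack([np.zeros((w, 2)), a, -a, b, -b])
        c = np.array([[1.0, -1.0, 0.0, 0.0, 0.0, 0.0]])
        assert ind.wcss_error(z, c) == pytest.approx(w * 1.0, abs=1e-9)

    def test_nearest_assignment_never_worse_than_labels(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((6, 8))
        labels = np.array([0, 0, 1, 1, 1, 0])
        cents = ind.contextual_centroids(z, labels)
        # label-assignment WCSS computed by direct enumeration
        d = correlation_distance(z, cents)
        labelled = float(np.sum(d[np.arange(6), labels] ** 2))
        assert ind.wcss_error(z, cents) <= labelled + 1e-12

    def test_constant_window_skipped_with_warning(self):
        z = np.vstack([np.ones(4), np.random.default_rng(5).standard_normal((3, 4))])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = ind.wcss_error(z, z[1:2])
        assert np.isfinite(out)


class TestBounds:
    def test_k_equals_w_upper_bound_zero(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal((6, 5))
        _, _, obj = ind.correlation_kmeans(z, k=6, restarts=3, seed=0)
        assert obj == pytest.approx(0.0, abs=1e-12)

    def test_upper_below_lower_across_seeds(self, default_fixture):
        dyn = default_fixture["dyn"]
        partition = default_fixture["partition"]
        cz = ind.cortex_windows_z(dyn)
        from contextconn._utils import edge_columns_for_nodes, fisher_z
        node_idx = [i for i, nid in enumerate(dyn.node_ids)
                    if partition.assignment.get(nid) == "net1"]
        cortex_nodes = np.nonzero(dyn.is_cortical)[0]
        local = {g: i for i, g in enumerate(cortex_nodes)}
        net_cols = edge_columns_for_nodes(
            np.array([local[i] for i in node_idx]), cortex_nodes.size
        )
        for seed in (0, 1):
            wcss, model = ind.subsystem_wcss(dyn, node_idx, 3, restarts=5, seed=seed, cortex_z=cz)
            upper, lower = ind.wcss_bounds(
                cz, 3, model.assignments, net_cols, fisher_z(model.centroids),
                restarts=5, seed=seed,
            )
            assert upper < lower
            assert upper <= wcss + 1e-6
            assert wcss <= lower * 1.02

    def test_constant_network_columns_degenerate_to_time_average(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((30, 10))
        net_cols = np.array([0, 1])
        z[:, net_cols] = 0.3  # constant in time
        from contextconn.state_detection import fit_ncstates
        model = fit_ncstates(z[:, net_cols], 2, restarts=3, seed=0)
        hybrid_wcss = ind.wcss_bounds(z, 2, model.assignments, net_cols, model.centroids,
                                      restarts=3, seed=0)[1]
        single = ind.wcss_error(z, z.mean(axis=0, keepdims=True))
        assert hybrid_wcss == pytest.approx(single, rel=1e-9)


class TestScore:
    def test_anchor_values_exact(self):
        null = np.array([8.0, 10.0, 12.0])
        assert ind.independence_score(5.0, 5.0, 20.0, null) == -1.0
        assert ind.independence_score(10.0, 5.0, 20.0, null) == 0.0
        assert ind.independence_score(20.0, 5.0, 20.0, null) == 1.0

    def test_strictly_decreasing_in_interdependence(self):
        null = np.array([10.0])
        xs = np.linspace(5, 20, 31)
        scores = [ind.independence_score(x, 5.0, 20.0, null) for x in xs]
        assert np.all(np.diff(scores) > 0)  # higher WCSS -> more independent

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert ind.independence_score(3.0, 5.0, 20.0, np.array([10.0])) == -1.0

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ind.independence_score(10.0, 10.0, 20.0, np.array([10.0]))


class TestIndependenceTest:
    def test_above_all_null_values(self):
        null = np.arange(199, dtype=float)
        assert ind.independence_test(500.0, null) == pytest.approx(1 / 200)

    def test_at_null_median(self):
        null = np.arange(199, dtype=float)
        assert ind.independence_test(99.0, null) == pytest.approx(0.5, abs=0.01)

    def test_small_null_rejected(self):
        with pytest.raises(ValueError):
            ind.independence_test(1.0, np.zeros(5))


class TestMeanConcordance:
    def test_perfect_coupling_gives_ln_k(self):
        seq = np.tile(np.arange(4), 50)
        pos, neg = ind.mean_concordance_independence(seq, seq)
        assert pos == pytest.approx(np.log(4))
        assert np.isnan(neg)  # off-diagonal cells are empty, not negative

    def test_independent_sequences_shrink(self):
        rng = np.random.default_rng(8)
        pos, neg = ind.mean_concordance_independence(
            rng.integers(0, 3, 20_000), rng.integers(0, 3, 20_000)
        )
        assert abs(pos) < 0.05 and abs(neg) < 0.05

    def test_signs_partition_cells(self):
        rng = np.random.default_rng(9)
        a, b = rng.integers(0, 3, 300), rng.integers(0, 3, 300)
        from contextconn import context
        c = context.concordance(a, b).C
        pos, neg = ind.mean_concordance_independence(a, b)
        finite = c[np.isfinite(c)]
        expect_pos = finite[finite > 0]
        if expect_pos.size:
            assert pos == pytest.approx(expect_pos.mean())


class TestPseudoNetworks:
    def test_draws_are_unique_sorted_subsets(self):
        pns = ind.draw_pseudo_networks(np.arange(30), size=8, n_pseudo=20, seed=0, k=3)
        for pn in pns:
            assert len(pn.nodes) == 8 == len(set(pn.nodes))
            assert pn.nodes == sorted(pn.nodes)
            assert pn.k == 3

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ind.PseudoNetwork(nodes=[1], k=2)


class TestAssayAgreement:
    def test_wcss_and_concordance_rank_hub_set_as_more_interdependent(self, hub_fixture):
        """The two independence assays order a modular network and the
        planted hub block the same way: the hub block explains more cortex
        variance (lower WCSS) and is more concordant with cortex states."""
        from contextconn.state_detection import fit_ncstates

        dyn = hub_fixture["dyn"]
        truth = hub_fixture["truth"]
        cz = ind.cortex_windows_z(dyn)
        cortex_model = ind.correlation_kmeans(cz, k=8, restarts=5, seed=0)
        cortex_assign = cortex_model[1]
        hub_idx = [i for i, nid in enumerate(dyn.node_ids) if nid in set(truth.hub_node_ids)]
        net_idx = [i for i, nid in enumerate(dyn.node_ids)
                   if truth.partition.get(nid) == "net2"]
        results = {}
        for name, nodes, k in (("hub", hub_idx, 8), ("net2", net_idx, 3)):
            wcss, model = ind.subsystem_wcss(dyn, nodes, k, restarts=5, seed=1, cortex_z=cz)
            pos, neg = ind.mean_concordance_independence(model.assignments, cortex_assign)
            results[name] = (wcss, pos)
        assert results["hub"][0] < results["net2"][0]      # more interdependent by WCSS
        assert results["hub"][1] > results["net2"][1]      # and by positive concordance


class TestInterdependentSystem:
    def test_argmin_tally_and_pool_properties(self, hub_fixture):
        dyn = hub_fixture["dyn"]
        pool = np.nonzero(dyn.is_cortical)[0]
        int_nodes, rep = ind.find_interdependent_system(
            dyn, pool, n_pseudo=50, size=8, k=8, restarts=3, seed=1
        )
        # argmin: INT WCSS is the smallest among restricted pseudo-networks
        assert rep.wcss == pytest.approx(rep.extras["restricted_wcss"].min())
        # tally sums to size x ceil(n_pseudo / 5)
        assert sum(rep.extras["tally"].values()) == 8 * int(np.ceil(50 / 5))
        assert len(int_nodes) == 8
        assert set(int_nodes) <= set(rep.extras["restricted_pool"])

    def test_pool_smaller_than_size_rejected(self, hub_fixture):
        dyn = hub_fixture["dyn"]
        pool = np.nonzero(dyn.is_cortical)[0][:9]
        with pytest.raises(ValueError):
            ind.find_interdependent_system(dyn, pool, n_pseudo=10, size=10, k=2, restarts=2, seed=0)

    def test_quintile_too_small_rejected(self, hub_fixture):
        dyn = hub_fixture["dyn"]
        pool = np.nonzero(dyn.is_cortical)[0]
        with pytest.raises(ValueError):
            ind.find_interdependent_system(dyn, pool, n_pseudo=3, size=8, k=2, seed=0)
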