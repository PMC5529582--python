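import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from contextconn import context
from contextconn.state_detection import NCStateModel
from contextconn.static_connectome import NetworkPartition


class TestMultilayerCommunities:
    def test_planted_blocks_recovered_every_layer(self, small_dyn):
        dyn = small_dyn["dyn"]
        labels = context.multilayer_communities(dyn, gamma=1.0, omega=1.0, seed=0)
        lab = labels.labels["sub-00"]
        truth = np.array([0] * 6 + [1] * 6)
        aris = [adjusted_rand_score(truth, lab[:, w]) for w in range(lab.shape[1])]
        assert np.mean(aris) > 0.8

    def test_huge_omega_freezes_labels_over_time(self, small_dyn):
        labels = context.multilayer_communities(small_dyn["dyn"], omega=100.0, seed=0)
        lab = labels.labels["sub-00"]
        assert np.all(lab == lab[:, [0]])

    def test_omega_zero_matches_independent_layer_runs(self, small_dyn):
        import leidenalg as la

        dyn = small_dyn["dyn"]
        labels = context.multilayer_communities(dyn, omega=0.0, seed=0)
        lab = labels.labels["sub-00"]
        rows = dyn.subject_rows("sub-00")
        rows = rows[~dyn.censored[rows]]
        aris = []
        for col, r in enumerate(rows):
            g = context._window_graph(dyn.windows[r], dyn.n_nodes)
            single = la.find_partition(
                g, la.RBConfigurationVertexPartition, weights="weight",
                resolution_parameter=1.0, seed=0,
            )
            aris.append(adjusted_rand_score(single.membership, lab[:, col]))
        assert np.mean(aris) > 0.9

    def test_negative_omega_rejected(self, small_dyn):
        with pytest.raises(ValueError):
            context.multilayer_communities(small_dyn["dyn"], omega=-1.0)


def _labels_fixture():
    # 4 nodes x 4 windows, hand-enumerable co-assignments
    lab = np.array(
        [
            [0, 0, 0, 0],
            [0, 0, 0, 1],
            [1, 1, 0, 1],
            [1, 1, 1, 1],
        ]
    )
    return context.MultilayerLabels(labels={"s": lab}, gamma=1.0, omega=1.0)


class TestAllegiance:
    def test_hand_enumerated_frequencies(self):
        a = context.allegiance(_labels_fixture()).A
        assert a[0, 1] == pytest.approx(0.75)  # same community in 3 of 4 windows
        assert a[2, 3] == pytest.approx(0.75)
        assert a[1, 3] == pytest.approx(0.25)
        assert a[0, 3] == 0.0
        np.testing.assert_allclose(np.diag(a), 1.0)
        np.testing.assert_allclose(a, a.T)

    def test_all_same_community_gives_ones(self):
        lab = np.zeros((5, 3), dtype=int)
        out = context.allegiance(
            context.MultilayerLabels(labels={"s": lab}, gamma=1.0, omega=1.0)
        )
        np.testing.assert_allclose(out.A, 1.0)

    def test_window_order_irrelevant(self):
        labels = _labels_fixture()
        perm = context.MultilayerLabels(
            labels={"s": labels.labels["s"][:, [3, 1, 0, 2]]}, gamma=1.0, omega=1.0
        )
        np.testing.assert_allclose(context.allegiance(labels).A, context.allegiance(perm).A)

    def test_entries_are_exact_rationals(self):
        out = context.allegiance(_labels_fixture())
        counts = out.A * out.n_windows
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            context.allegiance(_labels_fixture(), window_mask=np.zeros(4, bool))


class TestWBCC:
    def test_single_state_model_matches_overall_allegiance(self, small_dyn):
        dyn = small_dyn["dyn"]
        labels = context.multilayer_communities(dyn, seed=0)
        n_valid = int(dyn.valid_mask().sum())
        model = NCStateModel(
            network="a", k=1, centroids=np.zeros((1, 2)),
            assignments=np.zeros(n_valid, dtype=int), wcss=0.0,
        )
        wb = context.wbcc_for_state(dyn, labels, model, 0)
        np.testing.assert_allclose(wb.allegiance.A, context.allegiance(labels).A)

    def test_single_window_state_centroid_is_that_window(self, small_dyn):
        dyn = small_dyn["dyn"]
        labels = context.multilayer_communities(dyn, seed=0)
        n_valid = int(dyn.valid_mask().sum())
        assignments = np.zeros(n_valid, dtype=int)
        assignments[5] = 1
        model = NCStateModel(
            network="a", k=2, centroids=np.zeros((2, 2)), assignments=assignments, wcss=0.0
        )
        wb = context.wbcc_for_state(dyn, labels, model, 1)
        cort = dyn.windows[dyn.valid_mask()][:, dyn.cortical_edge_columns()]
        np.testing.assert_allclose(wb.contextual_centroid, cort[5], atol=1e-12)

    def test_absent_state_rejected_by_name(self, small_dyn):
        dyn = small_dyn["dyn"]
        labels = context.multilayer_communities(dyn, seed=0)
        model = NCStateModel(
            network="a", k=2, centroids=np.zeros((2, 2)),
            assignments=np.zeros(int(dyn.valid_mask().sum()), dtype=int), wcss=0.0,
        )
        with pytest.raises(ValueError, match="state 1"):
            context.wbcc_for_state(dyn, labels, model, 1)


class TestAllegianceDisplacement:
    def _partition(self):
        ids = [f"n{i}" for i in range(4)]
        return ids, NetworkPartition(assignment={"n0": "x", "n1": "x", "n2": "y", "n3": "y"})

    def test_identical_to_baseline_gives_unit_ratios(self):
        ids, part = self._partition()
        base = context.allegiance(_labels_fixture())
        wb = context.WBCC(state=("x", 0), allegiance=base, contextual_centroid=None, n_windows=4)
        ratios = context.allegiance_displacement(wb, base, part, ids)
        np.testing.assert_allclose(ratios, 1.0)

    def test_doubled_coassignment_doubles_ratio(self):
        ids, part = self._partition()
        a_base = np.full((4, 4), 0.25)
        np.fill_diagonal(a_base, 1.0)
        a_state = a_base.copy()
        a_state[0, 1] = a_state[1, 0] = 0.5
        base = context.AllegianceMatrix(A=a_base, n_windows=8)
        wb = context.WBCC(
            state=("x", 0),
            allegiance=context.AllegianceMatrix(A=a_state, n_windows=4),
            contextual_centroid=None, n_windows=4,
        )
        ratios = context.allegiance_displacement(wb, base, part, ids)
        assert ratios[0, 0] == pytest.approx(2.0)
        assert ratios[0, 1] == pytest.approx(1.0)

    def test_invariant_to_node_order_within_networks(self):
        ids, part = self._partition()
        rng = np.random.default_rng(0)
        a = rng.uniform(0.2, 0.9, (4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        base = context.AllegianceMatrix(A=np.full((4, 4), 0.5), n_windows=4)
        wb = context.WBCC(state=("x", 0), allegiance=context.AllegianceMatrix(A=a, n_windows=4),
                          contextual_centroid=None, n_windows=4)
        r1 = context.allegiance_displacement(wb, base, part, ids)
        order = [1, 0, 3, 2]
        a2 = a[np.ix_(order, order)]
        ids2 = [ids[i] for i in order]
        wb2 = context.WBCC(state=("x", 0), allegiance=context.AllegianceMatrix(A=a2, n_windows=4),
                           contextual_centroid=None, n_windows=4)
        r2 = context.allegiance_displacement(wb2, base, part, ids2)
        np.testing.assert_allclose(r1, r2)


class TestConcordance:
    def test_identical_equal_frequency_sequences_diagonal_ln_k(self):
        seq = np.tile(np.arange(4), 100)
        cm = context.concordance(seq, seq)
        np.testing.assert_allclose(np.diag(cm.C), np.log(4), atol=1e-12)
        off = cm.C[~np.eye(4, dtype=bool)]
        assert np.all(np.isnan(off))

    def test_independent_sequences_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 10_000)
        b = rng.integers(0, 3, 10_000)
        cm = context.concordance(a, b)
        assert np.nanmax(np.abs(cm.C)) < 0.05

    def test_sign_matches_2x2_count_arithmetic(self):
        # joint counts: [[30, 10], [10, 50]]
        a = np.array([0] * 40 + [1] * 60)
        b = np.array([0] * 30 + [1] * 10 + [0] * 10 + [1] * 50)
        cm = context.concordance(a, b)
        # P(A0|B0)=0.75 > P(A0)=0.4 -> positive; P(A0|B1)=1/6 < 0.4 -> negative
        assert cm.C[0, 0] == pytest.approx(np.log(0.75 / 0.4))
        assert cm.C[0, 1] == pytest.approx(np.log((10 / 60) / 0.4))
        assert cm.C[0, 0] > 0 > cm.C[0, 1]

    def test_probability_normalization(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 500)
        b = rng.integers(0, 3, 500)
        cm = context.concordance(a, b)
        p_a = cm.counts.sum(axis=1) / 500
        assert p_a.sum() == pytest.approx(1.0)
        p_cond = cm.counts / cm.counts.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(p_cond.sum(axis=0), 1.0)

    def test_empirical_transpose_relation(self):
        # the empirical estimator C = ln(n_ij W / (n_i n_j)) satisfies
        # C(A,B) = C(B,A)^T; asymmetry only enters through unequal marginals
        # in the population quantities, not the plug-in estimate
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 1000)
        b = np.where(rng.random(1000) < 0.3, 1 - a, a)
        cab = context.concordance(a, b)
        cba = context.concordance(b, a)
        np.testing.assert_allclose(cab.C, cba.C.T, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            context.concordance(np.zeros(5, int), np.zeros(6, int))


class TestConcordanceSignificance:
    @pytest.fixture()
    def coupled(self):
        rng = np.random.default_rng(3)
        assign_a, assign_b = {}, {}
        # enough subjects that the cross-subject permutation null is not
        # dominated by permutations fixing most subjects in place
        for s in range(8):
            a = rng.integers(0, 2, 150)
            b = np.where(rng.random(150) < 0.8, a, rng.integers(0, 2, 150))
            assign_a[f"s{s}"] = a
            assign_b[f"s{s}"] = b
        return assign_a, assign_b

    def test_coupled_cells_significant_and_mask_is_intersection(self, coupled):
        assign_a, assign_b = coupled
        cm = context.concordance_significance(assign_a, assign_b, n_reps=99, seed=0)
        assert cm.significant[0, 0] and cm.significant[1, 1]
        assert cm.C[0, 0] > 0

    def test_independent_sequences_rarely_significant(self):
        rng = np.random.default_rng(4)
        frac = []
        for trial in range(3):
            assign_a = {f"s{i}": rng.integers(0, 2, 200) for i in range(4)}
            assign_b = {f"s{i}": rng.integers(0, 2, 200) for i in range(4)}
            cm = context.concordance_significance(assign_a, assign_b, n_reps=99, seed=trial)
            frac.append(cm.significant.mean())
        assert np.mean(frac) <= 0.25

    def test_single_subject_drops_cross_subject_null(self):
        rng = np.random.default_rng(5)
        a = {"s": rng.integers(0, 2, 100)}
        b = {"s": rng.integers(0, 2, 100)}
        with pytest.warns(UserWarning, match="cross-subject"):
            context.concordance_significance(a, b, n_reps=19, seed=0)
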