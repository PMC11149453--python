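import numpy as np
import pytest

import graphomics as go
from graphomics.errors import InputError
from graphomics.model import LayerParams, _etype_codes

from conftest import tiny_graph
from oracles import dense_forward, mean_update, random_hetero_graph


def _identity_params(d, hops, activation_last="identity"):
    out = []
    for k in range(hops):
        act = "relu" if k < hops - 1 else activation_last
        out.append(LayerParams(W=np.eye(d), activation=act))
    return out


def _random_params(rng, d, hops, learned=False, n_et=8):
    out = []
    for k in range(hops):
        act = "relu" if k < hops - 1 else "identity"
        lp = dict(W=rng.normal(size=(d, d)) / np.sqrt(d), activation=act)
        if learned:
            lp["att_dst"] = 0.3 * rng.normal(size=(n_et, d))
            lp["att_src"] = 0.3 * rng.normal(size=(n_et, d))
        out.append(LayerParams(**lp))
    return out


class TestInitEmbeddings:
    def test_deterministic_under_seed(self, small_graph):
        a = go.init_embeddings(small_graph, d=16, seed=5)
        b = go.init_embeddings(small_graph, d=16, seed=5)
        assert np.array_equal(a.vectors, b.vectors)

    def test_default_dimension_is_100(self, small_graph):
        emb = go.init_embeddings(small_graph)
        assert emb.d == 100
        assert emb.vectors.shape == (small_graph.n, 100)

    def test_seeds_differ(self, small_graph):
        a = go.init_embeddings(small_graph, d=8, seed=1)
        b = go.init_embeddings(small_graph, d=8, seed=2)
        assert not np.array_equal(a.vectors, b.vectors)

    def test_nonpositive_dimension_rejected(self, small_graph):
        with pytest.raises(InputError):
            go.init_embeddings(small_graph, d=0)


class TestSampleNeighbors:
    def test_small_degree_returns_all_deterministically(self):
        g = tiny_graph()
        rng = np.random.default_rng(0)
        nbrs = go.sample_neighbors(g, g.node_index[("mirna", "m0")], 5, rng)
        assert set(nbrs) == {g.node_index[("patient", "P0")],
                             g.node_index[("mrna", "g0")]}

    def test_isolated_node_empty(self):
        g = tiny_graph()
        iso = g.add_node("circrna", "lonely")
        nbrs = go.sample_neighbors(g, iso, 3, np.random.default_rng(0))
        assert len(nbrs) == 0

    def test_subset_without_replacement(self):
        g = tiny_graph()
        p0 = g.node_index[("patient", "P0")]
        nbrs = go.sample_neighbors(g, p0, 2, np.random.default_rng(1))
        assert len(nbrs) == 2 and len(set(nbrs)) == 2


class TestAttentionRows:
    def test_uniform_values(self):
        np.testing.assert_allclose(go.uniform_attention(range(4)), [0.25] * 4)
        np.testing.assert_allclose(go.uniform_attention([0]), [1.0])

    def test_uniform_empty_rejected(self):
        with pytest.raises(InputError):
            go.uniform_attention([])

    def test_learned_uniform_for_identical_neighbors(self):
        rng = np.random.default_rng(3)
        lp = LayerParams(W=np.eye(4), activation="identity",
                         att_dst=rng.normal(size=4), att_src=rng.normal(size=4))
        h = rng.normal(size=4)
        row = go.learned_attention(h, [h.copy() for _ in range(5)], lp)
        np.testing.assert_allclose(row, 0.2, atol=1e-12)

    def test_learned_row_normalized_nonnegative(self):
        rng = np.random.default_rng(4)
        lp = LayerParams(W=rng.normal(size=(4, 4)), activation="identity",
                         att_dst=rng.normal(size=4), att_src=rng.normal(size=4))
        row = go.learned_attention(rng.normal(size=4), rng.normal(size=(7, 4)),
                                   lp, edge_weights=rng.normal(size=7))
        assert (row >= 0).all()
        assert abs(row.sum() - 1) < 1e-6

    def test_softmax_monotone_in_score(self):
        # att_src selects the first coordinate: boosting it boosts the weight
        lp = LayerParams(W=np.eye(2), activation="identity",
                         att_dst=np.zeros(2), att_src=np.array([1.0, 0.0]))
        h = np.zeros(2)
        base = go.learned_attention(h, [[1.0, 0], [0.5, 0], [0.2, 0]], lp)
        boosted = go.learned_attention(h, [[2.0, 0], [0.5, 0], [0.2, 0]], lp)
        assert boosted[0] > base[0]


class TestAggregation:
    def test_mean_hand_computed_example(self):
        out = go.aggregate_mean([0.0, 0.0], [[2.0, 4.0], [0.0, 0.0]],
                                np.eye(2), "identity")
        np.testing.assert_allclose(out, [2 / 3, 4 / 3])

    def test_mean_matches_longhand_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            k = int(rng.integers(0, 5))
            h = rng.normal(size=3)
            nb = rng.normal(size=(k, 3))
            W = rng.normal(size=(2, 3))
            np.testing.assert_allclose(
                go.aggregate_mean(h, nb, W, "relu"),
                mean_update(h, nb, W, "relu"), atol=1e-12)

    def test_mean_without_neighbors(self):
        h = np.array([1.0, -2.0])
        W = np.array([[2.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(go.aggregate_mean(h, [], W, "identity"),
                                   W @ h)

    def test_relu_on_zeros(self):
        out = go.aggregate_mean(np.zeros(3), [np.zeros(3)], np.eye(3), "relu")
        assert np.all(out == 0)

    def test_attention_uniform_selfloop_equals_mean(self):
        """Uniform attention with a self loop reduces to mean aggregation."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            k = int(rng.integers(1, 6))
            d = int(rng.integers(1, 5))
            h = rng.normal(size=d)
            nb = rng.normal(size=(k, d))
            W = rng.normal(size=(d, d))
            a = go.aggregate_attention(h, nb, np.full(k, 1.0 / k), W,
                                       "relu", self_loop=True)
            m = go.aggregate_mean(h, nb, W, "relu")
            worst = max(worst, np.abs(a - m).max())
        assert worst < 1e-6

    def test_attention_single_neighbor(self):
        W = np.diag([2.0, 3.0])
        hv = np.array([1.0, 1.0])
        out = go.aggregate_attention(np.zeros(2), [hv], [1.0], W,
                                     "identity", self_loop=False)
        np.testing.assert_allclose(out, W @ hv)

    def test_attention_concentrated_row(self):
        rng = np.random.default_rng(8)
        nb = rng.normal(size=(3, 2))
        W = rng.normal(size=(2, 2))
        out = go.aggregate_attention(np.zeros(2), nb, [1.0, 0.0, 0.0], W,
                                     "identity", self_loop=False)
        np.testing.assert_allclose(out, W @ nb[0])

    def test_unnormalized_row_rejected(self):
        with pytest.raises(InputError):
            go.aggregate_attention(np.zeros(2), [np.ones(2)], [0.7],
                                   np.eye(2), "identity", self_loop=False)


class TestClassify:
    def test_probabilities_normalized(self):
        rng = np.random.default_rng(9)
        Wc, bc = rng.normal(size=(3, 8)), rng.normal(size=3)
        p = go.classify(rng.normal(size=8), (Wc, bc))
        assert p.shape == (3,)
        assert abs(p.sum() - 1) < 1e-6 and (p >= 0).all()

    def test_zero_logits_uniform(self):
        p = go.classify(np.zeros(4), (np.zeros((3, 4)), np.zeros(3)))
        np.testing.assert_allclose(p, 1 / 3)

    def test_dimension_mismatch(self):
        with pytest.raises(InputError):
            go.classify(np.zeros(5), (np.zeros((3, 4)), np.zeros(3)))


class TestForward:
    def test_one_hop_matches_per_node_mean(self):
        g = tiny_graph()
        cfg = go.TrainConfig(hops=1, neighbors_per_hop=50, embedding_dim=3,
                             epochs=0)
        emb = go.init_embeddings(g, d=3, seed=0)
        params = _identity_params(3, 1)
        out, _, _ = go.forward(g, emb, params, cfg)
        H = emb.vectors
        for u in range(g.n):
            nbrs, w = g.neighbors(u)
            weighted = [w_i * H[v] for v, w_i in zip(nbrs, w)]
            expected = go.aggregate_attention(
                H[u], weighted, np.full(len(nbrs), 1 / max(len(nbrs), 1)),
                np.eye(3), "identity", self_loop=True)
            np.testing.assert_allclose(out.vectors[u], expected, atol=1e-9)

    def test_full_sampling_deterministic(self, small_graph):
        emb = go.init_embeddings(small_graph, d=8, seed=1)
        cfg = go.TrainConfig(hops=2, neighbors_per_hop=10_000, embedding_dim=8)
        params = _random_params(np.random.default_rng(2), 8, 2)
        a, _, _ = go.forward(small_graph, emb, params, cfg,
                             rng=np.random.default_rng(0))
        b, _, _ = go.forward(small_graph, emb, params, cfg,
                             rng=np.random.default_rng(99))
        assert np.array_equal(a.vectors, b.vectors)

    def test_two_hop_reach(self):
        """A node two hops from a patient influences it only at hops=2."""
        g = tiny_graph()
        p1 = g.node_index[("patient", "P1")]
        m0 = g.node_index[("mirna", "m0")]   # not adjacent to P1
        emb = go.init_embeddings(g, d=4, seed=3)
        bumped = go.EmbeddingSet(emb.vectors.copy(), 4)
        bumped.vectors[m0] += 10.0
        for hops, expect_change in ((1, False), (2, True)):
            cfg = go.TrainConfig(hops=hops, neighbors_per_hop=50,
                                 embedding_dim=4)
            params = _identity_params(4, hops)
            a, _, _ = go.forward(g, emb, params, cfg)
            b, _, _ = go.forward(g, bumped, params, cfg)
            changed = not np.allclose(a.vectors[p1], b.vectors[p1], atol=1e-9)
            assert changed == expect_change

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        g = random_hetero_graph(rng)
        perm = rng.permutation(g.n)
        g2 = go.HeteroGraph()
        order = np.argsort(perm)
        for i in order:
            g2.add_node(g.node_types[i], g.node_ids[i])
        for _, row in g.edges.iterrows():
            g2.add_edge(int(perm[int(row["u"])]), int(perm[int(row["v"])]),
                        float(row["weight"]))
        emb = go.init_embeddings(g, d=5, seed=4)
        emb2 = go.EmbeddingSet(emb.vectors[order], 5)
        cfg = go.TrainConfig(hops=2, neighbors_per_hop=10_000, embedding_dim=5)
        params = _random_params(np.random.default_rng(5), 5, 2)
        out1, _, _ = go.forward(g, emb, params, cfg)
        out2, _, _ = go.forward(g2, emb2, params, cfg)
        np.testing.assert_allclose(out2.vectors, out1.vectors[order],
                                   atol=1e-8)

    @pytest.mark.parametrize("mode,self_loop", [
        ("uniform", True), ("uniform", False),
        ("learned", True), ("learned", False),
    ])
    def test_matches_dense_oracle(self, mode, self_loop):
        rng = np.random.default_rng(21)
        worst = 0.0
        for trial in range(30):
            g = random_hetero_graph(rng)
            n_et = len(_etype_codes(g))
            params = _random_params(rng, 4, 2, learned=(mode == "learned"),
                                    n_et=n_et)
            emb = go.init_embeddings(g, d=4, seed=trial)
            cfg = go.TrainConfig(hops=2, neighbors_per_hop=10_000,
                                 embedding_dim=4, attention_mode=mode,
                                 self_loop=self_loop)
            out, att, _ = go.forward(g, emb, params, cfg)
            H_ref, attn_ref = dense_forward(
                g, emb.vectors, params, self_loop=self_loop,
                attention_mode=mode)
            worst = max(worst, np.abs(out.vectors - H_ref).max())
        assert worst < 1e-6


class TestTraining:
    def test_separable_cohort_fits_perfectly(self):
        net = go.simulate_network(20, 10, 5, 20, seed=1)
        cfg = go.CohortConfig(class_sizes=(12, 12, 12), effect_size=3.0,
                              noise_sd=0.3, n_informative=5, seed=2)
        cohort = go.simulate_cohort(net, cfg)
        model = go.MultiOmicsGNN(go.cohort_graph(cohort),
                                 config=go.TrainConfig(epochs=200,
                                                       embedding_dim=64,
                                                       seed=0))
        res = model.fit()
        assert res.loss_history[-1] < 0.05
        assert res.accuracy() == 1.0

    def test_loss_smoothed_nonincreasing(self):
        net = go.simulate_network(20, 10, 5, 20, seed=1)
        cfg = go.CohortConfig(class_sizes=(12, 12, 12), effect_size=3.0,
                              noise_sd=0.3, seed=2)
        cohort = go.simulate_cohort(net, cfg)
        res = go.MultiOmicsGNN(go.cohort_graph(cohort),
                               config=go.TrainConfig(epochs=120,
                                                     embedding_dim=32,
                                                     seed=1)).fit()
        smooth = np.convolve(res.loss_history, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(smooth) < 1e-3)

    def test_zero_epochs_returns_initial_state(self, small_graph):
        res = go.MultiOmicsGNN(small_graph,
                               config=go.TrainConfig(epochs=0,
                                                     embedding_dim=16,
                                                     seed=0)).fit()
        assert len(res.loss_history) == 0
        assert np.all(np.isfinite(res.embeddings.vectors))

    def test_fit_reproducible_under_seed(self, small_graph):
        cfg = go.TrainConfig(epochs=25, embedding_dim=16, seed=12)
        a = go.MultiOmicsGNN(small_graph, config=cfg).fit()
        b = go.MultiOmicsGNN(small_graph, config=cfg).fit()
        assert np.array_equal(a.loss_history, b.loss_history)
        assert np.array_equal(a.embeddings.vectors, b.embeddings.vectors)

    def test_no_labeled_patients_rejected(self, small_graph):
        model = go.MultiOmicsGNN(small_graph,
                                 config=go.TrainConfig(epochs=1,
                                                       embedding_dim=8))
        n_pat = len(model.patient_idx)
        with pytest.raises(InputError):
            model.fit(train_mask=np.zeros(n_pat, dtype=bool))

    def test_missing_label_rejected(self, small_graph):
        labels = small_graph.labels.iloc[:-1]
        with pytest.raises(InputError):
            go.MultiOmicsGNN(small_graph, labels=labels)

    @pytest.mark.parametrize("mode", ["uniform", "learned"])
    def test_attention_rows_normalized_after_fit(self, small_graph, mode):
        cfg = go.TrainConfig(epochs=15, embedding_dim=16,
                             attention_mode=mode, seed=2)
        res = go.MultiOmicsGNN(small_graph, config=cfg).fit()
        for att in res.attention_per_hop:
            sums = att.row_sums()
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            assert (att.alpha >= 0).all()

    def test_summary_mentions_key_facts(self, fitted_small):
        text = fitted_small.summary()
        assert "patients: 35" in text
        assert "cardioembolic" in text

    def test_predictions_align_with_labels_index(self, fitted_small):
        proba = fitted_small.predict_proba()
        assert list(proba.columns) == list(fitted_small.model.classes)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
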