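import numpy as np
import pytest

from mdagcan import (
    AssociationMatrix,
    RunConfig,
    SampleSets,
    SimilarityMatrix,
    build_hetnet,
    focal_loss,
    gat_aggregate,
    gat_coefficients,
    gcn_encode,
    predict,
    sym_norm_propagate,
    train,
)
from mdagcan.model import ModelConfig, _backward, _focal_terms, _forward, init_state
from mdagcan.pipeline import build_graph, fit_predict

from conftest import random_association


def two_node_graph():
    A = AssociationMatrix(np.ones((1, 1)), ("d1",), ("m1",))
    DS = SimilarityMatrix(np.eye(1), ("d1",))
    MS = SimilarityMatrix(np.eye(1), ("m1",))
    return build_hetnet(DS, MS, A, beta=2.0)


def random_graph(rng, nd=3, nm=4):
    A = random_association(rng, nd, nm)
    return build_graph(A, RunConfig(k=5, dp_node=0.0, dp_reg=0.0, epochs=1)), A


class TestGcnEncode:
    def test_single_layer_is_one_propagation(self):
        G = two_node_graph()
        cfg = ModelConfig(k=3, n_gcn_layers=1, dp_node=0.0, dp_reg=0.0)
        state = init_state(G, cfg)
        out = gcn_encode(G, state)
        np.testing.assert_array_equal(
            out, sym_norm_propagate(G, G.h0, state.gcn_weights[0])
        )

    def test_two_layer_hand_iteration(self):
        G = two_node_graph()
        cfg = ModelConfig(k=2, n_gcn_layers=2, dp_node=0.0, dp_reg=0.0)
        state = init_state(G, cfg)
        state.gcn_weights = [np.eye(2), np.eye(2)]
        out = gcn_encode(G, state)
        h1 = np.tanh(G.normalized_adjacency() @ G.h0)
        np.testing.assert_allclose(
            out, np.tanh(G.normalized_adjacency() @ h1), atol=1e-15
        )

    def test_inference_deterministic(self):
        rng = np.random.default_rng(5)
        G, _ = random_graph(rng)
        cfg = ModelConfig(k=4, dp_node=0.5, dp_reg=0.5)
        state = init_state(G, cfg)
        np.testing.assert_array_equal(gcn_encode(G, state), gcn_encode(G, state))


class TestGatCoefficients:
    def test_rows_sum_to_one_on_support(self):
        rng = np.random.default_rng(0)
        G, _ = random_graph(rng, 4, 5)
        H = rng.standard_normal((9, 3))
        W = rng.standard_normal((3, 3))
        a = rng.standard_normal(6)
        att = gat_coefficients(H, G, W, a)
        np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-12)
        nb = (G.adjacency > 0) | np.eye(9, dtype=bool)
        assert (att[~nb] == 0.0).all()

    def test_hand_scored_pair(self):
        # h = [1], [2]; W = [[1]]; a = [1, 1]: e_12 = relu(1 + 2) = 3
        G = two_node_graph()
        H = np.array([[1.0], [2.0]])
        att = gat_coefficients(H, G, np.array([[1.0]]), np.array([1.0, 1.0]))
        # row 0: softmax over (e_11, e_12) = (2, 3)
        assert att[0, 1] == pytest.approx(np.exp(3) / (np.exp(2) + np.exp(3)))
        assert att[1, 1] == pytest.approx(np.exp(4) / (np.exp(3) + np.exp(4)))

    def test_uniform_scores_give_uniform_attention(self):
        G = two_node_graph()
        att = gat_coefficients(
            np.zeros((2, 2)), G, np.eye(2), np.ones(4)
        )
        np.testing.assert_allclose(att, 0.25 * np.ones((2, 2)) * 2)


class TestGatAggregate:
    def test_identity_attention_is_identity(self):
        H = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(gat_aggregate(H, np.eye(4)), H)

    def test_uniform_over_identical_neighbors(self):
        H = np.tile([1.0, 2.0], (2, 1))
        att = 0.5 * np.ones((2, 2))
        np.testing.assert_allclose(gat_aggregate(H, att), H)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.standard_normal((5, 3))
        att = rng.random((5, 5))
        att /= att.sum(axis=1, keepdims=True)
        expected = np.array([
            sum(att[i, j] * H[j] for j in range(5)) for i in range(5)
        ])
        np.testing.assert_allclose(gat_aggregate(H, att), expected, atol=1e-12)


class TestFocalLoss:
    def test_single_positive_at_half(self):
        samples = SampleSets(frozenset({(0, 0)}), frozenset())
        loss = focal_loss(np.array([[0.5]]), np.array([[1.0]]), samples, 0.1, 2.0)
        assert loss == pytest.approx(0.1 * 0.25 * np.log(2), abs=1e-12)
        assert loss == pytest.approx(0.0173287, abs=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_gamma_zero_alpha_one_is_bce(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.01, 0.99, size=(4, 5))
        y = (rng.random((4, 5)) < 0.5).astype(float)
        samples = SampleSets.from_matrix(y)
        loss = focal_loss(p, y, samples, alpha=1.0, gamma=0.0)
        bce = -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert loss == pytest.approx(bce, abs=1e-12)

    def test_perfect_scores_vanish(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[1.0 - 1e-9, 1e-9]])
        samples = SampleSets.from_matrix(y)
        assert focal_loss(p, y, samples, 0.1, 2.0) < 1e-12

    def test_extreme_scores_clamped_finite(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[1e-300, 1.0 - 1e-16]])
        samples = SampleSets.from_matrix(y)
        assert np.isfinite(focal_loss(p, y, samples, 0.5, 2.0))


class TestBilinearDecode:
    def test_orthogonal_embeddings_score_half(self):
        from mdagcan import bilinear_decode

        s = bilinear_decode(
            np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]), np.eye(2),
            ("d1",), ("m1",),
        )
        assert s.values[0, 0] == 0.5

    def test_hand_evaluated_logit(self):
        from mdagcan import bilinear_decode

        W = np.array([[0.0, 1.0], [0.0, 0.0]])
        s = bilinear_decode(
            np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]), W, ("d1",), ("m1",)
        )
        assert s.values[0, 0] == pytest.approx(0.7310585786, abs=1e-10)

    def test_zero_decoder_gives_half_everywhere(self):
        from mdagcan import bilinear_decode

        rng = np.random.default_rng(3)
        s = bilinear_decode(
            rng.standard_normal((3, 4)), rng.standard_normal((5, 4)),
            np.zeros((4, 4)), tuple("abc"), tuple("vwxyz"),
        )
        assert (s.values == 0.5).all()


class TestTraining:
    def test_one_epoch_changes_weights(self, toy_assoc, fast_config):
        G = build_graph(toy_assoc, fast_config)
        cfg = fast_config.model_config()
        state0 = init_state(G, cfg)
        cfg1 = ModelConfig(**{**cfg.__dict__, "epochs": 1})
        state1 = train(G, toy_assoc, cfg1)
        assert state1.decoder_w.shape == state0.decoder_w.shape
        assert not np.array_equal(state1.decoder_w, state0.decoder_w)

    def test_same_seed_bitwise_identical(self, small_synthetic, fast_config):
        A, _ = small_synthetic
        s1 = fit_predict(A, fast_config)
        s2 = fit_predict(A, fast_config)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_loss_decreases_on_planted_structure(self, small_synthetic):
        A, _ = small_synthetic
        cfg = RunConfig(beta=2.0, lr=5e-3, dp_node=0.0, dp_reg=0.0,
                        epochs=120, k=16, seed=1)
        G = build_graph(A, cfg)
        _, history = train(G, A, cfg.model_config(), return_history=True)
        assert history[-1] < history[0]

    def test_prediction_deterministic_and_bounded(self, small_synthetic, fast_config):
        A, _ = small_synthetic
        G = build_graph(A, fast_config)
        state = train(G, A, fast_config.model_config())
        p1, p2 = predict(state, G), predict(state, G)
        np.testing.assert_array_equal(p1.values, p2.values)
        assert (p1.values > 0.0).all() and (p1.values < 1.0).all()

    def test_state_roundtrip(self, tmp_path, small_synthetic, fast_config):
        from mdagcan.model import ModelState

        A, _ = small_synthetic
        G = build_graph(A, fast_config)
        state = train(G, A, fast_config.model_config())
        path = tmp_path / "state.npz"
        state.save(path)
        loaded = ModelState.load(path)
        np.testing.assert_array_equal(
            predict(state, G).values, predict(loaded, G).values
        )
        assert loaded.config == state.config


class TestGradients:
    def _loss(self, G, state, A, alpha, gamma):
        cache = _forward(G, state, training=False)
        loss, _ = _focal_terms(cache["scores"], A.values, alpha, gamma)
        return loss.sum(), cache

    def test_finite_difference_full_model(self):
        """Backprop through decoder, attention, and both GCN layers matches
        central finite differences on a 3x4 toy within 1e-4 relative error."""
        rng = np.random.default_rng(0)
        cfg = RunConfig(k=5, dp_node=0.0, dp_reg=0.0, epochs=1)
        A = random_association(rng, 3, 4)
        G = build_graph(A, cfg)
        state = init_state(G, cfg.model_config())
        alpha, gamma = 0.1, 2.0

        _, cache = self._loss(G, state, A, alpha, gamma)
        _, dS = _focal_terms(cache["scores"], A.values, alpha, gamma)
        grads = _backward(cache, state, dS)

        h = 1e-6
        params = state.parameters()
        for key, w in params.items():
            numeric = np.zeros_like(w)
            it = np.nditer(w, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = w[idx]
                w[idx] = orig + h
                state.set_parameters(params)
                lp, _ = self._loss(G, state, A, alpha, gamma)
                w[idx] = orig - h
                state.set_parameters(params)
                lm, _ = self._loss(G, state, A, alpha, gamma)
                w[idx] = orig
                numeric[idx] = (lp - lm) / (2 * h)
            state.set_parameters(params)
            denom = max(np.abs(numeric).max(), 1e-8)
            assert np.abs(numeric - grads[key]).max() / denom < 1e-4, key


class TestPermutationEquivariance:
    def test_forward_pass_permutes_columns(self):
        """Permuting microbes (and the node-indexed rows of the first GCN
        weight) permutes the score columns identically."""
        rng = np.random.default_rng(7)
        cfg = RunConfig(k=6, dp_node=0.0, dp_reg=0.0, epochs=1)
        A = random_association(rng, 4, 6)
        nd, nm = A.values.shape
        perm = rng.permutation(nm)
        A_perm = AssociationMatrix(
            A.values[:, perm], A.disease_ids,
            tuple(A.microbe_ids[j] for j in perm),
        )
        G = build_graph(A, cfg)
        Gp = build_graph(A_perm, cfg)
        state = init_state(G, cfg.model_config())
        state_p = init_state(Gp, cfg.model_config())
        full_perm = np.concatenate([np.arange(nd), nd + perm])
        params = state.parameters()
        params_p = {k: v.copy() for k, v in params.items()}
        # first GCN weight has one row per node AND one column per node
        # feature (h0 is n x n): permute both
        params_p["gcn_0"] = params["gcn_0"][full_perm, :]
        state_p.set_parameters(params_p)
        state.set_parameters(params)
        scores = _forward(G, state)["scores"]
        scores_p = _forward(Gp, state_p)["scores"]
        np.testing.assert_allclose(scores_p, scores[:, perm], atol=1e-12)
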