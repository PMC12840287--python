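"""Forward pass, routing, gradients and training of the GCN-tree model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtsurv.graph import build_patient_graph, normalize_adjacency
from gtsurv.model import (
    GCNParams,
    GTModel,
    TrainConfig,
    TreeParams,
    backward,
    decision_node_gradient,
    forward,
    gcn_forward,
    init_model,
    leaf_gradient,
    loss,
    predict_rmst,
    routing_probs,
    train,
)


def small_model(rng, p=4, hidden=(6, 4), depth=2, K=2):
    taus = np.arange(1, K + 1, dtype=float)
    return init_model(p, hidden, depth, taus, rng,
                      leaf_init=rng.uniform(0.2, 1.0, K), dropout_rate=0.0)


def numerical_grad(f, arr, h=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + h
        fp = f()
        arr[i] = orig - h
        fm = f()
        arr[i] = orig
        g[i] = (fp - fm) / (2 * h)
    return g


class TestGCNForward:
    def test_identity_propagation_preserves_nonnegative_input(self):
        X = np.abs(np.random.default_rng(0).standard_normal((3, 2)))
        params = GCNParams(W0=np.eye(2), W1=np.eye(2), dropout_rate=0.0)
        *_, H2, _, _ = gcn_forward(X, np.eye(3), params)
        np.testing.assert_allclose(H2, X)

    def test_zero_input_gives_zero_output(self):
        params = GCNParams(W0=np.ones((2, 3)), W1=np.ones((3, 2)),
                           dropout_rate=0.0)
        *_, H2, _, _ = gcn_forward(np.zeros((4, 2)), np.eye(4), params)
        np.testing.assert_allclose(H2, 0.0)

    def test_complete_graph_averages_features(self):
        A_hat = normalize_adjacency(np.array([[0, 1], [1, 0]]))
        X = np.array([[1.0], [3.0]])
        Z1 = A_hat @ X @ np.eye(1)
        np.testing.assert_allclose(Z1, [[2.0], [2.0]])

    def test_shape_mismatch_rejected(self):
        params = GCNParams(W0=np.eye(3), W1=np.eye(3))
        with pytest.raises(ValueError, match="features"):
            gcn_forward(np.zeros((2, 2)), np.eye(2), params)

    def test_dropout_only_in_training(self):
        rng = np.random.default_rng(1)
        X = np.abs(rng.standard_normal((6, 3)))
        params = GCNParams(W0=np.eye(3), W1=np.eye(3), dropout_rate=0.5)
        *_, H_eval, _, _ = gcn_forward(X, np.eye(6), params, training=False)
        np.testing.assert_allclose(H_eval, X)
        *_, H_train, M1, M2 = gcn_forward(X, np.eye(6), params,
                                          training=True, rng=rng)
        assert M1 is not None and (M1 == 0).any()


class TestRouting:
    @pytest.mark.parametrize("depth,expected", [(1, 0.5), (2, 0.25)])
    def test_zero_scores_route_uniformly(self, depth, expected):
        tree = TreeParams(depth=depth, Wt=np.zeros((3, 2 ** depth - 1)),
                          bt=np.zeros(2 ** depth - 1),
                          leaves=np.zeros((2 ** depth, 1)))
        *_, P = routing_probs(np.zeros((5, 3)), tree)
        np.testing.assert_allclose(P, expected)

    def test_saturated_root_routes_left(self):
        # large positive score: d_e -> 1 routes to the LEFT child
        tree = TreeParams(depth=1, Wt=np.zeros((2, 1)), bt=np.array([50.0]),
                          leaves=np.array([[1.0], [2.0]]))
        *_, P = routing_probs(np.ones((1, 2)), tree)
        np.testing.assert_allclose(P, [[1.0, 0.0]], atol=1e-20)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 16), depth=st.integers(1, 4),
           scale=st.floats(0.1, 20.0))
    def test_rows_are_probability_vectors(self, seed, depth, scale):
        # normalization must hold for ANY parameters, including near-saturated
        rng = np.random.default_rng(seed)
        m = small_model(rng, depth=depth)
        m.tree.Wt *= scale
        H = rng.standard_normal((7, 4))
        *_, P = routing_probs(H, m.tree)
        assert np.all(P >= 0) and np.all(P <= 1)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)


class TestPrediction:
    def test_constant_leaves_give_constant_prediction(self):
        rng = np.random.default_rng(0)
        m = small_model(rng)
        m.tree.leaves[:] = 0.7
        G = predict_rmst(rng.standard_normal((5, 4)), np.eye(5), m)
        np.testing.assert_allclose(G, 0.7)

    def test_depth_one_uniform_routing_averages_leaves(self):
        tree = TreeParams(depth=1, Wt=np.zeros((2, 1)), bt=np.zeros(1),
                          leaves=np.array([[0.2], [0.8]]))
        gcn = GCNParams(W0=np.eye(2), W1=np.eye(2), dropout_rate=0.0)
        m = GTModel(gcn=gcn, tree=tree, taus=np.array([1.0]))
        G = predict_rmst(np.zeros((3, 2)), np.eye(3), m)
        np.testing.assert_allclose(G, 0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_convex_hull_bound(self, seed):
        rng = np.random.default_rng(seed)
        m = small_model(rng, depth=3)
        G = predict_rmst(rng.standard_normal((8, 4)), np.eye(8), m)
        for k in range(G.shape[1]):
            assert np.all(G[:, k] >= m.tree.leaves[:, k].min() - 1e-12)
            assert np.all(G[:, k] <= m.tree.leaves[:, k].max() + 1e-12)


class TestLoss:
    def test_examples(self):
        assert loss(np.array([[2.0]]), np.array([[2.0]])) == 0.0
        assert loss(np.array([[0.0]]), np.array([[2.0]])) == 4.0
        assert loss(np.array([[1.0], [-1.0]]),
                    np.array([[0.0], [0.0]])) == 1.0


class TestGradients:
    @pytest.mark.parametrize("seed", range(4))
    def test_backprop_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n, K, depth = 5, int(rng.integers(1, 4)), int(rng.integers(1, 4))
        m = small_model(rng, depth=depth, K=K)
        X = rng.standard_normal((n, 4))
        A = build_patient_graph(X, 2).normalized
        Y = rng.standard_normal((n, K))
        mask = rng.random(n) > 0.3
        mask[0] = True
        cache = forward(X, A, m)
        grads = backward(cache, m, Y, mask=mask)
        for key, arr in m.parameters.items():
            num = numerical_grad(
                lambda: loss(forward(X, A, m).G, Y, mask=mask), arr)
            np.testing.assert_allclose(
                grads[key], num, rtol=1e-4, atol=1e-7,
                err_msg=f"gradient mismatch for {key}")

    @pytest.mark.parametrize("seed", range(3))
    def test_closed_form_node_gradient_matches_finite_differences(self, seed):
        # the per-sample decision-node gradient: perturb node scores directly
        rng = np.random.default_rng(10 + seed)
        n, K = 3, 2
        m = small_model(rng, depth=2, K=K)
        X = rng.standard_normal((n, 4))
        A = np.eye(n)
        Y = rng.standard_normal((n, K))
        cache = forward(X, A, m)
        got = decision_node_gradient(cache, m.tree, Y)

        def loss_from_scores(F):
            d = 1.0 / (1.0 + np.exp(-F))
            total = 2 ** (m.tree.depth + 1) - 1
            probs = np.empty((n, total))
            probs[:, 0] = 1.0
            for e in range(m.tree.n_internal):
                probs[:, 2 * e + 1] = probs[:, e] * d[:, e]
                probs[:, 2 * e + 2] = probs[:, e] * (1 - d[:, e])
            G = probs[:, m.tree.n_internal:] @ m.tree.leaves
            return np.mean((Y - G) ** 2)

        h = 1e-5
        for i in range(n):
            for e in range(m.tree.n_internal):
                Fp = cache.F.copy()
                Fp[i, e] += h
                Fm = cache.F.copy()
                Fm[i, e] -= h
                num = (loss_from_scores(Fp) - loss_from_scores(Fm)) / (2 * h)
                assert got[i, e] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_saturated_node_gradient_vanishes(self):
        rng = np.random.default_rng(2)
        m = small_model(rng, depth=1, K=1)
        m.tree.bt[:] = 60.0  # d_e saturated at 1
        X = rng.standard_normal((4, 4))
        cache = forward(X, np.eye(4), m)
        Y = rng.standard_normal((4, 1))
        np.testing.assert_allclose(
            decision_node_gradient(cache, m.tree, Y), 0.0, atol=1e-20)

    def test_equal_subtrees_give_zero_node_gradient(self):
        rng = np.random.default_rng(3)
        m = small_model(rng, depth=1, K=1)
        m.tree.leaves[:] = 0.4  # identical left/right outputs
        cache = forward(rng.standard_normal((4, 4)), np.eye(4), m)
        Y = rng.standard_normal((4, 1))
        np.testing.assert_allclose(
            decision_node_gradient(cache, m.tree, Y), 0.0, atol=1e-15)

    def test_leaf_gradient_closed_form(self):
        rng = np.random.default_rng(4)
        m = small_model(rng, depth=2, K=3)
        X = rng.standard_normal((4, 4))
        cache = forward(X, np.eye(4), m)
        Y = rng.standard_normal((4, 3))
        got = leaf_gradient(cache, m.tree, Y)
        np.testing.assert_allclose(got, backward(cache, m, Y)["leaves"],
                                   atol=1e-12)
        # zero residuals -> zero gradient
        np.testing.assert_allclose(
            leaf_gradient(cache, m.tree, cache.G), 0.0, atol=1e-15)


class TestTraining:
    def test_constant_targets_are_fit_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        A = build_patient_graph(X, 3).normalized
        Y = np.full((20, 2), 0.6)
        cfg = TrainConfig(hidden=(8, 4), depth=2, epochs=200, dropout=0.0,
                          seed=0)
        res = train(X, A, Y, np.arange(14), np.arange(14, 17), cfg)
        assert res.train_loss[-1] < 1e-3

    def test_two_cluster_toy_beats_constant_predictor(self):
        rng = np.random.default_rng(1)
        n = 40
        labels = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 2)) + np.where(labels[:, None], 3.0, -3.0)
        Y = (np.where(labels, 0.9, 0.3) + 0.02 * rng.standard_normal(n))[:, None]
        A = build_patient_graph(X, 5).normalized
        perm = rng.permutation(n)
        tr, va, te = perm[:28], perm[28:32], perm[32:]
        cfg = TrainConfig(hidden=(8, 4), depth=2, epochs=500, dropout=0.0,
                          weight_decay=1e-4, seed=1)
        res = train(X, A, Y, tr, va, cfg)
        pred = predict_rmst(X, A, res.model)
        mse = float(np.mean((pred[te] - Y[te]) ** 2))
        assert mse < Y[te].var(), "should beat the constant predictor"

    def test_seeded_runs_are_identical(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 3))
        A = build_patient_graph(X, 3).normalized
        Y = rng.standard_normal((15, 1))
        cfg = TrainConfig(hidden=(6, 3), depth=2, epochs=50, seed=7)
        r1 = train(X, A, Y, np.arange(10), np.arange(10, 13), cfg)
        r2 = train(X, A, Y, np.arange(10), np.arange(10, 13), cfg)
        assert r1.train_loss == r2.train_loss
        np.testing.assert_array_equal(r1.model.tree.leaves,
                                      r2.model.tree.leaves)

    def test_divergence_aborts_with_diagnostics(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 2)) * 1e3
        A = np.eye(10)
        Y = np.full((10, 1), 1e200)  # squared residual overflows to inf
        cfg = TrainConfig(hidden=(4, 2), depth=1, epochs=50, seed=0)
        with pytest.raises(FloatingPointError, match="diverged"):
            train(X, A, Y, np.arange(8), np.arange(8, 10), cfg)


class TestCheckpoint:
    def test_save_load_roundtrip_reproduces_predictions(self, tmp_path):
        rng = np.random.default_rng(5)
        m = small_model(rng, depth=3, K=2)
        m.kn = 4
        X = rng.standard_normal((6, 4))
        A = build_patient_graph(X, 2).normalized
        path = tmp_path / "ckpt.zip"
        m.save(path)
        m2 = GTModel.load(path)
        np.testing.assert_array_equal(predict_rmst(X, A, m),
                                      predict_rmst(X, A, m2))
        assert m2.kn == 4 and m2.tree.depth == 3
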