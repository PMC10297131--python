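import math

import numpy as np
import pytest

from ckdfusion.graph import PatientGraph, build_knn_graph, normalize_adjacency
from ckdfusion.models import (
    BaselineModel,
    FusionModel,
    GCNModel,
    TabularModel,
    baseline_forward,
    build_model,
    fusion_forward,
    gcn_forward,
    gcn_layer_forward,
    init_params,
    tabular_forward,
)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def dense_normalized_adjacency(g: PatientGraph, use_weights=True):
    """Dense oracle: D^(-1/2) (A + I) D^(-1/2) built with plain numpy."""
    n = g.n_nodes
    A = np.zeros((n, n))
    for (i, j), w in g.weights.items():
        A[i, j] = A[j, i] = w if use_weights else 1.0
    A += np.eye(n)
    deg = A.sum(axis=1)
    return A / np.sqrt(np.outer(deg, deg))


def loop_gcn_layer(H, A_hat, W, b, act):
    """Per-node sum form: h_i' = act(sum_j a_ij W h_j + b)."""
    n, m_out = H.shape[0], W.shape[0]
    out = np.zeros((n, m_out))
    for i in range(n):
        acc = np.zeros(m_out)
        for j in range(n):
            if A_hat[i, j] != 0:
                acc += A_hat[i, j] * (W @ H[j])
        out[i] = act(acc + b)
    return out


@pytest.fixture
def small_graph(rng):
    X = rng.normal(size=(5, 3))
    g = build_knn_graph(X, k=2)
    return X, g, normalize_adjacency(g, "sym")


class TestGcnLayer:
    def test_isolated_node_identity_propagation(self):
        g = PatientGraph(n_nodes=1, weights={}, knn_k=1, metric="euclidean")
        A = normalize_adjacency(g, "sym")
        H = np.array([[1.5, -2.0]])
        out = gcn_layer_forward(H, A, W=np.eye(2), b=np.zeros(2),
                                activation="identity")
        assert np.allclose(out, H)

    def test_matches_dense_oracle(self, rng, small_graph):
        X, g, A = small_graph
        W = rng.normal(size=(4, 3))
        b = rng.normal(size=4)
        A_hat = dense_normalized_adjacency(g)
        expect = loop_gcn_layer(X, A_hat, W, b, lambda z: np.maximum(z, 0))
        got = gcn_layer_forward(X, A, W, b, "relu")
        assert np.allclose(got, expect, atol=1e-6)

    def test_shape_error_names_shapes(self, small_graph):
        X, _, A = small_graph
        with pytest.raises(ValueError, match="incompatible"):
            gcn_layer_forward(X, A, W=np.zeros((4, 7)), b=np.zeros(4))

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(6, 3))
        g = build_knn_graph(X, k=2)
        A = normalize_adjacency(g, "sym")
        perm = rng.permutation(6)
        gp = build_knn_graph(X[perm], k=2)
        Ap = normalize_adjacency(gp, "sym")
        W, b = rng.normal(size=(2, 3)), rng.normal(size=2)
        out = gcn_layer_forward(X, A, W, b, "relu")
        out_p = gcn_layer_forward(X[perm], Ap, W, b, "relu")
        assert np.allclose(out_p, out[perm], atol=1e-10)


class TestGcnForward:
    def test_constant_network(self, small_graph):
        X, _, A = small_graph
        model = GCNModel(A, in_dim=3, conv_dims=(4,), seed=0)
        for name, t in model.params.items():
            t.value[...] = 0.0
        model.params["head0.b"].value[...] = 0.7
        scores, _ = gcn_forward(model, X)
        assert np.allclose(scores, sigmoid(0.7))

    def test_scores_in_unit_interval(self, small_graph):
        X, _, A = small_graph
        model = GCNModel(A, in_dim=3, seed=1)
        scores, emb = gcn_forward(model, X)
        assert ((scores > 0) & (scores < 1)).all()
        assert emb.shape == (5, model.embedding_dim)

    def test_two_layer_matches_loop_oracle(self, rng):
        X = rng.normal(size=(4, 3))
        g = build_knn_graph(X, k=1)
        A = normalize_adjacency(g, "sym")
        model = GCNModel(A, in_dim=3, conv_dims=(5, 2), seed=2)
        A_hat = dense_normalized_adjacency(g)
        relu = lambda z: np.maximum(z, 0)
        H = loop_gcn_layer(X, A_hat, model.params["conv0.W"].value,
                           model.params["conv0.b"].value, relu)
        H = loop_gcn_layer(H, A_hat, model.params["conv1.W"].value,
                           model.params["conv1.b"].value, relu)
        expect = sigmoid(H @ model.params["head0.W"].value.T
                         + model.params["head0.b"].value).ravel()
        scores, emb = gcn_forward(model, X)
        assert np.allclose(emb, H, atol=1e-6)
        assert np.allclose(scores, expect, atol=1e-6)

    def test_score_multiset_invariant_under_relabeling(self, rng):
        X = rng.normal(size=(8, 3))
        perm = rng.permutation(8)
        A = normalize_adjacency(build_knn_graph(X, k=2), "sym")
        Ap = normalize_adjacency(build_knn_graph(X[perm], k=2), "sym")
        m = GCNModel(A, in_dim=3, seed=5)
        mp = GCNModel(Ap, in_dim=3, seed=5)
        s, e = m.forward(X)
        sp, ep = mp.forward(X[perm])
        assert np.allclose(np.sort(sp), np.sort(s), atol=1e-10)
        assert np.allclose(ep, e[perm], atol=1e-10)   # equivariant embeddings


class TestTabular:
    def test_zero_hidden_layers_is_logistic(self, rng):
        X = rng.normal(size=(5, 3))
        model = TabularModel(in_dim=3, hidden_dims=(), seed=0)
        scores, emb = tabular_forward(model, X)
        w = model.params["out.W"].value.ravel()
        b = model.params["out.b"].value[0]
        assert np.allclose(scores, sigmoid(X @ w + b))
        assert np.allclose(emb, X)

    def test_zero_weights_constant_output(self, rng):
        X = rng.normal(size=(4, 2))
        model = TabularModel(in_dim=2, hidden_dims=(3,), seed=0)
        for t in model.params.values():
            t.value[...] = 0.0
        model.params["out.b"].value[...] = -0.3
        scores, _ = tabular_forward(model, X)
        assert np.allclose(scores, sigmoid(-0.3))

    def test_hand_computed_forward(self):
        # 2 features -> 2 relu units -> sigmoid output, all weights chosen
        model = TabularModel(in_dim=2, hidden_dims=(2,), seed=0)
        model.params["hidden0.W"].value[...] = [[1.0, 0.0], [0.0, -1.0]]
        model.params["hidden0.b"].value[...] = [0.0, 0.5]
        model.params["out.W"].value[...] = [[2.0, -1.0]]
        model.params["out.b"].value[...] = [0.25]
        X = np.array([[1.0, -1.0]])
        # h = relu([1*1, -1*-1 + 0.5]) = [1, 1.5]; z = 2 - 1.5 + 0.25 = 0.75
        scores, emb = tabular_forward(model, X)
        assert np.allclose(emb, [[1.0, 1.5]], atol=1e-9)
        assert scores[0] == pytest.approx(1 / (1 + math.exp(-0.75)),
                                          abs=1e-9)

    def test_shape_error(self):
        model = TabularModel(in_dim=3)
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 4)))


class TestFusion:
    def _scalar_model(self):
        g = PatientGraph(n_nodes=1, weights={}, knn_k=1, metric="euclidean")
        A = normalize_adjacency(g, "sym")
        return FusionModel(A, in_dim=1, conv_dims=(1,), tab_hidden_dims=(1,),
                           p_prime=1, seed=0)

    def test_hand_computed_scalar_chain(self):
        m = self._scalar_model()
        m.params["gnn.conv0.W"].value[...] = [[2.0]]
        m.params["gnn.conv0.b"].value[...] = [0.0]
        m.params["tab.hidden0.W"].value[...] = [[3.0]]
        m.params["tab.hidden0.b"].value[...] = [0.0]
        m.params["transform_g.W"].value[...] = [[1.0]]
        m.params["transform_g.b"].value[...] = [0.0]
        m.params["transform_t.W"].value[...] = [[1.0]]
        m.params["transform_t.b"].value[...] = [0.0]
        m.params["head.W"].value[...] = [[1.0]]
        m.params["head.b"].value[...] = [0.1]
        X = np.array([[1.0]])
        # G = relu(2) = 2, T = relu(3) = 3, G_t = 2, T_t = 3, F = 2.5
        scores, favg = fusion_forward(m, X)
        assert favg[0, 0] == pytest.approx(2.5, abs=1e-12)
        assert scores[0] == pytest.approx(sigmoid(2.6), abs=1e-12)

    def test_average_of_equal_transforms(self, rng):
        X = rng.normal(size=(6, 3))
        A = normalize_adjacency(build_knn_graph(X, k=2), "sym")
        m = FusionModel(A, in_dim=3, conv_dims=(4,), tab_hidden_dims=(4,),
                        p_prime=2, seed=3)
        # zero both transforms: G_t == T_t == bias through the activation
        m.params["transform_g.W"].value[...] = 0.0
        m.params["transform_t.W"].value[...] = 0.0
        m.params["transform_g.b"].value[...] = [1.0, 2.0]
        m.params["transform_t.b"].value[...] = [1.0, 2.0]
        _, favg = fusion_forward(m, X)
        assert np.allclose(favg, np.tile([1.0, 2.0], (6, 1)))

    def test_sigmoid_transforms_keep_favg_in_unit_interval(self, rng):
        X = rng.normal(size=(6, 3))
        A = normalize_adjacency(build_knn_graph(X, k=2), "sym")
        m = FusionModel(A, in_dim=3, transform_activation="sigmoid", seed=1)
        scores, favg = fusion_forward(m, X)
        assert ((favg > 0) & (favg < 1)).all()
        assert ((scores > 0) & (scores < 1)).all()

    def test_degenerates_to_tabular_function_when_graph_branch_zeroed(self, rng):
        X = rng.normal(size=(6, 3))
        A = normalize_adjacency(build_knn_graph(X, k=2), "sym")
        m = FusionModel(A, in_dim=3, seed=4)
        m.params["transform_g.W"].value[...] = 0.0
        m.params["transform_g.b"].value[...] = 0.0
        scores1, _ = fusion_forward(m, X)
        # changing the graph branch weights must not change the output
        m.params["gnn.conv0.W"].value[...] += 1.0
        scores2, _ = fusion_forward(m, X)
        assert np.allclose(scores1, scores2)


class TestBaseline:
    def test_zero_weights_half(self):
        m = BaselineModel(in_dim=3, seed=0)
        m.params["W"].value[...] = 0.0
        scores = baseline_forward(m, np.ones((4, 3)))
        assert np.allclose(scores, 0.5)

    def test_equals_tabular_with_no_hidden_layers(self, rng):
        X = rng.normal(size=(5, 3))
        b = BaselineModel(in_dim=3, seed=7)
        t = TabularModel(in_dim=3, hidden_dims=(), seed=7)
        t.params["out.W"].value[...] = b.params["W"].value
        t.params["out.b"].value[...] = b.params["b"].value
        assert np.allclose(baseline_forward(b, X), t.forward(X)[0])

    def test_hand_computed(self):
        m = BaselineModel(in_dim=2, seed=0)
        m.params["W"].value[...] = [[1.0, -1.0]]
        m.params["b"].value[...] = [0.5]
        X = np.array([[1.0, 1.0], [2.0, 0.0]])
        assert np.allclose(baseline_forward(m, X),
                           sigmoid(np.array([0.5, 2.5])))


class TestInitParams:
    def test_determinism(self):
        a = init_params((4, 3), "glorot_uniform", seed=9)
        b = init_params((4, 3), "glorot_uniform", seed=9)
        assert np.array_equal(a, b)

    def test_glorot_bound(self):
        W = init_params((50, 30), "glorot_uniform", seed=0)
        bound = math.sqrt(6.0 / (30 + 50))
        assert np.abs(W).max() <= bound

    def test_he_bound(self):
        W = init_params((50, 30), "he_uniform", seed=0)
        assert np.abs(W).max() <= math.sqrt(6.0 / 30)

    def test_monte_carlo_mean_near_zero(self):
        W = init_params((500, 200), "glorot_uniform", seed=1)
        bound = math.sqrt(6.0 / 700)
        se = bound / math.sqrt(3 * W.size)
        assert abs(W.mean()) < 3 * se

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            init_params((0, 3), "glorot_uniform", 0)
        with pytest.raises(ValueError):
            init_params((2, 2), "magic", 0)


class TestCheckpointing:
    def test_round_trip_reproduces_forward(self, rng, tmp_path):
        X = rng.normal(size=(6, 3))
        A = normalize_adjacency(build_knn_graph(X, k=2), "sym")
        m = FusionModel(A, in_dim=3, seed=6)
        scores, _ = m.forward(X)
        m.save_checkpoint(str(tmp_path / "m.json"), str(tmp_path / "m.npz"))
        m2 = FusionModel(A, in_dim=3, seed=99)
        state = dict(np.load(str(tmp_path / "m.npz")))
        m2.load_state_dict(state)
        scores2, _ = m2.forward(X)
        assert np.array_equal(scores, scores2)

    def test_build_model_factory(self, rng):
        A = normalize_adjacency(build_knn_graph(rng.normal(size=(6, 3)), k=2))
        for fam in ("fusion", "gnn", "tabular", "baseline"):
            m = build_model(fam, 3, A, seed=0)
            assert m.family == fam
        with pytest.raises(ValueError):
            build_model("svm", 3, A)
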