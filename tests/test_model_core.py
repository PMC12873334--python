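import math

import numpy as np
import pytest

from kgdemand.model_core import (
    ForecastNetwork,
    GcnParams,
    HeadParams,
    LstmParams,
    LstmState,
    ModelParams,
    clipped_gcn_forward,
    count_parameters,
    gcn_layer_forward,
    init_model_params,
    lstm_forward,
    mse_loss,
    normalize_adjacency,
    predict_head,
    relu,
)
from conftest import random_adjacency


def path_adjacency(n):
    m = np.zeros((n, n))
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = 1
    return m


class TestNormalizeAdjacency:
    def test_single_node(self):
        assert np.array_equal(normalize_adjacency(np.zeros((1, 1))).propagation_matrix, [[1.0]])

    def test_two_node_edge(self):
        a_hat = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]])).propagation_matrix
        assert np.allclose(a_hat, [[0.5, 0.5], [0.5, 0.5]])

    def test_three_node_star(self):
        m = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)  # node 0 is the centre
        a_hat = normalize_adjacency(m).propagation_matrix
        assert a_hat[0, 0] == pytest.approx(1 / 3)
        assert a_hat[0, 1] == pytest.approx(1 / math.sqrt(6))
        assert a_hat[1, 1] == pytest.approx(1 / 2)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            normalize_adjacency(np.eye(2))

    def test_dense_oracle_and_spectrum(self, rng):
        """A_hat equals D'^{-1/2} (M+I) D'^{-1/2} evaluated longhand; its
        eigenvalues lie in [-1, 1]."""
        for _ in range(100):
            n = int(rng.integers(1, 9))
            m = random_adjacency(rng, n)
            got = normalize_adjacency(m)
            m_prime = m + np.eye(n)
            d_inv_sqrt = np.diag(1.0 / np.sqrt(m_prime.sum(axis=1)))
            expected = d_inv_sqrt @ m_prime @ d_inv_sqrt
            assert np.allclose(got.propagation_matrix, expected, atol=1e-8)
            eig = np.linalg.eigvalsh(got.propagation_matrix)
            assert eig.min() >= -1 - 1e-9 and eig.max() <= 1 + 1e-9


class TestGcnLayer:
    def test_identity_single_node(self):
        norm = normalize_adjacency(np.zeros((1, 1)))
        out = gcn_layer_forward(norm, np.array([[3.5]]), np.eye(1), np.zeros(1))
        assert out[0, 0] == 3.5
        out_neg = gcn_layer_forward(norm, np.array([[-2.0]]), np.eye(1), np.zeros(1))
        assert out_neg[0, 0] == 0.0  # ReLU clamp

    def test_zero_weights_zero_output(self, rng):
        norm = normalize_adjacency(random_adjacency(rng, 4))
        H = rng.normal(size=(4, 3))
        out = gcn_layer_forward(norm, H, np.zeros((3, 2)), np.zeros(2))
        assert np.array_equal(out, np.zeros((4, 2)))

    def test_per_node_loop_oracle(self, rng):
        """Matrix form equals the per-node aggregation sum_j A_ij (H_j W)."""
        for _ in range(20):
            norm = normalize_adjacency(random_adjacency(rng, 5))
            H = rng.normal(size=(5, 4))
            W = rng.normal(size=(4, 3))
            b = rng.normal(size=3)
            got = gcn_layer_forward(norm, H, W, b)
            a_hat = norm.propagation_matrix
            expected = np.empty((5, 3))
            for i in range(5):
                acc = np.zeros(3)
                for j in range(5):
                    acc += a_hat[i, j] * (H[j] @ W)
                expected[i] = relu(acc + b)
            assert np.allclose(got, expected, rtol=1e-6)

    def test_shape_mismatch_reported(self, rng):
        norm = normalize_adjacency(random_adjacency(rng, 4))
        with pytest.raises(ValueError, match="shape"):
            gcn_layer_forward(norm, np.ones((4, 3)), np.ones((5, 2)), np.zeros(2))


def two_layer_params(rng, f=6, d=5):
    return GcnParams(
        weights=[rng.normal(size=(f, d)), rng.normal(size=(d, d))],
        biases=[rng.normal(size=d), rng.normal(size=d)],
    )


class TestClippedGcn:
    def test_clip_is_target_row_of_full_output(self, rng):
        norm = normalize_adjacency(random_adjacency(rng, 5))
        params = two_layer_params(rng)
        X = rng.normal(size=(5, 6))
        full = X
        for W, b in zip(params.weights, params.biases):
            full = gcn_layer_forward(norm, full, W, b)
        for pos in range(5):
            assert np.array_equal(clipped_gcn_forward(norm, X, params, pos), full[pos])

    def test_locality_beyond_two_hops(self, rng):
        """On a 6-node path, perturbing a node >= 3 hops away leaves the
        clipped 2-layer output unchanged."""
        norm = normalize_adjacency(path_adjacency(6))
        params = two_layer_params(rng)
        X = rng.normal(size=(6, 6))
        base = clipped_gcn_forward(norm, X, params, 0)
        for far in (3, 4, 5):
            X2 = X.copy()
            X2[far] += rng.normal(size=6) * 10
            assert np.allclose(clipped_gcn_forward(norm, X2, params, 0), base, rtol=1e-6)
        X3 = X.copy()
        X3[2] += 1.0  # 2 hops: inside the receptive field
        assert not np.allclose(clipped_gcn_forward(norm, X3, params, 0), base)

    def test_permutation_invariance(self, rng):
        m = random_adjacency(rng, 5)
        params = two_layer_params(rng)
        X = rng.normal(size=(5, 6))
        base = clipped_gcn_forward(normalize_adjacency(m), X, params, 2)
        for _ in range(5):
            perm = rng.permutation(5)
            m_p = m[np.ix_(perm, perm)]
            X_p = X[perm]
            pos_p = int(np.flatnonzero(perm == 2)[0])
            out = clipped_gcn_forward(normalize_adjacency(m_p), X_p, params, pos_p)
            assert np.allclose(out, base, rtol=1e-6)

    def test_bad_target_position(self, rng):
        norm = normalize_adjacency(random_adjacency(rng, 3))
        with pytest.raises(ValueError, match="target_position"):
            clipped_gcn_forward(norm, np.ones((3, 6)), two_layer_params(rng), 7)


def scalar_lstm(w, u, b):
    return LstmParams(
        W={g: np.array([[w[g]]]) for g in "fico"},
        U={g: np.array([[u[g]]]) for g in "fico"},
        b={g: np.array([b[g]]) for g in "fico"},
    )


class TestLstm:
    def test_zero_weights_give_zero_states(self):
        params = scalar_lstm({g: 0 for g in "fico"}, {g: 0 for g in "fico"}, {g: 0 for g in "fico"})
        state = lstm_forward([np.array([x]) for x in (1.0, -2.0, 3.0)], params)
        # sigma(0) = 0.5 but tanh(0) = 0, so candidate, cell and hidden all stay 0
        assert state.hidden[0] == 0.0 and state.cell[0] == 0.0

    def test_single_step_hand_computed(self):
        """One scalar step checked against longhand gate arithmetic."""
        w = {"f": 0.5, "i": -0.3, "c": 0.8, "o": 0.2}
        u = {"f": 0.1, "i": 0.4, "c": -0.2, "o": 0.3}
        b = {"f": 0.05, "i": -0.1, "c": 0.2, "o": 0.0}
        x = 1.5
        sig = lambda z: 1 / (1 + math.exp(-z))
        f = sig(w["f"] * x + b["f"])  # h_prev = 0, c_prev = 0
        i = sig(w["i"] * x + b["i"])
        chat = math.tanh(w["c"] * x + b["c"])
        c = f * 0 + i * chat
        o = sig(w["o"] * x + b["o"])
        h = o * math.tanh(c)
        state = lstm_forward([np.array([x])], scalar_lstm(w, u, b))
        assert state.cell[0] == pytest.approx(c, rel=1e-12)
        assert state.hidden[0] == pytest.approx(h, rel=1e-12)
        assert state.forget_gate[0] == pytest.approx(f, rel=1e-12)

    def test_two_steps_use_recurrence(self):
        w = {"f": 0.5, "i": -0.3, "c": 0.8, "o": 0.2}
        u = {"f": 0.1, "i": 0.4, "c": -0.2, "o": 0.3}
        b = {"f": 0.05, "i": -0.1, "c": 0.2, "o": 0.0}
        xs = [1.5, -0.7]
        sig = lambda z: 1 / (1 + math.exp(-z))
        h = c = 0.0
        for x in xs:
            f = sig(w["f"] * x + u["f"] * h + b["f"])
            i = sig(w["i"] * x + u["i"] * h + b["i"])
            chat = math.tanh(w["c"] * x + u["c"] * h + b["c"])
            c = f * c + i * chat
            o = sig(w["o"] * x + u["o"] * h + b["o"])
            h = o * math.tanh(c)
        state = lstm_forward([np.array([x]) for x in xs], scalar_lstm(w, u, b))
        assert state.hidden[0] == pytest.approx(h, rel=1e-12)

    def test_zero_recurrent_matrices_reproduce_input_only_gates(self, rng):
        """With U = 0 the gates depend on x_t alone — the recurrence-free
        gate equations are a special case of the implementation."""
        hid, d = 4, 3
        params = LstmParams(
            W={g: rng.normal(size=(d, hid)) for g in "fico"},
            U={g: np.zeros((hid, hid)) for g in "fico"},
            b={g: rng.normal(size=hid) for g in "fico"},
        )
        xs = [rng.normal(size=d) for _ in range(5)]
        state = lstm_forward(xs, params)
        sig = lambda z: 1 / (1 + np.exp(-z))
        h = np.zeros(hid)
        c = np.zeros(hid)
        for x in xs:
            f = sig(params.W["f"].T @ x + params.b["f"])
            i = sig(params.W["i"].T @ x + params.b["i"])
            chat = np.tanh(params.W["c"].T @ x + params.b["c"])
            c = f * c + i * chat
            o = sig(params.W["o"].T @ x + params.b["o"])
            h = o * np.tanh(c)
        assert np.allclose(state.hidden, h, rtol=1e-10)

    def test_hidden_bounded(self, rng):
        hid, d = 4, 3
        params = LstmParams(
            W={g: rng.normal(size=(d, hid)) * 5 for g in "fico"},
            U={g: rng.normal(size=(hid, hid)) * 5 for g in "fico"},
            b={g: rng.normal(size=hid) for g in "fico"},
        )
        state = lstm_forward([rng.normal(size=d) * 100 for _ in range(8)], params)
        assert np.all(np.abs(state.hidden) < 1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lstm_forward([], scalar_lstm({g: 0 for g in "fico"}, {g: 0 for g in "fico"}, {g: 0 for g in "fico"}))


class TestHead:
    def test_zero_hidden_gives_zero(self):
        head = HeadParams(weight=np.ones(4))
        assert predict_head(LstmState(hidden=np.zeros(4), cell=np.zeros(4)), head) == 0.0

    def test_negative_preactivation_clamped(self):
        head = HeadParams(weight=np.array([1.0, 1.0]))
        state = LstmState(hidden=np.array([-3.0, 1.0]), cell=np.zeros(2))
        assert predict_head(state, head) == 0.0

    def test_dot_product_by_hand(self):
        head = HeadParams(weight=np.array([0.5, -1.0, 2.0]))
        state = LstmState(hidden=np.array([2.0, 1.0, 3.0]), cell=np.zeros(3))
        assert predict_head(state, head) == pytest.approx(0.5 * 2 - 1 + 2 * 3)

    def test_nonnegative_for_random_inputs(self, rng):
        head = HeadParams(weight=rng.normal(size=8))
        for _ in range(50):
            state = LstmState(hidden=rng.normal(size=8), cell=np.zeros(8))
            assert predict_head(state, head) >= 0.0


class TestMseLoss:
    def test_identity_zero(self):
        assert mse_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_hand_case(self):
        assert mse_loss(np.array([2.0, 4.0]), np.array([1.0, 2.0])) == pytest.approx(2.5)

    def test_quadratic_homogeneity(self, rng):
        y = rng.normal(size=10)
        p = rng.normal(size=10)
        base = mse_loss(p, y)
        scaled = mse_loss(y + 3 * (p - y), y)
        assert scaled == pytest.approx(9 * base)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mse_loss(np.ones(3), np.ones(4))


class TestCountParameters:
    def test_reference_configuration_matches_printed_counts(self, rng):
        p = init_model_params(rng)
        counts = count_parameters(p)
        assert counts["gcn_layer_1"] == 1088
        assert counts["gcn_layer_2"] == 4160
        assert counts["lstm"] == 33024
        assert counts["head"] == 64
        assert counts["total"] == 38336

    @pytest.mark.parametrize("hidden, expected_lstm", [(16, 5184), (32, 12416), (64, 33024)])
    def test_lstm_count_formula(self, rng, hidden, expected_lstm):
        p = init_model_params(rng, hidden_dim=hidden)
        assert count_parameters(p)["lstm"] == 4 * (64 * hidden + hidden * hidden + hidden) == expected_lstm

    def test_lstm_only_has_no_gcn_blocks(self, rng):
        p = init_model_params(rng, gcn_layers=0)
        counts = count_parameters(p)
        assert not any(k.startswith("gcn") for k in counts)
        assert counts["lstm"] == 4 * (16 * 64 + 64 * 64 + 64)  # input is the raw window


class TestForecastNetworkConsistency:
    """The batched training network must agree with the per-sample
    reference operations."""

    def test_batched_forward_equals_reference_composition(self, rng):
        n, f, d, hid = 5, 6, 4, 3
        params = init_model_params(rng, n_features=f, gcn_hidden=d, hidden_dim=hid, dropout_rate=0.0)
        net = ForecastNetwork(params, clip=True)
        m = random_adjacency(rng, n)
        norm = normalize_adjacency(m)
        X = rng.normal(size=(2, 7, n, f))
        got, _ = net.forward(X, norm.propagation_matrix, 1, train=False)
        for sample in range(2):
            zs = [clipped_gcn_forward(norm, X[sample, t], params.gcn, 1) for t in range(7)]
            state = lstm_forward(zs, params.lstm)
            expected = predict_head(state, params.head)
            assert got[sample] == pytest.approx(expected, rel=1e-10)

    def test_gradients_match_finite_differences(self, rng):
        for temporal, layers, clip in [("lstm", 2, True), ("lstm", 0, True), ("mlp", 2, True), ("lstm", 2, False)]:
            params = init_model_params(
                rng, n_features=5, gcn_layers=layers, gcn_hidden=4, hidden_dim=3,
                temporal=temporal, dropout_rate=0.0,
            )
            net = ForecastNetwork(params, clip=clip)
            # positive parameters + positive inputs keep every ReLU active,
            # so gradient flows through all blocks at the checked point
            for arr in net.parameter_dict().values():
                arr[:] = np.abs(arr) + 0.05
            m = path_adjacency(4)
            a_hat = normalize_adjacency(m).propagation_matrix
            X = np.abs(rng.normal(size=(6, 7, 4, 5)))
            y = np.abs(rng.normal(size=6))
            _, grads = net.loss_and_grads(X, y, a_hat, 1, train=False)
            assert all(np.abs(g).max() > 0 for g in grads.values())
            pd = net.parameter_dict()
            for k, arr in pd.items():
                idx = tuple(int(rng.integers(0, s)) for s in arr.shape)
                eps = 1e-6
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = net.loss_and_grads(X, y, a_hat, 1, train=False)
                arr[idx] = orig - eps
                lm, _ = net.loss_and_grads(X, y, a_hat, 1, train=False)
                arr[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)
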