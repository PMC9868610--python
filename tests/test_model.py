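import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvsl import (bce_loss, encode_views, gcn_layer, init_state, max_pool_views,
                  normalize_adjacency, pair_features, pooled_embedding,
                  predict_pair)
from mvsl.model import ModelState, _head_forward


def brute_force_gcn(A_hat, H, W):
    """Per-node loop oracle for one graph convolution."""
    A = np.asarray(A_hat if not hasattr(A_hat, "toarray") else A_hat.toarray())
    HW = H @ W
    out = np.zeros((A.shape[0], W.shape[1]))
    for j in range(A.shape[0]):
        acc = np.zeros(W.shape[1])
        for m in range(A.shape[0]):
            acc += A[j, m] * HW[m]
        out[j] = np.maximum(acc, 0.0)
    return out


def random_adjacency(rng, n, density=0.4):
    A = (rng.random((n, n)) < density).astype(float)
    A = np.triu(A, 1)
    return A + A.T


class TestGcnLayer:
    def test_identity_case(self, rng):
        H = np.abs(rng.standard_normal((5, 3)))
        out = gcn_layer(np.eye(5), H, np.eye(3))
        np.testing.assert_allclose(out, H)

    def test_zero_weights(self, rng):
        out = gcn_layer(np.eye(4), rng.standard_normal((4, 3)), np.zeros((3, 2)))
        assert not out.any()

    def test_path_graph_matches_loop_oracle(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        A_hat = normalize_adjacency(A).toarray()
        H = np.array([[1.0], [2.0], [3.0]])
        W = np.array([[1.0]])
        np.testing.assert_allclose(gcn_layer(A_hat, H, W),
                                   brute_force_gcn(A_hat, H, W), atol=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            A_hat = normalize_adjacency(random_adjacency(rng, 6))
            H = rng.standard_normal((6, 4))
            W = rng.standard_normal((4, 3))
            np.testing.assert_allclose(gcn_layer(A_hat, H, W),
                                       brute_force_gcn(A_hat, H, W), atol=1e-10)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            gcn_layer(np.eye(3), rng.standard_normal((4, 2)), np.eye(2))
        with pytest.raises(ValueError):
            gcn_layer(np.eye(3), rng.standard_normal((3, 2)), np.eye(3))


class TestEncodeViews:
    def test_identical_adjacencies_share_embeddings(self, rng, tiny_state):
        A = normalize_adjacency(random_adjacency(rng, 5))
        X = rng.standard_normal((5, 4))
        Z = encode_views([A, A], X, tiny_state)
        np.testing.assert_array_equal(Z[0], Z[1])

    def test_identity_view_means_no_mixing(self, rng, tiny_state):
        X = rng.standard_normal((6, 4))
        Z = encode_views([np.eye(6)], X, tiny_state)[0]
        expected = np.maximum(np.maximum(X @ tiny_state.W0, 0) @ tiny_state.W1, 0)
        np.testing.assert_allclose(Z, expected, atol=1e-12)
        # own-node dependence only: perturbing gene 0 leaves other rows fixed
        X2 = X.copy()
        X2[0] += 1.0
        Z2 = encode_views([np.eye(6)], X2, tiny_state)[0]
        np.testing.assert_array_equal(Z[1:], Z2[1:])

    def test_permutation_equivariance(self, rng, tiny_state):
        n = 5
        A = random_adjacency(rng, n)
        X = rng.standard_normal((n, 4))
        perm = np.array([3, 0, 4, 1, 2])
        P = np.eye(n)[perm]
        A_hat = normalize_adjacency(A)
        A_hat_p = normalize_adjacency(P @ A @ P.T)
        Z = pooled_embedding([A_hat], X, tiny_state)
        Zp = pooled_embedding([A_hat_p], P @ X, tiny_state)
        np.testing.assert_allclose(Zp, Z[perm], atol=1e-8)


class TestMaxPool:
    def test_identical_views_identity(self, rng):
        Z = rng.random((4, 3))
        np.testing.assert_array_equal(max_pool_views([Z] * 5), Z)

    def test_elementwise_max(self):
        views = [np.array([[1.0, 2.0]]), np.array([[0.0, 5.0]])] + \
                [np.zeros((1, 2))] * 3
        np.testing.assert_array_equal(max_pool_views(views), [[1.0, 5.0]])

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            max_pool_views([np.zeros((2, 2)), np.zeros((3, 2))])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 4), st.integers(0, 2), st.floats(0.01, 10.0))
    def test_monotone_in_each_view(self, view, col, bump):
        rng = np.random.default_rng(9)
        views = [rng.random((3, 3)) for _ in range(5)]
        before = max_pool_views(views)
        views[view] = views[view].copy()
        views[view][1, col] += bump
        after = max_pool_views(views)
        assert np.all(after >= before - 1e-15)


class TestPairFeatures:
    def test_equal_embeddings_zero_difference_half(self):
        Z = np.array([[1.0, 2.0], [1.0, 2.0]])
        f = pair_features(Z, 0, 1)
        np.testing.assert_array_equal(f[2:], 0.0)

    def test_symmetry_under_swap(self, rng):
        Z = rng.standard_normal((6, 4))
        np.testing.assert_array_equal(pair_features(Z, 2, 5), pair_features(Z, 5, 2))

    def test_hand_value(self):
        Z = np.array([[1.0, 2.0], [3.0, 0.0]])
        np.testing.assert_array_equal(pair_features(Z, 0, 1), [3.0, 0.0, 2.0, 2.0])

    def test_self_pair_rejected(self, rng):
        with pytest.raises(ValueError):
            pair_features(rng.random((3, 2)), 1, 1)


class TestPredictPair:
    def test_zero_weights_give_half(self, tiny_state):
        state = ModelState(tiny_state.W0, tiny_state.W1,
                           [np.zeros_like(W) for W in tiny_state.head_W],
                           [np.zeros_like(b) for b in tiny_state.head_b])
        assert predict_pair(np.zeros(10), state) == 0.5

    def test_output_strictly_in_unit_interval(self, rng, tiny_state):
        for _ in range(1000):
            p = predict_pair(rng.standard_normal(10), tiny_state)
            assert 0.0 < p < 1.0

    def test_deterministic(self, rng, tiny_state):
        f = rng.standard_normal(10)
        assert predict_pair(f, tiny_state) == predict_pair(f, tiny_state)

    def test_nonfinite_features_rejected(self, tiny_state):
        f = np.zeros(10)
        f[3] = np.nan
        with pytest.raises(ValueError):
            predict_pair(f, tiny_state)

    def test_wrong_length_rejected(self, tiny_state):
        with pytest.raises(ValueError):
            predict_pair(np.zeros(7), tiny_state)


class TestBceLoss:
    def test_single_sample_half_is_ln2(self):
        assert bce_loss([0.5], [1]) == pytest.approx(np.log(2), abs=1e-12)

    def test_near_perfect_prediction_near_zero(self):
        assert bce_loss([1 - 1e-7, 1e-7], [1, 0]) < 1e-6

    def test_hand_computed_two_sample_case(self):
        expected = -0.5 * (np.log(0.9) + np.log(0.9))
        assert bce_loss([0.9, 0.1], [1, 0]) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_probabilities_clamped(self):
        val = bce_loss([0.0, 1.0], [0, 1])
        assert np.isfinite(val)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss([0.5], [1, 0])


class TestDegenerateViews:
    def test_empty_graphs_reduce_to_feedforward_on_features(self, rng, tiny_state):
        """With all views empty (identity after normalization), embeddings
        depend on each gene's own features only."""
        n = 7
        A_hat = normalize_adjacency(np.zeros((n, n)))
        X = rng.standard_normal((n, 4))
        Z = pooled_embedding([A_hat] * 5, X, tiny_state)
        X2 = X.copy()
        X2[3] = rng.standard_normal(4)
        Z2 = pooled_embedding([A_hat] * 5, X2, tiny_state)
        changed = np.any(Z != Z2, axis=1)
        assert not changed[np.arange(n) != 3].any()


class TestHeadForward:
    def test_dropout_scales_expectation(self, rng, tiny_state):
        F = rng.standard_normal((200, 10))
        p_plain, _ = _head_forward(F, tiny_state)
        draws = [_head_forward(F, tiny_state, dropout=0.3,
                               rng=np.random.default_rng(s))[0]
                 for s in range(30)]
        assert abs(np.mean(draws) - p_plain.mean()) < 0.05
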