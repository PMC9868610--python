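import numpy as np
import pytest
import scipy.sparse as sp

from mvsl import GeneUniverse, normalize_adjacency, label_pairs
from mvsl.io import GIScoreTable
from mvsl.graphs import (PairLabelSet, build_correlation_graph, build_node_features,
                         build_sl_graph, correlation_pvalues)


@pytest.fixture()
def uni4():
    return GeneUniverse(["A", "B", "C", "D"])


class TestLabelPairs:
    @pytest.mark.parametrize("score,expected", [
        (-3.5, 1),        # below the threshold -> SL
        (-3.0, 0),        # boundary score is a negative (strict inequality)
        (1.2, 0),
    ])
    def test_threshold_rule(self, uni4, score, expected):
        labels = label_pairs(GIScoreTable([("A", "B", score)]), -3.0, uni4)
        assert labels.label[0] == expected

    def test_all_screened_pairs_retained(self, uni4):
        table = GIScoreTable([("A", "B", -4.0), ("A", "C", 0.0), ("B", "C", -1.0)])
        labels = label_pairs(table, -3.0, uni4)
        assert len(labels) == 3 and labels.n_positive == 1

    def test_nonfinite_threshold_rejected(self, uni4):
        with pytest.raises(ValueError):
            label_pairs(GIScoreTable([("A", "B", 0.0)]), np.inf, uni4)


class TestNormalizeAdjacency:
    def test_two_node_path_hand_value(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A).toarray(),
                                   [[0.5, 0.5], [0.5, 0.5]], atol=1e-15)

    def test_zero_matrix_gives_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((3, 3))).toarray(),
                                   np.eye(3), atol=1e-15)

    def test_isolated_node_row_is_self_indicator(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        row = normalize_adjacency(A).toarray()[2]
        np.testing.assert_allclose(row, [0.0, 0.0, 1.0], atol=1e-15)

    @pytest.mark.parametrize("k,A", [
        (1, np.kron(np.eye(3), [[0, 1], [1, 0]])),          # perfect matching
        (2, None),                                           # 6-cycle, built below
        (3, 1.0 - np.eye(4)),                                # K4
    ])
    def test_k_regular_closed_form(self, k, A):
        if A is None:
            n = 6
            A = np.zeros((n, n))
            for i in range(n):
                A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
        A_hat = normalize_adjacency(A).toarray()
        on_edges = A_hat[A > 0]
        np.testing.assert_allclose(on_edges, 1.0 / (k + 1), atol=1e-12)
        np.testing.assert_allclose(np.diag(A_hat), 1.0 / (k + 1), atol=1e-12)

    def test_eigenvalues_in_unit_interval(self, rng):
        A = (rng.random((12, 12)) < 0.3).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        eig = np.linalg.eigvalsh(normalize_adjacency(A).toarray())
        assert eig.min() >= -1 - 1e-12 and eig.max() <= 1 + 1e-12

    def test_sparsity_pattern_is_a_plus_identity(self, rng):
        A = (rng.random((10, 10)) < 0.2).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        A_hat = normalize_adjacency(A)
        expected = (A + np.eye(10)) > 0
        assert np.array_equal(A_hat.toarray() > 0, expected)

    def test_rejects_asymmetric_and_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="symmetric"):
            normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            normalize_adjacency(np.eye(2))


class TestBuildSLGraph:
    def test_single_positive_edge(self, uni4):
        labels = PairLabelSet(np.array([0, 0]), np.array([1, 2]),
                              np.array([1, 0]))
        g = build_sl_graph(labels, uni4)
        assert g.n_edges == 1 and g.adjacency[0, 1] == 1 and g.adjacency[0, 2] == 0

    def test_all_negative_gives_identity_normalization(self, uni4):
        labels = PairLabelSet(np.array([0]), np.array([1]), np.array([0]))
        g = build_sl_graph(labels, uni4)
        assert g.adjacency.nnz == 0
        np.testing.assert_allclose(g.normalized.toarray(), np.eye(4))

    def test_triangle(self, uni4):
        labels = PairLabelSet(np.array([0, 0, 1]), np.array([1, 2, 2]),
                              np.array([1, 1, 1]))
        g = build_sl_graph(labels, uni4)
        assert g.n_edges == 3
        deg = np.asarray(g.adjacency.sum(axis=1)).ravel()
        np.testing.assert_array_equal(deg, [2, 2, 2, 0])


class TestCorrelationGraph:
    def test_near_identical_profiles_connected(self, rng):
        base = rng.standard_normal(10)
        profiles = np.vstack([base, base + 1e-6 * rng.standard_normal(10),
                              rng.standard_normal(10)])
        uni = GeneUniverse(["A", "B", "C"])
        g = build_correlation_graph(profiles, 0.01, uni, "COEXPR")
        assert g.adjacency[0, 1] == 1

    def test_constant_profile_never_connects(self, rng):
        profiles = np.vstack([np.full(10, 2.0), rng.standard_normal(10),
                              rng.standard_normal(10)])
        uni = GeneUniverse(["A", "B", "C"])
        g = build_correlation_graph(profiles, 0.5, uni, "COESS")
        assert g.adjacency[0, 1] == 0 and g.adjacency[0, 2] == 0

    def test_too_few_samples_error(self, rng):
        uni = GeneUniverse(["A", "B"])
        with pytest.raises(ValueError, match="samples"):
            build_correlation_graph(rng.standard_normal((2, 2)), 0.01, uni, "COEXPR")

    def test_pvalue_matches_scipy_pearsonr(self, rng):
        from scipy.stats import pearsonr

        profiles = rng.standard_normal((4, 15))
        _, p = correlation_pvalues(profiles)
        for i in range(4):
            for j in range(i + 1, 4):
                expected = pearsonr(profiles[i], profiles[j]).pvalue
                assert p[i, j] == pytest.approx(expected, rel=1e-9)

    def test_null_edge_rate_matches_alpha(self):
        # independent Gaussian profiles: edge rate should equal alpha
        rng = np.random.default_rng(42)
        n_genes, alpha = 160, 0.01
        profiles = rng.standard_normal((n_genes, 10))
        uni = GeneUniverse([f"G{i}" for i in range(n_genes)])
        g = build_correlation_graph(profiles, alpha, uni, "COEXPR")
        n_pairs = n_genes * (n_genes - 1) // 2
        rate = g.n_edges / n_pairs
        se = np.sqrt(alpha * (1 - alpha) / n_pairs)
        assert abs(rate - alpha) < 3 * se


class TestNodeFeatures:
    def _raw(self, values):
        rows = [f"g{i}" for i in range(values.shape[0])]
        cols = ["expression", "copy_number", "mutation", "essentiality"]
        return rows, cols, values, np.zeros_like(values, dtype=bool)

    def test_mutation_binarized(self):
        vals = np.column_stack([np.arange(3.0), np.arange(3.0),
                                np.array([0.0, 2.0, 0.0]), np.arange(3.0)])
        rows, cols, v, m = self._raw(vals)
        uni = GeneUniverse(rows)
        X = build_node_features(rows, cols, v, m, uni).X
        np.testing.assert_array_equal(X[:, 2], [0.0, 1.0, 0.0])

    def test_zscore_and_constant_guard(self, rng):
        vals = np.column_stack([rng.standard_normal(5), np.full(5, 3.0),
                                rng.integers(0, 2, 5).astype(float),
                                rng.standard_normal(5)])
        rows, cols, v, m = self._raw(vals)
        uni = GeneUniverse(rows)
        X = build_node_features(rows, cols, v, m, uni).X
        assert abs(X[:, 0].mean()) < 1e-6 and abs(X[:, 0].std() - 1) < 1e-6
        np.testing.assert_array_equal(X[:, 1], 0.0)  # constant column -> zeros

    def test_missing_cells_mean_imputed(self, rng):
        vals = np.column_stack([np.array([1.0, np.nan, 3.0]),
                                rng.standard_normal(3),
                                np.zeros(3), rng.standard_normal(3)])
        rows, cols, v, m = self._raw(vals)
        m[1, 0] = True
        uni = GeneUniverse(rows)
        X = build_node_features(rows, cols, v, m, uni).X
        assert np.isfinite(X).all()
        # imputed to the column mean -> z-score exactly 0
        assert X[1, 0] == pytest.approx(0.0)

    def test_missing_column_error(self, rng):
        vals = rng.standard_normal((3, 4))
        rows = ["a", "b", "c"]
        cols = ["expression", "copy_number", "mutation", "dependency"]
        uni = GeneUniverse(rows)
        with pytest.raises(ValueError, match="essentiality"):
            build_node_features(rows, cols, vals, np.zeros_like(vals, bool), uni)
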