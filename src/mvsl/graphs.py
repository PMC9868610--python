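"""Construction of the five view graphs and the node-feature matrix.

The five views share one gene universe and ordering: the cell-specific
synthetic-lethality (SL) graph, physical and genetic protein-interaction
networks, and co-expression / co-essentiality correlation networks. All
adjacencies are binary, symmetric, zero-diagonal, and symmetrically
normalized after adding self-loops:

    A_hat = D~^(-1/2) (A + I) D~^(-1/2),   D~ = diag(degree of A + I)

A gene missing from a source network keeps its row (degree 0), so its
normalized row is the indicator of its own self-loop; genes are never
dropped from the universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .io import GeneUniverse, GIScoreTable

logger = logging.getLogger("mvsl")

#: View identifiers, in their conventional order.
VIEW_IDS = ("SL", "PPI_PHYS", "PPI_GEN", "COEXPR", "COESS")

FEATURE_NAMES = ("expression", "copy_number", "mutation", "essentiality")

__all__ = [
    "VIEW_IDS",
    "FEATURE_NAMES",
    "ViewGraph",
    "NodeFeatureMatrix",
    "PairLabelSet",
    "label_pairs",
    "build_sl_graph",
    "build_graph_from_edges",
    "build_correlation_graph",
    "normalize_adjacency",
    "build_node_features",
]


def normalize_adjacency(A: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Symmetrically normalize a binary adjacency after adding self-loops.

    Every eigenvalue of the result lies in [-1, 1]; an isolated node's row is
    the indicator of its own self-loop.
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if (A != A.T).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    if A.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    n = A.shape[0]
    A_tilde = A + sp.identity(n, format="csr")
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)  # deg >= 1 because of the self-loop
    D = sp.diags(d_inv_sqrt)
    return (D @ A_tilde @ D).tocsr()


@dataclass
class ViewGraph:
    """One input view: binary adjacency over the universe plus its
    symmetrically normalized form."""

    view_id: str
    adjacency: sp.csr_matrix
    normalized: sp.csr_matrix = field(init=False)

    def __post_init__(self) -> None:
        if self.view_id not in VIEW_IDS and self.view_id != "RANDOM":
            raise ValueError(f"unknown view id {self.view_id!r}")
        self.adjacency = sp.csr_matrix(self.adjacency, dtype=np.float64)
        self.normalized = normalize_adjacency(self.adjacency)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)


@dataclass
class NodeFeatureMatrix:
    """N x 4 per-gene omics features: expression, copy number, mutation
    (binary), essentiality. Continuous columns are z-scored over genes."""

    X: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError(f"expected N x {len(self.feature_names)} features, got {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("node features contain non-finite values")


class PairLabelSet:
    """Labelled unordered gene pairs in canonical (u < v) index order.

    Stored as parallel numpy arrays; ``gi`` is NaN where no score is known.
    """

    def __init__(self, u: np.ndarray, v: np.ndarray, label: np.ndarray,
                 gi: np.ndarray | None = None):
        self.u = np.asarray(u, dtype=np.int64)
        self.v = np.asarray(v, dtype=np.int64)
        self.label = np.asarray(label, dtype=np.int8)
        self.gi = (np.full(len(self.u), np.nan) if gi is None
                   else np.asarray(gi, dtype=np.float64))
        if not (len(self.u) == len(self.v) == len(self.label) == len(self.gi)):
            raise ValueError("pair arrays must have equal length")
        if np.any(self.u >= self.v):
            raise ValueError("pairs must be canonical (u < v)")
        if not np.all(np.isin(self.label, (0, 1))):
            raise ValueError("labels must be 0/1")
        keys = self.pair_keys()
        if len(np.unique(keys)) != len(keys):
            raise ValueError("duplicate pairs in label set")

    def __len__(self) -> int:
        return len(self.u)

    def pair_keys(self, n_genes: int | None = None) -> np.ndarray:
        """Unique integer key per unordered pair (for fast set operations)."""
        n = int(max(self.v.max(initial=0) + 1, n_genes or 0))
        return self.u * n + self.v

    def subset(self, idx: np.ndarray) -> "PairLabelSet":
        return PairLabelSet(self.u[idx], self.v[idx], self.label[idx], self.gi[idx])

    @property
    def n_positive(self) -> int:
        return int(self.label.sum())

    @property
    def positive_rate(self) -> float:
        return float(self.label.mean())

    def genes(self) -> np.ndarray:
        return np.unique(np.concatenate([self.u, self.v]))


def label_pairs(scores: GIScoreTable, threshold: float,
                universe: GeneUniverse) -> PairLabelSet:
    """Threshold genetic-interaction scores into SL labels.

    A pair is SL (label 1) iff its GI score is strictly below ``threshold``;
    a score exactly at the threshold is a negative. All screened pairs are
    retained. Pairs with genes outside the universe are dropped (logged).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    us, vs, labels, gis = [], [], [], []
    dropped = 0
    for a, b, s in scores.records:
        if a not in universe or b not in universe:
            dropped += 1
            continue
        i, j = universe.pair_indices(a, b)
        us.append(i)
        vs.append(j)
        labels.append(1 if s < threshold else 0)
        gis.append(s)
    if dropped:
        logger.info("label_pairs: dropped %d pairs outside the universe", dropped)
    if not us:
        raise ValueError("no labelled pairs inside the universe")
    order = np.lexsort((vs, us))
    return PairLabelSet(np.asarray(us)[order], np.asarray(vs)[order],
                        np.asarray(labels)[order], np.asarray(gis)[order])


def _adjacency_from_index_pairs(u: np.ndarray, v: np.ndarray, n: int) -> sp.csr_matrix:
    data = np.ones(len(u), dtype=np.float64)
    A = sp.coo_matrix((data, (u, v)), shape=(n, n))
    A = A + A.T
    A = (A > 0).astype(np.float64)
    A.setdiag(0)
    A.eliminate_zeros()
    return A.tocsr()


def build_sl_graph(labels: PairLabelSet, universe: GeneUniverse) -> ViewGraph:
    """Cell-specific SL view: one edge per positive pair in ``labels``.

    Callers are responsible for passing *training* positives only when the
    graph feeds a model that will be evaluated on held-out pairs; test-pair
    edges must never enter this view.
    """
    pos = labels.label == 1
    A = _adjacency_from_index_pairs(labels.u[pos], labels.v[pos], len(universe))
    return ViewGraph("SL", A)


def build_graph_from_edges(pairs: list[tuple[str, str]], universe: GeneUniverse,
                           view_id: str) -> ViewGraph:
    """Build a view from identifier pairs (e.g. a PPI edge list)."""
    if pairs:
        idx = np.array([universe.pair_indices(a, b) for a, b in pairs], dtype=np.int64)
        u, v = idx[:, 0], idx[:, 1]
    else:
        u = v = np.empty(0, dtype=np.int64)
    return ViewGraph(view_id, _adjacency_from_index_pairs(u, v, len(universe)))


def correlation_pvalues(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p-values from the exact t test.

    p is from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom. Rows with
    zero variance get NaN r and p = 1 (no edge).
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    n_samples = profiles.shape[1]
    if n_samples < 3:
        raise ValueError(f"need at least 3 samples per gene, got {n_samples}")
    sd = profiles.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(profiles)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    df = n_samples - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0  # |r| = 1 -> infinite t
    bad = constant[:, None] | constant[None, :]
    r[bad] = np.nan
    p[bad] = 1.0
    return r, p


def build_correlation_graph(profiles: np.ndarray, alpha: float,
                            universe: GeneUniverse, view_id: str) -> ViewGraph:
    """Connect gene pairs whose Pearson correlation across samples is
    significant at ``p < alpha`` (two-sided, either sign of r).

    Constant-profile genes yield no edges (warning).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    profiles = np.asarray(profiles, dtype=np.float64)
    if profiles.shape[0] != len(universe):
        raise ValueError("profile rows must match the universe")
    _, p = correlation_pvalues(profiles)
    n_const = int((profiles.std(axis=1) == 0).sum())
    if n_const:
        logger.warning("correlation graph: %d constant profiles produce no edges", n_const)
    adj = (p < alpha).astype(np.float64)
    np.fill_diagonal(adj, 0.0)
    return ViewGraph(view_id, sp.csr_matrix(np.triu(adj) + np.triu(adj, 1).T))


def build_node_features(row_ids: list[str], col_ids: list[str],
                        values: np.ndarray, mask: np.ndarray,
                        universe: GeneUniverse) -> NodeFeatureMatrix:
    """Preprocess the raw gene x 4 omics table into model-ready features.

    Missing cells are imputed with the column mean (logged count). The
    mutation column is binarized (any nonzero -> 1); the three continuous
    columns are z-scored over genes, with zero-variance columns set to all
    zeros (warning).
    """
    missing_cols = [c for c in FEATURE_NAMES if c not in col_ids]
    if missing_cols:
        raise ValueError(f"node-feature matrix missing columns: {missing_cols}")
    index_of = {g: i for i, g in enumerate(row_ids)}
    absent = [g for g in universe.genes if g not in index_of]
    if absent:
        raise ValueError(f"node features missing for genes: {absent[:5]}...")
    rows = np.array([index_of[g] for g in universe.genes])
    cols = np.array([col_ids.index(c) for c in FEATURE_NAMES])
    X = values[np.ix_(rows, cols)].astype(np.float64)
    M = mask[np.ix_(rows, cols)]

    n_missing = int(M.sum())
    if n_missing:
        logger.info("node features: imputing %d missing cells with column means", n_missing)
    for k in range(X.shape[1]):
        col = X[:, k]
        miss = M[:, k]
        if miss.all():
            raise ValueError(f"feature column {FEATURE_NAMES[k]!r} entirely missing")
        col[miss] = col[~miss].mean()

    mut = FEATURE_NAMES.index("mutation")
    X[:, mut] = (X[:, mut] != 0).astype(np.float64)
    for k in range(X.shape[1]):
        if k == mut:
            continue
        sd = X[:, k].std()
        if sd == 0:
            logger.warning("feature column %r is constant; z-scored to zeros",
                           FEATURE_NAMES[k])
            X[:, k] = 0.0
        else:
            X[:, k] = (X[:, k] - X[:, k].mean()) / sd
    return NodeFeatureMatrix(X)
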