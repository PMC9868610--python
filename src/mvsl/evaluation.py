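"""Train/test splitting and ranking metrics.

Two split protocols are supported. Leave-gene-combination-out ("pair" mode)
randomly partitions the labelled pairs, so a test pair's genes may appear in
training pairs. Leave-gene-out ("gene" mode) partitions the genes first and
keeps only within-group pairs, measuring generalization to entirely novel
genes; cross-group pairs are discarded (logged).

Metrics: ROC-AUC (Mann-Whitney convention, ties count 1/2), AUPR (precision-
recall step integral), Precision@k% (ceil rule for the top-set size, stable
input-order tie handling), and F-max (maximum F-measure over the distinct
score thresholds).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .graphs import PairLabelSet

logger = logging.getLogger("mvsl")

__all__ = [
    "SplitSpec",
    "EvalReport",
    "make_split",
    "cv_folds",
    "roc_auc",
    "aupr",
    "precision_at_percent",
    "f_max",
    "evaluate_ranking",
]


@dataclass
class SplitSpec:
    mode: str
    train_pairs: PairLabelSet
    test_pairs: PairLabelSet
    train_genes: np.ndarray | None
    test_genes: np.ndarray | None
    seed: int

    def __post_init__(self) -> None:
        tr = set(map(tuple, zip(self.train_pairs.u, self.train_pairs.v)))
        te = set(map(tuple, zip(self.test_pairs.u, self.test_pairs.v)))
        if tr & te:
            raise ValueError("train and test pairs overlap")
        if self.mode == "gene":
            if self.train_genes is None or self.test_genes is None:
                raise ValueError("gene mode requires gene partitions")
            if np.intersect1d(self.train_genes, self.test_genes).size:
                raise ValueError("train and test gene sets overlap")
            tr_g = set(self.train_genes.tolist())
            te_g = set(self.test_genes.tolist())
            for u, v in tr:
                if u not in tr_g or v not in tr_g:
                    raise ValueError("train pair endpoint outside train genes")
            for u, v in te:
                if u not in te_g or v not in te_g:
                    raise ValueError("test pair endpoint outside test genes")


def make_split(labels: PairLabelSet, mode: str, train_fraction: float,
               rng: np.random.Generator, seed: int = 0) -> SplitSpec:
    """Random train/test split of labelled pairs.

    pair mode: uniform split of pairs at ``train_fraction``. gene mode:
    uniform split of the genes appearing in ``labels``; pairs are kept only
    when both endpoints fall in the same partition.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(labels)
    if mode == "pair":
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        if n_train == 0 or n_train == n:
            raise ValueError("both partitions must be non-empty")
        train = labels.subset(np.sort(perm[:n_train]))
        test = labels.subset(np.sort(perm[n_train:]))
        spec = SplitSpec("pair", train, test, None, None, seed)
    elif mode == "gene":
        genes = labels.genes()
        perm = rng.permutation(len(genes))
        n_train = int(round(train_fraction * len(genes)))
        if n_train == 0 or n_train == len(genes):
            raise ValueError("both gene partitions must be non-empty")
        train_genes = np.sort(genes[perm[:n_train]])
        test_genes = np.sort(genes[perm[n_train:]])
        in_train = np.isin(labels.u, train_genes) & np.isin(labels.v, train_genes)
        in_test = np.isin(labels.u, test_genes) & np.isin(labels.v, test_genes)
        dropped = int(n - in_train.sum() - in_test.sum())
        if dropped:
            logger.info("gene-mode split discarded %d cross-group pairs", dropped)
        train = labels.subset(np.where(in_train)[0])
        test = labels.subset(np.where(in_test)[0])
        if len(train) == 0 or len(test) == 0:
            raise ValueError("a gene-mode partition has no pairs")
        spec = SplitSpec("gene", train, test, train_genes, test_genes, seed)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    for part, name in ((spec.train_pairs, "train"), (spec.test_pairs, "test")):
        if part.n_positive == 0:
            logger.warning("%s partition has zero positives; metrics degenerate", name)
    return spec


def cv_folds(train_pairs: PairLabelSet, k: int,
             rng: np.random.Generator) -> list[tuple[PairLabelSet, PairLabelSet]]:
    """k-fold partition of training pairs into (fit, holdout) sets.

    Holdouts are disjoint and their union is the full training set.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    n = len(train_pairs)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} pairs")
    perm = rng.permutation(n)
    folds = []
    for chunk in np.array_split(perm, k):
        holdout = np.sort(chunk)
        fit = np.sort(np.setdiff1d(perm, chunk))
        folds.append((train_pairs.subset(fit), train_pairs.subset(holdout)))
    return folds


# ----------------------------------------------------------------------------
# metrics


def _check_scores(scores, labels, need_both_classes: bool):
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if scores.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be 0/1")
    if need_both_classes and (labels.min() == labels.max()):
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    scores, labels = _check_scores(scores, labels, need_both_classes=True)
    return float(_skm.roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step integral)."""
    scores, labels = _check_scores(scores, labels, need_both_classes=True)
    return float(_skm.average_precision_score(labels, scores))


def precision_at_percent(scores, labels, k: float) -> float:
    """Fraction of positives among the ceil(k% * n) highest-scoring items.

    Ties are broken by stable input order.
    """
    scores, labels = _check_scores(scores, labels, need_both_classes=False)
    if not 0.0 < k <= 100.0:
        raise ValueError("k must lie in (0, 100]")
    m = math.ceil(k / 100.0 * scores.size)
    order = np.argsort(-scores, kind="stable")
    return float(labels[order[:m]].mean())


def f_max(scores, labels) -> float:
    """Maximum F-measure over thresholds at the distinct scores
    (predict positive iff score >= threshold)."""
    scores, labels = _check_scores(scores, labels, need_both_classes=False)
    if labels.sum() == 0:
        raise ValueError("f_max requires at least one positive")
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 2.0 * precision * recall / (precision + recall)
    return float(np.nanmax(f))


@dataclass
class EvalReport:
    roc_auc: float
    aupr: float
    precision_at_k: float
    k: float
    f_max: float
    n_test: int
    positive_rate: float

    def __post_init__(self) -> None:
        if self.n_test <= 0:
            raise ValueError("n_test must be positive")
        for name in ("roc_auc", "aupr", "precision_at_k", "f_max", "positive_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "aupr": self.aupr,
            f"precision_at_{self.k:g}pct": self.precision_at_k,
            "f_max": self.f_max,
            "n_test": self.n_test,
            "positive_rate": self.positive_rate,
        }

    def summary(self) -> str:
        return (
            f"n_test          {self.n_test}\n"
            f"positive_rate   {self.positive_rate:.4f}\n"
            f"ROC-AUC         {self.roc_auc:.4f}\n"
            f"AUPR            {self.aupr:.4f}\n"
            f"Precision@{self.k:g}%    {self.precision_at_k:.4f}\n"
            f"F-max           {self.f_max:.4f}"
        )


def evaluate_ranking(scores, labels, k: float = 5.0) -> EvalReport:
    """All four ranking metrics on one score/label set."""
    scores, labels = _check_scores(scores, labels, need_both_classes=True)
    return EvalReport(
        roc_auc=roc_auc(scores, labels),
        aupr=aupr(scores, labels),
        precision_at_k=precision_at_percent(scores, labels, k),
        k=k,
        f_max=f_max(scores, labels),
        n_test=int(scores.size),
        positive_rate=float(labels.mean()),
    )
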