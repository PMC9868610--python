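"""Training loop: balanced per-epoch negative sampling, Adam/SGD updates,
early stopping on validation AUPR, full seed control.

Because true SL pairs are rare (~1% of screened pairs), each epoch trains on
all training positives plus an equal-count random subset of training
negatives, resampled every epoch so the model eventually sees every
negative. The default update is full-batch Adam at learning rate 1e-4 (the
balanced epoch set is small); plain SGD and mini-batching are available via
config. All randomness (weight init, negative sampling, dropout) derives
from a single seed through named child streams, so identical seed + inputs
reproduce the loss trajectory bitwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import aupr
from .graphs import NodeFeatureMatrix, PairLabelSet
from .io import RunConfig
from .model import ModelState, init_state, loss_and_grads, predict_pairs

logger = logging.getLogger("mvsl")

__all__ = ["TrainReport", "sample_balanced_epoch", "train_model"]


@dataclass
class TrainReport:
    epoch_losses: list[float] = field(default_factory=list)
    val_metric_history: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.best_epoch > self.stopped_epoch:
            raise ValueError("best_epoch cannot exceed stopped_epoch")


def sample_balanced_epoch(labels: PairLabelSet, rng: np.random.Generator) -> PairLabelSet:
    """All positives plus an equal-count uniform random subset of negatives.

    Resampled on every call. If there are fewer negatives than positives,
    every negative is used (warning).
    """
    pos_idx = np.where(labels.label == 1)[0]
    neg_idx = np.where(labels.label == 0)[0]
    if pos_idx.size == 0:
        raise ValueError("balanced sampling needs at least one positive")
    if neg_idx.size < pos_idx.size:
        logger.warning("only %d negatives for %d positives; using all negatives",
                       neg_idx.size, pos_idx.size)
        chosen = neg_idx
    else:
        chosen = rng.choice(neg_idx, size=pos_idx.size, replace=False)
    idx = np.sort(np.concatenate([pos_idx, chosen]))
    return labels.subset(idx)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, p in params.items():
            p -= self.lr * grads[k]


def _pair_key_set(u: np.ndarray, v: np.ndarray, n: int) -> set[int]:
    return set((u.astype(np.int64) * n + v).tolist())


def train_model(A_hats: list, X: NodeFeatureMatrix | np.ndarray,
                fit_labels: PairLabelSet, val_labels: PairLabelSet,
                cfg: RunConfig,
                forbidden: PairLabelSet | None = None) -> tuple[ModelState, TrainReport]:
    """Fit the multi-view model.

    ``fit_labels`` drive gradients; ``val_labels`` are scored every epoch and
    early stopping keeps the weights of the best validation-AUPR epoch.
    ``forbidden`` pairs (the test set) are asserted never to enter a gradient
    batch — an instrumented anti-leakage check, run every epoch.

    The SL view inside ``A_hats`` must already be built from training
    positives only; this function cannot verify edge provenance beyond the
    overlap check the pipeline performs.
    """
    X = X.X if isinstance(X, NodeFeatureMatrix) else np.asarray(X, dtype=np.float64)
    n_genes = X.shape[0]

    ss = np.random.SeedSequence(cfg.seed, spawn_key=(0xBA7C,))
    init_rng, neg_rng, drop_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    state = init_state(init_rng, in_dim=X.shape[1], gcn_dims=cfg.gcn_dims,
                       head_dims=cfg.head_dims, rng_seed=cfg.seed)

    params = dict(state.param_items())
    opt = (_Adam(params, cfg.learning_rate) if cfg.optimizer == "adam"
           else _SGD(params, cfg.learning_rate))

    forbidden_keys: set[int] = set()
    if forbidden is not None and len(forbidden):
        forbidden_keys = _pair_key_set(forbidden.u, forbidden.v, n_genes)
        fit_keys = _pair_key_set(fit_labels.u, fit_labels.v, n_genes)
        if fit_keys & forbidden_keys:
            raise AssertionError("test pairs present in the training pair set")

    monitor_loss = val_labels.n_positive == 0 or val_labels.n_positive == len(val_labels)
    if monitor_loss:
        logger.warning("validation set is single-class; early stopping monitors "
                       "validation loss instead of AUPR")

    report = TrainReport(seed=cfg.seed)
    best_metric = -np.inf
    best_state = state.copy()
    best_epoch = 0
    since_best = 0

    for epoch in range(1, cfg.max_epochs + 1):
        batch = sample_balanced_epoch(fit_labels, neg_rng)
        if forbidden_keys:
            if _pair_key_set(batch.u, batch.v, n_genes) & forbidden_keys:
                raise AssertionError("anti-leakage violation: test pair in gradient batch")

        if cfg.batch_size is None or cfg.batch_size >= len(batch):
            chunks = [np.arange(len(batch))]
        else:
            perm = neg_rng.permutation(len(batch))
            chunks = np.array_split(perm, int(np.ceil(len(batch) / cfg.batch_size)))
        epoch_loss = 0.0
        n_seen = 0
        for chunk in chunks:
            sub = batch.subset(np.sort(chunk))
            loss, grads, _ = loss_and_grads(
                A_hats, X, state, sub.u, sub.v, sub.label.astype(np.float64),
                weight_decay=cfg.weight_decay, dropout=cfg.dropout, rng=drop_rng)
            opt.step(params, grads)
            epoch_loss += loss * len(sub)
            n_seen += len(sub)
        report.epoch_losses.append(epoch_loss / n_seen)
        state.check_finite()

        val_p = predict_pairs(A_hats, X, state, val_labels.u, val_labels.v)
        if monitor_loss:
            from .model import bce_loss
            metric = -bce_loss(val_p, val_labels.label.astype(np.float64))
        else:
            metric = aupr(val_p, val_labels.label)
        report.val_metric_history.append(float(metric))

        if metric > best_metric:
            best_metric = metric
            best_state = state.copy()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if since_best >= cfg.patience:
            break

    report.stopped_epoch = len(report.epoch_losses)
    report.best_epoch = best_epoch
    logger.info("training stopped at epoch %d (best %d, val metric %.4f)",
                report.stopped_epoch, best_epoch, best_metric)
    return best_state, report
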