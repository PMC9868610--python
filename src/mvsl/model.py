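"""Multi-view GCN forward pass, pair scoring, loss, and analytic gradients.

Each view i is encoded by the same two-layer graph convolution

    Z_i = ReLU( A_hat_i @ ReLU( A_hat_i @ X @ W0 ) @ W1 )

with W0, W1 shared across all views (a single copy each). The per-view
embeddings are fused by an element-wise maximum over the view axis, so a
gene absent from one network takes its representation from the views that
do contain it. A gene pair (u, v) is featurized symmetrically as

    [ Z_u * Z_v , |Z_u - Z_v| ]

(Hadamard product and absolute difference), which makes every pair score
invariant to the order of the two genes. A three-layer ReLU feed-forward
head followed by a logistic output maps pair features to an SL probability,
trained with binary cross-entropy.

Everything is NumPy/SciPy; gradients are derived by hand and verified by a
finite-difference check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ModelState",
    "init_state",
    "gcn_layer",
    "encode_views",
    "max_pool_views",
    "pair_features",
    "predict_pair",
    "predict_pairs",
    "pooled_embedding",
    "bce_loss",
    "loss_and_grads",
]

LOSS_EPS = 1e-7  # probability clamp in the cross-entropy


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ModelState:
    """All trainable weights.

    W0 (R x K1) and W1 (K1 x K2) are the graph-convolution weights shared by
    every view. head_W/head_b hold the three hidden layers (2*K2 -> h1 ->
    h2 -> h3) plus the final 1-unit output map. GCN layers carry no bias,
    head layers do.
    """

    W0: np.ndarray
    W1: np.ndarray
    head_W: list[np.ndarray]
    head_b: list[np.ndarray]
    rng_seed: int = 0

    @property
    def embed_dim(self) -> int:
        return self.W1.shape[1]

    def param_items(self):
        yield "W0", self.W0
        yield "W1", self.W1
        for i, W in enumerate(self.head_W):
            yield f"head_W{i}", W
        for i, b in enumerate(self.head_b):
            yield f"head_b{i}", b

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {name: arr for name, arr in self.param_items()}

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray], rng_seed: int = 0) -> "ModelState":
        n_head = sum(1 for k in arrays if k.startswith("head_W"))
        return cls(
            W0=np.asarray(arrays["W0"], dtype=np.float64),
            W1=np.asarray(arrays["W1"], dtype=np.float64),
            head_W=[np.asarray(arrays[f"head_W{i}"], dtype=np.float64) for i in range(n_head)],
            head_b=[np.asarray(arrays[f"head_b{i}"], dtype=np.float64) for i in range(n_head)],
            rng_seed=rng_seed,
        )

    def copy(self) -> "ModelState":
        return ModelState(self.W0.copy(), self.W1.copy(),
                          [W.copy() for W in self.head_W],
                          [b.copy() for b in self.head_b], self.rng_seed)

    def check_finite(self) -> None:
        for name, arr in self.param_items():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in parameter {name}")


def init_state(rng: np.random.Generator, in_dim: int = 4,
               gcn_dims: tuple[int, int] = (128, 64),
               head_dims: tuple[int, int, int] = (64, 32, 16),
               rng_seed: int = 0) -> ModelState:
    """Symmetric-uniform initialization scaled by each layer's fan-in
    (U(-1/sqrt(fan_in), 1/sqrt(fan_in))); biases start at zero."""
    k1, k2 = gcn_dims

    def u(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    widths = [2 * k2, *head_dims, 1]
    return ModelState(
        W0=u(in_dim, (in_dim, k1)),
        W1=u(k1, (k1, k2)),
        head_W=[u(widths[i], (widths[i], widths[i + 1])) for i in range(len(widths) - 1)],
        head_b=[np.zeros(widths[i + 1]) for i in range(len(widths) - 1)],
        rng_seed=rng_seed,
    )


# ----------------------------------------------------------------------------
# forward pieces


def gcn_layer(A_hat, H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One graph convolution: ReLU(A_hat @ H @ W)."""
    H = np.asarray(H, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    n = A_hat.shape[0]
    if A_hat.shape != (n, n):
        raise ValueError(f"A_hat must be square, got {A_hat.shape}")
    if H.shape[0] != n:
        raise ValueError(f"H has {H.shape[0]} rows, expected {n}")
    if W.shape[0] != H.shape[1]:
        raise ValueError(f"W expects input dim {W.shape[0]}, H has {H.shape[1]}")
    return _relu(A_hat @ (H @ W))


def encode_views(A_hats: list, X: np.ndarray, state: ModelState) -> list[np.ndarray]:
    """Two shared-weight graph convolutions per view."""
    return [gcn_layer(A, gcn_layer(A, X, state.W0), state.W1) for A in A_hats]


def max_pool_views(Z_views: list[np.ndarray]) -> np.ndarray:
    """Element-wise maximum across views."""
    shapes = {Z.shape for Z in Z_views}
    if len(shapes) != 1:
        raise ValueError(f"view embeddings disagree in shape: {shapes}")
    return np.max(np.stack(Z_views, axis=0), axis=0)


def pooled_embedding(A_hats: list, X: np.ndarray, state: ModelState) -> np.ndarray:
    return max_pool_views(encode_views(A_hats, X, state))


def pair_features(Z: np.ndarray, u, v) -> np.ndarray:
    """Symmetric pair featurization: [Z_u * Z_v, |Z_u - Z_v|].

    Accepts scalars or index arrays; invariant to swapping u and v.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if np.any(u == v):
        raise ValueError("pair features are undefined for u == v")
    Zu, Zv = Z[u], Z[v]
    return np.concatenate([Zu * Zv, np.abs(Zu - Zv)], axis=-1)


def _head_forward(F: np.ndarray, state: ModelState,
                  dropout: float = 0.0, rng: np.random.Generator | None = None):
    """Head forward pass; returns (probabilities, cache for backprop)."""
    acts = [np.atleast_2d(F)]
    masks: list[np.ndarray | None] = []
    a = acts[0]
    for W, b in zip(state.head_W[:-1], state.head_b[:-1]):
        a = _relu(a @ W + b)
        if dropout > 0.0 and rng is not None:
            m = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
            a = a * m
            masks.append(m)
        else:
            masks.append(None)
        acts.append(a)
    logits = a @ state.head_W[-1] + state.head_b[-1]
    p = _sigmoid(logits)
    return p, (acts, masks, logits)


def predict_pair(features: np.ndarray, state: ModelState) -> float:
    """Score one featurized pair; returns a probability strictly in (0, 1)."""
    features = np.asarray(features, dtype=np.float64)
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite pair features")
    if features.shape[-1] != state.head_W[0].shape[0]:
        raise ValueError(
            f"feature length {features.shape[-1]} != expected {state.head_W[0].shape[0]}")
    p, _ = _head_forward(features, state)
    return float(p.ravel()[0])


def predict_pairs(A_hats: list, X: np.ndarray, state: ModelState,
                  u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Full forward pass: encode, pool, featurize, score a batch of pairs."""
    Z = pooled_embedding(A_hats, X, state)
    F = pair_features(Z, u, v)
    p, _ = _head_forward(F, state)
    return p.ravel()


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities clamped to [eps, 1-eps]."""
    p = np.asarray(p, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if p.shape != y.shape:
        raise ValueError("p and y must have equal length")
    if np.any((p <= 0.0) | (p >= 1.0)):
        import logging
        logging.getLogger("mvsl").debug(
            "bce_loss: clamped %d probabilities to [%g, 1-%g]",
            int(((p <= 0.0) | (p >= 1.0)).sum()), LOSS_EPS, LOSS_EPS)
    p = np.clip(p, LOSS_EPS, 1.0 - LOSS_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ----------------------------------------------------------------------------
# analytic gradients


def loss_and_grads(A_hats: list, X: np.ndarray, state: ModelState,
                   u: np.ndarray, v: np.ndarray, y: np.ndarray,
                   weight_decay: float = 0.0, dropout: float = 0.0,
                   rng: np.random.Generator | None = None):
    """BCE loss on a pair batch and its gradient w.r.t. every parameter.

    Backpropagates through the head, the symmetric pair featurization, the
    max-pool (gradient routed to the first arg-max view at ties), and both
    shared graph convolutions of every view. Returns (loss, grads, p).
    """
    u = np.asarray(u, dtype=np.int64)
    v = np.asarray(v, dtype=np.int64)
    y = np.asarray(y, dtype=np.float64)
    m = len(u)
    X = np.asarray(X, dtype=np.float64)

    # forward with caches
    AX, P, H, AH, Q, Zv = [], [], [], [], [], []
    for A in A_hats:
        ax = A @ X
        p_pre = ax @ state.W0
        h = _relu(p_pre)
        ah = A @ h
        q_pre = ah @ state.W1
        AX.append(ax); P.append(p_pre); H.append(h); AH.append(ah); Q.append(q_pre)
        Zv.append(_relu(q_pre))
    Zstack = np.stack(Zv, axis=0)                      # (V, N, K2)
    arg = np.argmax(Zstack, axis=0)                    # ties -> first view
    Z = np.take_along_axis(Zstack, arg[None], axis=0)[0]

    Zu, Zvv = Z[u], Z[v]
    diff = Zu - Zvv
    F = np.concatenate([Zu * Zvv, np.abs(diff)], axis=1)
    prob, (acts, masks, logits) = _head_forward(F, state, dropout=dropout, rng=rng)
    prob = prob.reshape(m, 1)
    loss = bce_loss(prob.ravel(), y)

    grads = {name: np.zeros_like(arr) for name, arr in state.param_items()}

    # head backward; d(BCE)/d(logit) = (p - y) / m
    pc = np.clip(prob.ravel(), LOSS_EPS, 1.0 - LOSS_EPS).reshape(m, 1)
    delta = (pc - y.reshape(m, 1)) / m
    grads["head_W%d" % (len(state.head_W) - 1)] += acts[-1].T @ delta
    grads["head_b%d" % (len(state.head_b) - 1)] += delta.sum(axis=0)
    da = delta @ state.head_W[-1].T
    for i in range(len(state.head_W) - 2, -1, -1):
        if masks[i] is not None:
            da = da * masks[i]
        da = da * (acts[i + 1] > 0)
        grads[f"head_W{i}"] += acts[i].T @ da
        grads[f"head_b{i}"] += da.sum(axis=0)
        da = da @ state.head_W[i].T

    # pair featurization backward
    k2 = state.embed_dim
    dF = da  # (m, 2*k2)
    dprod, ddiff = dF[:, :k2], dF[:, k2:]
    s = np.sign(diff)
    dZu = dprod * Zvv + ddiff * s
    dZvv = dprod * Zu - ddiff * s
    dZ = np.zeros_like(Z)
    np.add.at(dZ, u, dZu)
    np.add.at(dZ, v, dZvv)

    # unpool + per-view GCN backward (W0, W1 shared -> accumulate)
    for i, A in enumerate(A_hats):
        dZi = np.where(arg == i, dZ, 0.0)
        if not dZi.any():
            continue
        dQ = dZi * (Q[i] > 0)
        grads["W1"] += AH[i].T @ dQ
        dH = (A @ dQ) @ state.W1.T      # A_hat is symmetric
        dP = dH * (P[i] > 0)
        grads["W0"] += AX[i].T @ dP

    if weight_decay > 0.0:
        for name, arr in state.param_items():
            if not name.startswith("head_b"):
                grads[name] += weight_decay * arr

    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")
    return loss, grads, prob.ravel()
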