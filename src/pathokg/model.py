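"""Two-stage pathogenicity predictor: GCN encoder + feed-forward pair decoder.

The encoder is a 2-layer graph convolutional network over the *masked*
heterogeneous graph (all unmasked edge types pooled into one symmetric
adjacency): ``H1 = ReLU(A_hat X W0 + b0)``, ``Z = ReLU(A_hat H1 W1 + b1)``
with ``A_hat = D^{-1/2}(A + I)D^{-1/2}`` and hidden widths 256 and 64.  The
decoder is a 3-layer network on the concatenated (variant, disease) encoder
embeddings (128 -> 64 -> 32 -> 1) with a sigmoid output giving the
probability that the pair is pathogenic.  Dropout 0.3 follows each hidden
activation during training; evaluation mode is deterministic.

Two reference baselines share the decoder architecture family but skip the
graph: a pair network on concatenated *raw* (pre-GCN) embeddings, and a
variant-only network modeling non-disease-specific pathogenicity.

Everything is plain numpy with hand-derived gradients; forward passes cache
what backward needs.  The graph scale this package targets (thousands of
nodes) makes full-graph sparse-dense products cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from pathokg.errors import ShapeError
from pathokg.graph_store import AdjacencyView

DROPOUT_RATE = 0.3
ENCODER_HIDDEN = 256
ENCODER_OUT = 64
DECODER_HIDDEN = (64, 32)
BASELINE_HIDDEN = (256, 64)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1.0 - eps)
    y = np.asarray(labels, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def normalized_adjacency(view: AdjacencyView) -> sp.csr_matrix:
    """Symmetric normalized adjacency with self-loops over an adjacency view.

    All unmasked edge types are pooled homogeneously; parallel typed edges
    between the same pair contribute a single unit weight.  Every node gets a
    self-loop, so isolated nodes have degree 1 and the matrix is well defined.
    """
    n = len(view.node_ids)
    pairs = {(min(i, j), max(i, j)) for i, j in view.edge_index_pairs() if i != j}
    if pairs:
        rows, cols = map(np.array, zip(*pairs))
        data = np.ones(len(pairs))
        a = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
        a = a + a.T
    else:
        a = sp.coo_matrix((n, n))
    a = (a + sp.identity(n, format="coo")).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    d = sp.diags(inv_sqrt)
    return (d @ a @ d).tocsr()


def _dropout_mask(
    rng: np.random.Generator | None, shape, rate: float, dtype=np.float64
) -> np.ndarray | None:
    if rng is None or rate <= 0.0:
        return None
    keep = rng.random(shape, dtype=np.float32) >= rate
    scale = np.asarray(1.0 / (1.0 - rate), dtype=dtype)
    return keep.astype(dtype) * scale


@dataclass
class GCNParams:
    W0: np.ndarray
    b0: np.ndarray
    W1: np.ndarray
    b1: np.ndarray

    @classmethod
    def init(cls, d_in: int, rng: np.random.Generator,
             d_hidden: int = ENCODER_HIDDEN, d_out: int = ENCODER_OUT) -> "GCNParams":
        return cls(
            W0=glorot_uniform(rng, d_in, d_hidden),
            b0=np.zeros(d_hidden),
            W1=glorot_uniform(rng, d_hidden, d_out),
            b1=np.zeros(d_out),
        )

    def arrays(self) -> list[np.ndarray]:
        return [self.W0, self.b0, self.W1, self.b1]


def gcn_encode(
    X: np.ndarray,
    A_hat: sp.csr_matrix,
    params: GCNParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
    dropout: float = DROPOUT_RATE,
):
    """Forward pass of the 2-layer GCN; returns (Z, cache) for backprop.

    In evaluation mode (``training=False``) no dropout is applied and the
    output is a deterministic function of (X, A_hat, params).
    """
    if X.shape[1] != params.W0.shape[0]:
        raise ShapeError(f"feature width {X.shape[1]} != encoder input {params.W0.shape[0]}")
    drop_rng = rng if training else None
    M1 = A_hat @ (X @ params.W0) + params.b0
    H1 = np.maximum(M1, 0.0)
    D1 = _dropout_mask(drop_rng, H1.shape, dropout, X.dtype)
    H1d = H1 * D1 if D1 is not None else H1
    M2 = A_hat @ (H1d @ params.W1) + params.b1
    Z = np.maximum(M2, 0.0)
    D2 = _dropout_mask(drop_rng, Z.shape, dropout, X.dtype)
    Zd = Z * D2 if D2 is not None else Z
    cache = {"X": X, "A": A_hat, "M1": M1, "H1d": H1d, "D1": D1, "M2": M2, "D2": D2}
    return Zd, cache


def gcn_backward(cache: dict, dZd: np.ndarray, params: GCNParams) -> list[np.ndarray]:
    """Gradients of the loss w.r.t. encoder parameters, given dL/dZ."""
    A = cache["A"]
    dZ = dZd * cache["D2"] if cache["D2"] is not None else dZd
    dM2 = dZ * (cache["M2"] > 0)
    db1 = dM2.sum(axis=0)
    dH1W1 = A.T @ dM2
    dW1 = cache["H1d"].T @ dH1W1
    dH1d = dH1W1 @ params.W1.T
    dH1 = dH1d * cache["D1"] if cache["D1"] is not None else dH1d
    dM1 = dH1 * (cache["M1"] > 0)
    db0 = dM1.sum(axis=0)
    dXW0 = A.T @ dM1
    dW0 = cache["X"].T @ dXW0
    return [dW0, db0, dW1, db1]


@dataclass
class MLPParams:
    """3-layer feed-forward net: two ReLU hidden layers, linear scalar output."""

    Ws: list[np.ndarray]
    bs: list[np.ndarray]

    @classmethod
    def init(cls, d_in: int, hidden: tuple[int, int], rng: np.random.Generator) -> "MLPParams":
        sizes = [d_in, *hidden, 1]
        Ws = [glorot_uniform(rng, sizes[i], sizes[i + 1]) for i in range(3)]
        bs = [np.zeros(sizes[i + 1]) for i in range(3)]
        return cls(Ws, bs)

    def arrays(self) -> list[np.ndarray]:
        return [*self.Ws, *self.bs]


def mlp_forward(
    X: np.ndarray,
    params: MLPParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
    dropout: float = DROPOUT_RATE,
):
    """Forward pass returning (logits, cache); dropout on hidden layers only."""
    if X.shape[1] != params.Ws[0].shape[0]:
        raise ShapeError(f"input width {X.shape[1]} != decoder input {params.Ws[0].shape[0]}")
    drop_rng = rng if training else None
    cache: dict = {"X": X, "pre": [], "drop": [], "act": []}
    h = X
    for layer in range(2):
        pre = h @ params.Ws[layer] + params.bs[layer]
        act = np.maximum(pre, 0.0)
        mask = _dropout_mask(drop_rng, act.shape, dropout, X.dtype)
        if mask is not None:
            act = act * mask
        cache["pre"].append(pre)
        cache["drop"].append(mask)
        cache["act"].append(act)
        h = act
    logits = (h @ params.Ws[2] + params.bs[2]).ravel()
    return logits, cache


def mlp_backward(cache: dict, dlogits: np.ndarray, params: MLPParams):
    """Gradients for MLP parameters and input, given dL/dlogits."""
    dl = dlogits.reshape(-1, 1)
    grads_W = [None] * 3
    grads_b = [None] * 3
    grads_W[2] = cache["act"][1].T @ dl
    grads_b[2] = dl.sum(axis=0)
    dh = dl @ params.Ws[2].T
    for layer in (1, 0):
        mask = cache["drop"][layer]
        if mask is not None:
            dh = dh * mask
        dpre = dh * (cache["pre"][layer] > 0)
        inp = cache["act"][layer - 1] if layer == 1 else cache["X"]
        grads_W[layer] = inp.T @ dpre
        grads_b[layer] = dpre.sum(axis=0)
        dh = dpre @ params.Ws[layer].T
    dX = dh
    return [*grads_W, *grads_b], dX


def decode_pairs(
    Z_variant: np.ndarray,
    Z_disease: np.ndarray,
    params: MLPParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Pathogenicity probabilities for (variant, disease) embedding pairs.

    Concatenation order is fixed: variant embedding first, disease second.
    """
    Z_variant = np.atleast_2d(Z_variant)
    Z_disease = np.atleast_2d(Z_disease)
    if Z_variant.shape != Z_disease.shape:
        raise ShapeError("variant/disease embedding shape mismatch")
    P = np.concatenate([Z_variant, Z_disease], axis=1)
    logits, cache = mlp_forward(P, params, training=training, rng=rng)
    return sigmoid(logits), logits, cache


@dataclass
class SGDOptimizer:
    """SGD with momentum and decoupled weight decay.

    Update per array: ``v <- mu * v + g``; ``p <- p - lr * (v + wd * p)``.
    The decay acts directly on the weights rather than entering the momentum
    buffer: routing it through momentum would amplify the effective decay by
    ``1/(1-mu)`` (10x at mu=0.9) and, at the configured learning rate, shrink
    every weight to zero faster than the cross-entropy gradients can move it.
    Decay applies to weights and biases alike.  ``coupled=True`` restores the
    classic L2-in-gradient formulation for comparison.
    """

    lr: float = 0.001
    weight_decay: float = 0.1
    momentum: float = 0.9
    coupled: bool = False
    _buffers: dict[int, np.ndarray] = field(default_factory=dict)

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(arrays, grads)):
            g = g.reshape(p.shape)
            if self.coupled:
                g = g + self.weight_decay * p
            buf = self._buffers.get(i)
            if buf is None:
                buf = np.zeros_like(p)
                self._buffers[i] = buf
            buf *= self.momentum
            buf += g
            if self.coupled:
                p -= self.lr * buf
            else:
                p -= self.lr * buf + self.lr * self.weight_decay * p


@dataclass
class ModelState:
    """Encoder + decoder parameters with the seed that initialized them."""

    encoder: GCNParams
    decoder: MLPParams
    seed: int

    @classmethod
    def init(cls, d_in: int, seed: int, dtype=np.float64) -> "ModelState":
        rng = np.random.default_rng(seed)
        state = cls(
            encoder=GCNParams.init(d_in, rng),
            decoder=MLPParams.init(2 * ENCODER_OUT, DECODER_HIDDEN, rng),
            seed=seed,
        )
        if dtype is not np.float64:
            state.encoder = GCNParams(*[a.astype(dtype) for a in state.encoder.arrays()])
            state.decoder = MLPParams(
                [w.astype(dtype) for w in state.decoder.Ws],
                [b.astype(dtype) for b in state.decoder.bs],
            )
        return state

    def arrays(self) -> list[np.ndarray]:
        return [*self.encoder.arrays(), *self.decoder.arrays()]

    def copy(self) -> "ModelState":
        enc = GCNParams(*[a.copy() for a in self.encoder.arrays()])
        dec = MLPParams([w.copy() for w in self.decoder.Ws], [b.copy() for b in self.decoder.bs])
        return ModelState(enc, dec, self.seed)

    def predict(self, X: np.ndarray, A_hat: sp.csr_matrix,
                vi: np.ndarray, di: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities for pairs given node-row indices."""
        Z, _ = gcn_encode(X, A_hat, self.encoder, training=False)
        probs, _, _ = decode_pairs(Z[vi], Z[di], self.decoder, training=False)
        return probs

    def save(self, path) -> None:
        payload = {
            "seed": self.seed,
            "encoder": {k: a.tolist() for k, a in
                        zip(("W0", "b0", "W1", "b1"), self.encoder.arrays())},
            "decoder": {
                "Ws": [w.tolist() for w in self.decoder.Ws],
                "bs": [b.tolist() for b in self.decoder.bs],
            },
            "shapes": {
                "encoder": [list(a.shape) for a in self.encoder.arrays()],
                "decoder": [list(a.shape) for a in self.decoder.arrays()],
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelState":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        enc = GCNParams(*[np.asarray(payload["encoder"][k]) for k in ("W0", "b0", "W1", "b1")])
        dec = MLPParams(
            [np.asarray(w) for w in payload["decoder"]["Ws"]],
            [np.asarray(b) for b in payload["decoder"]["bs"]],
        )
        return cls(enc, dec, int(payload["seed"]))


@dataclass
class BaselineState:
    """Graph-free 3-layer network (hidden 256/64) on raw embeddings.

    ``pair_input=True`` gives the disease-specific baseline on concatenated
    (variant, disease) raw embeddings; ``False`` gives the variant-only,
    non-disease-specific baseline.
    """

    net: MLPParams
    seed: int
    pair_input: bool

    @classmethod
    def init(cls, d_raw: int, seed: int, pair_input: bool = True,
             dtype=np.float64) -> "BaselineState":
        rng = np.random.default_rng(seed)
        d_in = 2 * d_raw if pair_input else d_raw
        net = MLPParams.init(d_in, BASELINE_HIDDEN, rng)
        if dtype is not np.float64:
            net = MLPParams([w.astype(dtype) for w in net.Ws], [b.astype(dtype) for b in net.bs])
        return cls(net, seed, pair_input)

    def arrays(self) -> list[np.ndarray]:
        return self.net.arrays()

    def copy(self) -> "BaselineState":
        return BaselineState(
            MLPParams([w.copy() for w in self.net.Ws], [b.copy() for b in self.net.bs]),
            self.seed,
            self.pair_input,
        )

    def forward(self, X_variant: np.ndarray, X_disease: np.ndarray | None = None,
                training: bool = False, rng: np.random.Generator | None = None):
        if self.pair_input:
            if X_disease is None:
                raise ShapeError("pair baseline requires a disease embedding")
            inp = np.concatenate([np.atleast_2d(X_variant), np.atleast_2d(X_disease)], axis=1)
        else:
            inp = np.atleast_2d(X_variant)
        logits, cache = mlp_forward(inp, self.net, training=training, rng=rng)
        return sigmoid(logits), logits, cache


def baseline_pair_forward(raw_variant, raw_disease, state: BaselineState,
                          training: bool = False, rng=None) -> np.ndarray:
    """Disease-specific baseline probability from raw (pre-GCN) embeddings."""
    probs, _, _ = state.forward(raw_variant, raw_disease, training=training, rng=rng)
    return probs


def baseline_variant_forward(raw_variant, state: BaselineState,
                             training: bool = False, rng=None) -> np.ndarray:
    """Non-disease-specific baseline probability from the variant embedding alone."""
    probs, _, _ = state.forward(raw_variant, training=training, rng=rng)
    return probs
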