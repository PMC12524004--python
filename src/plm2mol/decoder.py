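"""Protein-embedding-conditioned transformer decoder.

A decoder-only transformer over SMILES tokens in which the
"encoder-decoder" (cross) attention takes its queries from the previous
decoder sub-layer while keys and values are computed from a single
fixed-length protein embedding vector ``x``:

    Y = S E + P                          (token embedding + positional)
    Q_i = Y W^Q_i,  K_i = x W^K_i,  V_i = x W^V_i
    Z_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i
    Z   = concat(Z_1 .. Z_h) W^O

Because K_i and V_i have a single row, the softmax over a length-one key
axis is identically 1 and every row of ``Z_i`` equals ``V_i``: the
protein conditions every position identically before residual mixing.
Self-attention sub-layers are the standard causally masked multi-head
attention; residual connections and layer normalization follow the
post-norm arrangement of the original transformer, with a
position-wise feed-forward network of width ``ffn_dim``.

The implementation is pure numpy with hand-derived backpropagation and
an Adam optimizer; gradients are verified against finite differences in
the test suite.  Training is teacher-forced next-token cross-entropy
with padding positions excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codec import EncodedSmiles, TokenVocabulary, build_default_vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "DecoderConfig",
    "ParameterSet",
    "ProteinRecord",
    "AttentionTrace",
    "sinusoidal_positions",
    "init_parameters",
    "embed_inputs",
    "protein_cross_attention",
    "decoder_forward",
    "nll_loss",
    "loss_and_grads",
    "train",
]

_LN_EPS = 1e-5


@dataclass(frozen=True)
class DecoderConfig:
    """Architecture and optimization hyperparameters.

    Defaults are the full-scale settings: 2 layers, 32 heads, model
    dimension 1024 (matching the protein-embedding width), sequence
    length 97, vocabulary 33, feed-forward width 4*d_model, dropout 0.1,
    100 epochs with batches of 200 at a fixed Adam learning rate 0.001.
    """

    n_layers: int = 2
    n_heads: int = 32
    d_model: int = 1024
    seq_len: int = 97
    vocab_size: int = 33
    ffn_dim: Optional[int] = None
    dropout: float = 0.1
    epochs: int = 100
    batch_size: int = 200
    learning_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 4 * self.d_model)

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    def to_dict(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "d_model": self.d_model,
            "seq_len": self.seq_len,
            "vocab_size": self.vocab_size,
            "ffn_dim": self.ffn_dim,
            "dropout": self.dropout,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "DecoderConfig":
        return cls(**obj)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier with its fixed-length embedding vector."""

    id: str
    embedding: np.ndarray
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        emb = np.asarray(self.embedding, dtype=np.float64)
        if emb.ndim != 1:
            raise ValueError("embedding must be a 1-D vector")
        if not np.all(np.isfinite(emb)):
            raise ValueError(f"embedding of {self.id!r} contains non-finite values")
        object.__setattr__(self, "embedding", emb)


@dataclass
class AttentionTrace:
    """Intermediate cross-attention quantities for one layer.

    ``Q`` has shape (h, L, d_k); ``K`` and ``V`` have shape (h, 1, d_k)
    (the single protein-derived key/value row per head); ``Z_heads`` has
    shape (h, L, d_k) and ``Z`` is the concatenated, output-projected
    (L, d_model) matrix.
    """

    Y: np.ndarray
    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    Z_heads: np.ndarray
    Z: np.ndarray


def sinusoidal_positions(seq_len: int, d_model: int) -> np.ndarray:
    """The constant sinusoidal positional-encoding matrix (L x d_model)."""
    pos = np.arange(seq_len, dtype=np.float64)[:, None]
    i = np.arange(d_model, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    P = np.zeros((seq_len, d_model), dtype=np.float64)
    P[:, 0::2] = np.sin(angle[:, 0::2])
    P[:, 1::2] = np.cos(angle[:, 1::2])
    return P


@dataclass
class ParameterSet:
    """Learned weights plus the constant positional encoding."""

    config: DecoderConfig
    weights: dict[str, np.ndarray]
    positional: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.positional is None:
            self.positional = sinusoidal_positions(
                self.config.seq_len, self.config.d_model
            )

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            config=self.config,
            weights={k: v.copy() for k, v in self.weights.items()},
            positional=self.positional.copy(),
        )


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_parameters(config: DecoderConfig, seed: int = 0) -> ParameterSet:
    """Glorot-uniform initialization, seeded for reproducibility."""
    rng = np.random.default_rng(seed)
    d, f, s = config.d_model, config.ffn_dim, config.vocab_size
    w: dict[str, np.ndarray] = {}
    w["E"] = rng.normal(0.0, 0.02, size=(s, d))
    for layer in range(config.n_layers):
        p = f"layer{layer}."
        for block in ("self", "cross"):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                w[p + block + "." + name] = _glorot(rng, (d, d))
        w[p + "ffn.W1"] = _glorot(rng, (d, f))
        w[p + "ffn.b1"] = np.zeros(f)
        w[p + "ffn.W2"] = _glorot(rng, (f, d))
        w[p + "ffn.b2"] = np.zeros(d)
        for ln in ("ln1", "ln2", "ln3"):
            w[p + ln + ".g"] = np.ones(d)
            w[p + ln + ".b"] = np.zeros(d)
    w["Wout"] = _glorot(rng, (d, s))
    w["bout"] = np.zeros(s)
    return ParameterSet(config=config, weights=w)


# ---------------------------------------------------------------------------
# forward pieces (batched; leading axis B)
# ---------------------------------------------------------------------------


def _split_heads(x: np.ndarray, h: int) -> np.ndarray:
    B, L, d = x.shape
    return x.reshape(B, L, h, d // h).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    B, h, L, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, L, h * dk)


def _softmax(x: np.ndarray) -> np.ndarray:
    m = np.max(x, axis=-1, keepdims=True)
    e = np.exp(x - m)
    return e / np.sum(e, axis=-1, keepdims=True)


def _attention(Q, K, V, mask=None):
    dk = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(dk)
    if mask is not None:
        scores = scores + mask
    A = _softmax(scores)
    return A @ V, A


def _attention_backward(dO, Q, K, V, A):
    dk = Q.shape[-1]
    dA = dO @ np.swapaxes(V, -1, -2)
    dV = np.swapaxes(A, -1, -2) @ dO
    ds = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
    dQ = ds @ K / math.sqrt(dk)
    dK = np.swapaxes(ds, -1, -2) @ Q / math.sqrt(dk)
    return dQ, dK, dV


def _layernorm(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_backward(dy, g, cache):
    xhat, inv = cache
    dxhat = dy * g
    dg = np.sum(dy * xhat, axis=tuple(range(dy.ndim - 1)))
    db = np.sum(dy, axis=tuple(range(dy.ndim - 1)))
    mean1 = dxhat.mean(axis=-1, keepdims=True)
    mean2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - mean1 - xhat * mean2)
    return dx, dg, db


def _causal_mask(L: int) -> np.ndarray:
    m = np.triu(np.ones((L, L)), k=1)
    return np.where(m > 0, -np.inf, 0.0)


def _forward(
    params: ParameterSet,
    indices: np.ndarray,
    x: np.ndarray,
    train: bool = False,
    dropout_rng: Optional[np.random.Generator] = None,
    collect_trace: bool = False,
):
    """Run the decoder on token ``indices`` (B, L) and embeddings ``x`` (B, d).

    Returns (logits, cache); cache holds every intermediate needed by
    :func:`_backward` and, when ``collect_trace``, per-layer cross-attention
    traces.
    """
    cfg = params.config
    w = params.weights
    B, L = indices.shape
    if L > cfg.seq_len:
        raise ValueError(f"sequence length {L} exceeds configured {cfg.seq_len}")
    if x.shape != (B, cfg.d_model):
        raise ValueError(
            f"protein embeddings have shape {x.shape}, expected {(B, cfg.d_model)}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("protein embeddings contain non-finite values")
    h = cfg.n_heads
    p_drop = cfg.dropout if train else 0.0
    mask = _causal_mask(L)

    Y0 = w["E"][indices] + params.positional[:L]
    cache: dict = {"indices": indices, "x": x, "L": L, "layers": [], "traces": []}
    Y = Y0
    for layer in range(cfg.n_layers):
        pfx = f"layer{layer}."
        lc: dict = {"Y_in": Y}

        # --- causal self-attention ---
        Q = _split_heads(Y @ w[pfx + "self.Wq"], h)
        K = _split_heads(Y @ w[pfx + "self.Wk"], h)
        V = _split_heads(Y @ w[pfx + "self.Wv"], h)
        O, A = _attention(Q, K, V, mask)
        Om = _merge_heads(O)
        sa = Om @ w[pfx + "self.Wo"]
        lc["self"] = (Q, K, V, A, Om)
        sa, lc["drop1"] = _dropout(sa, p_drop, dropout_rng)
        Y1, lc["ln1"] = _layernorm(
            Y + sa, w[pfx + "ln1.g"], w[pfx + "ln1.b"]
        )

        # --- protein cross-attention (single key/value row per head) ---
        Qc = _split_heads(Y1 @ w[pfx + "cross.Wq"], h)
        Kc = (x @ w[pfx + "cross.Wk"]).reshape(B, 1, h, cfg.d_k).transpose(0, 2, 1, 3)
        Vc = (x @ w[pfx + "cross.Wv"]).reshape(B, 1, h, cfg.d_k).transpose(0, 2, 1, 3)
        Oc, Ac = _attention(Qc, Kc, Vc)
        Ocm = _merge_heads(Oc)
        ca = Ocm @ w[pfx + "cross.Wo"]
        lc["cross"] = (Qc, Kc, Vc, Ac, Ocm)
        if collect_trace:
            cache["traces"].append(
                AttentionTrace(
                    Y=Y1[0],
                    Q=Qc[0],
                    K=Kc[0],
                    V=Vc[0],
                    Z_heads=Oc[0],
                    Z=ca[0],
                )
            )
        ca, lc["drop2"] = _dropout(ca, p_drop, dropout_rng)
        Y2, lc["ln2"] = _layernorm(
            Y1 + ca, w[pfx + "ln2.g"], w[pfx + "ln2.b"]
        )

        # --- position-wise feed-forward ---
        H = Y2 @ w[pfx + "ffn.W1"] + w[pfx + "ffn.b1"]
        Hr = np.maximum(H, 0.0)
        ff = Hr @ w[pfx + "ffn.W2"] + w[pfx + "ffn.b2"]
        lc["ffn"] = (Y2, H, Hr)
        ff, lc["drop3"] = _dropout(ff, p_drop, dropout_rng)
        Y3, lc["ln3"] = _layernorm(
            Y2 + ff, w[pfx + "ln3.g"], w[pfx + "ln3.b"]
        )
        lc["Y1"], lc["Y2"], lc["Y3"] = Y1, Y2, Y3
        cache["layers"].append(lc)
        Y = Y3

    logits = Y @ w["Wout"] + w["bout"]
    cache["Y_top"] = Y
    return logits, cache


def _dropout(x, p, rng):
    if p <= 0.0 or rng is None:
        return x, None
    keep = (rng.random(x.shape) >= p).astype(x.dtype) / (1.0 - p)
    return x * keep, keep


def _backward(params: ParameterSet, cache: dict, dlogits: np.ndarray):
    """Backpropagate through :func:`_forward`; returns gradient dict."""
    cfg = params.config
    w = params.weights
    h = cfg.n_heads
    grads = {k: np.zeros_like(v) for k, v in w.items()}

    Y_top = cache["Y_top"]
    grads["Wout"] += np.tensordot(Y_top, dlogits, axes=([0, 1], [0, 1]))
    grads["bout"] += dlogits.sum(axis=(0, 1))
    dY = dlogits @ w["Wout"].T

    for layer in reversed(range(cfg.n_layers)):
        pfx = f"layer{layer}."
        lc = cache["layers"][layer]

        # ln3 <- residual(Y2 + ff)
        dsum, dg, db = _layernorm_backward(dY, w[pfx + "ln3.g"], lc["ln3"])
        grads[pfx + "ln3.g"] += dg
        grads[pfx + "ln3.b"] += db
        dY2 = dsum.copy()
        dff = dsum if lc["drop3"] is None else dsum * lc["drop3"]
        Y2, H, Hr = lc["ffn"]
        grads[pfx + "ffn.W2"] += np.tensordot(Hr, dff, axes=([0, 1], [0, 1]))
        grads[pfx + "ffn.b2"] += dff.sum(axis=(0, 1))
        dHr = dff @ w[pfx + "ffn.W2"].T
        dH = dHr * (H > 0)
        grads[pfx + "ffn.W1"] += np.tensordot(Y2, dH, axes=([0, 1], [0, 1]))
        grads[pfx + "ffn.b1"] += dH.sum(axis=(0, 1))
        dY2 += dH @ w[pfx + "ffn.W1"].T

        # ln2 <- residual(Y1 + cross-attention)
        dsum, dg, db = _layernorm_backward(dY2, w[pfx + "ln2.g"], lc["ln2"])
        grads[pfx + "ln2.g"] += dg
        grads[pfx + "ln2.b"] += db
        dY1 = dsum.copy()
        dca = dsum if lc["drop2"] is None else dsum * lc["drop2"]
        Qc, Kc, Vc, Ac, Ocm = lc["cross"]
        grads[pfx + "cross.Wo"] += np.tensordot(Ocm, dca, axes=([0, 1], [0, 1]))
        dOcm = dca @ w[pfx + "cross.Wo"].T
        dOc = _split_heads(dOcm, h)
        dQc, dKc, dVc = _attention_backward(dOc, Qc, Kc, Vc, Ac)
        Y1 = lc["Y1"]
        x = cache["x"]
        dQcm = _merge_heads(dQc)
        grads[pfx + "cross.Wq"] += np.tensordot(Y1, dQcm, axes=([0, 1], [0, 1]))
        dY1 += dQcm @ w[pfx + "cross.Wq"].T
        dKx = dKc.transpose(0, 2, 1, 3).reshape(x.shape[0], cfg.d_model)
        dVx = dVc.transpose(0, 2, 1, 3).reshape(x.shape[0], cfg.d_model)
        grads[pfx + "cross.Wk"] += x.T @ dKx
        grads[pfx + "cross.Wv"] += x.T @ dVx

        # ln1 <- residual(Y_in + self-attention)
        dsum, dg, db = _layernorm_backward(dY1, w[pfx + "ln1.g"], lc["ln1"])
        grads[pfx + "ln1.g"] += dg
        grads[pfx + "ln1.b"] += db
        dYin = dsum.copy()
        dsa = dsum if lc["drop1"] is None else dsum * lc["drop1"]
        Q, K, V, A, Om = lc["self"]
        grads[pfx + "self.Wo"] += np.tensordot(Om, dsa, axes=([0, 1], [0, 1]))
        dOm = dsa @ w[pfx + "self.Wo"].T
        dO = _split_heads(dOm, h)
        dQ, dK, dV = _attention_backward(dO, Q, K, V, A)
        Y_in = lc["Y_in"]
        for name, dproj in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            dm = _merge_heads(dproj)
            grads[pfx + "self." + name] += np.tensordot(
                Y_in, dm, axes=([0, 1], [0, 1])
            )
            dYin += dm @ w[pfx + "self." + name].T
        dY = dYin

    # token embedding
    indices = cache["indices"]
    np.add.at(grads["E"], indices.reshape(-1), dY.reshape(-1, cfg.d_model))
    return grads


# ---------------------------------------------------------------------------
# public single-example operations
# ---------------------------------------------------------------------------


def embed_inputs(S: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Bottom-of-decoder input ``Y = S E + P`` for a one-hot matrix S (L x s)."""
    E = params.weights["E"]
    if S.ndim != 2 or S.shape[1] != E.shape[0]:
        raise ValueError(
            f"one-hot matrix has shape {S.shape}, expected (L, {E.shape[0]})"
        )
    L = S.shape[0]
    if L > params.positional.shape[0]:
        raise ValueError("sequence longer than positional-encoding table")
    return S @ E + params.positional[:L]


def protein_cross_attention(
    x: np.ndarray,
    Y: np.ndarray,
    params: ParameterSet,
    layer: int = 0,
    return_trace: bool = False,
):
    """Multi-head cross-attention of decoder states ``Y`` onto a protein vector.

    Computes, per head i, ``Q_i = Y W^Q_i``, single-row ``K_i = x W^K_i``
    and ``V_i = x W^V_i``, then ``Z_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i``
    and the projected concatenation ``Z``.
    """
    cfg = params.config
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("protein embedding contains non-finite values")
    if x.shape != (cfg.d_model,):
        raise ValueError(f"embedding has shape {x.shape}, expected ({cfg.d_model},)")
    w = params.weights
    pfx = f"layer{layer}."
    h = cfg.n_heads
    L = Y.shape[0]
    Qc = _split_heads((Y @ w[pfx + "cross.Wq"])[None], h)
    Kc = (x[None] @ w[pfx + "cross.Wk"]).reshape(1, 1, h, cfg.d_k).transpose(0, 2, 1, 3)
    Vc = (x[None] @ w[pfx + "cross.Wv"]).reshape(1, 1, h, cfg.d_k).transpose(0, 2, 1, 3)
    Oc, _ = _attention(Qc, Kc, Vc)
    Z = _merge_heads(Oc)[0] @ w[pfx + "cross.Wo"]
    if return_trace:
        return Z, AttentionTrace(
            Y=Y, Q=Qc[0], K=Kc[0], V=Vc[0], Z_heads=Oc[0], Z=Z
        )
    return Z


def decoder_forward(
    x: np.ndarray,
    S: np.ndarray | EncodedSmiles,
    params: ParameterSet,
    return_trace: bool = False,
):
    """Full decoder forward pass for one (protein, molecule) input.

    ``S`` may be an :class:`EncodedSmiles`, a one-hot matrix (L x s) or an
    index vector of length L.  Returns the (L x s) logit matrix, plus the
    per-layer cross-attention traces when ``return_trace``.
    """
    if isinstance(S, EncodedSmiles):
        indices = S.indices
    else:
        S = np.asarray(S)
        if S.ndim == 2:
            if S.shape[1] != params.config.vocab_size:
                raise ValueError(
                    f"one-hot width {S.shape[1]} != vocabulary "
                    f"size {params.config.vocab_size}"
                )
            indices = np.argmax(S, axis=1)
        else:
            indices = S.astype(np.int64)
    x = np.asarray(x, dtype=np.float64)
    logits, cache = _forward(
        params, indices[None], x[None], train=False, collect_trace=return_trace
    )
    if return_trace:
        return logits[0], cache["traces"]
    return logits[0]


def nll_loss(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> float:
    """Mean negative log-likelihood over unmasked target positions."""
    logits = np.asarray(logits, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("all target positions are masked")
    logp = logits - np.max(logits, axis=-1, keepdims=True)
    logp = logp - np.log(np.sum(np.exp(logp), axis=-1, keepdims=True))
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    return float(-(picked * mask).sum() / mask.sum())


def _loss_and_dlogits(logits, targets, mask):
    logp = logits - np.max(logits, axis=-1, keepdims=True)
    logp = logp - np.log(np.sum(np.exp(logp), axis=-1, keepdims=True))
    probs = np.exp(logp)
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    n = mask.sum()
    loss = float(-(picked * mask).sum() / n)
    dlogits = probs.copy()
    rows = np.arange(targets.shape[0])[:, None]
    cols = np.arange(targets.shape[1])[None, :]
    dlogits[rows, cols, targets] -= 1.0
    dlogits *= (mask / n)[..., None]
    return loss, dlogits


def loss_and_grads(
    params: ParameterSet,
    indices: np.ndarray,
    x: np.ndarray,
    pad_id: int,
    train: bool = False,
    dropout_rng: Optional[np.random.Generator] = None,
):
    """Teacher-forced loss and parameter gradients on a batch.

    ``indices`` is (B, L); targets are the inputs shifted left by one,
    with positions whose target is the pad token excluded.
    """
    inp = indices[:, :-1]
    targets = indices[:, 1:]
    mask = (targets != pad_id).astype(np.float64)
    if mask.sum() == 0:
        raise ValueError("all target positions are masked")
    logits, cache = _forward(params, inp, x, train=train, dropout_rng=dropout_rng)
    loss, dlogits = _loss_and_dlogits(logits, targets, mask)
    grads = _backward(params, cache, dlogits)
    return loss, grads


class _Adam:
    def __init__(self, weights: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            weights[k] -= (
                self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            )


def train(
    dataset: Sequence[tuple[ProteinRecord | np.ndarray, EncodedSmiles | np.ndarray]],
    config: DecoderConfig,
    seed: int = 0,
    init: Optional[ParameterSet] = None,
    pad_id: Optional[int] = None,
    log_every: int = 0,
) -> tuple[ParameterSet, list[float]]:
    """Teacher-forced training with Adam at a fixed learning rate.

    ``dataset`` pairs each protein (record or raw embedding vector) with
    an encoded molecule (``EncodedSmiles`` or index vector).  Batches are
    reshuffled each epoch from a generator seeded by ``seed``; returns
    the trained parameters and the per-epoch mean loss history.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if pad_id is None:
        pad_id = build_default_vocabulary().pad_id

    emb = np.stack(
        [
            p.embedding if isinstance(p, ProteinRecord) else np.asarray(p, float)
            for p, _ in dataset
        ]
    )
    if emb.shape[1] != config.d_model:
        raise ValueError(
            f"embedding dimension {emb.shape[1]} != model dimension {config.d_model}"
        )
    idx = np.stack(
        [
            e.indices if isinstance(e, EncodedSmiles) else np.asarray(e, np.int64)
            for _, e in dataset
        ]
    )
    if idx.shape[1] > config.seq_len:
        raise ValueError(
            f"encoded length {idx.shape[1]} exceeds configured seq_len {config.seq_len}"
        )

    rng = np.random.default_rng(seed)
    params = init.copy() if init is not None else init_parameters(config, seed=seed)
    adam = _Adam(params.weights, config.learning_rate)
    drop_rng = np.random.default_rng(rng.integers(2**31)) if config.dropout > 0 else None

    history: list[float] = []
    n = len(dataset)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            loss, grads = loss_and_grads(
                params,
                idx[sel],
                emb[sel],
                pad_id,
                train=config.dropout > 0,
                dropout_rng=drop_rng,
            )
            adam.step(params.weights, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if log_every and (epoch + 1) % log_every == 0:
            logger.info("epoch %d/%d loss %.4f", epoch + 1, config.epochs, history[-1])
    return params, history
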