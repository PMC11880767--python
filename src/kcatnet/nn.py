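"""Network building blocks: positional encodings, attention, and GCN layers.

These are the mathematical primitives of the predictor:

* sinusoidal positional encoding  PE[pos, 2i] = sin(pos / 10000^(2i/d)),
  PE[pos, 2i+1] = cos(pos / 10000^(2i/d));
* scaled dot-product attention  softmax(QKᵀ/√d_k)V and its multi-head form
  Concat(head_1 … head_h)Wᵒ with per-head projections;
* the symmetric-normalised graph convolution
  H⁽ˡ⁺¹⁾ = σ(D̃^{-1/2} Ã D̃^{-1/2} H⁽ˡ⁾ W⁽ˡ⁾) with Ã = A + I.

All operations accept either plain NumPy arrays (returning arrays) or
autodiff :class:`~kcatnet.autodiff.Tensor` objects (returning tensors on the
tape), so the same code serves inference, training and the test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .errors import ConfigError, GraphError, ShapeError

__all__ = [
    "positional_encoding",
    "scaled_dot_attention",
    "multi_head_attention",
    "gcn_forward",
    "normalized_propagator",
    "AttentionParams",
    "GCNLayerParams",
    "LayerNormParams",
    "layer_norm",
    "glorot",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


def positional_encoding(length: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional-encoding matrix of shape (length, d_model)."""
    if length < 1:
        raise ConfigError(f"length must be >= 1, got {length}")
    if d_model % 2 != 0 or d_model < 2:
        raise ConfigError(f"d_model must be a positive even integer, got {d_model}")
    positions = np.arange(length)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = positions / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((length, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def _wants_array(*operands) -> bool:
    return not any(isinstance(op, Tensor) for op in operands)


def scaled_dot_attention(Q, K, V):
    """softmax(QKᵀ/√d_k) V with row-wise softmax."""
    plain = _wants_array(Q, K, V)
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    if Q.shape[-1] != K.shape[-1]:
        raise ShapeError(f"Q and K widths differ: {Q.shape[-1]} vs {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ShapeError(f"K and V row counts differ: {K.shape[-2]} vs {V.shape[-2]}")
    d_k = Q.shape[-1]
    scores = (Q @ K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)) * (
        1.0 / np.sqrt(d_k)
    )
    out = scores.softmax(axis=-1) @ V
    return out.numpy() if plain else out


@dataclass
class AttentionParams:
    """Per-head Q/K/V projections and the output projection of Eq-style MHA."""

    w_q: list[Tensor]  # h matrices, d_model x d_k
    w_k: list[Tensor]
    w_v: list[Tensor]
    w_o: Tensor  # (h * d_k) x d_model

    @property
    def n_heads(self) -> int:
        return len(self.w_q)

    @property
    def d_k(self) -> int:
        return self.w_q[0].shape[1]

    @classmethod
    def create(cls, d_model: int, n_heads: int, rng: np.random.Generator) -> "AttentionParams":
        if d_model % n_heads != 0:
            raise ConfigError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        d_k = d_model // n_heads
        make = lambda fi, fo: Tensor(glorot(rng, fi, fo), requires_grad=True)
        return cls(
            w_q=[make(d_model, d_k) for _ in range(n_heads)],
            w_k=[make(d_model, d_k) for _ in range(n_heads)],
            w_v=[make(d_model, d_k) for _ in range(n_heads)],
            w_o=make(n_heads * d_k, d_model),
        )

    def tensors(self) -> list[tuple[str, Tensor]]:
        named = []
        for i in range(self.n_heads):
            named += [
                (f"w_q.{i}", self.w_q[i]),
                (f"w_k.{i}", self.w_k[i]),
                (f"w_v.{i}", self.w_v[i]),
            ]
        named.append(("w_o", self.w_o))
        return named


def multi_head_attention(Q, K, V, params: AttentionParams):
    """Concat(head_1, …, head_h) Wᵒ, head_i = attention(QW_i^Q, KW_i^K, VW_i^V)."""
    plain = _wants_array(Q, K, V)
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    heads = [
        scaled_dot_attention(Q @ wq, K @ wk, V @ wv)
        for wq, wk, wv in zip(params.w_q, params.w_k, params.w_v)
    ]
    out = concat(heads, axis=-1) @ params.w_o
    return out.numpy() if plain else out


# ---------------------------------------------------------------------------
# graph convolution
# ---------------------------------------------------------------------------

def normalized_propagator(adjacency: np.ndarray) -> np.ndarray:
    """D̃^{-1/2} (A + I) D̃^{-1/2} for a symmetric binary adjacency."""
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise GraphError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise GraphError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise GraphError("adjacency must have a zero diagonal (self-loops are added here)")
    if not np.all(np.isin(A, (0.0, 1.0))):
        raise GraphError("adjacency must be binary")
    a_tilde = A + np.eye(A.shape[0])
    inv_sqrt_deg = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * inv_sqrt_deg[:, None] * inv_sqrt_deg[None, :]


@dataclass
class GCNLayerParams:
    """Stacked GCN layer weights sharing one activation σ."""

    weights: list[Tensor]
    activation: str = "relu"  # "relu" or "identity"

    @classmethod
    def create(
        cls,
        widths: Sequence[int],
        rng: np.random.Generator,
        activation: str = "relu",
    ) -> "GCNLayerParams":
        weights = [
            Tensor(glorot(rng, fi, fo), requires_grad=True)
            for fi, fo in zip(widths[:-1], widths[1:])
        ]
        return cls(weights=weights, activation=activation)

    def tensors(self) -> list[tuple[str, Tensor]]:
        return [(f"w.{i}", w) for i, w in enumerate(self.weights)]


def gcn_forward(H, A, layers: GCNLayerParams, propagator: np.ndarray | None = None):
    """Apply stacked symmetric-normalised graph convolutions.

    `A` is the self-loop-free binary adjacency; the propagator
    D̃^{-1/2}(A+I)D̃^{-1/2} may be passed precomputed (it only depends on the
    graph, so featurization caches it across epochs).
    """
    plain = _wants_array(H)
    H = as_tensor(H)
    S = Tensor(normalized_propagator(A) if propagator is None else propagator)
    if H.shape[0] != S.shape[0]:
        raise ShapeError(
            f"feature rows ({H.shape[0]}) must match adjacency size ({S.shape[0]})"
        )
    for W in layers.weights:
        H = S @ H @ W
        if layers.activation == "relu":
            H = H.relu()
        elif layers.activation != "identity":
            raise ConfigError(f"unknown GCN activation {layers.activation!r}")
    return H.numpy() if plain else H


# ---------------------------------------------------------------------------
# layer normalisation (transformer sublayer plumbing)
# ---------------------------------------------------------------------------

@dataclass
class LayerNormParams:
    gamma: Tensor
    beta: Tensor

    @classmethod
    def create(cls, width: int) -> "LayerNormParams":
        return cls(
            gamma=Tensor(np.ones(width), requires_grad=True),
            beta=Tensor(np.zeros(width), requires_grad=True),
        )

    def tensors(self) -> list[tuple[str, Tensor]]:
        return [("gamma", self.gamma), ("beta", self.beta)]


def layer_norm(x: Tensor, params: LayerNormParams, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return params.gamma * (centered / (var + eps).sqrt()) + params.beta
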