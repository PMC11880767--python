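"""The kcat prediction network.

Three feature streams are fused into one embedding and regressed onto
log10(kcat):

* **sequence stream** — n-gram token embeddings plus sinusoidal positional
  encodings, passed through a transformer encoder; yields the hidden-vector
  set C = {c_1 … c_n};
* **protein structure stream** — learned residue-type embeddings propagated
  by a GCN over the Cα contact map, mean-pooled to s_structure (the
  per-residue outputs also drive residue-importance interpretation);
* **substrate stream** — atom-environment token embeddings propagated by a
  dedicated GCN over the bond adjacency, mean-pooled to y_substrate.

Fusion uses a neural attention mechanism: both y_substrate and each c_i are
passed through a shared affine map with ReLU (h = f(W_inter·x + b)), the
attention weight of position i is a_i = sigmoid(h_substrateᵀ h_i), and the
sequence stream is aggregated as the a-weighted mean of the h_i. The fused
embedding (attended sequence ‖ substrate ‖ pooled structure, depending on
the input mode) feeds a small dense head ending in a single linear output.

Ablation modes: ``full`` uses all three streams, ``sequence_only`` omits the
structure stream, ``structure_only`` omits the sequence stream, and
``substrate_only`` keeps only the substrate stream (a baseline).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat
from .errors import ConfigError, FusionError, InputError
from .nn import (
    AttentionParams,
    GCNLayerParams,
    LayerNormParams,
    gcn_forward,
    glorot,
    layer_norm,
    multi_head_attention,
    positional_encoding,
)
from .sequence import AMINO_ACIDS, NGramVocab
from .substrate import AtomEnvVocab

__all__ = ["ModelConfig", "FusionParams", "KcatNetwork", "fuse_and_attend", "MODES"]

MODES = ("full", "sequence_only", "structure_only", "substrate_only")

CHECKPOINT_SCHEMA = "kcatnet-checkpoint-1"


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the small desk-scale configuration used throughout the
    package: embedding width 32 split over 4 attention heads, one
    transformer encoder layer and two GCN layers per graph stream,
    tri-gram sequence tokens, radius-2 atom environments, and the 10 Å
    Cα–Cα contact threshold.
    """

    d_model: int = 32
    n_heads: int = 4
    n_transformer_layers: int = 1
    n_gcn_layers_protein: int = 2
    n_gcn_layers_substrate: int = 2
    ngram_n: int = 3
    env_radius: int = 2
    contact_threshold: float = 10.0
    mode: str = "full"
    seed: int = 0
    ffn_multiplier: int = 4
    head_width: int = 32
    keep_sequential_contacts: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.d_model % 2 != 0:
            raise ConfigError(f"d_model must be even, got {self.d_model}")
        if self.d_model % self.n_heads != 0:
            raise ConfigError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        for name in (
            "d_model",
            "n_heads",
            "n_transformer_layers",
            "n_gcn_layers_protein",
            "n_gcn_layers_substrate",
            "ngram_n",
            "head_width",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.env_radius < 0:
            raise ConfigError("env_radius must be >= 0")
        if self.contact_threshold <= 0:
            raise ConfigError("contact_threshold must be positive")

    @property
    def uses_sequence(self) -> bool:
        return self.mode in ("full", "sequence_only")

    @property
    def uses_structure(self) -> bool:
        return self.mode in ("full", "structure_only")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        return cls(**data)


@dataclass
class FusionParams:
    """Shared interaction map of the attention fusion: h = f(W_inter·x + b)."""

    w_inter: Tensor  # d_model x d_model
    b: Tensor  # d_model

    @classmethod
    def create(cls, d_model: int, rng: np.random.Generator) -> "FusionParams":
        return cls(
            w_inter=Tensor(glorot(rng, d_model, d_model), requires_grad=True),
            b=Tensor(np.zeros(d_model), requires_grad=True),
        )

    def tensors(self) -> list[tuple[str, Tensor]]:
        return [("w_inter", self.w_inter), ("b", self.b)]


def fuse_and_attend(
    C: Tensor | np.ndarray | None,
    y_substrate: Tensor | np.ndarray,
    s_structure: Tensor | np.ndarray | None,
    params: FusionParams,
    mode: str = "full",
) -> tuple[Tensor, Tensor]:
    """Attention fusion of the three stream outputs.

    Returns ``(fused, a)`` where `a` holds the per-position attention
    weights a_i = sigmoid(h_substrateᵀ h_i) ∈ (0, 1) and `fused` is the
    concatenation (as a 1×· row) of the a-weighted mean of the h_i, the
    transformed substrate vector, and the pooled structure vector —
    according to `mode`. The a-weighted mean is normalised by Σ a_i so its
    scale does not grow with sequence length.
    """
    if mode not in MODES:
        raise ConfigError(f"unknown fusion mode {mode!r}")
    use_seq = mode in ("full", "sequence_only")
    use_struct = mode in ("full", "structure_only")

    def as2d(x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        return x.reshape(1, -1) if x.ndim == 1 else x

    y_substrate = as2d(y_substrate)
    h_substrate = (y_substrate @ params.w_inter.T + params.b).relu()  # 1 x d

    pieces: list[Tensor] = []
    a = Tensor(np.zeros((0,)))
    if use_seq:
        if C is None or (getattr(C, "shape", (0,))[0] == 0):
            raise FusionError("sequence hidden-vector set C is empty")
        C = C if isinstance(C, Tensor) else Tensor(C)
        H = (C @ params.w_inter.T + params.b).relu()  # n x d
        a = (H @ h_substrate.T).sigmoid().reshape(-1)  # n
        weights = a.reshape(1, -1)
        attended = (weights @ H) / a.sum()  # 1 x d
        pieces.append(attended)
    pieces.append(h_substrate)
    if use_struct:
        if s_structure is None:
            raise FusionError(f"mode {mode!r} requires a structure vector")
        pieces.append(as2d(s_structure))
    fused = concat(pieces, axis=-1) if len(pieces) > 1 else pieces[0]
    return fused, a


@dataclass
class _TransformerLayer:
    ln1: LayerNormParams
    attn: AttentionParams
    ln2: LayerNormParams
    w_ff1: Tensor
    b_ff1: Tensor
    w_ff2: Tensor
    b_ff2: Tensor

    @classmethod
    def create(cls, d_model: int, n_heads: int, ffn_mult: int, rng) -> "_TransformerLayer":
        d_ff = ffn_mult * d_model
        return cls(
            ln1=LayerNormParams.create(d_model),
            attn=AttentionParams.create(d_model, n_heads, rng),
            ln2=LayerNormParams.create(d_model),
            w_ff1=Tensor(glorot(rng, d_model, d_ff), requires_grad=True),
            b_ff1=Tensor(np.zeros(d_ff), requires_grad=True),
            w_ff2=Tensor(glorot(rng, d_ff, d_model), requires_grad=True),
            b_ff2=Tensor(np.zeros(d_model), requires_grad=True),
        )

    def tensors(self, prefix: str) -> list[tuple[str, Tensor]]:
        named = [(f"{prefix}.ln1.{n}", t) for n, t in self.ln1.tensors()]
        named += [(f"{prefix}.attn.{n}", t) for n, t in self.attn.tensors()]
        named += [(f"{prefix}.ln2.{n}", t) for n, t in self.ln2.tensors()]
        named += [
            (f"{prefix}.w_ff1", self.w_ff1),
            (f"{prefix}.b_ff1", self.b_ff1),
            (f"{prefix}.w_ff2", self.w_ff2),
            (f"{prefix}.b_ff2", self.b_ff2),
        ]
        return named

    def forward(self, x: Tensor) -> Tensor:
        # pre-norm residual sublayers
        h = layer_norm(x, self.ln1)
        x = x + multi_head_attention(h, h, h, self.attn)
        h = layer_norm(x, self.ln2)
        x = x + (((h @ self.w_ff1 + self.b_ff1).relu()) @ self.w_ff2 + self.b_ff2)
        return x


class KcatNetwork:
    """Parameter container and forward pass of the kcat predictor."""

    N_RESIDUE_TYPES = len(AMINO_ACIDS) + 1  # 20 canonical + X

    def __init__(
        self,
        config: ModelConfig,
        seq_vocab: NGramVocab | None,
        env_vocab: AtomEnvVocab,
    ):
        if config.uses_sequence and seq_vocab is None:
            raise ConfigError(f"mode {config.mode!r} requires an n-gram vocabulary")
        self.config = config
        self.seq_vocab = seq_vocab
        self.env_vocab = env_vocab
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        scale = 1.0 / np.sqrt(d)

        self.seq_embedding = Tensor(
            rng.normal(0.0, scale, size=(len(seq_vocab) if seq_vocab else 1, d)),
            requires_grad=True,
        )
        self.transformer_layers = [
            _TransformerLayer.create(d, config.n_heads, config.ffn_multiplier, rng)
            for _ in range(config.n_transformer_layers)
        ]
        self.final_ln = LayerNormParams.create(d)

        self.residue_embedding = Tensor(
            rng.normal(0.0, scale, size=(self.N_RESIDUE_TYPES, d)), requires_grad=True
        )
        self.protein_gcn = GCNLayerParams.create(
            [d] * (config.n_gcn_layers_protein + 1), rng
        )

        self.env_embedding = Tensor(
            rng.normal(0.0, scale, size=(len(env_vocab), d)), requires_grad=True
        )
        self.substrate_gcn = GCNLayerParams.create(
            [d] * (config.n_gcn_layers_substrate + 1), rng
        )

        # the sequence stream is layer-normalised; normalising the pooled
        # graph-stream vectors too keeps the three fusion inputs on one scale
        self.structure_norm = LayerNormParams.create(d)
        self.substrate_norm = LayerNormParams.create(d)

        self.fusion = FusionParams.create(d, rng)
        fused_width = {
            "full": 3 * d,
            "sequence_only": 2 * d,
            "structure_only": 2 * d,
            "substrate_only": d,
        }[config.mode]
        w = config.head_width
        self.head_w1 = Tensor(glorot(rng, fused_width, w), requires_grad=True)
        self.head_b1 = Tensor(np.zeros(w), requires_grad=True)
        self.head_w2 = Tensor(glorot(rng, w, w), requires_grad=True)
        self.head_b2 = Tensor(np.zeros(w), requires_grad=True)
        self.head_w3 = Tensor(glorot(rng, w, 1), requires_grad=True)
        self.head_b3 = Tensor(np.zeros(1), requires_grad=True)

        self._pe_cache: dict[int, np.ndarray] = {}

    # -- parameters --------------------------------------------------------

    def parameters(self) -> list[tuple[str, Tensor]]:
        named: list[tuple[str, Tensor]] = [("seq_embedding", self.seq_embedding)]
        for i, layer in enumerate(self.transformer_layers):
            named += layer.tensors(f"transformer.{i}")
        named += [(f"final_ln.{n}", t) for n, t in self.final_ln.tensors()]
        named.append(("residue_embedding", self.residue_embedding))
        named += [(f"protein_gcn.{n}", t) for n, t in self.protein_gcn.tensors()]
        named.append(("env_embedding", self.env_embedding))
        named += [(f"substrate_gcn.{n}", t) for n, t in self.substrate_gcn.tensors()]
        named += [(f"structure_norm.{n}", t) for n, t in self.structure_norm.tensors()]
        named += [(f"substrate_norm.{n}", t) for n, t in self.substrate_norm.tensors()]
        named += [(f"fusion.{n}", t) for n, t in self.fusion.tensors()]
        named += [
            ("head_w1", self.head_w1),
            ("head_b1", self.head_b1),
            ("head_w2", self.head_w2),
            ("head_b2", self.head_b2),
            ("head_w3", self.head_w3),
            ("head_b3", self.head_b3),
        ]
        return named

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.parameters():
            t.data = np.array(state[name], dtype=np.float64)

    # -- streams -----------------------------------------------------------

    def _pe(self, length: int) -> np.ndarray:
        if length not in self._pe_cache:
            self._pe_cache[length] = positional_encoding(length, self.config.d_model)
        return self._pe_cache[length]

    def transformer_encode(self, token_ids: np.ndarray) -> Tensor:
        """Sequence stream: returns the hidden-vector set C (n × d_model)."""
        x = self.seq_embedding.take_rows(token_ids)
        x = x + Tensor(self._pe(len(token_ids)))
        for layer in self.transformer_layers:
            x = layer.forward(x)
        return layer_norm(x, self.final_ln)

    def protein_node_features(self, residue_type_ids, adjacency, propagator=None) -> Tensor:
        """Structure stream before pooling: per-residue GCN outputs (N × d)."""
        h0 = self.residue_embedding.take_rows(residue_type_ids)
        return gcn_forward(h0, adjacency, self.protein_gcn, propagator=propagator)

    def substrate_vector(self, atom_token_ids, adjacency, propagator=None) -> Tensor:
        h0 = self.env_embedding.take_rows(atom_token_ids)
        nodes = gcn_forward(h0, adjacency, self.substrate_gcn, propagator=propagator)
        return layer_norm(nodes.mean(axis=0, keepdims=True), self.substrate_norm)

    # -- full forward ------------------------------------------------------

    def forward(self, feat) -> tuple[Tensor, Tensor]:
        """Predict log10(kcat) for one featurized record.

        Returns ``(prediction, attention_weights)``; the prediction is a
        1-element tensor on the tape.
        """
        cfg = self.config
        C = None
        s_structure = None
        if cfg.uses_sequence:
            if feat.token_ids is None:
                raise InputError(
                    f"mode {cfg.mode!r} requires sequence tokens (record {feat.record_id})"
                )
            C = self.transformer_encode(feat.token_ids)
        if cfg.uses_structure:
            if feat.contact_adjacency is None:
                raise InputError(
                    f"mode {cfg.mode!r} requires a structure (record {feat.record_id})"
                )
            nodes = self.protein_node_features(
                feat.residue_type_ids,
                feat.contact_adjacency,
                propagator=feat.protein_propagator,
            )
            s_structure = layer_norm(
                nodes.mean(axis=0, keepdims=True), self.structure_norm
            )
        y_substrate = self.substrate_vector(
            feat.atom_token_ids,
            feat.substrate_adjacency,
            propagator=feat.substrate_propagator,
        )
        fused, attn = fuse_and_attend(
            C, y_substrate, s_structure, self.fusion, mode=cfg.mode
        )
        h = (fused @ self.head_w1 + self.head_b1).relu()
        h = (h @ self.head_w2 + self.head_b2).relu()
        out = h @ self.head_w3 + self.head_b3
        return out.reshape(-1), attn

    def predict_one(self, feat) -> float:
        return float(self.forward(feat)[0].numpy()[0])

    def predict(self, feats: Sequence) -> np.ndarray:
        return np.array([self.predict_one(f) for f in feats])

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a single checkpoint file (config + vocabularies + weights)."""
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "config": self.config.to_dict(),
            "seq_vocab": None
            if self.seq_vocab is None
            else {"n": self.seq_vocab.n, "token_to_id": self.seq_vocab.token_to_id},
            "env_vocab": {
                "radius": self.env_vocab.radius,
                "env_to_id": self.env_vocab.env_to_id,
            },
        }
        arrays = {f"param:{name}": t.data for name, t in self.parameters()}
        np.savez_compressed(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "KcatNetwork":
        path = Path(path)
        if not path.exists():
            raise InputError(f"model checkpoint not found: {path}")
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise InputError(
                    f"unsupported checkpoint schema {meta.get('schema')!r} in {path}"
                )
            config = ModelConfig.from_dict(meta["config"])
            seq_vocab = (
                NGramVocab(
                    n=meta["seq_vocab"]["n"],
                    token_to_id=meta["seq_vocab"]["token_to_id"],
                )
                if meta["seq_vocab"]
                else None
            )
            env_vocab = AtomEnvVocab(
                radius=meta["env_vocab"]["radius"],
                env_to_id=meta["env_vocab"]["env_to_id"],
            )
            network = cls(config, seq_vocab, env_vocab)
            state = {
                key[len("param:") :]: data[key]
                for key in data.files
                if key.startswith("param:")
            }
            network.load_state_dict(state)
        return network
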