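"""Multi-scale self- and cross-attention encoder and its ablation variants.

A 41-nt window is viewed at three centered scales (default order
21, 41, 31).  The first scale in the order is the query stream; the other
two feed the cross-attention branches as key/value sources.  Each of N
stacked layers applies a multi-branch multi-head attention sublayer and a
position-wise feed-forward sublayer, both with residual connections and
post-layer normalization.  The head averages the encoded query rows,
applies a linear map and a sigmoid to emit a methylation probability.

Variants mask attention branches:

====== =====================================
MSCAN  self + both cross branches
SCAN   self + cross toward the second scale
SAN    self only (single-scale baseline)
MCAN   both cross branches, no self
CAN    one cross branch only
====== =====================================

Per head and per branch the query, key and value projections are
independent; branch outputs are summed per head, heads are concatenated
and projected by an output matrix.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import kmer_embedding as ke
from .nn import Tensor, dropout, glorot_uniform
from .sequence_io import WINDOW_LENGTH, MethylDataset

__all__ = [
    "ModelConfig", "ScaleBundle", "VARIANTS", "extract_subsequences",
    "centered_window", "positional_encoding", "project_embedding",
    "scaled_dot_attention", "msca_sublayer", "ffn", "layer_norm",
    "encoder_forward", "classify", "build_variant", "MSCANModel", "Predictor",
]

VARIANTS = ("MSCAN", "SCAN", "SAN", "MCAN", "CAN")

#: attention branches active in each variant
BRANCHES = {
    "MSCAN": ("self", "cross1", "cross2"),
    "SCAN": ("self", "cross1"),
    "SAN": ("self",),
    "MCAN": ("cross1", "cross2"),
    "CAN": ("cross1",),
}

#: stream index (position in scale_order) a branch draws keys/values from
BRANCH_SOURCE = {"self": 0, "cross1": 1, "cross2": 2}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters."""

    d_model: int = 64
    h: int = 8
    d_k: int = 8
    d_v: int = 8
    d_ff: int = 256
    layers: int = 3
    dropout: float = 0.2
    scale_order: tuple[int, int, int] = (21, 41, 31)
    d_embed: int = 100
    variant: str = "MSCAN"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.h <= 0 or self.d_model % self.h != 0:
            raise ValueError("d_model must be divisible by h")
        if self.d_k != self.d_model // self.h or self.d_v != self.d_model // self.h:
            raise ValueError("require d_k == d_v == d_model / h")
        so = tuple(self.scale_order)
        object.__setattr__(self, "scale_order", so)
        if len(so) != 3 or len(set(so)) != 3:
            raise ValueError("scale_order must be three distinct lengths")
        if any(s % 2 == 0 or s > WINDOW_LENGTH or s < 3 for s in so):
            raise ValueError(
                f"scale_order entries must be odd and in [3, {WINDOW_LENGTH}]"
            )
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.layers < 0:
            raise ValueError("layers must be >= 0")

    @property
    def streams(self) -> tuple[int, ...]:
        """Indices of scale streams the variant actually consumes."""
        used = sorted({BRANCH_SOURCE[b] for b in BRANCHES[self.variant]} | {0})
        return tuple(used)

    def token_count(self, stream: int) -> int:
        return self.scale_order[stream] - 2


@dataclass
class ScaleBundle:
    """Query-scale matrix plus the two auxiliary-scale matrices."""

    query_matrix: np.ndarray
    aux_matrices: tuple[np.ndarray, ...] = ()

    def __post_init__(self):
        self.query_matrix = np.asarray(self.query_matrix, dtype=np.float64)
        self.aux_matrices = tuple(
            np.asarray(a, dtype=np.float64) for a in self.aux_matrices
        )
        width = self.query_matrix.shape[-1]
        for a in self.aux_matrices:
            if a.shape[-1] != width:
                raise ValueError("all bundle matrices must share their width")


def centered_window(sequence: str, length: int) -> str:
    """Extract the length-``length`` substring centered on the midpoint."""
    if len(sequence) % 2 == 0 or length % 2 == 0:
        raise ValueError("centered_window requires odd lengths")
    if length > len(sequence):
        raise ValueError(
            f"window {length} longer than sequence {len(sequence)}"
        )
    start = (len(sequence) - length) // 2
    return sequence[start:start + length]


def extract_subsequences(sequence: str) -> tuple[str, str]:
    """The 21-nt and 31-nt subsequences centered on index 20 of a 41-nt window."""
    if len(sequence) != WINDOW_LENGTH:
        raise ValueError(
            f"expected a {WINDOW_LENGTH}-character window, got {len(sequence)}"
        )
    return centered_window(sequence, 21), centered_window(sequence, 31)


def positional_encoding(m: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal position encodings, shape (m, d_model)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if d_model % 2 != 0:
        raise ValueError("d_model must be even")
    pos = np.arange(m)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((m, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def project_embedding(x: np.ndarray, weight: np.ndarray,
                      bias: np.ndarray) -> np.ndarray:
    """Row-wise affine map from d_embed to d_model width."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != weight.shape[0]:
        raise ValueError(
            f"input width {x.shape[-1]} does not match projection "
            f"fan-in {weight.shape[0]}"
        )
    return x @ weight + bias


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray,
                         V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """softmax(QK^T / sqrt(d_k)) V; returns (output, attention weights)."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if not (np.isfinite(Q).all() and np.isfinite(K).all() and np.isfinite(V).all()):
        raise ValueError("non-finite attention inputs")
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K widths differ")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V row counts differ")
    d_k = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ V, weights


# ---------------------------------------------------------------------------
# Tensor-level building blocks (shared by the public ops and the model)
# ---------------------------------------------------------------------------

def _split_heads(x: Tensor, h: int) -> Tensor:
    """(B, m, h*d) -> (B, h, m, d)."""
    b, m, hd = x.shape
    return x.reshape(b, m, h, hd // h).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    """(B, h, m, d) -> (B, m, h*d)."""
    b, h, m, d = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, m, h * d)


def _attention_t(q: Tensor, k: Tensor, v: Tensor, d_k: int) -> Tensor:
    scores = (q @ k.swap_last()) * (1.0 / np.sqrt(d_k))
    return scores.softmax() @ v


def _msca_t(xq: Tensor, sources: Mapping[int, Tensor], params: Mapping[str, Tensor],
            variant: str, h: int) -> Tensor:
    """Multi-branch multi-head attention on batched (B, m, d_model) tensors."""
    d_model = xq.shape[-1]
    d_k = d_model // h
    head_sum = None
    for branch in BRANCHES[variant]:
        src = xq if branch == "self" else sources[BRANCH_SOURCE[branch]]
        q = _split_heads(xq @ params[f"{branch}_Wq"], h)
        k = _split_heads(src @ params[f"{branch}_Wk"], h)
        v = _split_heads(src @ params[f"{branch}_Wv"], h)
        att = _attention_t(q, k, v, d_k)
        head_sum = att if head_sum is None else head_sum + att
    return _merge_heads(head_sum) @ params["Wo"]


def _ffn_t(x: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor) -> Tensor:
    return (x @ w1 + b1).relu() @ w2 + b2


def _layer_norm_t(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * gamma + beta


def _as_batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None], True
    return x, False


def msca_sublayer(bundle: ScaleBundle, params: Mapping[str, np.ndarray],
                  variant: str, h: int) -> np.ndarray:
    """Functional multi-scale attention sublayer on a single bundle.

    ``params`` holds, per active branch ``b``, ``{b}_Wq``, ``{b}_Wk`` and
    ``{b}_Wv`` of shape (d_model, h*d_k), plus ``Wo`` of shape
    (h*d_v, d_model); heads are packed along the columns.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    xq, squeeze = _as_batched(bundle.query_matrix)
    sources = {
        i + 1: Tensor(_as_batched(a)[0]) for i, a in enumerate(bundle.aux_matrices)
    }
    tp = {k: Tensor(v) for k, v in params.items()}
    out = _msca_t(Tensor(xq), sources, tp, variant, h).data
    return out[0] if squeeze else out


def ffn(x: np.ndarray, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray,
        b2: np.ndarray) -> np.ndarray:
    """Position-wise feed-forward: max(0, xW1 + b1) W2 + b2."""
    return _ffn_t(Tensor(x), Tensor(W1), Tensor(b1), Tensor(W2), Tensor(b2)).data


def layer_norm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
               eps: float = 1e-5) -> np.ndarray:
    return _layer_norm_t(Tensor(x), Tensor(gamma), Tensor(beta), eps).data


def classify(encoded: np.ndarray, weight: np.ndarray, bias: float) -> float:
    """sigmoid(w . mean_rows(encoded) + b)."""
    encoded = np.asarray(encoded, dtype=np.float64)
    if encoded.ndim != 2 or encoded.shape[0] < 1:
        raise ValueError("encoded must be a nonempty 2-D matrix")
    z = float(np.mean(encoded, axis=0) @ np.ravel(weight) + float(bias))
    return float(1.0 / (1.0 + np.exp(-z)))


# ---------------------------------------------------------------------------
# The trainable model
# ---------------------------------------------------------------------------

class MSCANModel:
    """The encoder network with named parameters and a sigmoid head.

    Parameter initialization is Glorot-uniform from a seeded generator, so
    a given (config, seed) pair always yields bitwise-identical weights.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, Tensor] = {}

        def param(name: str, value: np.ndarray):
            p[name] = Tensor(value, requires_grad=True)

        for s in c.streams:
            param(f"proj{s}_W", glorot_uniform(rng, c.d_embed, c.d_model))
            param(f"proj{s}_b", np.zeros(c.d_model))
        for l in range(c.layers):
            for branch in BRANCHES[c.variant]:
                param(f"l{l}_{branch}_Wq",
                      glorot_uniform(rng, c.d_model, c.h * c.d_k))
                param(f"l{l}_{branch}_Wk",
                      glorot_uniform(rng, c.d_model, c.h * c.d_k))
                param(f"l{l}_{branch}_Wv",
                      glorot_uniform(rng, c.d_model, c.h * c.d_v))
            param(f"l{l}_Wo", glorot_uniform(rng, c.h * c.d_v, c.d_model))
            param(f"l{l}_ffn_W1", glorot_uniform(rng, c.d_model, c.d_ff))
            param(f"l{l}_ffn_b1", np.zeros(c.d_ff))
            param(f"l{l}_ffn_W2", glorot_uniform(rng, c.d_ff, c.d_model))
            param(f"l{l}_ffn_b2", np.zeros(c.d_model))
            param(f"l{l}_ln1_g", np.ones(c.d_model))
            param(f"l{l}_ln1_b", np.zeros(c.d_model))
            param(f"l{l}_ln2_g", np.ones(c.d_model))
            param(f"l{l}_ln2_b", np.zeros(c.d_model))
        param("cls_w", glorot_uniform(rng, c.d_model, 1))
        param("cls_b", np.zeros(1))
        self.params = p

    # -- bookkeeping ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.parameters())

    # -- forward -------------------------------------------------------------
    def _layer_params(self, l: int) -> dict[str, Tensor]:
        prefix = f"l{l}_"
        return {
            k[len(prefix):]: v for k, v in self.params.items()
            if k.startswith(prefix)
        }

    def encode_t(self, bundles: Sequence[np.ndarray], training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Run the encoder stack; bundles[i] is (B, m_i, d_embed) per stream.

        Only streams the variant consumes need to be present (others may
        be None).  Auxiliary streams are projected and position-encoded
        once and re-enter every layer unchanged; only the query stream is
        re-encoded across layers.
        """
        c = self.config
        if training and rng is None:
            raise ValueError("training mode requires an rng for dropout")
        streams: dict[int, Tensor] = {}
        for s in c.streams:
            x = np.asarray(bundles[s], dtype=np.float64)
            if x.ndim != 3 or x.shape[-1] != c.d_embed:
                raise ValueError(
                    f"stream {s}: expected (B, m, {c.d_embed}) array"
                )
            t = Tensor(x) @ self.params[f"proj{s}_W"] + self.params[f"proj{s}_b"]
            t = t + Tensor(positional_encoding(x.shape[1], c.d_model))
            streams[s] = dropout(t, c.dropout, rng, training)
        xq = streams[0]
        for l in range(c.layers):
            lp = self._layer_params(l)
            sub = _msca_t(xq, streams, lp, c.variant, c.h)
            xq = _layer_norm_t(xq + dropout(sub, c.dropout, rng, training),
                               lp["ln1_g"], lp["ln1_b"])
            f = _ffn_t(xq, lp["ffn_W1"], lp["ffn_b1"],
                       lp["ffn_W2"], lp["ffn_b2"])
            xq = _layer_norm_t(xq + dropout(f, c.dropout, rng, training),
                               lp["ln2_g"], lp["ln2_b"])
        return xq

    def forward(self, bundles: Sequence[np.ndarray], training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Probabilities for a batch, shape (B,)."""
        encoded = self.encode_t(bundles, training=training, rng=rng)
        pooled = encoded.mean(axis=1)                      # (B, d_model)
        logit = pooled @ self.params["cls_w"] + self.params["cls_b"]
        b = encoded.shape[0]
        return logit.reshape(b).sigmoid()

    def encode(self, bundles: Sequence[np.ndarray]) -> np.ndarray:
        """Evaluation-mode encoder output as a plain array."""
        return self.encode_t(bundles, training=False).data

    def predict_proba(self, bundles: Sequence[np.ndarray]) -> np.ndarray:
        return self.forward(bundles, training=False).data

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        meta = {"schema": 1, "seed": self.seed, "config": asdict(self.config)}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "MSCANModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = meta["config"]
            cfg["scale_order"] = tuple(cfg["scale_order"])
            model = cls(ModelConfig(**cfg), seed=meta.get("seed", 0))
            for k in model.params:
                model.params[k].data = np.asarray(data[k], dtype=np.float64)
        return model


def build_variant(variant: str, config: ModelConfig, seed: int) -> MSCANModel:
    """Initialize a model for one of the five variants."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    return MSCANModel(replace(config, variant=variant), seed=seed)


def encoder_forward(model: MSCANModel,
                    bundles: Sequence[np.ndarray]) -> np.ndarray:
    """Evaluation-mode encoder output for a batch (deterministic)."""
    return model.encode(bundles)


# ---------------------------------------------------------------------------
# Sequence-level predictor (model + embedding front-end)
# ---------------------------------------------------------------------------

class Predictor:
    """Bundles the trained network with its k-mer vocabulary and table."""

    def __init__(self, model: MSCANModel, vocab: ke.KmerVocabulary,
                 table: ke.EmbeddingTable, oov: str = "error"):
        if table.d_embed != model.config.d_embed:
            raise ValueError("embedding width does not match model d_embed")
        self.model = model
        self.vocab = vocab
        self.table = table
        self.oov = oov

    def bundles_for(self, sequences: Sequence[str]) -> list[np.ndarray | None]:
        """Embedded (B, m_s, d_embed) arrays for each consumed stream."""
        c = self.model.config
        bundles: list[np.ndarray | None] = [None, None, None]
        for s in c.streams:
            length = c.scale_order[s]
            mats = [
                ke.embed(ke.tokenize(centered_window(seq, length)),
                         self.vocab, self.table, oov=self.oov)
                for seq in sequences
            ]
            bundles[s] = np.stack(mats)
        return bundles

    def predict_proba(self, data: MethylDataset | Sequence[str]) -> np.ndarray:
        sequences = data.sequences() if isinstance(data, MethylDataset) else list(data)
        return self.model.predict_proba(self.bundles_for(sequences))

    def save(self, path) -> None:
        arrays = {f"param_{k}": t.data for k, t in self.model.params.items()}
        meta = {
            "schema": 1,
            "seed": self.model.seed,
            "config": asdict(self.model.config),
            "oov": self.oov,
            "training_meta": self.table.training_meta,
        }
        np.savez(
            path,
            __meta__=np.array(json.dumps(meta)),
            __tokens__=np.array(self.vocab.tokens()),
            __vectors__=self.table.vectors,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "Predictor":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = meta["config"]
            cfg["scale_order"] = tuple(cfg["scale_order"])
            model = MSCANModel(ModelConfig(**cfg), seed=meta.get("seed", 0))
            for k in model.params:
                model.params[k].data = np.asarray(data[f"param_{k}"],
                                                  dtype=np.float64)
            tokens = [str(t) for t in data["__tokens__"]]
            vocab = ke.KmerVocabulary({t: i for i, t in enumerate(tokens)})
            table = ke.EmbeddingTable(data["__vectors__"],
                                      training_meta=meta.get("training_meta", {}))
        return cls(model, vocab, table, oov=meta.get("oov", "error"))
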