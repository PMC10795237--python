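"""Overlapping k-mer tokenization and CBOW word-vector training.

Sequences are treated as sentences and overlapping 3-mers as words.  A
41-character window yields 39 tokens; each token maps to a learned
d-dimensional vector, so a window becomes a 39 x d matrix.

The CBOW trainer is a self-contained numpy implementation of word2vec
with negative sampling (mean-of-context variant, fixed context window,
per-sentence mini-batched updates, linear learning-rate decay).  It is
sequential and therefore bit-reproducible for a given corpus, parameter
set and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KmerVocabulary", "EmbeddingTable", "tokenize", "build_vocab",
    "train_cbow", "embed", "save_embedding", "load_embedding",
]


@dataclass(frozen=True)
class KmerVocabulary:
    """Injective token -> index map with gap-free 0-based indices."""

    kmer_to_index: dict[str, int]
    k: int = 3

    def __post_init__(self):
        indices = sorted(self.kmer_to_index.values())
        if indices != list(range(len(indices))):
            raise ValueError("vocabulary indices must be 0..V-1 without gaps")

    def __len__(self) -> int:
        return len(self.kmer_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.kmer_to_index

    def tokens(self) -> list[str]:
        """Tokens in index order."""
        inv = {i: t for t, i in self.kmer_to_index.items()}
        return [inv[i] for i in range(len(inv))]


@dataclass
class EmbeddingTable:
    """One d_embed row vector per vocabulary entry."""

    vectors: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a V x d matrix")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding table contains non-finite entries")

    @property
    def d_embed(self) -> int:
        return self.vectors.shape[1]


def tokenize(sequence: str, k: int = 3) -> list[str]:
    """Slide a window of size ``k`` with stride 1; order preserved."""
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k={k}"
        )
    return [sequence[i:i + k] for i in range(len(sequence) - k + 1)]


def build_vocab(corpus: Iterable[Sequence[str]], k: int = 3) -> KmerVocabulary:
    """Vocabulary of exactly the distinct tokens present, lexicographic order."""
    tokens: set[str] = set()
    n_sentences = 0
    for sentence in corpus:
        n_sentences += 1
        tokens.update(sentence)
    if n_sentences == 0 or not tokens:
        raise ValueError("corpus is empty")
    return KmerVocabulary({t: i for i, t in enumerate(sorted(tokens))}, k=k)


def _context_matrix(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Padded context-index matrix and mask for a sentence of length n."""
    offsets = np.concatenate([np.arange(-window, 0), np.arange(1, window + 1)])
    positions = np.arange(n)[:, None] + offsets[None, :]
    mask = (positions >= 0) & (positions < n)
    return np.clip(positions, 0, n - 1), mask


def train_cbow(corpus: Sequence[Sequence[str]], d_embed: int = 100,
               window: int = 5, epochs: int = 50, seed: int = 0,
               negative: int = 5, learning_rate: float = 0.025,
               min_count: int = 1) -> tuple[KmerVocabulary, EmbeddingTable]:
    """Train CBOW embeddings with negative sampling on a token corpus.

    Returns the vocabulary (tokens kept when their corpus count reaches
    ``min_count``) and the input-embedding table, one row per token.
    Deterministic for fixed inputs and seed.
    """
    if d_embed <= 0:
        raise ValueError(f"d_embed must be positive, got {d_embed}")
    corpus = [list(s) for s in corpus]
    if not corpus:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    for sentence in corpus:
        for t in sentence:
            counts[t] = counts.get(t, 0) + 1
    kept = sorted(t for t, c in counts.items() if c >= min_count)
    if not kept:
        raise ValueError("no token reaches min_count")
    vocab = KmerVocabulary({t: i for i, t in enumerate(kept)})
    V = len(vocab)
    index = vocab.kmer_to_index
    sentences = [
        np.array([index[t] for t in s if t in index], dtype=np.int64)
        for s in corpus
    ]
    sentences = [s for s in sentences if len(s) >= 2]

    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-0.5 / d_embed, 0.5 / d_embed, size=(V, d_embed))
    w_out = np.zeros((V, d_embed))

    # unigram^0.75 noise distribution for negative sampling
    freq = np.array([counts[t] for t in kept], dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())

    for epoch in range(epochs):
        lr = max(learning_rate * (1.0 - epoch / epochs), 1e-4)
        for sent in sentences:
            n = len(sent)
            ctx_pos, mask = _context_matrix(n, window)
            ctx = sent[ctx_pos]                              # (n, 2w)
            counts_per = mask.sum(axis=1)                    # (n,)
            h = (w_in[ctx] * mask[..., None]).sum(axis=1) / counts_per[:, None]

            negs = np.searchsorted(noise_cdf, rng.random((n, negative)))
            targets = np.concatenate([sent[:, None], negs], axis=1)  # (n, 1+neg)
            outs = w_out[targets]                            # (n, 1+neg, d)
            scores = np.einsum("nd,nkd->nk", h, outs)
            sig = 1.0 / (1.0 + np.exp(-scores))
            labels = np.zeros_like(sig)
            labels[:, 0] = 1.0
            g = (labels - sig) * lr                          # (n, 1+neg)

            grad_h = np.einsum("nk,nkd->nd", g, outs)
            grad_out = (g[..., None] * h[:, None, :]).reshape(-1, d_embed)
            # scatter-add via one-hot matmul: much faster than np.add.at
            # for the small closed vocabularies seen here
            flat_t = targets.ravel()
            onehot_t = flat_t[:, None] == np.arange(V)[None, :]
            w_out += onehot_t.T.astype(np.float64) @ grad_out
            per_ctx = ((grad_h / counts_per[:, None])[:, None, :]
                       * mask[..., None]).reshape(-1, d_embed)
            flat_c = ctx.ravel()
            onehot_c = flat_c[:, None] == np.arange(V)[None, :]
            w_in += onehot_c.T.astype(np.float64) @ per_ctx

    meta = {
        "model": "CBOW", "window": window, "epochs": epochs, "seed": seed,
        "negative": negative, "learning_rate": learning_rate,
        "min_count": min_count, "d_embed": d_embed,
    }
    return vocab, EmbeddingTable(w_in, training_meta=meta)


def embed(tokens: Sequence[str], vocab: KmerVocabulary, table: EmbeddingTable,
          oov: str = "error") -> np.ndarray:
    """Stack the table rows for ``tokens`` into a len(tokens) x d matrix.

    ``oov`` is ``"error"`` (default) or ``"zero"`` (map unknown tokens to
    the zero vector).
    """
    if len(table.vectors) != len(vocab):
        raise ValueError("embedding table and vocabulary sizes differ")
    rows = np.empty((len(tokens), table.d_embed))
    for i, t in enumerate(tokens):
        idx = vocab.kmer_to_index.get(t)
        if idx is None:
            if oov == "zero":
                rows[i] = 0.0
                continue
            raise KeyError(f"token {t!r} not in vocabulary")
        rows[i] = table.vectors[idx]
    return rows


def save_embedding(vocab: KmerVocabulary, table: EmbeddingTable, prefix) -> None:
    """Plain-text word2vec format plus a JSON metadata sidecar."""
    prefix = Path(prefix)
    tokens = vocab.tokens()
    with open(prefix.with_suffix(".w2v"), "w") as fh:
        fh.write(f"{len(tokens)} {table.d_embed}\n")
        for t, row in zip(tokens, table.vectors):
            fh.write(t + " " + " ".join(repr(float(x)) for x in row) + "\n")
    with open(prefix.with_suffix(".meta.json"), "w") as fh:
        json.dump(table.training_meta, fh, indent=2)


def load_embedding(prefix) -> tuple[KmerVocabulary, EmbeddingTable]:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".w2v")) as fh:
        header = fh.readline().split()
        v, d = int(header[0]), int(header[1])
        tokens, vectors = [], np.empty((v, d))
        for i in range(v):
            parts = fh.readline().split()
            tokens.append(parts[0])
            vectors[i] = [float(x) for x in parts[1:]]
    meta_path = prefix.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    vocab = KmerVocabulary({t: i for i, t in enumerate(tokens)})
    return vocab, EmbeddingTable(vectors, training_meta=meta)
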