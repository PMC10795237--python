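"""Optimization loop and exhaustive grid search.

Defaults follow the tuned values: 100 epochs, learning rate 5e-4,
mini-batches of 10, dropout 0.2, Adam.  The loss is binary cross-entropy
on the sigmoid output.  All shuffling and dropout randomness derives from
the run seed, so a run is bit-reproducible on one device.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .kmer_embedding import tokenize, train_cbow
from .multiscale_encoder import ModelConfig, MSCANModel, Predictor
from .nn import Adam, Tensor
from .sequence_io import MethylDataset, kfold_split

__all__ = ["TrainConfig", "TrainHistory", "train", "fit_pipeline", "grid_search"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 5e-4
    batch_size: int = 10
    dropout: float = 0.2
    seed: int = 0
    optimizer: str = "adam"
    pos_weight: float | None = None

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """Per-epoch mean training loss, plus optional validation AUPRC."""

    losses: list[float] = field(default_factory=list)
    val_auprc: list[float] = field(default_factory=list)


def _bce(probs: Tensor, labels: np.ndarray,
         pos_weight: float | None) -> Tensor:
    eps = 1e-12
    y = labels.astype(np.float64)
    pos_term = (probs + eps).log() * Tensor(y)
    neg_term = (1.0 - probs + eps).log() * Tensor(1.0 - y)
    if pos_weight is not None:
        pos_term = pos_term * pos_weight
    return -(pos_term + neg_term).mean()


def train(predictor: Predictor, dataset: MethylDataset,
          config: TrainConfig,
          val_dataset: MethylDataset | None = None
          ) -> tuple[Predictor, TrainHistory]:
    """Fit the predictor's network on ``dataset`` in place.

    The embedding front-end is frozen; only network parameters move.
    Batches are reshuffled every epoch from the run seed; the last
    partial batch is kept.
    """
    labels = dataset.labels()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if labels.min() == labels.max():
        raise ValueError("training requires both labels present")
    model = predictor.model
    model.config = replace(model.config, dropout=config.dropout)

    bundles = predictor.bundles_for(dataset.sequences())
    n = len(dataset)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [
                b[idx] if b is not None else None for b in bundles
            ]
            probs = model.forward(batch, training=True, rng=rng)
            loss = _bce(probs, labels[idx], config.pos_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data) * len(idx))
        history.losses.append(sum(epoch_losses) / n)
        if val_dataset is not None:
            scores = predictor.predict_proba(val_dataset)
            history.val_auprc.append(
                evaluation.auprc(val_dataset.labels(), scores)
            )
    return predictor, history


def fit_pipeline(train_dataset: MethylDataset, model_config: ModelConfig,
                 train_config: TrainConfig,
                 embed_params: Mapping | None = None,
                 val_dataset: MethylDataset | None = None
                 ) -> tuple[Predictor, TrainHistory]:
    """End-to-end fit: CBOW on the training sequences, then the network.

    The embedding corpus is the training split only, never validation or
    test sequences.
    """
    ep = {"d_embed": model_config.d_embed, "seed": train_config.seed,
          **(embed_params or {})}
    corpus = [tokenize(seq) for seq in train_dataset.sequences()]
    vocab, table = train_cbow(corpus, **ep)
    model = MSCANModel(model_config, seed=train_config.seed)
    predictor = Predictor(model, vocab, table, oov="zero")
    return train(predictor, train_dataset, train_config,
                 val_dataset=val_dataset)


def grid_search(space: Mapping[str, Sequence], dataset: MethylDataset, k: int,
                seed: int, model_config: ModelConfig | None = None,
                base_config: TrainConfig | None = None,
                embed_params: Mapping | None = None
                ) -> tuple[TrainConfig, pd.DataFrame]:
    """Exhaustive Cartesian-product search scored by k-fold mean AUPRC.

    Ties break by higher mean AUROC, then by enumeration order (the
    product of candidate lists in the order given).  Returns the winning
    config and the full score table.
    """
    if not space:
        raise ValueError("search space is empty")
    for key, candidates in space.items():
        if not candidates:
            raise ValueError(f"empty candidate list for {key!r}")
    model_config = model_config or ModelConfig()
    base = base_config or TrainConfig()
    folds = kfold_split(dataset, k, seed)
    rows = []
    best = None
    for order, values in enumerate(itertools.product(*space.values())):
        overrides = dict(zip(space.keys(), values))
        candidate = replace(base, seed=seed, **overrides)
        auprcs, aurocs = [], []
        for train_ds, val_ds in folds:
            predictor, _ = fit_pipeline(train_ds, model_config, candidate,
                                        embed_params=embed_params)
            scores = predictor.predict_proba(val_ds)
            auprcs.append(evaluation.auprc(val_ds.labels(), scores))
            aurocs.append(evaluation.auroc(val_ds.labels(), scores))
        row = {**overrides,
               "mean_auprc": float(np.mean(auprcs)),
               "mean_auroc": float(np.mean(aurocs))}
        rows.append(row)
        key = (row["mean_auprc"], row["mean_auroc"], -order)
        if best is None or key > best[0]:
            best = (key, candidate)
    return best[1], pd.DataFrame(rows)
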