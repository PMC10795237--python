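"""Synthetic labeled 41-nt window datasets with a planted center motif.

Positives carry a position-weight-matrix motif near the center with a
configurable per-sample probability (``signal_strength``); negatives are
pure background.  The center base is forced in every sample, so at
``signal_strength == 0`` positives and negatives are exactly
exchangeable.  Generation is fully determined by the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .sequence_io import PAD, WINDOW_LENGTH, MethylDataset, RnaSample

__all__ = ["SyntheticSpec", "random_motif", "generate", "generate_pair", "holdout_spec"]

BASES = ("A", "C", "G", "U")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def random_motif(width: int, rng: np.random.Generator,
                 dominance: float = 0.9) -> np.ndarray:
    """A degenerate PWM: per column one dominant base with prob ``dominance``."""
    if not (0.25 <= dominance <= 1.0):
        raise ValueError("dominance must be in [0.25, 1]")
    motif = np.full((width, 4), (1.0 - dominance) / 3.0)
    for j, b in enumerate(rng.integers(0, 4, size=width)):
        motif[j, b] = dominance
    return motif


@dataclass
class SyntheticSpec:
    """Everything needed to draw one dataset deterministically."""

    n_pos: int
    n_neg: int
    window: int = WINDOW_LENGTH
    center_base: str = "A"
    motif: np.ndarray | None = None
    motif_width: int = 8
    motif_offset: int = -4
    motif_dominance: float = 0.9
    signal_strength: float = 1.0
    background: np.ndarray | None = None
    pad_fraction: float = 0.0
    max_pad: int = 10
    seed: int = 0
    name: str = "synthetic"
    modification: str = "unknown"

    def __post_init__(self):
        if self.center_base not in BASES:
            raise ValueError(f"center_base must be one of {BASES}")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must be in [0, 1]")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.motif is not None:
            self.motif = np.asarray(self.motif, dtype=np.float64)
            if self.motif.ndim != 2 or self.motif.shape[1] != 4:
                raise ValueError("motif must be a w x 4 matrix")
            if not np.allclose(self.motif.sum(axis=1), 1.0):
                raise ValueError("motif columns must each sum to 1")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=np.float64)
            if self.background.shape != (self.window, 4):
                raise ValueError("background must be window x 4")
            if not np.allclose(self.background.sum(axis=1), 1.0):
                raise ValueError("background rows must each sum to 1")
        if not (0.0 <= self.pad_fraction < 1.0):
            raise ValueError("pad_fraction must be in [0, 1)")
        if not (0 <= self.max_pad < self.window // 2):
            raise ValueError("max_pad must leave the center base intact")

    @property
    def center(self) -> int:
        return self.window // 2

    def resolved_motif(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """The spec's motif, drawing a seeded random one when unset."""
        if self.motif is not None:
            return self.motif
        rng = rng or np.random.default_rng(self.seed + 7919)
        motif = random_motif(self.motif_width, rng, self.motif_dominance)
        start = self.center + self.motif_offset
        if start < 0 or start + len(motif) > self.window:
            raise ValueError("motif does not fit inside the window")
        return motif


def _draw_window(rng: np.random.Generator, background: np.ndarray) -> np.ndarray:
    """Per-position categorical draw; returns base indices."""
    u = rng.random(len(background))
    cdf = np.cumsum(background, axis=1)
    return (u[:, None] > cdf).sum(axis=1)


def generate(spec: SyntheticSpec) -> MethylDataset:
    """Draw the dataset described by ``spec`` (deterministic given seed)."""
    rng = np.random.default_rng(spec.seed)
    motif = spec.resolved_motif()
    start = spec.center + spec.motif_offset
    if start < 0 or start + len(motif) > spec.window:
        raise ValueError("motif does not fit inside the window")
    background = spec.background
    if background is None:
        background = np.full((spec.window, 4), 0.25)
    samples: list[RnaSample] = []
    motif_cdf = np.cumsum(motif, axis=1)
    for i in range(spec.n_pos + spec.n_neg):
        label = 1 if i < spec.n_pos else 0
        idx = _draw_window(rng, background)
        if label == 1 and rng.random() < spec.signal_strength:
            u = rng.random(len(motif))
            idx[start:start + len(motif)] = (u[:, None] > motif_cdf).sum(axis=1)
        idx[spec.center] = _BASE_INDEX[spec.center_base]
        seq = "".join(BASES[j] for j in idx)
        if spec.pad_fraction > 0 and rng.random() < spec.pad_fraction:
            run = int(rng.integers(1, spec.max_pad + 1))
            if rng.random() < 0.5:
                seq = PAD * run + seq[run:]
            else:
                seq = seq[:len(seq) - run] + PAD * run
        samples.append(RnaSample(
            id=f"{spec.name}_{'pos' if label else 'neg'}_{i}",
            sequence=seq, label=label, modification=spec.modification,
        ))
    return MethylDataset(samples, name=spec.name)


def holdout_spec(spec: SyntheticSpec, n_pos: int, n_neg: int,
                 seed: int) -> SyntheticSpec:
    """A spec for fresh samples from the SAME motif as ``spec``.

    Pins the resolved motif explicitly so the new seed redraws only the
    sequences, not the planted signal.
    """
    return replace(spec, motif=spec.resolved_motif(), n_pos=n_pos,
                   n_neg=n_neg, seed=seed, name=f"{spec.name}-holdout")


def generate_pair(spec_a: SyntheticSpec, spec_b: SyntheticSpec,
                  shared_motif: bool) -> tuple[MethylDataset, MethylDataset]:
    """Two datasets whose positives embed the same or independent motifs.

    With ``shared_motif`` both datasets plant spec_a's (resolved) motif;
    otherwise each spec resolves its own, and specs without explicit
    motifs get independent seeded draws.
    """
    motif_a = spec_a.resolved_motif()
    if shared_motif:
        spec_b = replace(spec_b, motif=motif_a,
                         motif_offset=spec_a.motif_offset)
        spec_a = replace(spec_a, motif=motif_a)
    else:
        spec_a = replace(spec_a, motif=motif_a)
        if spec_b.motif is None:
            rng_b = np.random.default_rng(spec_b.seed + 104729)
            spec_b = replace(spec_b, motif=random_motif(
                spec_b.motif_width, rng_b, spec_b.motif_dominance))
    return generate(spec_a), generate(spec_b)
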