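"""Reading, validation, padding and splitting of labeled RNA windows.

A sample is a fixed-length 41-character window over {A, C, G, U} with the
candidate site at the center (0-based index 20).  Windows shorter than 41
characters are padded with a contiguous run of ``-`` at the head or the
tail.  Two on-disk dialects are supported:

* FASTA with self-describing headers ``>id|label={0,1}|mod={tag}``
* two-column TSV ``sequence<TAB>label`` (no header row)

``T`` is normalized to ``U`` and lowercase is uppercased on ingestion; the
typographic minus sign is normalized to the ASCII hyphen pad character.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 41
PAD = "-"
ALPHABET = frozenset("ACGU")
FULL_ALPHABET = frozenset("ACGU" + PAD)

MODIFICATION_TAGS = (
    "m6A", "m1A", "m5C", "m5U", "m6Am", "m7G", "Psi", "I", "Am", "Cm", "Gm", "Um",
)

#: expected center base per modification type (site chemistry)
MODIFICATION_BASE = {
    "m6A": "A", "m1A": "A", "m6Am": "A", "Am": "A", "I": "A",
    "m5C": "C", "Cm": "C",
    "m7G": "G", "Gm": "G",
    "m5U": "U", "Um": "U", "Psi": "U",
}


class SequenceFormatError(ValueError):
    """Raised when an input record violates the window contract."""


def normalize_sequence(raw: str) -> str:
    """Uppercase, map T->U and the unicode minus to the ASCII pad char."""
    return raw.strip().upper().replace("T", "U").replace("−", PAD)


def _check_pad_run(sequence: str) -> None:
    """Pads must form one contiguous run at the head or at the tail."""
    if PAD not in sequence:
        return
    core = sequence.strip(PAD)
    if PAD in core:
        raise SequenceFormatError(
            f"interior pad character in {sequence!r}: pads must be a single "
            "contiguous head or tail run"
        )
    head = sequence.startswith(PAD)
    tail = sequence.endswith(PAD)
    if head and tail:
        raise SequenceFormatError(
            f"pads on both ends of {sequence!r}: only one side may be padded"
        )
    if not core:
        raise SequenceFormatError("window consists only of pad characters")


@dataclass(frozen=True)
class RnaSample:
    """One 41-nt labeled window; the atomic classification unit."""

    id: str
    sequence: str
    label: int
    modification: str = "unknown"

    def __post_init__(self):
        if len(self.sequence) != WINDOW_LENGTH:
            raise SequenceFormatError(
                f"sample {self.id!r}: sequence length {len(self.sequence)} != "
                f"{WINDOW_LENGTH}"
            )
        bad = set(self.sequence) - FULL_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"sample {self.id!r}: illegal character(s) {sorted(bad)!r}"
            )
        _check_pad_run(self.sequence)
        if self.label not in (0, 1):
            raise SequenceFormatError(
                f"sample {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )
        expected = MODIFICATION_BASE.get(self.modification)
        if expected is not None and self.center_base != expected:
            warnings.warn(
                f"sample {self.id!r}: center base {self.center_base!r} does not "
                f"match modification {self.modification} (expected {expected!r})",
                stacklevel=2,
            )

    @property
    def center_base(self) -> str:
        return self.sequence[WINDOW_LENGTH // 2]


@dataclass
class MethylDataset:
    """An ordered collection of samples for one modification task."""

    samples: list[RnaSample]
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[RnaSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> RnaSample:
        return self.samples[i]

    @property
    def ratio(self) -> tuple[int, int]:
        """(positive count, negative count)."""
        pos = sum(s.label for s in self.samples)
        return pos, len(self.samples) - pos

    def sequences(self) -> list[str]:
        return [s.sequence for s in self.samples]

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "MethylDataset":
        return MethylDataset(
            [self.samples[int(i)] for i in indices], name=name or self.name
        )


def pad_to_length(sequence: str, target: int = WINDOW_LENGTH,
                  side: str = "tail") -> str:
    """Pad ``sequence`` with a contiguous ``-`` run on one side to ``target``."""
    if side not in ("head", "tail"):
        raise ValueError(f"side must be 'head' or 'tail', got {side!r}")
    if len(sequence) > target:
        raise SequenceFormatError(
            f"sequence length {len(sequence)} exceeds target {target}; "
            "use center_crop for long sequences"
        )
    run = PAD * (target - len(sequence))
    return run + sequence if side == "head" else sequence + run


def center_crop(sequence: str, target: int = WINDOW_LENGTH) -> str:
    """Crop a long sequence to ``target`` keeping the middle character.

    Explicit opt-in for over-length input; both input and output lengths
    must be odd so the candidate site stays centered.
    """
    if len(sequence) < target:
        raise SequenceFormatError(
            f"sequence length {len(sequence)} shorter than target {target}"
        )
    if len(sequence) % 2 == 0 or target % 2 == 0:
        raise SequenceFormatError("center_crop requires odd lengths")
    start = (len(sequence) - target) // 2
    return sequence[start:start + target]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def _parse_fasta_header(header: str) -> tuple[str, int, str]:
    fields = header.split("|")
    sample_id = fields[0]
    label: int | None = None
    mod = "unknown"
    for f in fields[1:]:
        if f.startswith("label="):
            try:
                label = int(f[len("label="):])
            except ValueError as exc:
                raise SequenceFormatError(
                    f"record {sample_id!r}: malformed label field {f!r}"
                ) from exc
        elif f.startswith("mod="):
            mod = f[len("mod="):]
    if label is None:
        raise SequenceFormatError(
            f"record {sample_id!r}: FASTA header lacks a label= field"
        )
    return sample_id, label, mod


def read_samples(path, format: str | None = None, *,
                 pad_side: str = "tail", allow_crop: bool = False,
                 name: str | None = None) -> MethylDataset:
    """Read and validate a labeled window file (FASTA or TSV).

    Under-length sequences are padded on ``pad_side``; over-length
    sequences are center-cropped only when ``allow_crop`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    samples: list[RnaSample] = []
    normalized_t = 0
    if fmt == "fasta":
        for record in SeqIO.parse(str(path), "fasta"):
            sample_id, label, mod = _parse_fasta_header(record.description)
            raw = str(record.seq)
            normalized_t += raw.upper().count("T")
            samples.append(_build_sample(sample_id, raw, label, mod,
                                         pad_side, allow_crop))
    elif fmt == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise SequenceFormatError(
                        f"{path}:{lineno}: expected sequence<TAB>label"
                    )
                raw, label_text = parts[0], parts[1]
                try:
                    label = int(label_text)
                except ValueError as exc:
                    raise SequenceFormatError(
                        f"{path}:{lineno}: malformed label {label_text!r}"
                    ) from exc
                normalized_t += raw.upper().count("T")
                samples.append(_build_sample(f"row{lineno}", raw, label,
                                             "unknown", pad_side, allow_crop))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if normalized_t:
        logger.info("normalized %d T characters to U in %s", normalized_t, path)
    return MethylDataset(samples, name=name or path.stem)


def _build_sample(sample_id: str, raw: str, label: int, mod: str,
                  pad_side: str, allow_crop: bool) -> RnaSample:
    seq = normalize_sequence(raw)
    if len(seq) > WINDOW_LENGTH:
        if not allow_crop:
            raise SequenceFormatError(
                f"sample {sample_id!r}: length {len(seq)} > {WINDOW_LENGTH} "
                "(pass allow_crop=True to center-crop)"
            )
        seq = center_crop(seq)
    elif len(seq) < WINDOW_LENGTH:
        seq = pad_to_length(seq, side=pad_side)
    return RnaSample(id=sample_id, sequence=seq, label=label, modification=mod)


def write_samples(dataset: MethylDataset, path, format: str | None = None) -> None:
    """Write a dataset in a dialect ``read_samples`` round-trips exactly."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(s.sequence),
                      id=f"{s.id}|label={s.label}|mod={s.modification}",
                      description="")
            for s in dataset
        ]
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            for s in dataset:
                fh.write(f"{s.sequence}\t{s.label}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def kfold_split(dataset: MethylDataset, k: int,
                seed: int) -> list[tuple[MethylDataset, MethylDataset]]:
    """Deterministic label-stratified k-fold partitions.

    Returns ``k`` (train, validation) pairs; every sample appears in
    exactly one validation fold.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    labels = dataset.labels()
    minority = min(int((labels == 0).sum()), int((labels == 1).sum()))
    if minority < k:
        raise ValueError(
            f"k={k} exceeds the minority-class count {minority}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (train_idx, val_idx) in enumerate(skf.split(labels, labels)):
        folds.append((
            dataset.subset(train_idx, name=f"{dataset.name}-fold{i}-train"),
            dataset.subset(val_idx, name=f"{dataset.name}-fold{i}-val"),
        ))
    return folds
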