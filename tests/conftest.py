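import numpy as np
import pytest

from mscan.sequence_io import MethylDataset, RnaSample
from mscan.synthetic_data import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_sample(sequence: str, label: int, sid: str = "s",
                mod: str = "unknown") -> RnaSample:
    return RnaSample(id=sid, sequence=sequence, label=label, modification=mod)


@pytest.fixture
def tiny_dataset() -> MethylDataset:
    """Four hand-built windows, two per label."""
    seqs = [
        ("A" * 41, 1),
        ("ACGU" * 10 + "A", 1),
        ("U" * 20 + "A" + "U" * 20, 0),
        ("GC" * 10 + "A" + "CG" * 10, 0),
    ]
    return MethylDataset(
        [make_sample(s, y, sid=f"t{i}") for i, (s, y) in enumerate(seqs)],
        name="tiny",
    )


@pytest.fixture(scope="session")
def small_signal_dataset() -> MethylDataset:
    """A modest strong-signal dataset shared by slower tests."""
    spec = SyntheticSpec(n_pos=100, n_neg=100, motif_width=6,
                         motif_dominance=0.97, signal_strength=1.0, seed=42,
                         name="signal")
    return generate(spec)


@pytest.fixture(scope="session")
def small_signal_spec() -> SyntheticSpec:
    return SyntheticSpec(n_pos=100, n_neg=100, motif_width=6,
                         motif_dominance=0.97, signal_strength=1.0, seed=42,
                         name="signal")
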