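import numpy as np
import pytest

from plantrbp.seqio import AMINO_ACIDS, LabeledSequence
from plantrbp.simulate import SyntheticSpec, generate
from plantrbp.textcnn import TextCNNConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sequences():
    return [
        LabeledSequence("a", "ACDEFG", 1),
        LabeledSequence("b", "MKVLAWCY", 1),
        LabeledSequence("c", "PPPQRSTVWY", 0),
        LabeledSequence("d", "GGHIKLMNAC", 0),
    ]


def random_sequences(rng, n, length_range=(10, 60), labels=True):
    seqs = []
    for i in range(n):
        L = int(rng.integers(*length_range))
        residues = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        seqs.append(LabeledSequence(f"s{i:04d}", residues,
                                    int(i % 2) if labels else None))
    return seqs


@pytest.fixture
def small_benchmark():
    """A small but learnable synthetic dataset (strong composition signal)."""
    spec = SyntheticSpec(n_pos=80, n_neg=80, length_mean=120, length_sd=30,
                         length_range=(50, 300), effect_size=5.0, seed=7)
    return generate(spec)


@pytest.fixture
def fast_cnn_config():
    """A scaled-down classifier configuration for quick pipeline tests."""
    return TextCNNConfig(filters_per_kernel=8, dense_units=16, max_epochs=20,
                         patience=5, learning_rate=3e-3, seed=0)
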