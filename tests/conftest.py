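import numpy as np
import pytest

from nucperiod import NucLibrary

BASES = "ACGT"


def random_library(n, rng, length=147, alphabet="ACGT", max_weight=5, label="rand"):
    """Small random library with random integer weights."""
    probs = None
    chars = np.array(list(alphabet))
    seqs = [
        "".join(rng.choice(chars, size=length, p=probs)) for _ in range(n)
    ]
    weights = rng.integers(1, max_weight + 1, size=n)
    return NucLibrary.from_sequences(seqs, weights, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_library(rng):
    return random_library(30, rng)


@pytest.fixture
def tiny_genome(tmp_path):
    """Two-chromosome FASTA with a reproducible random sequence."""
    g = np.random.default_rng(7)
    chrom1 = "".join(g.choice(list(BASES), size=400))
    chrom2 = "".join(g.choice(list(BASES), size=300))
    path = tmp_path / "genome.fa"
    path.write_text(f">chrI\n{chrom1}\n>chrII\n{chrom2}\n")
    return path, {"chrI": chrom1, "chrII": chrom2}
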