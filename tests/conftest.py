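import numpy as np
import pytest

from cannaseq.seqcore import NucSequence
from cannaseq.simulate import GenomeSpec, generate_genome

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


MUT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def diverged_copy(src: str, n_mismatch: int, pad: int = 8) -> str:
    """Copy of ``src`` with exactly ``n_mismatch`` isolated substitutions,
    each chosen to differ from both neighbours (so the optimal alignment is
    the ungapped full-span one and its identity is exact), none within
    ``pad`` of either end."""
    L = len(src)
    out = list(src)
    if n_mismatch == 0:
        return src
    lo, hi = pad, L - pad - 1
    positions = np.round(np.linspace(lo, hi, n_mismatch)).astype(int)
    for i in range(1, len(positions)):
        if positions[i] <= positions[i - 1] + 1:
            positions[i] = positions[i - 1] + 2
    assert positions[-1] <= hi
    for p in positions:
        forbidden = {src[p], src[p - 1], src[p + 1]}
        out[p] = next(b for b in "ACGT" if b not in forbidden)
    return "".join(out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_genome():
    """A 2-scaffold, 8-gene genome shared across tests."""
    return generate_genome(
        GenomeSpec(n_scaffolds=2, scaffold_length=30_000, n_genes=8), seed=3
    )


@pytest.fixture(scope="session")
def medium_genome():
    """A 4-scaffold, 30-gene genome for orientation/merging tests."""
    return generate_genome(GenomeSpec(), seed=7)
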