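import numpy as np
import pytest

from seqtf import DNA_ALPHABET, identity_similarity
from seqtf.similarity import Alphabet, SimilarityMatrix


@pytest.fixture
def dna_identity():
    return identity_similarity(DNA_ALPHABET)


@pytest.fixture
def random_similarity():
    """Factory for random DNA similarity matrices (negative entries allowed)."""

    def make(seed: int, symmetric: bool = True, nonneg: bool = False) -> SimilarityMatrix:
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-2.0, 2.0, size=(4, 4))
        if nonneg:
            vals = np.abs(vals)
            vals += np.diag(vals.max(axis=None) + rng.uniform(0.5, 1.0, size=4))
        if symmetric:
            vals = (vals + vals.T) / 2.0
        return SimilarityMatrix(DNA_ALPHABET, vals, name=f"random{seed}")

    return make


@pytest.fixture
def random_dna():
    def make(n: int, seed: int) -> str:
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=n))

    return make
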