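"""Indicator-sequence DNA spectrum (the classical comparison method).

A DNA sequence maps to four binary tracks u_A, u_C, u_G, u_T marking the
positions of each nucleotide.  The DNA spectrum is the summed DFT power

    S[k] = |U_A[k]|^2 + |U_C[k]|^2 + |U_G[k]|^2 + |U_T[k]|^2

with an unnormalized length-N forward transform.  For protein-coding DNA
this spectrum shows the well-known peak at k = N/3 (period 3 nt).

Because sum_i u_i[n] u_i[(n+t) mod N] is exactly the identity-similarity
circular autocorrelation of the sequence, the DNA spectrum coincides
bin-by-bin (Wiener-Khinchin) with the similarity-based spectrum computed
in circular mode with the identity matrix; ``interpretive_dna_spectrum``
exposes that route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import DNA_ALPHABET, SimilarityMatrix, identity_similarity
from .sequence_io import GenomicSequence, encode_sequence
from .core import Spectrum1D, instantaneous_correlation, correlation_function, spectrum

__all__ = ["IndicatorSet", "indicator_sequences", "dna_spectrum", "interpretive_dna_spectrum"]


@dataclass
class IndicatorSet:
    """Four binary indicator tracks of common length N.

    ``tracks[i, n] = 1`` iff symbol i (alphabet order A, C, G, T) occurs
    at position n.  Columns of out-of-alphabet positions are all zero, so
    column sums are 1 for in-alphabet positions and 0 otherwise.
    """

    tracks: np.ndarray          # (4, N) of 0/1
    metadata: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return self.tracks.shape[1]

    def track(self, symbol: str) -> np.ndarray:
        return self.tracks[DNA_ALPHABET.index(symbol)]


def indicator_sequences(x) -> IndicatorSet:
    """Binary presence tracks for A, C, G, T (lenient: ambiguity codes
    yield all-zero columns)."""
    codes = encode_sequence(x, DNA_ALPHABET, mode="lenient")
    n = len(codes)
    tracks = np.zeros((4, n))
    for i in range(4):
        tracks[i] = codes == i
    ident = x.identifier if isinstance(x, GenomicSequence) else ""
    return IndicatorSet(tracks, metadata={"sequence": ident})


def dna_spectrum(ind: IndicatorSet) -> Spectrum1D:
    """Summed indicator DFT power S[k] on k = 0..N//2 (frequency k/N)."""
    n = ind.n_positions
    U = np.fft.fft(ind.tracks, axis=1)
    S = np.sum(np.abs(U) ** 2, axis=0)
    half = n // 2 + 1
    freqs = np.arange(half) / n
    meta = dict(ind.metadata)
    meta.update({"transform": "indicator-dna-spectrum", "fft_length": n,
                 "dft_normalization": "unnormalized-forward"})
    return Spectrum1D(freqs, S[:half], n, complex_values=S.astype(complex), metadata=meta)


def interpretive_dna_spectrum(x, sim: SimilarityMatrix | None = None) -> Spectrum1D:
    """Spectrum of the circular similarity autocorrelation (one full lag
    period, length-N DFT).

    With the identity similarity this equals ``dna_spectrum`` exactly.
    """
    if sim is None:
        sim = identity_similarity(x.alphabet if isinstance(x, GenomicSequence) else DNA_ALPHABET)
    rc = instantaneous_correlation(x, sim=sim, max_lag=1)
    R = correlation_function(rc, mode="circular", normalization="sum")
    return spectrum(R)
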