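"""Synthetic sequence generators.

Three kinds of test material, all pure functions of their parameters
including the seed (NumPy PCG64 generator, so seeds are portable):

* noisy tandem repeats -- a motif repeated to a target length with
  independent per-site substitutions (replacement uniform over the other
  three nucleotides), the standard model of a decaying microsatellite;
* i.i.d. random sequences -- the stationary, structureless null;
* codon-position-biased sequences -- a protein-coding surrogate in which
  each codon position draws from its own nucleotide distribution, which
  produces the period-3 spectral peak at DFT index N/3.
"""

from __future__ import annotations

import numpy as np

from .similarity import DNA_ALPHABET, Alphabet
from .sequence_io import GenomicSequence

__all__ = ["synth_periodic", "synth_random", "synth_coding"]

_UNIFORM = (0.25, 0.25, 0.25, 0.25)


def _check_probs(p, k: int, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (k,):
        raise ValueError(f"{what} must have {k} entries, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError(f"{what} contains negative probabilities")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1 (got {p.sum()!r})")
    return p


def synth_periodic(
    motif: str,
    length: int,
    substitution_rate: float = 0.1,
    seed: int = 0,
    alphabet: Alphabet = DNA_ALPHABET,
) -> GenomicSequence:
    """Motif repeated to ``length`` with random substitutions.

    Each site is independently replaced with probability
    ``substitution_rate``; the replacement is drawn uniformly from the
    other ``|alphabet| - 1`` symbols, so a substituted site never keeps its
    original symbol.
    """
    motif = str(motif).upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must be in [0, 1]")
    for s in motif:
        if s not in alphabet:
            raise ValueError(f"motif symbol {s!r} not in alphabet")
    syms = np.array(list(alphabet.symbols))
    k = len(syms)
    base = np.array([alphabet.index(s) for s in motif], dtype=np.int64)
    codes = np.tile(base, length // len(motif) + 1)[:length].copy()
    rng = np.random.default_rng(seed)
    hit = rng.random(length) < substitution_rate
    # offset in 1..k-1 from the original symbol => never a silent substitution
    offsets = rng.integers(1, k, size=length)
    codes[hit] = (codes[hit] + offsets[hit]) % k
    ident = f"periodic_{motif}_L{length}_r{substitution_rate}_s{seed}"
    desc = f"kind=periodic motif={motif} length={length} substitution_rate={substitution_rate} seed={seed}"
    return GenomicSequence(ident, "".join(syms[codes]), alphabet, description=desc)


def synth_random(
    length: int,
    symbol_probabilities=None,
    seed: int = 0,
    alphabet: Alphabet = DNA_ALPHABET,
) -> GenomicSequence:
    """I.i.d. draws from a per-symbol distribution (default uniform)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    k = len(alphabet)
    p = _check_probs(
        symbol_probabilities if symbol_probabilities is not None else np.full(k, 1.0 / k),
        k,
        "symbol_probabilities",
    )
    rng = np.random.default_rng(seed)
    codes = rng.choice(k, size=length, p=p)
    syms = np.array(list(alphabet.symbols))
    ident = f"random_L{length}_s{seed}"
    desc = f"kind=random length={length} probs={tuple(np.round(p, 6))} seed={seed}"
    return GenomicSequence(ident, "".join(syms[codes]), alphabet, description=desc)


def synth_coding(
    n_codons: int,
    codon_position_bias=None,
    seed: int = 0,
) -> GenomicSequence:
    """Codon-position-biased DNA: position j draws from distribution j mod 3.

    The default bias concentrates codon position 1 on G (probability 0.7,
    0.1 elsewhere) with uniform positions 2 and 3 -- a caricature of the
    G-richness of first codon positions that drives the period-3 signature
    of coding DNA.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if codon_position_bias is None:
        # A,C,G,T order: G-rich first codon position
        codon_position_bias = ((0.1, 0.1, 0.7, 0.1), _UNIFORM, _UNIFORM)
    if len(codon_position_bias) != 3:
        raise ValueError("codon_position_bias must give three distributions")
    dists = [_check_probs(p, 4, f"codon position {j + 1} distribution")
             for j, p in enumerate(codon_position_bias)]
    rng = np.random.default_rng(seed)
    n = 3 * n_codons
    codes = np.empty(n, dtype=np.int64)
    for j in range(3):
        codes[j::3] = rng.choice(4, size=len(codes[j::3]), p=dists[j])
    syms = np.array(list(DNA_ALPHABET.symbols))
    ident = f"coding_{n_codons}codons_s{seed}"
    desc = f"kind=coding n_codons={n_codons} seed={seed}"
    return GenomicSequence(ident, "".join(syms[codes]), DNA_ALPHABET, description=desc)
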