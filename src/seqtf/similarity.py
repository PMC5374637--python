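"""Alphabets and symbol-similarity matrices.

The similarity matrix S plays the role of multiplication in every bilinear
transform: r[n, tau] = S(x[n], y[n + tau]).  For DNA the default is the
identity matrix over (A, C, G, T) -- each nucleotide resembles only itself.
Zeroing rows/columns gives selective analysis of a subset of symbols;
protein work typically loads BLOSUM or PAM scoring matrices, whose negative
entries are kept as-is (the transforms are linear in S).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Alphabet",
    "SimilarityMatrix",
    "DNA_ALPHABET",
    "PROTEIN_ALPHABET",
    "identity_similarity",
    "selective_similarity",
    "load_similarity",
    "write_similarity",
]


class SimilarityFormatError(ValueError):
    """Raised when a similarity-matrix file cannot be parsed."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of single-character symbols."""

    symbols: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        syms = tuple(str(s).upper() for s in self.symbols)
        if not syms:
            raise ValueError("alphabet must contain at least one symbol")
        if any(len(s) != 1 for s in syms):
            raise ValueError("alphabet symbols must be single characters")
        if len(set(syms)) != len(syms):
            raise ValueError("alphabet symbols must be unique")
        object.__setattr__(self, "symbols", syms)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol.upper())


DNA_ALPHABET = Alphabet(("A", "C", "G", "T"), name="DNA")
PROTEIN_ALPHABET = Alphabet(tuple("ARNDCQEGHILKMFPSTWYV"), name="protein")


@dataclass
class SimilarityMatrix:
    """Square table of pairwise symbol similarities over an alphabet.

    ``values[i, j]`` is the similarity of symbol i (row) to symbol j
    (column) in alphabet order.  Entries may be negative (BLOSUM/PAM).
    """

    alphabet: Alphabet
    values: np.ndarray
    name: str = ""
    is_symmetric: bool = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.alphabet)
        if self.values.shape != (k, k):
            raise ValueError(
                f"similarity grid shape {self.values.shape} does not match "
                f"alphabet size {k}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity entries must be finite")
        self.is_symmetric = bool(np.array_equal(self.values, self.values.T))

    def lookup(self, a: str, b: str, mode: str = "lenient") -> float:
        """Similarity of an (unordered in the symmetric case) symbol pair.

        Unknown symbols score 0 in lenient mode (they contribute nothing to
        any transform) and raise in strict mode.
        """
        a, b = a.upper(), b.upper()
        try:
            i = self.alphabet.index(a)
            j = self.alphabet.index(b)
        except ValueError:
            if mode == "strict":
                bad = a if a not in self.alphabet else b
                raise KeyError(f"symbol {bad!r} not in alphabet {self.alphabet.name or self.alphabet.symbols}")
            return 0.0
        return float(self.values[i, j])

    def padded(self) -> np.ndarray:
        """Values with one extra all-zero row/column for the out-of-alphabet
        sentinel index (used by vectorized transform code)."""
        k = len(self.alphabet)
        out = np.zeros((k + 1, k + 1))
        out[:k, :k] = self.values
        return out


def identity_similarity(alphabet: Alphabet = DNA_ALPHABET) -> SimilarityMatrix:
    """Kronecker-delta similarity: each symbol resembles only itself."""
    return SimilarityMatrix(alphabet, np.eye(len(alphabet)), name=f"identity[{alphabet.name}]")


def selective_similarity(S: SimilarityMatrix, keep: set[str]) -> SimilarityMatrix:
    """Zero every entry whose row or column symbol is outside ``keep``.

    Restricting the identity matrix to one nucleotide turns every transform
    into a selective-pattern analysis of that nucleotide alone.
    """
    keep_up = {str(s).upper() for s in keep}
    unknown = keep_up - set(S.alphabet.symbols)
    if unknown:
        raise ValueError(
            f"keep-set symbols {sorted(unknown)} are not in alphabet "
            f"{S.alphabet.name or S.alphabet.symbols}"
        )
    mask = np.array([s in keep_up for s in S.alphabet.symbols], dtype=bool)
    vals = np.where(np.outer(mask, mask), S.values, 0.0)
    return SimilarityMatrix(S.alphabet, vals, name=f"{S.name}|keep={''.join(sorted(keep_up))}")


def _parse_square_table(lines: list[tuple[int, str]], path: str) -> SimilarityMatrix:
    header = lines[0][1].split()
    if len(set(header)) != len(header):
        raise SimilarityFormatError(f"{path}:{lines[0][0]}: duplicate header symbols")
    k = len(header)
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    for lineno, text in lines[1:]:
        parts = text.split()
        if len(parts) != k + 1:
            raise SimilarityFormatError(
                f"{path}:{lineno}: expected symbol plus {k} values, got {len(parts)} fields"
            )
        sym = parts[0]
        try:
            rows[sym] = [float(p) for p in parts[1:]]
        except ValueError as e:
            raise SimilarityFormatError(f"{path}:{lineno}: non-numeric cell ({e})") from None
        order.append(sym)
    if order != header:
        # allow any row order as long as the same symbol set appears
        if set(order) != set(header):
            raise SimilarityFormatError(
                f"{path}: row symbols {order} do not match header {header}"
            )
    alphabet = Alphabet(tuple(header), name=os.path.basename(path))
    vals = np.array([rows[s] for s in header])
    return SimilarityMatrix(alphabet, vals, name=os.path.basename(path))


def load_similarity(path: str, format: str = "auto") -> SimilarityMatrix:
    """Load a similarity matrix from a plain-text file.

    Two dialects are understood:

    ``square-table``
        First line: whitespace-separated column symbols.  Each following
        line: row symbol then one real value per column.
    ``ncbi-scoring``
        The layout used to distribute BLOSUM/PAM matrices: ``#`` comment
        lines, then a column-symbol header, then rows led by their symbol.
        Trailing columns for ``*`` (stop) and ambiguity codes are kept as
        ordinary symbols.

    ``auto`` treats a leading ``#`` comment as ncbi-scoring, otherwise
    square-table; the two differ only in comment handling.
    """
    with open(path) as fh:
        raw = fh.readlines()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw)]
    lines = [(n, t) for n, t in lines if t]
    if format == "auto":
        format = "ncbi-scoring" if lines and lines[0][1].startswith("#") else "square-table"
    if format == "ncbi-scoring":
        lines = [(n, t) for n, t in lines if not t.startswith("#")]
    elif format != "square-table":
        raise ValueError(f"unknown similarity format {format!r}")
    if not lines:
        raise SimilarityFormatError(f"{path}: empty similarity file")
    return _parse_square_table(lines, path)


def write_similarity(S: SimilarityMatrix, path: str) -> None:
    """Write in the square-table dialect with full float precision."""
    with open(path, "w") as fh:
        fh.write(" ".join(S.alphabet.symbols) + "\n")
        for sym, row in zip(S.alphabet.symbols, S.values):
            fh.write(sym + " " + " ".join(repr(float(v)) for v in row) + "\n")
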