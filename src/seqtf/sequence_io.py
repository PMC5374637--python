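"""Sequence and result-table input/output.

FASTA reading goes through Biopython; results are written as delimited
text with ``#``-prefixed metadata headers so every table is self-describing
and round-trips to full float precision.  Sequence positions are 0-based
internally; written tables use 1-based positions (stated in their headers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .similarity import Alphabet, DNA_ALPHABET

__all__ = [
    "GenomicSequence",
    "ResultTable",
    "read_fasta",
    "write_fasta",
    "encode_sequence",
    "write_table",
    "read_table",
    "SENTINEL",
]

#: Index assigned to out-of-alphabet symbols; similarity tables are padded
#: with a zero row/column at this position (see SimilarityMatrix.padded).
SENTINEL = -1


class FastaFormatError(ValueError):
    pass


@dataclass
class GenomicSequence:
    """A named symbol sequence over an alphabet."""

    identifier: str
    symbols: str
    alphabet: Alphabet = DNA_ALPHABET
    description: str = ""

    def __post_init__(self) -> None:
        self.symbols = str(self.symbols).upper()
        if len(self.symbols) == 0:
            raise ValueError(f"sequence {self.identifier!r} is empty")

    def __len__(self) -> int:
        return len(self.symbols)

    def out_of_alphabet_positions(self) -> list[int]:
        return [i for i, s in enumerate(self.symbols) if s not in self.alphabet]


def read_fasta(path: str, alphabet: Alphabet = DNA_ALPHABET) -> list[GenomicSequence]:
    """Read all records of a FASTA file, preserving order.

    Whitespace inside sequences is stripped and case is normalized to
    upper.  Out-of-alphabet symbols (IUPAC ambiguity codes etc.) are kept
    so positions still match the source file; downstream code treats them
    as similar to nothing.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).replace(" ", "").replace("\t", "")
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(GenomicSequence(rec.id, seq, alphabet, description=rec.description))
    return out


def write_fasta(seqs: list[GenomicSequence], path: str, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.symbols), id=s.identifier, description=s.description or "")
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def encode_sequence(
    seq: GenomicSequence | str,
    alphabet: Alphabet = DNA_ALPHABET,
    mode: str = "lenient",
) -> np.ndarray:
    """Map symbols to alphabet row indices.

    Out-of-alphabet symbols map to the SENTINEL index (lenient) or raise
    with the 1-based offending position (strict).
    """
    symbols = seq.symbols if isinstance(seq, GenomicSequence) else str(seq).upper()
    lut = np.full(256, SENTINEL, dtype=np.int64)
    for i, s in enumerate(alphabet.symbols):
        lut[ord(s)] = i
        lut[ord(s.lower())] = i
    codes = lut[np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)]
    if mode == "strict":
        bad = np.flatnonzero(codes == SENTINEL)
        if bad.size:
            pos = int(bad[0])
            raise ValueError(
                f"symbol {symbols[pos]!r} at position {pos + 1} is not in "
                f"alphabet {alphabet.name or alphabet.symbols}"
            )
    elif mode != "lenient":
        raise ValueError(f"unknown mode {mode!r}")
    return codes


@dataclass
class ResultTable:
    """A 1- or 2-axis grid of real values with named numeric axes.

    The serialization format is delimited text: ``#`` metadata lines, then
    for one axis a two-column (coordinate, value) block, for two axes a
    matrix block whose first row/column carry the axis coordinates.
    """

    axes: list[tuple[str, np.ndarray]]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.axes = [(name, np.asarray(c, dtype=float)) for name, c in self.axes]
        expected = tuple(len(c) for _, c in self.axes)
        if self.values.shape != expected:
            raise ValueError(
                f"value grid shape {self.values.shape} does not match axis lengths {expected}"
            )


def write_table(table: ResultTable, path: str, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for key, val in table.metadata.items():
            fh.write(f"# {key} = {val}\n")
        names = delimiter.join(name for name, _ in table.axes)
        if len(table.axes) == 1:
            fh.write(f"# columns: {names}{delimiter}value\n")
            coords = table.axes[0][1]
            for c, v in zip(coords, table.values):
                fh.write(f"{float(c)!r}{delimiter}{float(v)!r}\n")
        elif len(table.axes) == 2:
            fh.write(f"# matrix: rows={table.axes[0][0]} cols={table.axes[1][0]}\n")
            cols = table.axes[1][1]
            fh.write(delimiter.join(["axis"] + [repr(float(c)) for c in cols]) + "\n")
            for r, row in zip(table.axes[0][1], table.values):
                fh.write(delimiter.join([repr(float(r))] + [repr(float(v)) for v in row]) + "\n")
        else:
            raise ValueError("only 1- or 2-axis tables are supported")


def read_table(path: str, delimiter: str = "\t") -> ResultTable:
    metadata: dict = {}
    axis_names: list[str] = []
    rows: list[list[float]] = []
    two_axis = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("columns:"):
                    axis_names = body[len("columns:"):].split()
                elif body.startswith("matrix:"):
                    two_axis = True
                    for part in body[len("matrix:"):].split():
                        axis_names.append(part.split("=", 1)[1])
                elif "=" in body:
                    key, val = body.split("=", 1)
                    metadata[key.strip()] = val.strip()
                continue
            rows.append(line.split(delimiter))
    if two_axis:
        col_coords = np.array([float(v) for v in rows[0][1:]])
        row_coords = np.array([float(r[0]) for r in rows[1:]])
        values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        axes = [(axis_names[0], row_coords), (axis_names[1], col_coords)]
    else:
        coords = np.array([float(r[0]) for r in rows])
        values = np.array([float(r[1]) for r in rows])
        axes = [(axis_names[0] if axis_names else "x", coords)]
    return ResultTable(axes, values, metadata)
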