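"""Sequence and interval data model for circular genomes.

Coordinates are 0-based, half-open everywhere inside the library; user-facing
reports (TSV/CLI) convert to 1-based inclusive, following SAM convention.

Sequences are plain uppercase strings over ``{A, C, G, T, N}``.  For numeric
work the module also exposes a small integer encoding (A=0, C=1, G=2, T=3,
N=4) shared by the repeat finder, the read mapper and the simulator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularSequence",
    "Interval",
    "InputError",
    "reverse_complement",
    "gc_fraction",
    "rotate",
    "encode_seq",
    "decode_seq",
    "revcomp_codes",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]

A, C, G, T, N = 0, 1, 2, 3, 4


class InputError(ValueError):
    """Malformed user input (bad characters, bad coordinates, bad files)."""


# --- encoding tables -------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement in code space: A<->T, C<->G, N->N
_COMP_CODES = np.array([T, G, C, A, N], dtype=np.uint8)

_COMP_BYTES = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTNacgtn", b"TGCANTGCAN"):
    _COMP_BYTES[_x] = _y


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes, validating the alphabet."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    bad = np.flatnonzero(codes < 0)
    if bad.size:
        pos = int(bad[0])
        raise InputError(
            f"non-nucleotide character {seq[pos]!r} at position {pos} "
            "(allowed: A, C, G, T, N, case-insensitive)"
        )
    return codes.astype(np.uint8)


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODES[codes[::-1]]


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; N maps to N.

    Raises :class:`InputError` naming the first offending position when the
    input contains characters outside ``{A,C,G,T,N}`` (case-insensitive).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if raw.size and np.any(_CODE[raw] < 0):
        encode_seq(seq)  # raises with position information
    return _COMP_BYTES[raw[::-1]].tobytes().decode("ascii").upper()


def gc_fraction(seq: str) -> float:
    """(G + C) / (A + C + G + T); N is excluded from both sides.

    Raises :class:`InputError` on an empty sequence or one consisting only
    of N (the fraction is undefined).
    """
    if not seq:
        raise InputError("gc_fraction of an empty sequence is undefined")
    codes = encode_seq(seq)
    counts = np.bincount(codes, minlength=5)
    denom = int(counts[:4].sum())
    if denom == 0:
        raise InputError("gc_fraction undefined: sequence contains only N")
    return float(counts[C] + counts[G]) / denom


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a (possibly circular) sequence.

    ``wraps`` marks an interval crossing the origin of the circle, in which
    case ``start > end`` and the interval covers ``[start, length) + [0, end)``.
    """

    start: int
    end: int
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise InputError(f"negative interval bound: {self}")
        if not self.wraps and self.start >= self.end:
            raise InputError(f"empty or inverted interval: {self}")

    def span(self, length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if length is None:
            raise InputError("span of a wrapping interval requires the sequence length")
        return (length - self.start) + self.end

    def contains(self, pos: int) -> bool:
        if not self.wraps:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        if self.wraps or other.wraps:
            raise InputError("overlap test not supported for wrapping intervals")
        return self.start < other.end and other.start < self.end


@dataclass
class CircularSequence:
    """A nucleotide sequence with an explicit circularity flag.

    The sequence is uppercased and validated on construction; characters
    outside ``{A,C,G,T,N}`` are rejected rather than silently converted.
    """

    id: str
    seq: str
    circular: bool = True
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputError(f"sequence {self.id!r} is empty")
        self._codes = encode_seq(self.seq)
        self.seq = decode_seq(self._codes)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        assert self._codes is not None
        return self._codes

    def subseq(self, start: int, end: int) -> str:
        """Substring ``[start, end)``; indices beyond length wrap when circular."""
        L = self.length
        if 0 <= start <= end <= L:
            return self.seq[start:end]
        if not self.circular:
            raise InputError(
                f"coordinates [{start}, {end}) outside linear sequence of length {L}"
            )
        if end - start > L:
            raise InputError("requested subsequence longer than the genome")
        s = start % L
        e = s + (end - start)
        doubled = self.seq + self.seq
        return doubled[s:e]

    def fetch(self, iv: Interval) -> str:
        if iv.wraps:
            return self.seq[iv.start :] + self.seq[: iv.end]
        return self.seq[iv.start : iv.end]


def rotate(genome: CircularSequence, k: int) -> CircularSequence:
    """Rotate the origin of a circular genome: result is ``seq[k:] + seq[:k]``."""
    if not genome.circular:
        raise InputError(f"cannot rotate non-circular sequence {genome.id!r}")
    if not 0 <= k < genome.length:
        raise InputError(f"rotation offset {k} outside [0, {genome.length})")
    return CircularSequence(genome.id, genome.seq[k:] + genome.seq[:k], circular=True)


# --- FASTA / FASTQ ---------------------------------------------------------


def read_fasta(path: str | os.PathLike | TextIO, circular: bool = True) -> list[CircularSequence]:
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        records.append(CircularSequence(rec.id, str(rec.seq), circular=circular))
    if not records:
        raise InputError(f"no FASTA records found in {path!r}")
    return records


def write_fasta(records: Iterable[CircularSequence], path: str | os.PathLike | TextIO) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    # Biopython's fasta writer wraps at 60; the conventional 70 is set via
    # the two-line format with explicit wrapping.
    if hasattr(path, "write"):
        _write_fasta_handle(seqrecs, path)
    else:
        with open(path, "w") as fh:
            _write_fasta_handle(seqrecs, fh)


def _write_fasta_handle(seqrecs: list[SeqRecord], fh: TextIO, width: int = 70) -> None:
    for rec in seqrecs:
        fh.write(f">{rec.id}\n")
        s = str(rec.seq)
        for i in range(0, len(s), width):
            fh.write(s[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike | TextIO) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) from a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq), qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | os.PathLike | TextIO) -> None:
    if hasattr(path, "write"):
        for rid, seq, qual in records:
            path.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    else:
        with open(path, "w") as fh:
            for rid, seq, qual in records:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
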