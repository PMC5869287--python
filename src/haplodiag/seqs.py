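"""Nucleotide encoding, sequence containers, and FASTA/FASTQ helpers.

Sequences are held internally as ``numpy.uint8`` code arrays (A=0, C=1, G=2,
T=3; anything else, e.g. N or hard-masked bases, is 255 and never matches a
k-mer). This keeps the mapper and the simulator fully vectorisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
INVALID = np.uint8(255)

_ENCODE = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.full(256, ord("N"), dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _DECODE[_i] = ord(_b)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a code array back into an upper-case nucleotide string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; invalid bases stay invalid."""
    out = codes[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


class ContigSet:
    """An ordered set of named contigs stored as code arrays.

    Duplicate names are rejected at construction; ordering is insertion
    order and deterministic, which downstream seeded operations rely on.
    """

    def __init__(self, items: Mapping[str, str | np.ndarray] | Iterable[tuple[str, str | np.ndarray]]):
        if isinstance(items, Mapping):
            items = items.items()
        self._seqs: dict[str, np.ndarray] = {}
        for name, seq in items:
            if name in self._seqs:
                raise ValueError(f"duplicate contig id: {name!r}")
            codes = seq if isinstance(seq, np.ndarray) else encode(seq)
            self._seqs[name] = np.asarray(codes, dtype=np.uint8)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ContigSet":
        pairs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            pairs.append((rec.id, str(rec.seq)))
        return cls(pairs)

    def to_fasta(self, path: str | Path) -> None:
        records = (
            SeqRecord(Seq(decode(codes)), id=name, description="")
            for name, codes in self._seqs.items()
        )
        SeqIO.write(records, str(path), "fasta")

    # --- mapping-style access -------------------------------------------
    def __getitem__(self, name: str) -> np.ndarray:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    @property
    def total_span(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def sequence(self, name: str) -> str:
        return decode(self._seqs[name])


@dataclass
class ReadSet:
    """A batch of equal-length reads, single- or paired-end.

    ``r1``/``r2`` are ``(n, L)`` uint8 code matrices; ``r2`` is ``None`` for
    single-end data. Read names carry simulator truth when synthetic (see
    README for the name grammar) but are otherwise opaque.
    """

    names: list[str]
    r1: np.ndarray
    r2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r1 = np.atleast_2d(np.asarray(self.r1, dtype=np.uint8))
        if self.r2 is not None:
            self.r2 = np.atleast_2d(np.asarray(self.r2, dtype=np.uint8))
            if self.r2.shape != self.r1.shape:
                raise ValueError("mate matrices must have identical shape")
        if len(self.names) != self.r1.shape[0]:
            raise ValueError("name count does not match read count")

    @property
    def n(self) -> int:
        return self.r1.shape[0]

    @property
    def read_length(self) -> int:
        return self.r1.shape[1]

    @property
    def is_paired(self) -> bool:
        return self.r2 is not None

    def to_single(self) -> "ReadSet":
        """Flatten mates into independent single-end reads (mate tag appended)."""
        if not self.is_paired:
            return self
        names = [f"{n}/1" for n in self.names] + [f"{n}/2" for n in self.names]
        return ReadSet(names, np.vstack([self.r1, self.r2]), None)

    def subset(self, idx: np.ndarray | list[int]) -> "ReadSet":
        idx = np.asarray(idx)
        return ReadSet(
            [self.names[i] for i in idx],
            self.r1[idx],
            self.r2[idx] if self.r2 is not None else None,
        )

    @classmethod
    def from_fastq(cls, path1: str | Path, path2: str | Path | None = None) -> "ReadSet":
        names, mat1 = _read_fastq_matrix(path1)
        if path2 is None:
            return cls(names, mat1)
        names2, mat2 = _read_fastq_matrix(path2)
        if len(names2) != len(names):
            raise ValueError("mate FASTQ files differ in read count")
        return cls(names, mat1, mat2)

    def to_fastq(self, path1: str | Path, path2: str | Path | None = None) -> None:
        _write_fastq_matrix(path1, self.names, self.r1)
        if self.is_paired:
            if path2 is None:
                raise ValueError("paired reads require two output paths")
            _write_fastq_matrix(path2, self.names, self.r2)


def _read_fastq_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    names: list[str] = []
    seqs: list[np.ndarray] = []
    length = None
    for rec in SeqIO.parse(str(path), "fastq"):
        s = encode(str(rec.seq))
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise ValueError("variable-length FASTQ not supported in batch reader")
        names.append(rec.id)
        seqs.append(s)
    if not seqs:
        raise ValueError(f"no reads in {path}")
    return names, np.vstack(seqs)


def _write_fastq_matrix(path: str | Path, names: list[str], mat: np.ndarray) -> None:
    qual = "I" * mat.shape[1]
    with open(path, "w") as fh:
        for name, row in zip(names, mat):
            fh.write(f"@{name}\n{decode(row)}\n+\n{qual}\n")
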