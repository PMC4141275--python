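"""Reference sequences as compact numpy code arrays.

Bases are encoded A=0, C=1, G=2, T=3, N=4.  N is a legal character that
breaks repeat runs and is excluded from callable-length accounting; any
other character is rejected with the offset of the first offender.
"""

from __future__ import annotations

from typing import Dict, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

A, C, G, T, N = 0, 1, 2, 3, 4

_ALPHABET = b"ACGTN"
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_ALPHABET):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(_ALPHABET, dtype=np.uint8)

#: complement of each code (N stays N)
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(sequence) -> np.ndarray:
    """Encode a DNA string/bytes into uint8 codes, validating the alphabet."""
    if isinstance(sequence, np.ndarray):
        if sequence.dtype != np.uint8:
            raise TypeError("code arrays must be uint8")
        return sequence
    if isinstance(sequence, str):
        raw = sequence.encode("ascii")
    else:
        raw = bytes(sequence)
    codes = _LUT[np.frombuffer(raw, dtype=np.uint8)]
    bad = np.flatnonzero(codes == 255)
    if bad.size:
        off = int(bad[0])
        raise ValueError(
            f"non-IUPAC character {chr(raw[off])!r} at offset {off}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


class Genome:
    """A set of named contigs held as uint8 code arrays.

    Thin container shared by the simulator and every analysis stage; it
    knows how to round-trip FASTA and to answer the handful of sequence
    statistics the analyses need (dinucleotide abundance, GC, callable
    length).
    """

    def __init__(self, contigs: Mapping[str, object]):
        self._contigs: Dict[str, np.ndarray] = {
            name: encode(seq) for name, seq in contigs.items()
        }
        if not self._contigs:
            raise ValueError("genome must contain at least one contig")

    # -- basic access -------------------------------------------------
    @property
    def contigs(self):
        return list(self._contigs)

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def codes(self, contig: str) -> np.ndarray:
        return self._contigs[contig]

    def length(self, contig: str) -> int:
        return int(self._contigs[contig].size)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: arr.size for name, arr in self._contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(arr.size for arr in self._contigs.values())

    def sequence(self, contig: str, start: int = 0, end: int | None = None) -> str:
        return decode(self._contigs[contig][start:end])

    def base_at(self, contig: str, pos) -> np.ndarray:
        return self._contigs[contig][pos]

    # -- statistics ----------------------------------------------------
    def callable_length(self, contig: str | None = None) -> int:
        if contig is not None:
            return int(np.count_nonzero(self._contigs[contig] < 4))
        return sum(
            int(np.count_nonzero(arr < 4)) for arr in self._contigs.values()
        )

    def gc_fraction(self, contig: str, start: int = 0, end: int | None = None) -> float:
        arr = self._contigs[contig][start:end]
        acgt = np.count_nonzero(arr < 4)
        if acgt == 0:
            return float("nan")
        gc = np.count_nonzero((arr == C) | (arr == G))
        return gc / acgt

    def dinucleotide_counts(self) -> np.ndarray:
        """4x4 counts of adjacent (base, following base) pairs, N excluded."""
        out = np.zeros((4, 4), dtype=np.int64)
        for arr in self._contigs.values():
            if arr.size < 2:
                continue
            a, b = arr[:-1], arr[1:]
            ok = (a < 4) & (b < 4)
            np.add.at(out, (a[ok], b[ok]), 1)
        return out

    # -- FASTA ---------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "Genome":
        records = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(records)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(decode(arr)), id=name, description="")
            for name, arr in self._contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")
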