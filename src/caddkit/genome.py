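"""Mutable in-memory genome container with FASTA round-tripping.

Sequences are plain uppercase strings keyed by chromosome name. Hot paths
(mutation simulation, CpG detection) work on numpy uint8 code arrays via
:func:`encode` / :func:`decode`; code 255 marks an unknown base (``N``).
"""

from __future__ import annotations

from typing import Dict, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
UNKNOWN = np.uint8(255)

_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(BASES):
    _ENCODE_TABLE[ord(_c)] = _i
    _ENCODE_TABLE[ord(_c.lower())] = _i  # soft-masked bases are valid


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, else 255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; 255 decodes to ``N``."""
    lookup = np.frombuffer((BASES + "N").encode("ascii"), dtype=np.uint8)
    idx = np.where(codes == UNKNOWN, 4, codes).astype(np.intp)
    return lookup[idx].tobytes().decode("ascii")


class Genome(Dict[str, str]):
    """A set of named chromosome sequences (chrom -> uppercase string)."""

    def lengths(self) -> Dict[str, int]:
        return {chrom: len(seq) for chrom, seq in self.items()}

    def base_at(self, chrom: str, pos0: int) -> str:
        """Base at a 0-based position."""
        return self[chrom][pos0].upper()

    def codes(self, chrom: str) -> np.ndarray:
        return encode(self[chrom])

    def write_fasta(self, path: str) -> None:
        records = (
            SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in self.items()
        )
        SeqIO.write(records, path, "fasta")

    @classmethod
    def read_fasta(cls, path: str) -> "Genome":
        genome = cls()
        for record in SeqIO.parse(path, "fasta"):
            genome[record.id] = str(record.seq).upper()
        return genome


def cpg_mask(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of CpG-context sites.

    A CpG is the dinucleotide 5'-CG-3' on the forward strand; both the C and
    the G are flagged (symmetric hypermutability of the methylated context).
    """
    mask = np.zeros(codes.shape, dtype=bool)
    if codes.size < 2:
        return mask
    is_cg = (codes[:-1] == 1) & (codes[1:] == 2)
    mask[:-1] |= is_cg
    mask[1:] |= is_cg
    return mask


def iter_windows(length: int, window_size: int) -> Iterator[tuple[int, int, int]]:
    """Yield (window_index, start, end) half-open tiles covering ``length``.

    The last partial window is kept.
    """
    k = 0
    for start in range(0, length, window_size):
        yield k, start, min(start + window_size, length)
        k += 1


def n_windows(length: int, window_size: int) -> int:
    return (length + window_size - 1) // window_size


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def validate_mapping_covers(genome: Mapping[str, str], chrom: str, pos0: int) -> None:
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from sequence set")
    if not 0 <= pos0 < len(genome[chrom]):
        raise IndexError(
            f"position {pos0} outside chromosome {chrom!r} (length {len(genome[chrom])})"
        )
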