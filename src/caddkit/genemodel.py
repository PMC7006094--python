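"""Gene models: transcripts with exon/CDS/UTR/intron structure plus miRNAs.

Coordinates are 0-based half-open internally and 1-based inclusive in GFF3.
Parsing goes through :mod:`gffutils`; writing emits plain GFF3 text with
``gene``/``mRNA``/``exon``/``CDS``/``five_prime_UTR``/``three_prime_UTR``/
``miRNA`` features so models round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genome import Genome, revcomp

Interval = Tuple[int, int]  # 0-based half-open


def _merge_sorted(intervals: Sequence[Interval]) -> Tuple[Interval, ...]:
    return tuple(sorted((int(a), int(b)) for a, b in intervals))


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    cds: Tuple[Interval, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        object.__setattr__(self, "exons", _merge_sorted(self.exons))
        object.__setattr__(self, "cds", _merge_sorted(self.cds))
        for a, b in self.exons + self.cds:
            if a >= b:
                raise ValueError("empty or inverted interval")

    # -- derived structure ------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> Tuple[Interval, ...]:
        """Introns in genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def introns_by_position(self) -> Tuple[Interval, ...]:
        """Introns in transcription order (first intron nearest the TSS)."""
        ivs = self.introns
        return ivs if self.strand == "+" else ivs[::-1]

    @property
    def utr5(self) -> Tuple[Interval, ...]:
        return self._utr(five_prime=True)

    @property
    def utr3(self) -> Tuple[Interval, ...]:
        return self._utr(five_prime=False)

    def _utr(self, five_prime: bool) -> Tuple[Interval, ...]:
        if not self.cds:
            return ()
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        left = five_prime if self.strand == "+" else not five_prime
        out: List[Interval] = []
        for a, b in self.exons:
            if left:
                lo, hi = a, min(b, cds_lo)
            else:
                lo, hi = max(a, cds_hi), b
            if lo < hi:
                out.append((lo, hi))
        return tuple(out)

    def cds_positions(self) -> np.ndarray:
        """Genomic 0-based CDS positions in translation order."""
        pos = np.concatenate([np.arange(a, b) for a, b in self.cds])
        return pos if self.strand == "+" else pos[::-1]

    def codon_positions(self) -> Tuple[np.ndarray, np.ndarray]:
        """(genomic positions, codon position 1/2/3) in translation order."""
        pos = self.cds_positions()
        return pos, (np.arange(pos.size) % 3) + 1

    def coding_sequence(self, genome: Mapping[str, str]) -> str:
        seq = "".join(genome[self.chrom][a:b] for a, b in self.cds).upper()
        return seq if self.strand == "+" else revcomp(seq)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        seq = "".join(genome[self.chrom][a:b] for a, b in self.exons).upper()
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: Tuple[Transcript, ...]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass(frozen=True)
class MiRNA:
    mirna_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class GeneModel:
    genes: Tuple[Gene, ...]
    mirnas: Tuple[MiRNA, ...] = ()
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, GeneModel):
            return NotImplemented
        return (
            sorted(self.genes, key=lambda g: g.gene_id)
            == sorted(other.genes, key=lambda g: g.gene_id)
            and sorted(self.mirnas, key=lambda m: m.mirna_id)
            == sorted(other.mirnas, key=lambda m: m.mirna_id)
        )

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self.genes:
            yield from gene.transcripts

    def single_transcript_genes(self) -> List[Gene]:
        return [g for g in self.genes if len(g.transcripts) == 1]

    # -- GFF3 -------------------------------------------------------------
    def write_gff3(self, path: str, source: str = "caddkit") -> None:
        lines = ["##gff-version 3"]
        for chrom, length in sorted(self.chrom_lengths.items()):
            lines.append(f"##sequence-region {chrom} 1 {length}")

        def row(chrom, ftype, start0, end0, strand, phase, attrs):
            return "\t".join(
                [
                    chrom,
                    source,
                    ftype,
                    str(start0 + 1),
                    str(end0),
                    ".",
                    strand,
                    phase,
                    attrs,
                ]
            )

        for gene in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
            lines.append(
                row(gene.chrom, "gene", gene.start, gene.end, gene.strand, ".",
                    f"ID={gene.gene_id}")
            )
            for t in gene.transcripts:
                lines.append(
                    row(t.chrom, "mRNA", t.start, t.end, t.strand, ".",
                        f"ID={t.transcript_id};Parent={gene.gene_id}")
                )
                for a, b in t.exons:
                    lines.append(
                        row(t.chrom, "exon", a, b, t.strand, ".",
                            f"Parent={t.transcript_id}")
                    )
                # phase: bases to skip to reach the next codon start
                cds_iter = t.cds if t.strand == "+" else t.cds[::-1]
                done = 0
                phased = {}
                for a, b in cds_iter:
                    phased[(a, b)] = (3 - done % 3) % 3
                    done += b - a
                for a, b in t.cds:
                    lines.append(
                        row(t.chrom, "CDS", a, b, t.strand, str(phased[(a, b)]),
                            f"Parent={t.transcript_id}")
                    )
                for name, ivs in (("five_prime_UTR", t.utr5), ("three_prime_UTR", t.utr3)):
                    for a, b in ivs:
                        lines.append(
                            row(t.chrom, name, a, b, t.strand, ".",
                                f"Parent={t.transcript_id}")
                        )
        for m in sorted(self.mirnas, key=lambda m: (m.chrom, m.start)):
            lines.append(
                row(m.chrom, "miRNA", m.start, m.end, m.strand, ".", f"ID={m.mirna_id}")
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def read_gff3(cls, path: str) -> "GeneModel":
        import gffutils

        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        chrom_lengths: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _one, length = line.split()
                    chrom_lengths[chrom] = int(length)
                elif not line.startswith("#"):
                    break

        genes: List[Gene] = []
        for g in db.features_of_type("gene"):
            transcripts = []
            for t in db.children(g, featuretype="mRNA"):
                exons = tuple(
                    (e.start - 1, e.end) for e in db.children(t, featuretype="exon")
                )
                cds = tuple(
                    (c.start - 1, c.end) for c in db.children(t, featuretype="CDS")
                )
                transcripts.append(
                    Transcript(t.id, g.id, t.seqid, t.strand, exons, cds)
                )
            genes.append(Gene(g.id, g.seqid, g.strand, tuple(transcripts)))
        mirnas = tuple(
            MiRNA(m.id, m.seqid, m.strand, m.start - 1, m.end)
            for m in db.features_of_type("miRNA")
        )
        return cls(tuple(genes), mirnas, chrom_lengths)
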