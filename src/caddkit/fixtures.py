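"""Synthetic genomes, ancestors, populations, gene models and tracks.

Everything downstream of this module (derived-class construction, de novo
simulation, annotation, training, region tests) is exercisable on the data
generated here, with ground-truth labels retained so expected outputs can be
computed exactly. All generators are pure functions of (spec, seed).

Sequence evolution is SNV-only: ancestors conserve length so coordinates are
shared across the whole set and no alignment step is needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import BASES, Genome, cpg_mask, decode, encode, revcomp
from .genemodel import Gene, GeneModel, MiRNA, Transcript

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOP_CODONS
)

#: Tissue panel used by the synthetic expression table (16 tissues).
TISSUES = (
    "cartilage-tendon", "blood", "cerebellum", "dermal", "epithelium", "eye",
    "kidney", "liver", "lung", "muscle", "neuronal", "pancreas", "placenta",
    "salivary-gland", "testis", "vasculature",
)


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Reference genome shape: ``n_chromosomes`` of ``chrom_length`` bases at
    the given GC content."""

    n_chromosomes: int = 2
    chrom_length: int = 100_000
    gc_content: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("n_chromosomes and chrom_length must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")


def generate_reference(spec: SyntheticGenomeSpec) -> Genome:
    """I.i.d. nucleotide sequence with the requested GC content."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = Genome()
    for i in range(spec.n_chromosomes):
        codes = rng.choice(4, size=spec.chrom_length, p=p).astype(np.uint8)
        genome[f"chr{i + 1}"] = decode(codes)
    return genome


# ---------------------------------------------------------------------------
# ancestor chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestorTree:
    """A chain of increasingly distant ancestors.

    ``branches`` lists (node name, per-site substitution probability) from the
    reference outward; each node evolves from the previous one. CpG-context
    sites (the C and the G of a 5'-CG-3' dinucleotide, read off the parent at
    mutation time) mutate at ``cpg_multiplier`` times the branch rate.
    """

    branches: Tuple[Tuple[str, float], ...] = (
        ("anc_close", 0.06),
        ("anc_mid1", 0.03),
        ("anc_mid2", 0.03),
        ("anc_far", 0.04),
    )
    cpg_multiplier: float = 8.0

    def __post_init__(self):
        for name, p in self.branches:
            if not 0.0 <= p < 0.5:
                raise ValueError(f"branch probability for {name!r} outside [0, 0.5)")
        if self.cpg_multiplier < 1.0:
            raise ValueError("cpg_multiplier must be >= 1")


def evolve_ancestors(
    reference: Genome, tree: AncestorTree, seed: int
) -> Dict[str, Genome]:
    """Evolve the chain of ancestors from the reference.

    Returns a dict of node name -> genome, in branch order. Substitutions
    only; sequence lengths are conserved.
    """
    rng = np.random.default_rng(seed)
    ancestors: Dict[str, Genome] = {}
    parent = reference
    for name, p in tree.branches:
        child = Genome()
        for chrom in parent:
            codes = encode(parent[chrom]).copy()
            rate = np.where(
                cpg_mask(codes), min(p * tree.cpg_multiplier, 0.95), p
            )
            hit = rng.random(codes.size) < rate
            shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
            codes[hit] = (codes[hit] + shift) % 4
            child[chrom] = decode(codes)
        ancestors[name] = child
        parent = child
    return ancestors


# ---------------------------------------------------------------------------
# population sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """Biallelic site panel for a diploid population of ``n_individuals``.

    Sites fall into ground-truth categories (``category`` column):

    - ``fixed_derived``: alternate allele nearly fixed (AF >= 0.96) and
      different from the ancestral allele; the residual ancestral allele stays
      below the 0.05 screening ceiling.
    - ``segregating``: intermediate-frequency polymorphism (0.055 < AF <= 0.9).
    - ``ancestral_trap``: alternate allele just above the 0.9 threshold but
      with the ancestral allele still segregating above 0.05 — these mimic the
      sites the derived-class screen must discard.
    - ``ancestral_matching``: population essentially fixed for the ancestral
      allele, with a rare non-ancestral allele (AF <= 0.05).

    Allele frequencies are quantised to allele-count multiples of 1/(2N).
    """

    n_individuals: int = 50
    n_sites: int = 400
    fixed_derived_fraction: float = 0.25
    segregating_fraction: float = 0.45
    ancestral_trap_fraction: float = 0.10
    afs_beta: Tuple[float, float] = (0.8, 0.8)
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        fracs = (
            self.fixed_derived_fraction,
            self.segregating_fraction,
            self.ancestral_trap_fraction,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0 + 1e-9:
            raise ValueError("category fractions must lie in [0,1] and sum to <= 1")


def generate_population(
    reference: Genome,
    spec: PopulationSpec,
    ancestor: Optional[Genome] = None,
) -> pd.DataFrame:
    """Emit a biallelic site table (VCF-writable) with ground-truth categories.

    ``ancestor`` is the sequence the derived-class screen will compare
    against; it defaults to the reference itself (no ancestral differences).

    Returns a DataFrame with columns chrom, pos (1-based), ref, alt, af,
    ancestral, category.
    """
    if ancestor is None:
        ancestor = reference
    rng = np.random.default_rng(spec.seed)
    two_n = 2 * spec.n_individuals

    n_fd = int(round(spec.fixed_derived_fraction * spec.n_sites))
    n_seg = int(round(spec.segregating_fraction * spec.n_sites))
    n_trap = int(round(spec.ancestral_trap_fraction * spec.n_sites))
    n_match = spec.n_sites - n_fd - n_seg - n_trap
    if n_match < 0:
        raise ValueError("category fractions exceed 1")

    # candidate positions, margin 5 from chromosome ends, split into a pool of
    # ancestor-matching positions (ref == ancestral) and a free pool
    match_pool: List[Tuple[str, int]] = []
    free_pool: List[Tuple[str, int]] = []
    total = sum(len(s) for s in reference.values())
    for chrom, seq in reference.items():
        n_chrom = max(0, int(round(spec.n_sites * 3 * len(seq) / total)))
        positions = rng.choice(len(seq) - 10, size=min(n_chrom, len(seq) - 10),
                               replace=False) + 5
        for p in positions:
            ref, anc = reference.base_at(chrom, int(p)), ancestor.base_at(chrom, int(p))
            if ref == "N" or anc == "N":
                continue
            (match_pool if ref == anc else free_pool).append((chrom, int(p)))
    rng.shuffle(match_pool)
    rng.shuffle(free_pool)

    needs_match = {"ancestral_trap", "ancestral_matching"}
    plan = (
        ["fixed_derived"] * n_fd
        + ["segregating"] * n_seg
        + ["ancestral_trap"] * n_trap
        + ["ancestral_matching"] * n_match
    )
    rows = []
    for category in plan:
        if category in needs_match:
            if not match_pool:
                raise ValueError("position pool exhausted; reduce n_sites")
            chrom, pos0 = match_pool.pop()
        else:
            source = free_pool if free_pool else match_pool
            if not source:
                raise ValueError("position pool exhausted; reduce n_sites")
            chrom, pos0 = source.pop()
        ref = reference.base_at(chrom, pos0)
        anc = ancestor.base_at(chrom, pos0)

        others = [b for b in BASES if b != ref]
        if category == "fixed_derived":
            choices = [b for b in others if b != anc] or others
            alt = choices[rng.integers(len(choices))]
            k = rng.integers(int(np.ceil(0.96 * two_n)), two_n + 1)
        elif category == "segregating":
            # keep both alleles in (0.1, 0.9) so neither side can masquerade
            # as a (nearly) fixed non-ancestral allele
            alt = others[rng.integers(3)]
            af = 0.11 + rng.beta(*spec.afs_beta) * (0.89 - 0.11)
            k = int(np.clip(round(af * two_n), np.ceil(0.105 * two_n),
                            np.floor(0.895 * two_n)))
        elif category == "ancestral_trap":
            alt = others[rng.integers(3)]
            lo = int(np.ceil(0.905 * two_n))
            hi = int(np.floor(0.93 * two_n))
            k = rng.integers(lo, max(lo, hi) + 1)
        else:  # ancestral_matching
            alt = others[rng.integers(3)]
            k = rng.integers(1, max(1, int(np.floor(0.05 * two_n))) + 1)
        rows.append(
            dict(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                 af=k / two_n, ancestral=anc, category=category)
        )

    df = pd.DataFrame(rows).drop_duplicates(subset=["chrom", "pos"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def write_population_vcf(sites: pd.DataFrame, reference: Genome, path: str) -> None:
    """Write the site table as VCF v4.2 with the alternate AF in INFO."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">'
    )
    for chrom, length in reference.lengths().items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for row in sites.sort_values(["chrom", "pos"]).itertuples():
            rec = vcf.new_record(
                contig=row.chrom, start=row.pos - 1, stop=row.pos,
                alleles=(row.ref, row.alt),
            )
            rec.info["AF"] = float(row.af)
            vcf.write(rec)


def read_population_vcf(path: str) -> pd.DataFrame:
    """Read a biallelic-SNV VCF into the site-table schema (AF from INFO)."""
    import pysam

    rows = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"non-biallelic record at {rec.chrom}:{rec.pos}")
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"non-SNV record at {rec.chrom}:{rec.pos}")
            rows.append(
                dict(chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                     af=float(rec.info["AF"][0] if isinstance(rec.info["AF"], tuple)
                              else rec.info["AF"]))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + sense codons + stop; translates without internal stops."""
    middle = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(3)]
    return "ATG" + "".join(SENSE_CODONS[i] for i in middle) + stop


def _mrna_to_genomic(
    exons: Sequence[Tuple[int, int]], strand: str, m_lo: int, m_hi: int
) -> List[Tuple[int, int]]:
    """Map an mRNA sub-interval onto genomic exon intervals."""
    tx = list(exons) if strand == "+" else list(exons)[::-1]
    out = []
    m = 0
    for a, b in tx:
        length = b - a
        lo, hi = max(m_lo, m), min(m_hi, m + length)
        if lo < hi:
            if strand == "+":
                out.append((a + lo - m, a + hi - m))
            else:
                out.append((b - (hi - m), b - (lo - m)))
        m += length
    return sorted(out)


def generate_gene_model(
    genome: Genome,
    n_genes: int = 12,
    n_mirnas: int = 5,
    seed: int = 0,
    exons_per_gene: Tuple[int, int] = (2, 5),
    cds_codons: Tuple[int, int] = (40, 120),
    intron_length: Tuple[int, int] = (20, 200),
    utr_length: Tuple[int, int] = (12, 60),
    intergenic_gap: Tuple[int, int] = (2500, 4000),
    mirna_length: Tuple[int, int] = (70, 90),
) -> GeneModel:
    """Plant protein-coding genes and miRNAs into the genome.

    The exonic sequence of each transcript is **written into** the genome so
    that every CDS starts with ATG, ends with a stop codon and translates
    without internal stops, on either strand. Genes do not overlap; introns
    are at least 20 bp so splice-region offsets up to 8 bp exist; miRNAs are
    placed in intergenic gaps, disjoint from all gene spans.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    cursors = {c: rng.integers(*intergenic_gap) for c in chroms}
    seqs = {c: list(genome[c]) for c in chroms}
    genes: List[Gene] = []
    gaps: List[Tuple[str, int, int]] = []  # intergenic gaps for miRNA placement

    chrom_cycle = itertools.cycle(chroms)
    for gi in range(n_genes):
        strand = "+-"[rng.integers(2)]
        n_codons = int(rng.integers(*cds_codons))
        cds_seq = _random_cds(rng, n_codons)
        u5 = int(rng.integers(*utr_length))
        u3 = int(rng.integers(*utr_length))
        mrna = (
            decode(rng.choice(4, size=u5).astype(np.uint8))
            + cds_seq
            + decode(rng.choice(4, size=u3).astype(np.uint8))
        )
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        n_exons = min(n_exons, max(1, len(mrna) // 25))
        # split the mRNA into n_exons chunks, each >= 10 bp
        cuts = np.sort(rng.choice(len(mrna) - 20 * n_exons + 1, size=n_exons - 1,
                                  replace=True)) if n_exons > 1 else np.array([], int)
        bounds = [0] + [int(c) + 10 * (i + 1) for i, c in enumerate(cuts)] + [len(mrna)]
        chunk_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
        intron_lens = [int(rng.integers(*intron_length)) for _ in range(n_exons - 1)]
        span = sum(chunk_lens) + sum(intron_lens)

        placed = False
        for _ in range(len(chroms)):
            chrom = next(chrom_cycle)
            start = cursors[chrom]
            tail = intergenic_gap[1]
            if start + span + tail <= len(genome[chrom]):
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot pack gene {gi + 1}/{n_genes}: chromosomes too short"
            )

        # genomic exon intervals (genomic order)
        exons = []
        pos = start
        for i, length in enumerate(chunk_lens):
            exons.append((pos, pos + length))
            pos += length + (intron_lens[i] if i < len(intron_lens) else 0)
        gene_end = exons[-1][1]
        gap_start = cursors[chrom] if gi == 0 else None
        gaps.append((chrom, gene_end, gene_end))  # placeholder; fixed below
        next_gap = int(rng.integers(*intergenic_gap))
        cursors[chrom] = gene_end + next_gap
        gaps[-1] = (chrom, gene_end + 300, min(cursors[chrom] - 300, len(genome[chrom])))

        # write exonic sequence: transcription-order exons take mRNA chunks
        tx_exons = exons if strand == "+" else exons[::-1]
        m = 0
        for a, b in tx_exons:
            chunk = mrna[m:m + (b - a)]
            seqs[chrom][a:b] = list(chunk if strand == "+" else revcomp(chunk))
            m += b - a

        cds_ivs = _mrna_to_genomic(exons, strand, u5, u5 + len(cds_seq))
        tid = f"tx{gi + 1:03d}"
        transcript = Transcript(tid, f"gene{gi + 1:03d}", chrom, strand,
                                tuple(exons), tuple(cds_ivs))
        genes.append(Gene(f"gene{gi + 1:03d}", chrom, strand, (transcript,)))

    for chrom in chroms:
        genome[chrom] = "".join(seqs[chrom])

    # miRNAs in intergenic gaps, disjoint from gene spans
    mirnas: List[MiRNA] = []
    usable = [g for g in gaps if g[2] - g[1] >= mirna_length[1] + 20]
    if n_mirnas > 0 and not usable:
        raise ValueError("no intergenic gap wide enough for miRNAs")
    for mi in range(n_mirnas):
        chrom, lo, hi = usable[mi % len(usable)]
        length = int(rng.integers(*mirna_length))
        start = int(rng.integers(lo, hi - length))
        mirnas.append(MiRNA(f"mir{mi + 1:03d}", chrom, "+-"[rng.integers(2)],
                            start, start + length))
        # shrink the gap so miRNAs in the same gap cannot overlap
        usable[mi % len(usable)] = (chrom, start + length + 5, hi)

    return GeneModel(tuple(genes), tuple(mirnas), genome.lengths())


# ---------------------------------------------------------------------------
# conservation tracks and expression
# ---------------------------------------------------------------------------

def generate_conservation_tracks(
    genome: Genome,
    gene_model: GeneModel,
    seed: int = 0,
    coverage: float = 1.0,
    track_names: Sequence[str] = ("phylop", "phastcons", "gerp"),
    conserved_shift: float = 2.0,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-position numeric tracks: unit-variance noise, shifted upward by
    ``conserved_shift`` inside CDS and miRNA intervals. A fraction
    ``1 - coverage`` of positions is missing (NaN), independently per track,
    to exercise downstream imputation.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    conserved = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
    for t in gene_model.transcripts():
        for a, b in t.cds:
            conserved[t.chrom][a:b] = True
    for m in gene_model.mirnas:
        conserved[m.chrom][m.start:m.end] = True

    tracks: Dict[str, Dict[str, np.ndarray]] = {}
    for name in track_names:
        per_chrom = {}
        for chrom, seq in genome.items():
            values = rng.normal(0.0, 1.0, len(seq))
            values[conserved[chrom]] += conserved_shift
            if coverage < 1.0:
                values[rng.random(len(seq)) >= coverage] = np.nan
            per_chrom[chrom] = values
        tracks[name] = per_chrom
    return tracks


def generate_expression(
    gene_model: GeneModel,
    seed: int = 0,
    n_housekeeping: int = 10,
    tissues: Sequence[str] = TISSUES,
    active_level: float = 300.0,
    inactive_level: float = 20.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic RMA-like expression (gene x tissue, long form) plus gene sets.

    Housekeeping genes express at ``active_level`` in every tissue; each other
    gene is assigned one tissue where it is active and stays near
    ``inactive_level`` elsewhere. Returns (expression, gene_sets) where
    gene_sets has columns gene_id, set_name (``housekeeping`` or the tissue).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in gene_model.genes]
    if n_housekeeping > len(gene_ids):
        raise ValueError("n_housekeeping exceeds the number of genes")
    order = rng.permutation(len(gene_ids))
    hk = {gene_ids[i] for i in order[:n_housekeeping]}
    assignment = {}
    for j, i in enumerate(order[n_housekeeping:]):
        assignment[gene_ids[i]] = tissues[j % len(tissues)]

    expr_rows, set_rows = [], []
    for gid in gene_ids:
        if gid in hk:
            set_rows.append(dict(gene_id=gid, set_name="housekeeping"))
        else:
            set_rows.append(dict(gene_id=gid, set_name=assignment[gid]))
        for tissue in tissues:
            active = gid in hk or assignment.get(gid) == tissue
            level = active_level if active else inactive_level
            expr_rows.append(
                dict(gene_id=gid, tissue=tissue,
                     value=float(level * rng.lognormal(0.0, 0.2)))
            )
    return pd.DataFrame(expr_rows), pd.DataFrame(set_rows)


def generate_tracks(
    genome: Genome,
    gene_model: GeneModel,
    seed: int = 0,
    coverage: float = 1.0,
    n_housekeeping: int = 10,
):
    """Convenience bundle: (conservation tracks, expression table, gene sets)."""
    tracks = generate_conservation_tracks(genome, gene_model, seed, coverage)
    expression, gene_sets = generate_expression(
        gene_model, seed + 1, n_housekeeping=n_housekeeping
    )
    return tracks, expression, gene_sets


def write_track_tsv(track: Mapping[str, np.ndarray], path: str) -> None:
    """Write one track as TSV (chrom, pos 1-based, value); missing rows omitted."""
    frames = []
    for chrom, values in track.items():
        covered = ~np.isnan(values)
        frames.append(pd.DataFrame(
            dict(chrom=chrom, pos=np.flatnonzero(covered) + 1, value=values[covered])
        ))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_track_tsv(path: str, chrom_lengths: Mapping[str, int]) -> Dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    track = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    for chrom, sub in df.groupby("chrom"):
        track[chrom][sub["pos"].to_numpy() - 1] = sub["value"].to_numpy()
    return track
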