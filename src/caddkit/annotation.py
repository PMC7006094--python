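"""Variant annotation: consequences, substitution severity, DNA shape,
conservation tracks, and assembly into a numeric feature matrix.

The consequence classifier is self-contained: it evaluates each variant
against the gene model (GFF3-derived) with a severity hierarchy of 14
categories, most severe first. When a variant hits several transcripts or
features, the most severe applicable category wins. Reverse-strand CDS
variants are evaluated on the reverse complement.

Feature-matrix assembly follows the CADD family recipe: categorical columns
are one-hot encoded, missing numeric values are imputed (median for generic
numerics, 0 for conservation tracks) with a companion was-missing indicator,
and every column is scaled by its training-set standard deviation. The
column catalogue, imputation values and divisors are serialized so scoring
time reuses exactly the training-time transform.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genemodel import GeneModel, Transcript
from .genome import revcomp
from .grantham import grantham

logger = logging.getLogger(__name__)

#: severity hierarchy, most severe first (rank 1..14)
DEFAULT_HIERARCHY: Tuple[str, ...] = (
    "splice_acceptor",
    "splice_donor",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "missense",
    "splice_region",
    "synonymous",
    "five_prime_utr",
    "three_prime_utr",
    "non_coding_transcript",
    "intronic",
    "upstream_downstream",
    "intergenic",
)

SHAPE_PARAMS = ("mgw", "roll", "prot", "helt")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class AnnotationConfig:
    hierarchy: Tuple[str, ...] = DEFAULT_HIERARCHY
    #: 1-based offsets into the intron that are splice donor/acceptor sites
    splice_site_intron: Tuple[int, int] = (1, 2)
    #: 1-based offsets into the intron that are splice region
    splice_region_intron: Tuple[int, int] = (3, 8)
    #: exonic bases adjacent to an intron that are splice region
    splice_region_exon: int = 3
    #: up/downstream flank around a transcript, in bases
    flank: int = 1000
    #: half-width of the sequence context used for shape features
    shape_radius: int = 4
    #: add severity x conservation interaction columns to the matrix
    include_interactions: bool = False

    def rank(self, category: str) -> int:
        return self.hierarchy.index(category) + 1


@dataclass(frozen=True)
class ShapeDelta:
    mgw_delta: Optional[float]
    roll_delta: Optional[float]
    prot_delta: Optional[float]
    helt_delta: Optional[float]

    @property
    def missing(self) -> bool:
        return self.mgw_delta is None


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

def _codon_change(
    t: Transcript, pos0: int, alt: str, genome: Mapping[str, str]
) -> Tuple[str, str, int]:
    """(ref_codon, alt_codon, codon_index) in translation orientation."""
    cds_pos = t.cds_positions()
    i = int(np.flatnonzero(cds_pos == pos0)[0])
    codon_idx = i // 3
    codon_pos = cds_pos[codon_idx * 3: codon_idx * 3 + 3]
    seq = genome[t.chrom]

    def tx_base(p, base=None):
        b = (base or seq[p]).upper()
        return b if t.strand == "+" else b.translate(_COMPLEMENT)

    ref_codon = "".join(tx_base(p) for p in codon_pos)
    alt_codon = "".join(
        tx_base(p, alt if p == pos0 else None) for p in codon_pos
    )
    return ref_codon, alt_codon, codon_idx


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _transcript_categories(
    t: Transcript,
    pos0: int,
    alt: str,
    genome: Mapping[str, str],
    cfg: AnnotationConfig,
) -> Tuple[List[str], Optional[str], Optional[str]]:
    """Applicable categories for one transcript, plus (ref_aa, alt_aa)."""
    cats: List[str] = []
    ref_aa = alt_aa = None

    exon_hit = any(a <= pos0 < b for a, b in t.exons)
    if exon_hit:
        if any(a <= pos0 < b for a, b in t.cds):
            ref_codon, alt_codon, codon_idx = _codon_change(t, pos0, alt, genome)
            ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
            if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
                cats.append("start_lost")
            elif ref_aa != "*" and alt_aa == "*":
                cats.append("stop_gained")
            elif ref_aa == "*" and alt_aa != "*":
                cats.append("stop_lost")
            elif ref_aa == alt_aa:
                cats.append("synonymous")
            else:
                cats.append("missense")
        elif any(a <= pos0 < b for a, b in t.utr5):
            cats.append("five_prime_utr")
        elif any(a <= pos0 < b for a, b in t.utr3):
            cats.append("three_prime_utr")
        else:
            cats.append("non_coding_transcript")
        # exonic splice region: within splice_region_exon bases of an intron
        for a, b in t.introns:
            if a - cfg.splice_region_exon <= pos0 < a or b <= pos0 < b + cfg.splice_region_exon:
                cats.append("splice_region")
                break
    else:
        for a, b in t.introns:
            if not a <= pos0 < b:
                continue
            if t.strand == "+":
                donor_off, acceptor_off = pos0 - a + 1, b - pos0
            else:
                donor_off, acceptor_off = b - pos0, pos0 - a + 1
            lo, hi = cfg.splice_site_intron
            rlo, rhi = cfg.splice_region_intron
            if lo <= donor_off <= hi:
                cats.append("splice_donor")
            elif lo <= acceptor_off <= hi:
                cats.append("splice_acceptor")
            elif rlo <= min(donor_off, acceptor_off) <= rhi:
                cats.append("splice_region")
            else:
                cats.append("intronic")
            break
        else:
            if t.start - cfg.flank <= pos0 < t.end + cfg.flank:
                cats.append("upstream_downstream")
    return cats, ref_aa, alt_aa


def annotate_consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_model: GeneModel,
    genome: Mapping[str, str],
    config: AnnotationConfig = AnnotationConfig(),
) -> Dict[str, object]:
    """Classify one SNV; returns {category, ref_aa, alt_aa}.

    ``pos`` is 1-based. The most severe applicable category across all
    overlapping transcripts and miRNAs is selected.
    """
    if chrom in genome and not 1 <= pos <= len(genome[chrom]):
        raise IndexError(f"position {chrom}:{pos} beyond chromosome end")
    pos0 = pos - 1
    best: Optional[str] = None
    best_aa: Tuple[Optional[str], Optional[str]] = (None, None)

    def consider(cat, aa=(None, None)):
        nonlocal best, best_aa
        if best is None or config.rank(cat) < config.rank(best):
            best = cat
            if aa[0] is not None:
                best_aa = aa
        elif aa[0] is not None and best_aa[0] is None and cat == best:
            best_aa = aa

    for gene in gene_model.genes:
        if gene.chrom != chrom:
            continue
        for t in gene.transcripts:
            if not t.start - config.flank <= pos0 < t.end + config.flank:
                continue
            cats, ref_aa, alt_aa = _transcript_categories(
                t, pos0, alt, genome, config
            )
            for cat in cats:
                consider(cat, (ref_aa, alt_aa))
    for m in gene_model.mirnas:
        if m.chrom == chrom and m.start <= pos0 < m.end:
            consider("non_coding_transcript")
    return dict(category=best or "intergenic",
                ref_aa=best_aa[0], alt_aa=best_aa[1])


def classify_consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_model: GeneModel,
    genome: Mapping[str, str],
    config: AnnotationConfig = AnnotationConfig(),
) -> str:
    """The consequence category only (see :func:`annotate_consequence`)."""
    return annotate_consequence(chrom, pos, ref, alt, gene_model, genome, config)[
        "category"
    ]


# ---------------------------------------------------------------------------
# DNA shape
# ---------------------------------------------------------------------------

def synthetic_shape_table(seed: int = 0) -> Dict[str, Dict[str, float]]:
    """Synthetic pentamer -> shape-parameter lookup.

    Deterministic stand-in values on realistic scales (minor groove width in
    angstrom around 5, roll/propeller twist/helix twist in degrees); they are
    generated pseudo-randomly per pentamer, not measured, and exist so that
    shape-delta features can be exercised without an external table. A real
    pentamer table with the same mapping shape can be passed anywhere this
    one is accepted.
    """
    rng = np.random.default_rng(seed)
    from itertools import product

    table = {}
    for pent in ("".join(p) for p in product("ACGT", repeat=5)):
        table[pent] = dict(
            mgw=float(rng.normal(5.0, 0.5)),
            roll=float(rng.normal(0.0, 2.0)),
            prot=float(rng.normal(-5.0, 2.0)),
            helt=float(rng.normal(34.0, 1.0)),
        )
    return table


def shape_delta(
    ref_context: str,
    alt_context: str,
    lookup: Mapping[str, Mapping[str, float]],
) -> ShapeDelta:
    """Mean shape over alt-context pentamer windows minus ref-context mean.

    Contexts must be equal-length windows centred on the variant. Any N in
    either context, or a pentamer absent from the lookup, marks all four
    deltas missing.
    """
    ref_context = ref_context.upper()
    alt_context = alt_context.upper()
    if len(ref_context) != len(alt_context):
        raise ValueError("contexts must have equal length")
    if len(ref_context) < 5 or "N" in ref_context or "N" in alt_context:
        return ShapeDelta(None, None, None, None)

    def means(context):
        sums = dict.fromkeys(SHAPE_PARAMS, 0.0)
        n = 0
        for i in range(len(context) - 4):
            entry = lookup.get(context[i:i + 5])
            if entry is None:
                return None
            for p in SHAPE_PARAMS:
                if p in entry:
                    sums[p] += entry[p]
            n += 1
        return {p: sums[p] / n for p in SHAPE_PARAMS}

    ref_mean, alt_mean = means(ref_context), means(alt_context)
    if ref_mean is None or alt_mean is None:
        return ShapeDelta(None, None, None, None)
    return ShapeDelta(*(alt_mean[p] - ref_mean[p] for p in SHAPE_PARAMS))


# ---------------------------------------------------------------------------
# conservation tracks
# ---------------------------------------------------------------------------

def annotate_tracks(
    chrom: str,
    pos: int,
    tracks: Mapping[str, Mapping[str, np.ndarray]],
) -> Dict[str, float]:
    """Per-track value at a 1-based position; NaN where uncovered."""
    out = {}
    for name, per_chrom in tracks.items():
        values = per_chrom.get(chrom)
        if values is None or not 1 <= pos <= len(values):
            out[name] = np.nan
        else:
            out[name] = float(values[pos - 1])
    return out


# ---------------------------------------------------------------------------
# raw per-variant annotation
# ---------------------------------------------------------------------------

def annotate_variants(
    variants: pd.DataFrame,
    gene_model: GeneModel,
    genome: Mapping[str, str],
    tracks: Mapping[str, Mapping[str, np.ndarray]],
    config: AnnotationConfig = AnnotationConfig(),
    shape_table: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Raw (pre-encoding) annotation table for a variant set.

    Adds: consequence category, Grantham distance (missense and friends),
    four shape deltas, and one column per conservation track.
    """
    if shape_table is None:
        shape_table = synthetic_shape_table()
    r = config.shape_radius
    rows = []
    for row in variants.itertuples():
        chrom, pos, ref, alt = row.chrom, int(row.pos), row.ref, row.alt
        ann = annotate_consequence(chrom, pos, ref, alt, gene_model, genome, config)
        g = None
        if ann["ref_aa"] is not None and ann["alt_aa"] is not None:
            g = grantham(ann["ref_aa"], ann["alt_aa"])

        seq = genome[chrom]
        pos0 = pos - 1
        if pos0 - r < 0 or pos0 + r + 1 > len(seq):
            sd = ShapeDelta(None, None, None, None)
        else:
            ref_ctx = seq[pos0 - r: pos0 + r + 1].upper()
            alt_ctx = ref_ctx[:r] + alt + ref_ctx[r + 1:]
            sd = shape_delta(ref_ctx, alt_ctx, shape_table)

        rec = dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            consequence=ann["category"],
            grantham=np.nan if g is None else g,
            mgw_delta=np.nan if sd.mgw_delta is None else sd.mgw_delta,
            roll_delta=np.nan if sd.roll_delta is None else sd.roll_delta,
            prot_delta=np.nan if sd.prot_delta is None else sd.prot_delta,
            helt_delta=np.nan if sd.helt_delta is None else sd.helt_delta,
        )
        for name, value in annotate_tracks(chrom, pos, tracks).items():
            rec[f"track_{name}"] = value
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

KEY_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class FeatureMatrix:
    """Encoded, imputed, scaled features plus the raw missingness mask."""

    frame: pd.DataFrame
    missing_mask: pd.DataFrame
    divisors: pd.Series
    fingerprint: str

    @property
    def columns(self) -> List[str]:
        return list(self.frame.columns)


class FeatureMatrixBuilder:
    """Learns the encoding/imputation/scaling transform on training variants
    and replays it verbatim on any later variant set (no leakage: divisors
    and imputation values come from the training rows only)."""

    def __init__(self, config: AnnotationConfig = AnnotationConfig()):
        self.config = config
        self.categories_: Optional[List[str]] = None
        self.impute_: Optional[Dict[str, float]] = None
        self.divisors_: Optional[pd.Series] = None
        self.columns_: Optional[List[str]] = None

    # numeric columns that default to "neutral 0" rather than the median
    @staticmethod
    def _imputes_to_zero(column: str) -> bool:
        return column.startswith("track_")

    def _numeric_columns(self, raw: pd.DataFrame) -> List[str]:
        skip = set(KEY_COLUMNS) | {"consequence", "class_label", "alt_frequency"}
        return [
            c for c in raw.columns
            if c not in skip and pd.api.types.is_numeric_dtype(raw[c])
        ]

    def fit(self, raw: pd.DataFrame) -> "FeatureMatrixBuilder":
        numeric = self._numeric_columns(raw)
        self.categories_ = sorted(raw["consequence"].unique())
        self.impute_ = {}
        for c in numeric:
            if self._imputes_to_zero(c):
                self.impute_[c] = 0.0
            else:
                med = raw[c].median()
                self.impute_[c] = float(0.0 if np.isnan(med) else med)
        encoded, _ = self._encode(raw)
        std = encoded.std(axis=0, ddof=0)
        self.divisors_ = std.where(std > 0, 1.0)
        self.columns_ = list(encoded.columns)
        return self

    def _encode(self, raw: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
        """One-hot + impute; returns (unscaled matrix, missingness mask)."""
        numeric = list(self.impute_)
        out = {}
        unseen = set(raw["consequence"].unique()) - set(self.categories_)
        if unseen:
            warnings.warn(
                f"consequence categories unseen in training map to all-zero "
                f"indicators: {sorted(unseen)}"
            )
        for cat in self.categories_:
            out[f"consequence={cat}"] = (raw["consequence"] == cat).astype(float)
        mask = {}
        for c in numeric:
            col = raw[c] if c in raw.columns else pd.Series(np.nan, index=raw.index)
            missing = col.isna()
            out[c] = col.fillna(self.impute_[c]).astype(float)
            out[f"{c}_missing"] = missing.astype(float)
            mask[c] = missing
        if self.config.include_interactions:
            severity = raw["consequence"].map(
                {c: len(self.config.hierarchy) - self.config.rank(c)
                 for c in self.config.hierarchy}
            ).fillna(0.0)
            for c in numeric:
                if self._imputes_to_zero(c):
                    out[f"severity_x_{c}"] = severity.to_numpy() * out[c].to_numpy()
        frame = pd.DataFrame(out, index=raw.index)
        return frame, pd.DataFrame(mask, index=raw.index)

    def transform(self, raw: pd.DataFrame) -> FeatureMatrix:
        if self.columns_ is None:
            raise RuntimeError("builder is not fitted")
        encoded, mask = self._encode(raw)
        encoded = encoded.reindex(columns=self.columns_, fill_value=0.0)
        scaled = encoded / self.divisors_
        return FeatureMatrix(scaled, mask, self.divisors_.copy(), self.fingerprint())

    def fit_transform(self, raw: pd.DataFrame) -> FeatureMatrix:
        return self.fit(raw).transform(raw)

    def fingerprint(self) -> str:
        payload = json.dumps(
            [self.columns_, [round(float(d), 12) for d in self.divisors_]],
        ).encode()
        return hashlib.sha1(payload).hexdigest()

    # -- sidecar ----------------------------------------------------------
    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                dict(
                    categories=self.categories_,
                    impute=self.impute_,
                    divisors={c: float(d) for c, d in self.divisors_.items()},
                    columns=self.columns_,
                    include_interactions=self.config.include_interactions,
                    fingerprint=self.fingerprint(),
                ),
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path: str,
                  config: AnnotationConfig = AnnotationConfig()) -> "FeatureMatrixBuilder":
        with open(path) as fh:
            blob = json.load(fh)
        builder = cls(config)
        builder.categories_ = blob["categories"]
        builder.impute_ = {k: float(v) for k, v in blob["impute"].items()}
        builder.columns_ = blob["columns"]
        builder.divisors_ = pd.Series(blob["divisors"])[blob["columns"]]
        return builder


def build_feature_matrix(
    variants: pd.DataFrame,
    gene_model: GeneModel,
    genome: Mapping[str, str],
    tracks: Mapping[str, Mapping[str, np.ndarray]],
    config: AnnotationConfig = AnnotationConfig(),
    builder: Optional[FeatureMatrixBuilder] = None,
    shape_table: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> Tuple[FeatureMatrix, FeatureMatrixBuilder]:
    """Annotate and encode variants.

    With ``builder`` given (already fitted on training variants), its stored
    transform is replayed; otherwise a new builder is fitted on these rows.
    """
    raw = annotate_variants(variants, gene_model, genome, tracks, config, shape_table)
    if builder is None:
        builder = FeatureMatrixBuilder(config)
        builder.fit(raw)
    return builder.transform(raw), builder
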