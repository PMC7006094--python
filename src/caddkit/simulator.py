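"""De novo SNV simulation from ancestor-derived substitution rates.

The proxy-deleterious class is built by (1) counting substitutions between
pairs of increasingly distant ancestor sequences in fixed genomic windows,
separately for CpG and non-CpG contexts, and (2) sampling de novo variants
from the resulting position- and context-dependent rates. Such variants have
experienced no purifying selection, so relative to the derived class they are
enriched in deleterious alleles.

Windows are half-open tiles ``[k*W, (k+1)*W)`` (default W = 100 kb) with the
last partial window kept. Context is the 5'-CG-3' dinucleotide on the older
sequence of a pair (both the C and the G count as CpG). Rates from windows
with zero opportunity fall back to the chromosome-wide, then genome-wide,
pooled rate so sparse fixtures have no zero-probability deserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genome import BASES, Genome, cpg_mask, encode, n_windows

SeqPair = Tuple[Union[str, Mapping[str, str]], Union[str, Mapping[str, str]]]

CONTEXTS = ("nonCpG", "CpG")


@dataclass(frozen=True)
class SimulatorConfig:
    n_variants: int
    seed: int = 0
    restrict_to_known_ancestral: bool = True

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


@dataclass
class RateTable:
    """Windowed substitution counts and opportunities.

    ``counts[chrom]`` has shape (n_windows, 2, 4, 4): substitutions from base
    X (axis 2) to base Y (axis 3) per context (0 = non-CpG, 1 = CpG);
    ``opportunities[chrom]`` has shape (n_windows, 2, 4): columns with base X
    in the older sequence.
    """

    window_size: int
    counts: Dict[str, np.ndarray] = field(default_factory=dict)
    opportunities: Dict[str, np.ndarray] = field(default_factory=dict)

    def rates(self, chrom: str) -> np.ndarray:
        """Raw per-window rates; NaN where the opportunity count is zero."""
        opp = self.opportunities[chrom][..., None]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(opp > 0, self.counts[chrom] / np.maximum(opp, 1), np.nan)

    def pooled_rates(self, chroms: Optional[Sequence[str]] = None) -> np.ndarray:
        """(2, 4, 4) rates pooled over windows of the given chromosomes."""
        chroms = list(self.counts) if chroms is None else list(chroms)
        c = sum(self.counts[ch].sum(axis=0) for ch in chroms)
        o = sum(self.opportunities[ch].sum(axis=0) for ch in chroms)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(o[..., None] > 0, c / np.maximum(o[..., None], 1), np.nan)

    def effective_rates(self, chrom: str) -> np.ndarray:
        """Per-window rates with undefined cells imputed from the chromosome-
        wide, then genome-wide, pooled average (0 if undefined everywhere)."""
        r = self.rates(chrom)
        for fallback in (self.pooled_rates([chrom]), self.pooled_rates(), 0.0):
            nan = np.isnan(r)
            if not nan.any():
                break
            filler = np.broadcast_to(fallback, r.shape)
            r = np.where(nan, filler, r)
        return np.nan_to_num(r, nan=0.0)

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.counts):
            r = self.rates(chrom)
            opp = self.opportunities[chrom]
            for w in range(r.shape[0]):
                for ctx_i, ctx in enumerate(CONTEXTS):
                    for xi, x in enumerate(BASES):
                        for yi, y in enumerate(BASES):
                            if xi == yi:
                                continue
                            rows.append(dict(
                                chrom=chrom, window_start=w * self.window_size,
                                context=ctx, ref=x, alt=y,
                                rate=r[w, ctx_i, xi, yi],
                                opportunities=int(opp[w, ctx_i, xi]),
                                count=int(self.counts[chrom][w, ctx_i, xi, yi]),
                            ))
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, window_size: Optional[int] = None) -> "RateTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if window_size is None:
            starts = sorted(df.window_start.unique())
            window_size = int(starts[1] - starts[0]) if len(starts) > 1 else int(
                df.window_start.max() + 1 or 1
            )
        table = cls(window_size=window_size)
        base_i = {b: i for i, b in enumerate(BASES)}
        ctx_i = {c: i for i, c in enumerate(CONTEXTS)}
        for chrom, sub in df.groupby("chrom"):
            nw = int(sub.window_start.max() // window_size) + 1
            counts = np.zeros((nw, 2, 4, 4))
            opp = np.zeros((nw, 2, 4))
            for row in sub.itertuples():
                w = int(row.window_start // window_size)
                ci, xi, yi = ctx_i[row.context], base_i[row.ref], base_i[row.alt]
                counts[w, ci, xi, yi] = row.count
                opp[w, ci, xi] = row.opportunities
            table.counts[chrom] = counts
            table.opportunities[chrom] = opp
        return table


def _normalize_pair(pair: SeqPair) -> Tuple[Mapping[str, str], Mapping[str, str]]:
    older, younger = pair
    if isinstance(older, str):
        older = {"chr1": older}
    if isinstance(younger, str):
        younger = {"chr1": younger}
    return older, younger


def estimate_rates(
    ancestor_pairs: Sequence[SeqPair], window_size: int = 100_000
) -> RateTable:
    """Estimate windowed substitution rates from gapless ancestor-pair
    alignments, pooling counts equally over pairs.

    Each pair is (older, younger) — either bare sequences or chrom->sequence
    mappings of equal per-chromosome length.
    """
    if window_size < 1:
        raise ValueError("window_size must be positive")
    table = RateTable(window_size=window_size)
    for pair in ancestor_pairs:
        older, younger = _normalize_pair(pair)
        for chrom in older:
            if chrom not in younger or len(older[chrom]) != len(younger[chrom]):
                raise ValueError(
                    f"alignment length mismatch on {chrom!r}"
                )
            o = encode(older[chrom])
            y = encode(younger[chrom])
            known = (o != 255) & (y != 255)
            ctx = cpg_mask(o).astype(np.intp)
            w = (np.arange(o.size) // window_size).astype(np.intp)
            nw = n_windows(o.size, window_size)
            if chrom not in table.counts:
                table.counts[chrom] = np.zeros((nw, 2, 4, 4))
                table.opportunities[chrom] = np.zeros((nw, 2, 4))
            k = known
            np.add.at(table.opportunities[chrom],
                      (w[k], ctx[k], o[k].astype(np.intp)), 1)
            diff = k & (o != y)
            np.add.at(table.counts[chrom],
                      (w[diff], ctx[diff], o[diff].astype(np.intp),
                       y[diff].astype(np.intp)), 1)
    return table


def simulate_variants(
    rate_table: RateTable,
    host: Mapping[str, str],
    known_ancestral_mask: Optional[Mapping[str, np.ndarray]] = None,
    config: SimulatorConfig = SimulatorConfig(n_variants=1000),
    exclude_positions: Optional[Sequence[Tuple[str, int]]] = None,
) -> pd.DataFrame:
    """Draw ``config.n_variants`` de novo SNVs (class 1) from the rate table.

    Sampling is weighted without replacement over (site, alternate-allele)
    pairs, with weights given by the window- and context-appropriate rate for
    the host base at each site. Sites outside ``known_ancestral_mask`` (when
    supplied and ``restrict_to_known_ancestral`` is on) and any 1-based
    ``exclude_positions`` get zero weight.
    """
    rng = np.random.default_rng(config.seed)
    excluded = set(exclude_positions or ())

    chrom_names: List[str] = []
    weight_blocks: List[np.ndarray] = []
    pos_blocks: List[np.ndarray] = []
    alt_blocks: List[np.ndarray] = []
    ref_blocks: List[np.ndarray] = []
    for chrom, seq in host.items():
        if chrom not in rate_table.counts:
            raise ValueError(f"rate table does not cover chromosome {chrom!r}")
        codes = encode(seq)
        ctx = cpg_mask(codes).astype(np.intp)
        w = (np.arange(codes.size) // rate_table.window_size).astype(np.intp)
        eff = rate_table.effective_rates(chrom)  # (nw, 2, 4, 4)
        known = codes != 255
        site_weights = np.zeros((codes.size, 4))
        site_weights[known] = eff[w[known], ctx[known], codes[known].astype(np.intp)]
        # no self-substitutions
        site_weights[np.arange(codes.size)[known], codes[known].astype(np.intp)] = 0.0
        if config.restrict_to_known_ancestral and known_ancestral_mask is not None:
            site_weights[~known_ancestral_mask[chrom].astype(bool)] = 0.0
        if excluded:
            drop = [p - 1 for c, p in excluded if c == chrom and 1 <= p <= codes.size]
            site_weights[drop] = 0.0
        keep = site_weights.ravel() > 0
        idx = np.flatnonzero(keep)
        chrom_names.append(chrom)
        weight_blocks.append(site_weights.ravel()[idx])
        pos_blocks.append(idx // 4)
        alt_blocks.append(idx % 4)
        ref_blocks.append(codes[idx // 4])

    weights = np.concatenate(weight_blocks) if weight_blocks else np.array([])
    if config.n_variants > weights.size:
        raise ValueError(
            f"requested {config.n_variants} variants but only {weights.size} "
            "eligible (site, alt) combinations"
        )
    # Efraimidis-Spirakis via Gumbel keys: top-n keys realise weighted
    # sampling without replacement
    keys = np.log(weights) + rng.gumbel(size=weights.size)
    top = np.argpartition(-keys, config.n_variants - 1)[: config.n_variants]

    block_sizes = [b.size for b in weight_blocks]
    offsets = np.cumsum([0] + block_sizes)
    rows = []
    for j in top:
        b = int(np.searchsorted(offsets, j, side="right")) - 1
        local = j - offsets[b]
        rows.append(dict(
            chrom=chrom_names[b],
            pos=int(pos_blocks[b][local]) + 1,
            ref=BASES[int(ref_blocks[b][local])],
            alt=BASES[int(alt_blocks[b][local])],
            alt_frequency=np.nan,
            class_label=1,
        ))
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos", "alt"]).reset_index(drop=True)
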