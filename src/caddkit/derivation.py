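"""Derived (proxy-benign/neutral) variant class construction.

A *derived* variant is an allele (nearly) fixed in the study population that
differs from the allele of the inferred ancestor: such alleles reached
fixation by drift or positive selection and are therefore depleted in
deleterious variants. The screen applied here:

(a) the ancestral allele at the site is known (not N);
(b) one population allele has frequency above ``high_af_threshold`` (strictly
    greater than, default 0.9) and differs from the ancestral allele;
(c) the site is discarded if any allele with frequency above
    ``ancestral_af_ceiling`` (default 0.05) equals the ancestral allele —
    i.e. the ancestral allele still segregates appreciably;
(d) with ``adjacency_exclusion`` (default on), sites with another variant
    site at distance exactly 1 bp are discarded, guarding against artifacts
    from misaligned indels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .genome import Genome

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class DerivationConfig:
    high_af_threshold: float = 0.9
    ancestral_af_ceiling: float = 0.05
    adjacency_exclusion: bool = True
    #: count segregating population sites (not only fixed differences) as
    #: "variant sites" for the adjacency rule
    adjacency_counts_segregating: bool = True

    def __post_init__(self):
        if not 0.0 < self.ancestral_af_ceiling < self.high_af_threshold < 1.0:
            raise ValueError(
                "need 0 < ancestral_af_ceiling < high_af_threshold < 1"
            )


def find_derived_variants(
    sites: pd.DataFrame,
    ancestor: Mapping[str, str],
    config: DerivationConfig = DerivationConfig(),
    reference: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Select derived variants (class 0) from a biallelic site table.

    ``sites`` needs columns chrom, pos (1-based), ref, alt, af (alternate
    allele frequency). ``ancestor`` supplies the ancestral allele per
    position. If ``reference`` is given, fixed reference-vs-ancestor
    differences also count as variant sites for the adjacency rule.

    Returns a DataFrame with columns chrom, pos, ref (ancestral allele),
    alt (derived allele), alt_frequency, class_label (0).
    """
    required = {"chrom", "pos", "ref", "alt", "af"}
    if not required.issubset(sites.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")

    variant_positions: Set[Tuple[str, int]] = set()
    if config.adjacency_exclusion:
        for row in sites.itertuples():
            variant_positions.add((row.chrom, int(row.pos)))
        if reference is not None:
            for chrom, anc_seq in ancestor.items():
                if chrom not in reference:
                    continue
                ref_seq = reference[chrom]
                n = min(len(ref_seq), len(anc_seq))
                a = np.frombuffer(anc_seq[:n].upper().encode(), dtype="S1")
                r = np.frombuffer(ref_seq[:n].upper().encode(), dtype="S1")
                for pos0 in np.flatnonzero(a != r):
                    variant_positions.add((chrom, int(pos0) + 1))

    multiallelic = set(
        map(tuple, sites.loc[sites.duplicated(["chrom", "pos"], keep=False),
                             ["chrom", "pos"]].itertuples(index=False))
    )
    out_rows = []
    for row in sites.itertuples():
        chrom, pos = row.chrom, int(row.pos)
        ref, alt, af = row.ref.upper(), row.alt.upper(), float(row.af)
        if ref not in VALID_BASES or alt not in VALID_BASES or ref == alt:
            raise ValueError(f"non-SNV record at {chrom}:{pos} ({ref}>{alt})")
        if chrom not in ancestor or not 1 <= pos <= len(ancestor[chrom]):
            raise ValueError(f"site {chrom}:{pos} outside ancestor coverage")
        if (chrom, pos) in multiallelic:
            logger.warning("multi-allelic site at %s:%d skipped", chrom, pos)
            continue
        ancestral = ancestor[chrom][pos - 1].upper()
        if ancestral not in VALID_BASES:  # unknown ancestral allele
            continue

        eps = 1e-9  # guard strict comparisons against float round-off
        freqs = {ref: 1.0 - af, alt: af}
        major = [b for b, f in freqs.items() if f > config.high_af_threshold + eps]
        if not major or major[0] == ancestral:
            continue
        derived_allele = major[0]
        # (c): ancestral allele still segregating above the ceiling
        if freqs.get(ancestral, 0.0) > config.ancestral_af_ceiling + eps:
            continue
        # (d): adjacency to any other variant site
        if config.adjacency_exclusion and (
            (chrom, pos - 1) in variant_positions
            or (chrom, pos + 1) in variant_positions
        ):
            continue
        out_rows.append(
            dict(chrom=chrom, pos=pos, ref=ancestral, alt=derived_allele,
                 alt_frequency=freqs[derived_allele], class_label=0)
        )

    columns = ["chrom", "pos", "ref", "alt", "alt_frequency", "class_label"]
    if not out_rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(out_rows, columns=columns).sort_values(
        ["chrom", "pos"]
    ).reset_index(drop=True)


def write_variant_tsv(variants: pd.DataFrame, path: str) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variant_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
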