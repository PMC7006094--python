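"""PHRED-like log-rank scores and per-position browser tracks.

Raw classifier posteriors are sorted in descending order; the variant at
rank i of N receives the score ``-10 * log10(i / N)``. Rank 1 gets the
maximum, rank N gets 0, and by construction the top 1% and 0.1% of variants
score above 20 and 30 respectively, for any N. Tied raw scores share the
rank of the first element of the tied block, so equal inputs map to equal
(and maximal-within-block) scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ScoreRanking:
    """Raw scores with their descending-sort ranks and PHRED-like scores."""

    raw: np.ndarray
    rank: np.ndarray  # 1 = highest raw score; ties share the minimum rank
    phred: np.ndarray
    N: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(raw=self.raw, rank=self.rank, phred=self.phred))


def phred_transform(raw_scores: Sequence[float]) -> ScoreRanking:
    """Rank-transform raw scores onto the PHRED-like scale.

    Ranks are assigned on the descending sort; ``phred = -10*log10(rank/N)``.
    Order is preserved: higher raw score never yields a lower PHRED score.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one raw score")
    if np.isnan(raw).any():
        raise ValueError("raw scores contain NaN")
    rank = rankdata(-raw, method="min").astype(np.int64)
    phred = -10.0 * np.log10(rank / raw.size) + 0.0  # +0.0 drops -0.0 at rank N
    return ScoreRanking(raw=raw, rank=rank, phred=phred, N=int(raw.size))


def percentile_of(score: float, reference: Sequence[float]) -> float:
    """Percentile of ``score`` within a reference score set.

    Defined as 100 x (fraction of reference scores strictly below the query).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference set is empty")
    return 100.0 * float(np.count_nonzero(ref < score)) / ref.size


def summarize_positions(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-position max/median/min/std over the 3 alternate-allele scores.

    ``scored`` needs columns chrom, pos, phred with exactly 3 rows per
    (chrom, pos); the standard deviation is the population formula over the
    three values. Output is in coordinate order.
    """
    counts = scored.groupby(["chrom", "pos"]).size()
    bad = counts[counts != 3]
    if len(bad):
        chrom, pos = bad.index[0]
        raise ValueError(
            f"incomplete scoring: {chrom}:{pos} has {bad.iloc[0]} alternates "
            "(expected 3)"
        )
    g = scored.groupby(["chrom", "pos"])["phred"]
    out = pd.DataFrame(dict(
        max=g.max(),
        median=g.median(),
        min=g.min(),
        std=g.std(ddof=0),
    )).reset_index()
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def score_table(
    variants: pd.DataFrame, raw: Sequence[float], phred: Sequence[float]
) -> pd.DataFrame:
    """Assemble the user-facing score table (sorted by chrom, pos, alt)."""
    df = variants[["chrom", "pos", "ref", "alt"]].copy()
    df["raw"] = np.asarray(raw, dtype=float)
    df["phred"] = np.round(np.asarray(phred, dtype=float), 3)
    return df.sort_values(["chrom", "pos", "alt"]).reset_index(drop=True)


def write_score_table(df: pd.DataFrame, path: str, tabix: bool = False) -> str:
    """Write a coordinate-sorted score TSV; optionally bgzip + tabix index.

    Returns the path of the file written (``path + '.gz'`` when indexing).
    """
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    if not tabix:
        return path
    import pysam

    gz = path + ".gz"
    pysam.tabix_compress(path, gz, force=True)
    pysam.tabix_index(gz, force=True, seq_col=0, start_col=1, end_col=1,
                      line_skip=1)
    return gz


def write_summary_tracks(
    summary: pd.DataFrame, prefix: str
) -> Mapping[str, str]:
    """Write four bedGraph-style TSVs (max, median, min, std) and return the
    path per statistic."""
    paths = {}
    for stat in ("max", "median", "min", "std"):
        out = pd.DataFrame(dict(
            chrom=summary["chrom"],
            start=summary["pos"] - 1,
            end=summary["pos"],
            value=np.round(summary[stat], 3),
        ))
        paths[stat] = f"{prefix}.{stat}.bedgraph"
        out.to_csv(paths[stat], sep="\t", index=False, header=False)
    return paths
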