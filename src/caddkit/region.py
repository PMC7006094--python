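"""Region-level rank tests on a score track.

All analyses share the same machinery: one-tailed Mann-Whitney U-tests with
the ROC-AUC effect size U/(n1*n2), Bonferroni correction over the test
family, and "significant" meaning adjusted p < 0.05. Per-site scores come
from a per-position summary of the three alternate-allele scores — maximum
for the miRNA/intron/tissue analyses, minimum for the codon analysis.

P-values use exact enumeration over label assignments when the combined
sample size is at most 12 (correct under ties), and the normal approximation
with continuity and tie correction otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genemodel import GeneModel
from .genome import BASES

logger = logging.getLogger(__name__)

EXACT_LIMIT = 12
ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float  # Mann-Whitney U for the first sample
    p_value: float
    effect_size: float  # U / (n1 * n2), a ROC-AUC
    direction: str  # the one-tailed alternative tested
    n1: int
    n2: int
    p_adjusted: float = np.nan

    def adjusted(self, m: int) -> "TestResult":
        return replace(self, p_adjusted=min(1.0, self.p_value * m))

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if np.isfinite(self.p_adjusted) else self.p_value
        return p < ALPHA


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Pairs with x > y plus half the ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_one_tailed(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> TestResult:
    """One-tailed Mann-Whitney U-test of ``x`` against ``y``.

    ``alternative='greater'`` tests whether x is stochastically larger than
    y; ``'less'`` the reverse. The reported U and effect size are always for
    x over y, whatever the tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    u = _u_statistic(x, y)

    n1, n2 = x.size, y.size
    if n1 + n2 <= EXACT_LIMIT:
        combined = np.concatenate([x, y])
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(combined[mask], combined[~mask])
            total += 1
            if alternative == "greater":
                extreme += u_perm >= u - 1e-12
            else:
                extreme += u_perm <= u + 1e-12
        p = extreme / total
    else:
        p = float(
            mannwhitneyu(x, y, alternative=alternative, method="asymptotic",
                         use_continuity=True).pvalue
        )
    return TestResult(
        statistic=u, p_value=p, effect_size=u / (n1 * n2),
        direction=alternative, n1=n1, n2=n2,
    )


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else m
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# score-track plumbing
# ---------------------------------------------------------------------------

def site_score_map(
    summary: pd.DataFrame, stat: str, chrom_lengths: Mapping[str, int]
) -> Dict[str, np.ndarray]:
    """Expand a per-position summary table into chrom -> score array (NaN
    where the track has no value). ``stat`` is max/median/min/std."""
    track = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    for chrom, sub in summary.groupby("chrom"):
        track[chrom][sub["pos"].to_numpy() - 1] = sub[stat].to_numpy()
    return track


def _scores_at(track: Mapping[str, np.ndarray], chrom: str,
               positions: np.ndarray) -> np.ndarray:
    values = track[chrom][positions]
    return values[~np.isnan(values)]


# ---------------------------------------------------------------------------
# codon analysis
# ---------------------------------------------------------------------------

def codon_position_tests(
    gene_model: GeneModel,
    site_scores: Mapping[str, np.ndarray],
    alpha: float = ALPHA,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise codon-position score contrasts over single-transcript genes.

    For each gene, per-site scores (conventionally the per-position minimum
    over alternates) are grouped by codon position 1/2/3 and each ordered
    pair (larger, smaller) is tested one-tailed. P-values are Bonferroni
    corrected over genes, separately per comparison. Returns (per-gene
    results, 3x3 count matrix of significant tests with rows = smaller
    position, columns = larger position).
    """
    per_gene_rows = []
    for gene in gene_model.single_transcript_genes():
        t = gene.transcripts[0]
        pos, codon_pos = t.codon_positions()
        if pos.size % 3 != 0:
            logger.warning("gene %s CDS length not divisible by 3; skipped",
                           gene.gene_id)
            continue
        sets = {
            k: _scores_at(site_scores, t.chrom, pos[codon_pos == k])
            for k in (1, 2, 3)
        }
        if any(s.size == 0 for s in sets.values()):
            continue
        for larger, smaller in itertools.permutations((1, 2, 3), 2):
            res = mann_whitney_one_tailed(sets[larger], sets[smaller], "greater")
            per_gene_rows.append(dict(
                gene_id=gene.gene_id, larger=larger, smaller=smaller,
                U=res.statistic, p_value=res.p_value,
                effect_size=res.effect_size,
            ))
    per_gene = pd.DataFrame(per_gene_rows)
    counts = pd.DataFrame(0, index=[1, 2, 3], columns=[1, 2, 3])
    if len(per_gene):
        for (larger, smaller), sub in per_gene.groupby(["larger", "smaller"]):
            adj = bonferroni(sub["p_value"].to_numpy())
            per_gene.loc[sub.index, "p_adjusted"] = adj
            counts.loc[smaller, larger] = int((adj < alpha).sum())
    counts.index.name = "smaller"
    counts.columns.name = "larger"
    return per_gene, counts


# ---------------------------------------------------------------------------
# miRNA vs flanks
# ---------------------------------------------------------------------------

def mirna_flank_test(
    gene_model: GeneModel,
    site_scores: Mapping[str, np.ndarray],
    training_positions: Optional[Sequence[Tuple[str, int]]] = None,
    alpha: float = ALPHA,
) -> Tuple[TestResult, pd.DataFrame]:
    """miRNA scores against equally long up- plus downstream flanks.

    Per miRNA: one-tailed test (miRNA > pooled flanks), Bonferroni over
    miRNAs. Globally: all miRNA sites pooled against all flank sites.
    miRNAs overlapping any 1-based training position are excluded when a
    training set is supplied. Flanks are truncated at contig edges (logged).
    """
    training: Set[Tuple[str, int]] = set(training_positions or ())
    mirna_pool: List[np.ndarray] = []
    flank_pool: List[np.ndarray] = []
    rows = []
    for m in gene_model.mirnas:
        if training and any(
            (m.chrom, p) in training for p in range(m.start + 1, m.end + 1)
        ):
            continue
        length = m.end - m.start
        chrom_len = site_scores[m.chrom].size
        up_lo = max(0, m.start - length)
        if m.start - length < 0 or m.end + length > chrom_len:
            logger.info("flank of %s truncated at contig edge", m.mirna_id)
        up = np.arange(up_lo, m.start)
        down = np.arange(m.end, min(chrom_len, m.end + length))
        inside = _scores_at(site_scores, m.chrom, np.arange(m.start, m.end))
        flank = _scores_at(site_scores, m.chrom, np.concatenate([up, down]))
        if inside.size == 0 or flank.size == 0:
            continue
        res = mann_whitney_one_tailed(inside, flank, "greater")
        rows.append(dict(
            mirna_id=m.mirna_id, n_mirna=res.n1, n_flank=res.n2,
            U=res.statistic, p_value=res.p_value, effect_size=res.effect_size,
        ))
        mirna_pool.append(inside)
        flank_pool.append(flank)
    if not mirna_pool:
        raise ValueError("no testable miRNA after exclusions")
    per_mirna = pd.DataFrame(rows)
    per_mirna["p_adjusted"] = bonferroni(per_mirna["p_value"].to_numpy())
    per_mirna["significant"] = per_mirna["p_adjusted"] < alpha
    global_result = mann_whitney_one_tailed(
        np.concatenate(mirna_pool), np.concatenate(flank_pool), "greater"
    )
    return global_result, per_mirna


# ---------------------------------------------------------------------------
# intron-position analysis
# ---------------------------------------------------------------------------

def intron_position_tests(
    gene_model: GeneModel,
    site_scores: Mapping[str, np.ndarray],
    max_position: int = 20,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Does intron k score higher than the other introns of its transcript?

    For each transcript with at least two introns and each intron ordinal k
    (1-based, transcription order), the sites of intron k are tested
    one-tailed against the pooled sites of all other introns of the same
    transcript. Bonferroni is applied per ordinal across transcripts; the
    rejection count is reported normalized by the number of tests, which
    shrinks as k grows.
    """
    p_by_position: Dict[int, List[float]] = {}
    for t in gene_model.transcripts():
        introns = t.introns_by_position
        if len(introns) < 2:
            continue
        per_intron = [
            _scores_at(site_scores, t.chrom, np.arange(a, b)) for a, b in introns
        ]
        for k in range(min(len(introns), max_position)):
            x = per_intron[k]
            others = [s for j, s in enumerate(per_intron) if j != k]
            y = np.concatenate(others) if others else np.array([])
            if x.size == 0 or y.size == 0:
                continue
            res = mann_whitney_one_tailed(x, y, "greater")
            p_by_position.setdefault(k + 1, []).append(res.p_value)
    rows = []
    for k in sorted(p_by_position):
        p = np.asarray(p_by_position[k])
        adj = bonferroni(p)
        n_sig = int((adj < alpha).sum())
        rows.append(dict(
            position=k, n_tests=p.size, n_significant=n_sig,
            normalized_fraction=n_sig / p.size,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tissue-specific vs housekeeping genes
# ---------------------------------------------------------------------------

def tissue_vs_housekeeping(
    expression: pd.DataFrame,
    gene_sets: pd.DataFrame,
    gene_model: GeneModel,
    site_scores: Mapping[str, np.ndarray],
    min_expression: float = 100.0,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-tissue rank test of CDS site scores against housekeeping genes.

    Genes pass the activity filter when their expression in their own set's
    tissue (mean over tissues for housekeeping genes) reaches
    ``min_expression``. Each gene contributes its deduplicated CDS sites
    (a CDS interval shared by several transcripts counts once), annotated
    with the per-site summary score. Both one-tailed alternatives are
    reported: p_value for tissue < housekeeping (the headline direction) and
    p_value_reverse for the opposite tail; the ROC-AUC is for housekeeping
    over tissue. Bonferroni is applied across tissues per tail.
    """
    wide = expression.pivot_table(index="gene_id", columns="tissue",
                                  values="value")
    sets = dict(gene_sets[["gene_id", "set_name"]].itertuples(index=False))
    genes_by_id = {g.gene_id: g for g in gene_model.genes}

    def gene_active(gid: str, set_name: str) -> bool:
        if gid not in wide.index:
            return False
        if set_name == "housekeeping":
            return float(wide.loc[gid].mean()) >= min_expression
        if set_name not in wide.columns:
            return False
        return float(wide.loc[gid, set_name]) >= min_expression

    def gene_scores(gid: str) -> np.ndarray:
        gene = genes_by_id.get(gid)
        if gene is None:
            return np.array([])
        positions: Set[int] = set()
        for t in gene.transcripts:
            for a, b in t.cds:
                positions.update(range(a, b))
        return _scores_at(site_scores, gene.chrom,
                          np.fromiter(sorted(positions), dtype=int))

    pooled: Dict[str, List[np.ndarray]] = {}
    for gid, set_name in sets.items():
        if not gene_active(gid, set_name):
            continue
        s = gene_scores(gid)
        if s.size:
            pooled.setdefault(set_name, []).append(s)

    if "housekeeping" not in pooled:
        raise ValueError("housekeeping set empty after the expression filter")
    hk = np.concatenate(pooled.pop("housekeeping"))
    tissues = sorted(set(sets.values()) - {"housekeeping"})
    rows = []
    for tissue in tissues:
        if tissue not in pooled:
            raise ValueError(
                f"tissue set {tissue!r} empty after the expression filter"
            )
        ts = np.concatenate(pooled[tissue])
        forward = mann_whitney_one_tailed(hk, ts, "greater")  # tissue < hk
        reverse = mann_whitney_one_tailed(hk, ts, "less")
        rows.append(dict(
            tissue=tissue, n_tissue=ts.size, n_housekeeping=hk.size,
            p_value=forward.p_value, p_value_reverse=reverse.p_value,
            roc_auc_housekeeping_vs_tissue=forward.effect_size,
        ))
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bonferroni(out["p_value"].to_numpy())
    out["p_adjusted_reverse"] = bonferroni(out["p_value_reverse"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    return out


# ---------------------------------------------------------------------------
# prioritization of segregating variants
# ---------------------------------------------------------------------------

def prioritize_segregating(
    variants: pd.DataFrame, top_k: int = 20
) -> pd.DataFrame:
    """Rank variants by PHRED-like score times alternate allele frequency.

    ``variants`` needs columns phred and alt_frequency (in [0, 1]); the
    top_k rows by the product are returned with both factors.
    """
    freq = variants["alt_frequency"].to_numpy(dtype=float)
    if np.any((freq < 0) | (freq > 1) | ~np.isfinite(freq)):
        raise ValueError("alt_frequency outside [0, 1]")
    out = variants.copy()
    out["phred_x_freq"] = out["phred"] * out["alt_frequency"]
    out = out.sort_values("phred_x_freq", ascending=False, kind="mergesort")
    return out.head(top_k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# genetic-code enumeration
# ---------------------------------------------------------------------------

def codon_position_nonsynonymous_fractions() -> Dict[int, float]:
    """Fraction of non-synonymous single-base changes per codon position.

    Brute-force over all 64 codons and 3 alternates per position under the
    standard genetic code (a change to or from a stop codon counts as
    non-synonymous). The biological expectation is position 2 > 1 > 3.
    """
    from Bio.Seq import Seq

    fractions = {}
    for position in (1, 2, 3):
        total = nonsyn = 0
        for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
            aa = str(Seq(codon).translate())
            for alt in BASES:
                if alt == codon[position - 1]:
                    continue
                mutated = codon[: position - 1] + alt + codon[position:]
                total += 1
                if str(Seq(mutated).translate()) != aa:
                    nonsyn += 1
        fractions[position] = nonsyn / total
    return fractions
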