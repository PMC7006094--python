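"""Test-set evaluation: genomic subsets and ROC-AUC per subset.

The held-out test set is partitioned into six overlapping subsets by
consequence category: all variants; non-transcribed (not cDNA); transcribed
(cDNA); transcribed-not-coding (UTRs and introns); coding (CDS); synonymous;
missense. Discrimination between simulated (1) and derived (0) variants is
summarized per subset as ROC-AUC, which equals the Mann-Whitney probability
U/(n1*n0) with ties counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: consequence categories counted as coding sequence
CDS_CATEGORIES = frozenset(
    {"missense", "synonymous", "stop_gained", "stop_lost", "start_lost"}
)
#: categories outside any transcript (intergenic side of the partition)
NOT_CDNA_CATEGORIES = frozenset({"intergenic", "upstream_downstream"})


@dataclass(frozen=True)
class SubsetSpec:
    name: str
    predicate: Callable[[str], bool]


def default_subsets() -> Sequence[SubsetSpec]:
    def is_cdna(cat: str) -> bool:
        return cat not in NOT_CDNA_CATEGORIES

    return (
        SubsetSpec("all", lambda c: True),
        SubsetSpec("not_cDNA", lambda c: c in NOT_CDNA_CATEGORIES),
        SubsetSpec("cDNA", is_cdna),
        SubsetSpec("cDNA_not_CDS", lambda c: is_cdna(c) and c not in CDS_CATEGORIES),
        SubsetSpec("CDS", lambda c: c in CDS_CATEGORIES),
        SubsetSpec("synonymous", lambda c: c == "synonymous"),
        SubsetSpec("missense", lambda c: c == "missense"),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC-AUC as the Mann-Whitney probability that a random positive
    outscores a random negative (ties contribute 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both labels must be present")
    ranks = rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def evaluate_subsets(
    test_variants: pd.DataFrame,
    scores: Sequence[float],
    subsets: Sequence[SubsetSpec] = None,
) -> pd.DataFrame:
    """Per-subset size, class proportions and ROC-AUC.

    ``test_variants`` needs columns consequence and class_label; ``scores``
    aligns row-wise. Subsets with one class (or empty) report AUC NaN.
    """
    if subsets is None:
        subsets = default_subsets()
    scores = np.asarray(scores, dtype=float)
    cats = test_variants["consequence"].to_numpy()
    labels = test_variants["class_label"].to_numpy()
    n_total = len(test_variants)
    rows = []
    for spec in subsets:
        member = np.fromiter((spec.predicate(c) for c in cats), dtype=bool,
                             count=len(cats))
        n = int(member.sum())
        n1 = int((labels[member] == 1).sum())
        n0 = n - n1
        try:
            auc = roc_auc(scores[member], labels[member]) if n else np.nan
        except ValueError:
            auc = np.nan
        rows.append(dict(
            subset=spec.name,
            n=n,
            proportion_of_test=100.0 * n / n_total if n_total else np.nan,
            n_simulated=n1,
            n_derived=n0,
            pct_simulated=100.0 * n1 / n if n else np.nan,
            pct_derived=100.0 * n0 / n if n else np.nan,
            roc_auc=auc,
        ))
    return pd.DataFrame(rows)
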