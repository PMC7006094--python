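"""Region-level analyses on a genome-wide score track.

Scores one whole chromosome, summarizes per position, and runs the four
biological-signal analyses: codon-position contrasts, miRNA vs. flanks,
intron-position enrichment, and tissue-specific vs. housekeeping genes —
plus score x allele-frequency prioritization of segregating variants.
"""

import numpy as np

import caddkit as ck
from caddkit.region import (
    codon_position_tests,
    intron_position_tests,
    mirna_flank_test,
    prioritize_segregating,
    site_score_map,
    tissue_vs_housekeeping,
)

world = ck.build_world(seed=31, n_chromosomes=1, chrom_length=40_000,
                       n_genes=6, n_mirnas=3, n_sites=250, track_coverage=1.0)
variants, _ = ck.build_training_variants(world, seed=32)
scorer = ck.train_and_evaluate(world, variants, seed=33)
table, ranking, summary = ck.score_region(world, scorer, "chr1", 1, 40_000)

max_track = site_score_map(summary, "max", world.genome.lengths())
min_track = site_score_map(summary, "min", world.genome.lengths())

_, counts = codon_position_tests(world.gene_model, min_track)
print("codon-position contrasts (count of significant one-tailed tests,")
print("rows = smaller position, columns = larger position):")
print(counts.to_string())

global_res, per_mirna = mirna_flank_test(world.gene_model, max_track)
print(f"\nmiRNA vs flanks: effect size (ROC-AUC) = "
      f"{global_res.effect_size:.3f}, p = {global_res.p_value:.3g}")
print(f"significant miRNAs: {int(per_mirna.significant.sum())} "
      f"of {len(per_mirna)} (Bonferroni)")

introns = intron_position_tests(world.gene_model, max_track)
if len(introns):
    print("\nintron-position enrichment (normalized rejection fraction):")
    print(introns.to_string(index=False))

tissue = tissue_vs_housekeeping(world.expression, world.gene_sets,
                                world.gene_model, max_track)
print("\ntissue vs housekeeping (one-tailed, Bonferroni):")
print(tissue[["tissue", "roc_auc_housekeeping_vs_tissue", "p_adjusted",
              "significant"]].head(6).to_string(index=False))

# prioritize segregating population variants by phred x allele frequency
seg = world.population[world.population.category == "segregating"]
scored = seg.merge(table, on=["chrom", "pos", "alt"], how="inner")
scored = scored.rename(columns={"af": "alt_frequency"})
top = prioritize_segregating(
    scored[["chrom", "pos", "alt", "phred", "alt_frequency"]], top_k=5
)
print("\ntop segregating candidates by phred x alt frequency:")
print(top.to_string(index=False))
# A high product needs both a high deleteriousness rank and a high carrier
# frequency — the shortlist a breeder would validate first.
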