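"""Build a synthetic study system and export it in standard formats.

Generates a reference genome, a chain of increasingly distant ancestors,
a population site table, a gene model, and conservation/expression tables,
then writes FASTA / VCF / GFF3 / TSV files. Every downstream analysis can be
run from these files alone.
"""

import os
import tempfile

import caddkit as ck
from caddkit.fixtures import write_population_vcf, write_track_tsv

world = ck.build_world(seed=11, n_chromosomes=2, chrom_length=30_000,
                       n_genes=8, n_mirnas=4, n_sites=300)

out = tempfile.mkdtemp(prefix="caddkit_world_")
world.genome.write_fasta(os.path.join(out, "reference.fa"))
for name, ancestor in world.ancestors.items():
    ancestor.write_fasta(os.path.join(out, f"{name}.fa"))
world.gene_model.write_gff3(os.path.join(out, "genes.gff3"))
write_population_vcf(world.population, world.genome,
                     os.path.join(out, "population.vcf"))
write_track_tsv(world.tracks["phylop"], os.path.join(out, "phylop.tsv"))
world.expression.to_csv(os.path.join(out, "expression.tsv"), sep="\t",
                        index=False)

print(f"wrote study system to {out}")
print(f"chromosomes: {world.genome.lengths()}")
print(f"ancestor chain: {list(world.ancestors)}")
print(f"genes: {len(world.gene_model.genes)}, "
      f"miRNAs: {len(world.gene_model.mirnas)}")
print("population site categories:")
print(world.population.category.value_counts().to_string())
# The categories are the ground truth the derived-class screen must recover:
# 'fixed_derived' sites are the proxy-benign class; 'ancestral_trap' sites
# look nearly fixed but keep the ancestral allele segregating above 5% and
# must be screened out.
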