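# Methods

`caddkit` implements the combined annotation dependent depletion (CADD)
approach to variant deleteriousness scoring, end to end, in a form that runs
on synthetic genomes with known ground truth. This note records the model,
the conventions and numerical choices, what the synthetic data does and does
not emulate, and the known limitations.

## The model

Two classes of single-nucleotide variants (SNVs) are contrasted:

- **Derived (class 0, proxy benign/neutral).** Alleles (nearly) fixed in the
  study population that differ from the allele of the closest inferred
  ancestor. Having survived to (near) fixation under drift or positive
  selection, these are depleted in deleterious variants.
- **Simulated (class 1, proxy deleterious).** De novo SNVs drawn from
  substitution rates estimated between pairs of increasingly distant
  ancestors. Never having been exposed to selection, this class is
  relatively enriched in deleterious variants.

A logistic regressor `P(class = 1 | x) = σ(wᵀx + b)` is trained on a
feature vector `x` per variant (consequence categories, conservation
tracks, amino-acid substitution severity, DNA-shape deltas). Raw posteriors
over all possible SNVs are sorted in descending order and rank `i` of `N`
receives the PHRED-like score

    score(i) = −10 · log10(i / N),

so the top 1% scores above 20 and the top 0.1% above 30, for any `N`.
Neither class is a clean label: the discrimination measured on held-out
data (ROC-AUC) indicates how much selection-correlated signal the features
carry, not a true benign/deleterious error rate.

## Derived-class screen

Given a biallelic site table with alternate allele frequencies and an
ancestor sequence, a site yields a derived variant when:

1. the ancestral allele is known (A/C/G/T; soft-masked lowercase accepted,
   `N` unknown);
2. one population allele has frequency strictly above 0.9 and differs from
   the ancestral allele;
3. no allele with frequency strictly above 0.05 equals the ancestral allele
   (otherwise the "fixed" reading of the site is doubtful);
4. no other variant site — another table row, or a fixed
   reference-vs-ancestor difference when the reference is supplied — lies
   at distance exactly 1 bp (guards against misaligned-indel artifacts).

Strict inequalities are guarded by a 1e-9 epsilon so quantized frequencies
like 19/20 do not trip the 0.05 ceiling through float round-off.
Multi-allelic rows are skipped with a warning (conservative; the method is
defined for biallelic SNVs). Whether segregating sites count as "variant
sites" for rule 4 is configurable; the default counts them (stricter).

## Substitution-rate estimation and simulation

Rates are estimated from gapless ancestor-pair alignments in half-open
windows `[kW, (k+1)W)`, default `W = 100 kb` (tests and fixtures use 20–50
kb so several windows exist at desk scale). For each window, context
(CpG / non-CpG) and ordered base pair X→Y, the rate is
`#(X in older, Y in younger) / #(X in older)`, pooled with equal weight over
pairs (pair weights are not specified in the underlying method; equal
pooling is the neutral choice and is exposed in the API by passing pairs).
CpG context is the 5'-CG-3' dinucleotide on the forward strand of the
*older* sequence, with both the C and the G counted as CpG sites — the
symmetric convention, matching how the fixture generator mutates.

Windows with zero opportunity fall back to the chromosome-wide, then
genome-wide, pooled rate, so small fixtures have no zero-probability
deserts. Simulation samples (site, alternate-allele) pairs **without
replacement** — a genome-wide score table has at most three alternates per
site — with weights given by the window- and context-appropriate rate.
Sampling uses exponential/Gumbel keys (Efraimidis–Spirakis), which realises
successive weighted draws exactly and vectorises. Sites without a known
oldest-ancestor allele, and (by default) positions already used by the
derived class, get zero weight; requesting more variants than eligible
pairs is a capacity error. The pipeline driver matches the simulated count
to the derived count so training classes are balanced.

## Annotation

A self-contained consequence classifier evaluates each variant against the
GFF3 gene model with a 14-category severity hierarchy (most severe first):
splice acceptor, splice donor, stop gained, stop lost, start lost,
missense, splice region, synonymous, 5' UTR, 3' UTR, non-coding transcript,
intronic, upstream/downstream, intergenic. When several transcripts or
features overlap a variant, the most severe applicable category wins. The
hierarchy is configurable. Conventions:

- splice donor/acceptor: intronic offsets 1–2 bp from the
  transcription-orientation intron ends; splice region: 3–8 bp into the
  intron or 1–3 bp into the exon (so an intronic variant 4 bp from a splice
  site is splice region);
- coding calls re-translate the affected codon, on the reverse complement
  for minus-strand transcripts (validated against a brute-force
  whole-CDS re-translation oracle);
- up/downstream flank: 1 kb.

Amino-acid severity uses the Grantham (1974) distance matrix, bundled in
full; stop codons and non-standard residues mark the feature missing.
DNA-shape features are the difference in mean pentamer-window shape
(minor groove width, roll, propeller twist, helix twist) between the
alternate and reference 9-mer contexts. The bundled pentamer table is
**synthetic** — deterministic pseudo-random values on realistic scales — so
the feature path is fully exercisable; a real pentamer table can be passed
in with the same mapping shape.

Feature-matrix assembly: categorical columns are one-hot encoded against
the training-observed level set (unseen levels at scoring time map to
all-zero indicators with a warning); missing numerics are imputed — 0
(neutral) for conservation tracks, the training median otherwise — and
every imputed column gains a was-missing indicator; every column is scaled
by its training-set population standard deviation (constant columns divide
by 1). Divisors and imputation values come from the training rows only and
are serialized in a JSON sidecar with the column catalogue; a fingerprint
of the catalogue is checked at prediction time so a model can never be
applied to an incompatible matrix. The full 867-column catalogue of the
genome-scale setting is out of scope; an optional flag adds
severity × conservation interaction columns as a documented minimal
composite set.

## Training

Scikit-learn's lbfgs logistic regression is the solver. The objective is
`Σ log-loss + λ‖w‖²` with `λ = 0.1` by default, realised by setting
`C = 1/(2λ)`; the intercept is not penalized. `max_iterations = 100` is an
iteration cap, not an exact count; reaching it is logged. Internal feature
rescaling is off — scaling already happened in the matrix builder. Training
is deterministic for a fixed seed. The class-balanced split assigns
`round(n_class · test_fraction)` rows per class to the test set (default
test fraction 1/11, i.e. a ≈10:1 train:test ratio).

## Score creation

Raw posteriors are ranked descending; ties share the rank of the first
element of the tied block (method "min"), so equal raw scores map to equal
— and maximal within the block — PHRED-like scores. The transform is
rank-preserving, rank `N` maps to exactly 0, and the top-q fraction is
bounded below by `−10·log10(q)` (property-tested). Percentile of a score
within a reference set is `100 × (fraction strictly below)`. Per-position
summary tracks (max, median, min, population-formula std over the three
alternates) are emitted in coordinate order and written as bedGraph-style
TSVs; the score table writer can bgzip-compress and tabix-index its output.
User-facing scores print at 3 decimals.

## Statistics

ROC-AUC is computed as the Mann–Whitney probability `U/(n₁·n₀)` with ties
worth one half (rank-based; verified against all-pairs counting and
scikit-learn). One-tailed Mann–Whitney U-tests use exact enumeration over
label assignments when `n₁+n₂ ≤ 12` (correct under ties) and the normal
approximation with continuity and tie correction above that; the reported
effect size is always `U/(n₁·n₂)` for the first sample. Multiple testing is
Bonferroni (`p·m`, capped at 1) and "significant" means adjusted `p < 0.05`
throughout.

Region analyses summarize sites by the **maximum** of the three alternate
scores (miRNA, intron, tissue analyses) or the **minimum** (codon
analysis); both are exposed. The codon analysis uses single-transcript
genes only, skipping (with a warning) any CDS not divisible by 3, and tests
all six ordered codon-position pairs per gene with Bonferroni over genes
per comparison. miRNA flanks are one upstream plus one downstream interval
of the miRNA's own length, pooled, truncated at contig edges; miRNAs
overlapping training SNVs are excluded when a training set is supplied.
Intron tests compare intron ordinal k (transcription order) against the
pooled sites of the other introns of the same transcript — pooling rather
than pairwise testing, the configurable reading of an ambiguous procedure —
with Bonferroni per ordinal and rejection counts reported normalized by the
number of tests. The tissue analysis filters genes by an expression level
of at least 100 (own-tissue value; mean over tissues for housekeeping
genes), deduplicates CDS sites shared between transcripts, and reports both
one-tailed alternatives per tissue, since the headline direction
(tissue < housekeeping) is genuinely reversed for some tissues.
Prioritization of segregating variants ranks by PHRED-like score ×
alternate allele frequency.

## The synthetic study system

Generators are pure functions of (spec, seed) — byte-identical on repeat —
and emit ground-truth labels sufficient to compute exact expected outputs
of the derivation and simulation steps. Defaults, chosen once as a
desk-scale caricature of a livestock resequencing study:

- **Reference**: i.i.d. bases at GC 0.42 (mammalian-like); 2 × 60 kb
  chromosomes in the default pipeline world, smaller in unit tests.
- **Ancestor chain**: branch substitution probabilities 0.06, 0.03, 0.03,
  0.04 from the reference outward — the closest ancestor sits at ~6%
  divergence (a within-order mammalian ancestor distance) and the farthest
  accumulates
  ~16%; CpG sites mutate at 8× the branch rate, the order of magnitude of
  observed CpG transition hypermutability. Evolution is SNV-only, so
  coordinates are shared and no aligner is needed.
- **Population**: 50 diploid individuals; frequencies quantized to
  1/100ths. Site categories: fixed-derived (AF ≥ 0.96, non-ancestral, the
  proxy-benign ground truth), segregating (AF in (0.1, 0.9), kept away from
  both screen thresholds so neither allele can masquerade as fixed),
  ancestral-trap (AF just above 0.9 with the ancestral allele still above
  0.05 — sites the screen must discard), ancestral-matching (rare
  non-ancestral allele, AF ≤ 0.05).
- **Gene models**: non-overlapping single-transcript genes (multi-transcript
  and overlapping structures are deliberately absent, mirroring the codon
  analysis' restriction); exonic sequence is written into the genome so
  every CDS starts with ATG, ends with a stop and translates without
  internal stops on either strand; introns ≥ 20 bp; miRNAs placed in
  intergenic gaps.
- **Tracks**: unit-variance noise, +2 in CDS and miRNA intervals, with a
  configurable covered fraction to exercise imputation. **Expression**:
  RMA-like levels ~300 (active) vs ~20 (inactive) with log-normal spread;
  housekeeping genes active everywhere, others in one assigned tissue.

What passing tests show — and do not show. The fixtures validate the
machinery: exact screen semantics, rate recovery, transform analytics,
planted-signal detection. They do not emulate linkage, demography, indels,
alignment error, real annotation richness, or the genome-scale N of 7.16
billion substitutions, so the held-out AUC of a default synthetic world is
near 0.5 (the fixture plants no class-feature correlation) and headline
genome-scale numbers are not reproduced here. Where a test needs signal, it
is planted explicitly and the expected outcome is computed from the
planting (binomial/multinomial bounds at 3 standard errors, closed-form
two-normal AUC, enumeration oracles).

## Problem sizes

Unit and acceptance tests run at: genomes of 20–150 kb, populations of
200–600 sites, 10,000 simulated variants for multinomial checks, 20,000
rows for weight recovery, 1,000 permutations for the AUC null, whole-test
enumeration for all Mann–Whitney instances with `n₁+n₂ ≤ 12`. The full
suite completes in a few seconds.

## Known limitations

- The consequence classifier covers the 14 summary categories, not the full
  granularity of a production effect predictor (no codon-spanning indels,
  no NMD or canonical-transcript logic).
- The PHRED-like maximum at rank 1 is `−10·log10(1/N)` (≈98.55 at the
  genome-scale N above); published genome-scale tables citing a ~95 ceiling
  reflect tie blocks at the top of the ranking, which the min-rank tie
  policy reproduces when ties are present but the analytic formula is
  otherwise followed.
- Window-sparse rate estimates borrow strength from chromosome/genome-wide
  pools; at genome scale with 100-kb windows this fallback is essentially
  never exercised.
- The score-table writer streams through pandas at fixture scale; the
  design (coordinate-sorted TSV, bgzip/tabix) is what a genome-scale
  implementation would shard per chromosome.
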