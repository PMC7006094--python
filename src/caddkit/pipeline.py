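"""End-to-end driver: synthetic world -> training classes -> model -> scores.

This wires the modules together the way the full method runs on real data:
build (or load) a genome with annotations, derive the proxy-benign class
from population frequencies against the closest ancestor, simulate the
proxy-deleterious class from rates estimated between distant ancestor pairs
(matching the derived count, so classes are balanced), train the logistic
model, and rank-transform raw scores into PHRED-like scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import annotation, derivation, evaluation, fixtures, model as model_mod
from . import scoring, simulator
from .genemodel import GeneModel
from .genome import BASES, Genome


@dataclass
class SyntheticWorld:
    """A self-contained study system with ground truth."""

    genome: Genome
    ancestors: Dict[str, Genome]
    gene_model: GeneModel
    tracks: Dict[str, Dict[str, np.ndarray]]
    expression: pd.DataFrame
    gene_sets: pd.DataFrame
    population: pd.DataFrame
    tree: fixtures.AncestorTree

    @property
    def closest_ancestor(self) -> Genome:
        return next(iter(self.ancestors.values()))


def build_world(
    seed: int = 0,
    n_chromosomes: int = 2,
    chrom_length: int = 60_000,
    gc_content: float = 0.42,
    n_genes: int = 10,
    n_mirnas: int = 4,
    n_sites: int = 400,
    track_coverage: float = 0.9,
    n_housekeeping: Optional[int] = None,
    tree: Optional[fixtures.AncestorTree] = None,
    population_spec: Optional[fixtures.PopulationSpec] = None,
) -> SyntheticWorld:
    """Generate a complete synthetic study system.

    Genes are planted into the reference before ancestors are evolved, so
    ancestral sequences carry the same gene loci modulo substitutions.
    """
    tree = tree or fixtures.AncestorTree()
    genome = fixtures.generate_reference(fixtures.SyntheticGenomeSpec(
        n_chromosomes=n_chromosomes, chrom_length=chrom_length,
        gc_content=gc_content, seed=seed,
    ))
    gene_model = fixtures.generate_gene_model(
        genome, n_genes=n_genes, n_mirnas=n_mirnas, seed=seed + 1
    )
    ancestors = fixtures.evolve_ancestors(genome, tree, seed=seed + 2)
    tracks = fixtures.generate_conservation_tracks(
        genome, gene_model, seed=seed + 3, coverage=track_coverage
    )
    if n_housekeeping is None:
        n_housekeeping = min(10, max(2, n_genes // 3))
    expression, gene_sets = fixtures.generate_expression(
        gene_model, seed=seed + 4, n_housekeeping=n_housekeeping
    )
    spec = population_spec or fixtures.PopulationSpec(n_sites=n_sites, seed=seed + 5)
    population = fixtures.generate_population(
        genome, spec, ancestor=next(iter(ancestors.values()))
    )
    return SyntheticWorld(genome, ancestors, gene_model, tracks, expression,
                          gene_sets, population, tree)


def ancestor_pairs(world: SyntheticWorld):
    """(older, younger) genome pairs along the ancestor chain, most distant
    ancestor first in each pair."""
    names = list(world.ancestors)
    return [
        (world.ancestors[names[i + 1]], world.ancestors[names[i]])
        for i in range(len(names) - 1)
    ]


def build_training_variants(
    world: SyntheticWorld,
    window_size: int = 20_000,
    seed: int = 0,
    derivation_config: Optional[derivation.DerivationConfig] = None,
) -> Tuple[pd.DataFrame, simulator.RateTable]:
    """Derived (class 0) plus an equal number of simulated (class 1) SNVs.

    The simulated count is matched to the derived count so the training
    classes are balanced; simulated variants never reuse a derived position.
    """
    cfg = derivation_config or derivation.DerivationConfig()
    derived = derivation.find_derived_variants(
        world.population, world.closest_ancestor, cfg
    )
    rates = simulator.estimate_rates(
        [(dict(o), dict(y)) for o, y in ancestor_pairs(world)], window_size
    )
    simulated = simulator.simulate_variants(
        rates, world.genome, None,
        simulator.SimulatorConfig(n_variants=len(derived), seed=seed),
        exclude_positions=list(
            map(tuple, derived[["chrom", "pos"]].itertuples(index=False))
        ),
    )
    variants = pd.concat([derived, simulated], ignore_index=True)
    return variants.sort_values(["chrom", "pos", "alt"]).reset_index(drop=True), rates


@dataclass
class TrainedScorer:
    builder: annotation.FeatureMatrixBuilder
    model: model_mod.LogisticModel
    train_variants: pd.DataFrame
    test_variants: pd.DataFrame
    test_raw_annotation: pd.DataFrame
    test_scores: np.ndarray
    subset_report: pd.DataFrame


def train_and_evaluate(
    world: SyntheticWorld,
    variants: pd.DataFrame,
    test_fraction: float = 1 / 11,
    seed: int = 0,
    annotation_config: annotation.AnnotationConfig = annotation.AnnotationConfig(),
    training_config: model_mod.TrainingConfig = model_mod.TrainingConfig(),
) -> TrainedScorer:
    """Split, annotate, train and evaluate on the held-out set."""
    train_v, test_v = model_mod.split_train_test(variants, test_fraction, seed)
    raw_train = annotation.annotate_variants(
        train_v, world.gene_model, world.genome, world.tracks, annotation_config
    )
    raw_test = annotation.annotate_variants(
        test_v, world.gene_model, world.genome, world.tracks, annotation_config
    )
    builder = annotation.FeatureMatrixBuilder(annotation_config).fit(raw_train)
    m_train = builder.transform(raw_train)
    m_test = builder.transform(raw_test)
    fitted = model_mod.train(m_train, train_v["class_label"].to_numpy(),
                             training_config)
    test_scores = model_mod.predict(fitted, m_test)
    report = evaluation.evaluate_subsets(
        raw_test.assign(class_label=test_v["class_label"].to_numpy()),
        test_scores,
    )
    return TrainedScorer(builder, fitted, train_v, test_v, raw_test,
                         test_scores, report)


def enumerate_all_snvs(
    genome: Mapping[str, str], chrom: str, start: int, end: int
) -> pd.DataFrame:
    """All 3 possible alternates per position in [start, end] (1-based)."""
    seq = genome[chrom]
    rows = []
    for pos in range(start, end + 1):
        ref = seq[pos - 1].upper()
        if ref not in BASES:
            continue
        for alt in BASES:
            if alt != ref:
                rows.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt))
    return pd.DataFrame(rows)


def score_region(
    world: SyntheticWorld,
    scorer: TrainedScorer,
    chrom: str,
    start: int,
    end: int,
    annotation_config: annotation.AnnotationConfig = annotation.AnnotationConfig(),
) -> Tuple[pd.DataFrame, scoring.ScoreRanking, pd.DataFrame]:
    """Score every possible SNV in a region and summarize per position.

    Returns (score table, ranking, per-position summary). PHRED-like scores
    are computed within the scored set (N = rows scored here).
    """
    snvs = enumerate_all_snvs(world.genome, chrom, start, end)
    raw = annotation.annotate_variants(
        snvs, world.gene_model, world.genome, world.tracks, annotation_config
    )
    matrix = scorer.builder.transform(raw)
    posterior = model_mod.predict(scorer.model, matrix)
    ranking = scoring.phred_transform(posterior)
    table = scoring.score_table(snvs, posterior, ranking.phred)
    summary = scoring.summarize_positions(
        table[["chrom", "pos", "phred"]]
    )
    return table, ranking, summary
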