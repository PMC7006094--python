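"""Region-level rank tests: exact MWU oracle, planted-signal analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest

from caddkit.region import (
    bonferroni,
    codon_position_nonsynonymous_fractions,
    codon_position_tests,
    intron_position_tests,
    mann_whitney_one_tailed,
    mirna_flank_test,
    prioritize_segregating,
    tissue_vs_housekeeping,
)


def enumeration_oracle(x, y, alternative):
    """Independent exhaustive p-value over label assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def u_of(a, b):
        return sum(
            1.0 if ai > bi else (0.5 if ai == bi else 0.0)
            for ai in a for bi in b
        )

    observed = u_of(x, y)
    combined = np.concatenate([x, y])
    n1 = len(x)
    hits = total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        mask = np.zeros(len(combined), bool)
        mask[list(idx)] = True
        u = u_of(combined[mask], combined[~mask])
        total += 1
        if alternative == "greater":
            hits += u >= observed - 1e-12
        else:
            hits += u <= observed + 1e-12
    return observed, hits / total


class TestMannWhitney:
    def test_hand_enumerated_example(self):
        res = mann_whitney_one_tailed([3, 4, 5], [1, 2], "greater")
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(1 / 10)
        assert res.effect_size == 1.0

    def test_identical_multisets_effect_half(self):
        res = mann_whitney_one_tailed([1, 2, 2, 3], [1, 2, 2, 3], "greater")
        assert res.effect_size == 0.5

    def test_disjoint_supports_minimal_p(self):
        res = mann_whitney_one_tailed([10, 11, 12], [1, 2, 3], "greater")
        assert res.effect_size == 1.0
        assert res.p_value == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_exact_path_matches_independent_enumeration(self, rng):
        for _ in range(40):
            n1 = int(rng.integers(1, 7))
            n2 = int(rng.integers(1, 13 - n1))
            x = rng.choice([0.0, 1.0, 2.0, 3.0], size=n1)  # ties likely
            y = rng.choice([0.0, 1.0, 2.0, 3.0], size=n2)
            alt = "greater" if rng.random() < 0.5 else "less"
            res = mann_whitney_one_tailed(x, y, alt)
            u, p = enumeration_oracle(x, y, alt)
            assert res.statistic == u
            assert res.p_value == pytest.approx(p)

    def test_effect_size_u_consistency(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=20)
        res = mann_whitney_one_tailed(x, y)
        assert res.effect_size * res.n1 * res.n2 == pytest.approx(res.statistic)

    def test_asymptotic_close_to_exact_at_boundary(self, rng):
        # just above the exact-enumeration limit the normal approximation
        # should be in the same ballpark as enumeration
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        res = mann_whitney_one_tailed(x, y, "greater")
        _, p_exact = enumeration_oracle(x, y, "greater")
        assert abs(res.p_value - p_exact) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0])

    def test_bonferroni_properties(self, rng):
        p = rng.random(20)
        adj = bonferroni(p)
        assert (adj >= p).all() and (adj <= 1.0).all()
        fewer = bonferroni(p, m=5)
        assert (bonferroni(p, m=50) >= fewer).all()


@pytest.fixture()
def planted_tracks(world):
    """Score-track factory over the fixture world's chromosomes."""
    def make(fill=0.0):
        return {c: np.full(n, float(fill))
                for c, n in world.genome.lengths().items()}
    return make


class TestCodonAnalysis:
    def test_planted_position_effects_recovered(self, world, planted_tracks, rng):
        track = planted_tracks()
        means = {1: 5.0, 2: 8.0, 3: 2.0}
        for gene in world.gene_model.single_transcript_genes():
            t = gene.transcripts[0]
            pos, cp = t.codon_positions()
            for k in (1, 2, 3):
                sel = pos[cp == k]
                track[t.chrom][sel] = rng.normal(means[k], 1.0, sel.size)
        per_gene, counts = codon_position_tests(world.gene_model, track)
        n_genes = len(world.gene_model.single_transcript_genes())
        assert counts.loc[3, 2] == n_genes  # second > third everywhere
        assert counts.loc[3, 1] == n_genes
        assert counts.loc[1, 2] == n_genes
        assert counts.loc[2, 3] == 0

    def test_uniform_scores_give_near_zero_rejections(self, world, planted_tracks, rng):
        track = planted_tracks()
        for chrom in track:
            track[chrom][:] = rng.random(track[chrom].size)
        _, counts = codon_position_tests(world.gene_model, track)
        # expected rejections under the null is about m*alpha before the
        # Bonferroni division; across 6 comparisons x 8 genes allow a few
        assert counts.to_numpy().sum() <= 3

    def test_strand_symmetric_track_ignores_strand(self, world, planted_tracks):
        from dataclasses import replace

        track = planted_tracks()
        for chrom in track:
            track[chrom][:] = np.arange(track[chrom].size) % 17
        per_gene, _ = codon_position_tests(world.gene_model, track)
        flipped_genes = tuple(
            replace(g, strand="-" if g.strand == "+" else "+",
                    transcripts=tuple(
                        replace(t, strand="-" if t.strand == "+" else "+")
                        for t in g.transcripts
                    ))
            for g in world.gene_model.genes
        )
        flipped = replace_model(world.gene_model, flipped_genes)
        per_gene_f, _ = codon_position_tests(flipped, track)
        # codon position labels swap (1<->3) on the flipped strand, but the
        # union of the three score sets per gene is unchanged: statistics for
        # (larger, smaller) on + equal (4-larger, 4-smaller) on -
        for (gid, larger, smaller), row in per_gene.set_index(
            ["gene_id", "larger", "smaller"]
        ).iterrows():
            flipped_row = per_gene_f.set_index(
                ["gene_id", "larger", "smaller"]
            ).loc[(gid, 4 - larger, 4 - smaller)]
            assert row.U == pytest.approx(flipped_row.U)


def replace_model(model, genes):
    from caddkit.genemodel import GeneModel

    return GeneModel(genes, model.mirnas, model.chrom_lengths)


class TestMirnaAnalysis:
    def test_planted_normal_effect_matches_closed_form(self, world, planted_tracks, rng):
        from scipy.stats import norm

        track = planted_tracks()
        for chrom in track:
            track[chrom][:] = rng.normal(7.0, 2.0, track[chrom].size)
        for m in world.gene_model.mirnas:
            track[m.chrom][m.start:m.end] = rng.normal(10.0, 2.0, m.end - m.start)
        global_res, per_mirna = mirna_flank_test(world.gene_model, track)
        expected_auc = norm.cdf(3.0 / (2.0 * np.sqrt(2.0)))  # ~0.856
        assert global_res.effect_size == pytest.approx(expected_auc, abs=0.05)
        assert global_res.p_value < 1e-6
        assert per_mirna.significant.mean() >= 0.5

    def test_identical_distributions_null(self, world, planted_tracks, rng):
        track = planted_tracks()
        for chrom in track:
            track[chrom][:] = rng.normal(size=track[chrom].size)
        global_res, per_mirna = mirna_flank_test(world.gene_model, track)
        assert abs(global_res.effect_size - 0.5) < 0.08
        assert not per_mirna.significant.any()

    def test_training_overlap_excluded(self, world, planted_tracks):
        track = planted_tracks(1.0)
        m = world.gene_model.mirnas[0]
        training = [(m.chrom, m.start + 1)]
        _, per_mirna = mirna_flank_test(world.gene_model, track,
                                        training_positions=training)
        assert m.mirna_id not in set(per_mirna.mirna_id)


class TestIntronAnalysis:
    def multi_intron_transcripts(self, world):
        return [t for t in world.gene_model.transcripts() if len(t.introns) >= 2]

    def test_planted_decreasing_effect(self, world, planted_tracks, rng):
        track = planted_tracks()
        for chrom in track:
            track[chrom][:] = rng.normal(0.0, 1.0, track[chrom].size)
        for t in self.multi_intron_transcripts(world):
            for k, (a, b) in enumerate(t.introns_by_position):
                track[t.chrom][a:b] = rng.normal(8.0 - 3.0 * k, 1.0, b - a)
        out = intron_position_tests(world.gene_model, track)
        assert out.iloc[0].position == 1
        assert out.iloc[0].normalized_fraction == 1.0
        assert out.iloc[0].normalized_fraction > out.iloc[-1].normalized_fraction

    def test_n_tests_weakly_decreasing_in_position(self, world, planted_tracks):
        track = planted_tracks(1.0)
        out = intron_position_tests(world.gene_model, track)
        n = out.sort_values("position").n_tests.to_numpy()
        assert (np.diff(n) <= 0).all()

    def test_uniform_scores_near_alpha_rejections(self, world, planted_tracks, rng):
        track = planted_tracks()
        for chrom in track:
            track[chrom][:] = rng.random(track[chrom].size)
        out = intron_position_tests(world.gene_model, track)
        assert out.n_significant.sum() <= max(1, int(0.1 * out.n_tests.sum()))


@pytest.fixture(scope="module")
def tissue_world():
    import caddkit as ck

    return ck.build_world(
        seed=17, n_chromosomes=2, chrom_length=60_000, n_genes=22,
        n_mirnas=2, n_sites=200, n_housekeeping=4,
    )


class TestTissueAnalysis:
    def test_planted_directions_recovered(self, tissue_world, rng):
        w = tissue_world
        sets = dict(w.gene_sets[["gene_id", "set_name"]].itertuples(index=False))
        tissues = sorted({s for s in sets.values() if s != "housekeeping"})
        low = set(tissues[:12])
        track = {c: np.full(n, np.nan) for c, n in w.genome.lengths().items()}
        for g in w.gene_model.genes:
            name = sets[g.gene_id]
            mean = 8.0 if name == "housekeeping" else (
                5.0 if name in low else 11.0
            )
            for t in g.transcripts:
                for a, b in t.cds:
                    track[g.chrom][a:b] = rng.normal(mean, 1.0, b - a)
        out = tissue_vs_housekeeping(
            w.expression, w.gene_sets, w.gene_model, track, min_expression=100.0
        ).set_index("tissue")
        for tissue in tissues:
            if tissue in low:
                assert out.loc[tissue, "significant"], tissue
                assert out.loc[tissue, "roc_auc_housekeeping_vs_tissue"] > 0.5
            else:
                assert not out.loc[tissue, "significant"], tissue
                assert out.loc[tissue, "p_adjusted_reverse"] < 0.05

    def test_identical_scores_give_null_auc(self, tissue_world, rng):
        w = tissue_world
        track = {c: rng.normal(size=n) for c, n in w.genome.lengths().items()}
        out = tissue_vs_housekeeping(
            w.expression, w.gene_sets, w.gene_model, track, min_expression=100.0
        )
        assert (out.roc_auc_housekeeping_vs_tissue - 0.5).abs().max() < 0.1

    def test_filter_above_all_expression_raises(self, tissue_world):
        w = tissue_world
        track = {c: np.ones(n) for c, n in w.genome.lengths().items()}
        with pytest.raises(ValueError):
            tissue_vs_housekeeping(
                w.expression, w.gene_sets, w.gene_model, track,
                min_expression=1e9,
            )


class TestPrioritization:
    def test_published_style_product(self):
        v = pd.DataFrame(dict(phred=[26.559], alt_frequency=[0.986]))
        out = prioritize_segregating(v, top_k=1)
        assert out.phred_x_freq.iloc[0] == pytest.approx(26.185, abs=0.01)

    def test_zero_frequency_ranks_last_and_one_equals_phred(self):
        v = pd.DataFrame(dict(
            phred=[30.0, 10.0, 20.0],
            alt_frequency=[0.0, 1.0, 0.5],
        ))
        out = prioritize_segregating(v, top_k=3)
        assert out.phred_x_freq.iloc[-1] == 0.0
        assert out.phred_x_freq.iloc[0] == 10.0  # freq 1 -> product = phred

    def test_invalid_frequency_rejected(self):
        v = pd.DataFrame(dict(phred=[1.0], alt_frequency=[1.5]))
        with pytest.raises(ValueError):
            prioritize_segregating(v)


class TestGeneticCodeEnumeration:
    def test_nonsynonymous_fraction_ordering(self):
        f = codon_position_nonsynonymous_fractions()
        assert f[2] > f[1] > f[3]
        # position 2 changes are essentially all non-synonymous (190/192)
        assert f[2] == pytest.approx(190 / 192)
        assert f[3] < 0.5
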