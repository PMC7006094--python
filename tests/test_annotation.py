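"""Consequence calls, Grantham, shape deltas, tracks, feature matrix."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import caddkit as ck
from caddkit.annotation import (
    AnnotationConfig,
    FeatureMatrixBuilder,
    annotate_consequence,
    annotate_tracks,
    annotate_variants,
    classify_consequence,
    shape_delta,
    synthetic_shape_table,
)
from caddkit.genemodel import Gene, GeneModel, Transcript
from caddkit.grantham import GRANTHAM, grantham

CFG = AnnotationConfig()


def simple_model(strand="+"):
    """One gene: exon 10-40 / intron 40-60 / exon 60-100, CDS 16-87.

    The exonic sequence is written so the CDS translates cleanly on the
    requested strand.
    """
    t = Transcript("tx1", "g1", "chr1", strand, ((10, 40), (60, 100)),
                   ((16, 40), (60, 87)))
    return GeneModel((Gene("g1", "chr1", strand, (t,)),), (), {"chr1": 200})


def genome_for(model):
    """Background of A's with a valid CDS written into the transcript."""
    t = next(model.transcripts())
    seq = list("A" * 200)
    n_codons = sum(b - a for a, b in t.cds) // 3
    # codons chosen to include Lys (AAA) at codon 2 for targeted edits
    body = "AAA" + "TGC" * (n_codons - 3)
    cds = "ATG" + body[: 3 * (n_codons - 2)] + "TAA"
    from caddkit.fixtures import _mrna_to_genomic
    from caddkit.genome import revcomp

    u5 = sum(b - a for a, b in t.utr5)
    mrna = "G" * u5 + cds + "G" * sum(b - a for a, b in t.utr3)
    tx_exons = t.exons if t.strand == "+" else t.exons[::-1]
    m = 0
    for a, b in tx_exons:
        chunk = mrna[m:m + (b - a)]
        seq[a:b] = list(chunk if t.strand == "+" else revcomp(chunk))
        m += b - a
    return {"chr1": "".join(seq)}


class TestConsequences:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_synonymous_and_missense_on_lysine_codon(self, strand):
        model = simple_model(strand)
        genome = genome_for(model)
        t = next(model.transcripts())
        pos, codon_pos = t.codon_positions()
        # second codon is AAA (Lys); third base AAA->AAG stays Lys
        wobble = int(pos[5])
        ref = genome["chr1"][wobble].upper()
        alt_syn = "G" if strand == "+" else "C"  # codes Lys via AAG
        assert classify_consequence(
            "chr1", wobble + 1, ref, alt_syn, model, genome, CFG
        ) == "synonymous"
        # first base AAA->GAA is Lys->Glu
        first = int(pos[3])
        ref1 = genome["chr1"][first].upper()
        alt_mis = "G" if strand == "+" else "C"
        assert classify_consequence(
            "chr1", first + 1, ref1, alt_mis, model, genome, CFG
        ) == "missense"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_strand_correct_against_translation_oracle(self, strand):
        """Every CDS substitution agrees with re-translating the whole CDS."""
        model = simple_model(strand)
        genome = genome_for(model)
        t = next(model.transcripts())
        ref_protein = str(Seq(t.coding_sequence(genome)).translate())
        pos, _ = t.codon_positions()
        for p in map(int, pos):
            ref = genome["chr1"][p].upper()
            for alt in "ACGT":
                if alt == ref:
                    continue
                mutated = dict(genome)
                mutated["chr1"] = genome["chr1"][:p] + alt + genome["chr1"][p + 1:]
                alt_protein = str(Seq(t.coding_sequence(mutated)).translate())
                cat = classify_consequence("chr1", p + 1, ref, alt, model,
                                           genome, CFG)
                i = next(
                    (k for k, (a, b) in enumerate(zip(ref_protein, alt_protein))
                     if a != b), None
                )
                if i is None:
                    expected = {"synonymous", "splice_region"}
                elif i == 0 and ref_protein[0] == "M":
                    expected = {"start_lost"}
                elif alt_protein[i] == "*":
                    expected = {"stop_gained"}
                elif ref_protein[i] == "*":
                    expected = {"stop_lost"}
                else:
                    expected = {"missense", "splice_region"}
                assert cat in expected, (p, ref, alt, cat, expected)

    def test_intron_four_bp_from_splice_site_is_splice_region(self):
        model = simple_model("+")
        genome = genome_for(model)
        # intron is 40-60; 4 bp into the intron from the donor side
        assert classify_consequence("chr1", 44, "A", "C", model, genome, CFG) \
            == "splice_region"
        # and from the acceptor side (4 bp upstream of the next exon)
        assert classify_consequence("chr1", 57, "A", "C", model, genome, CFG) \
            == "splice_region"

    def test_intron_splice_sites_and_deep_intron(self):
        model = simple_model("+")
        genome = genome_for(model)
        assert classify_consequence("chr1", 41, "A", "C", model, genome, CFG) \
            == "splice_donor"
        assert classify_consequence("chr1", 60, "A", "C", model, genome, CFG) \
            == "splice_acceptor"
        assert classify_consequence("chr1", 50, "A", "C", model, genome, CFG) \
            == "intronic"

    def test_utr_flank_intergenic(self):
        model = simple_model("+")
        genome = genome_for(model)
        assert classify_consequence("chr1", 12, "G", "C", model, genome, CFG) \
            == "five_prime_utr"
        assert classify_consequence("chr1", 95, "G", "C", model, genome, CFG) \
            == "three_prime_utr"
        assert classify_consequence("chr1", 150, "A", "C", model, genome, CFG) \
            == "upstream_downstream"
        cfg = AnnotationConfig(flank=10)
        assert classify_consequence("chr1", 150, "A", "C", model, genome, cfg) \
            == "intergenic"

    def test_position_beyond_chromosome_end_raises(self):
        model = simple_model("+")
        genome = genome_for(model)
        with pytest.raises(IndexError):
            classify_consequence("chr1", 500, "A", "C", model, genome, CFG)

    def test_most_severe_category_wins_on_fixture_world(self, world):
        # miRNA positions report the non-coding transcript category
        m = world.gene_model.mirnas[0]
        ref = world.genome.base_at(m.chrom, m.start + 5)
        alt = "A" if ref != "A" else "C"
        assert classify_consequence(
            m.chrom, m.start + 6, ref, alt, world.gene_model, world.genome, CFG
        ) == "non_coding_transcript"


class TestGrantham:
    def test_identity_is_zero(self):
        assert grantham("L", "L") == 0.0

    def test_symmetry_positive_off_diagonal(self):
        aas = sorted({a for a, _ in GRANTHAM})
        assert len(aas) == 20
        for a in aas:
            for b in aas:
                assert GRANTHAM[(a, b)] == GRANTHAM[(b, a)]
                if a != b:
                    assert GRANTHAM[(a, b)] > 0

    def test_extremes_are_leu_ile_and_cys_trp(self):
        off = {k: v for k, v in GRANTHAM.items() if k[0] != k[1]}
        assert grantham("L", "I") == min(off.values())
        assert grantham("C", "W") == max(off.values())

    def test_stop_and_nonstandard_are_missing(self):
        assert grantham("*", "L") is None
        assert grantham("X", "L") is None


class TestShapeDelta:
    TOY = {"AAAAA": dict(mgw=1.0, roll=0.0, prot=0.0, helt=0.0),
           "AACAA": dict(mgw=2.0, roll=0.0, prot=0.0, helt=0.0)}

    def test_identity_context_gives_zero(self):
        table = synthetic_shape_table()
        sd = shape_delta("ACGTACGTA", "ACGTACGTA", table)
        assert sd.mgw_delta == 0.0 and sd.helt_delta == 0.0

    def test_antisymmetry(self):
        table = synthetic_shape_table()
        a = shape_delta("ACGTACGTA", "ACGTTCGTA", table)
        b = shape_delta("ACGTTCGTA", "ACGTACGTA", table)
        assert np.isclose(a.mgw_delta, -b.mgw_delta)
        assert np.isclose(a.roll_delta, -b.roll_delta)

    def test_toy_lookup_hand_value(self):
        sd = shape_delta("AAAAA", "AACAA", self.TOY)
        assert sd.mgw_delta == 1.0

    def test_n_in_context_marks_all_missing(self):
        table = synthetic_shape_table()
        sd = shape_delta("ACGTNCGTA", "ACGTACGTA", table)
        assert sd.missing

    def test_synthetic_table_is_deterministic_and_complete(self):
        a = synthetic_shape_table(0)
        b = synthetic_shape_table(0)
        assert a == b and len(a) == 1024


class TestTracks:
    def test_covered_and_gap_positions(self):
        tracks = {"t": {"chr1": np.array([1.0, np.nan, 3.0])}}
        assert annotate_tracks("chr1", 1, tracks)["t"] == 1.0
        assert np.isnan(annotate_tracks("chr1", 2, tracks)["t"])
        assert np.isnan(annotate_tracks("chr2", 1, tracks)["t"])


class TestFeatureMatrix:
    @pytest.fixture()
    def raw(self, world):
        variants, _ = ck.build_training_variants(world, seed=5)
        return annotate_variants(
            variants, world.gene_model, world.genome, world.tracks, CFG
        )

    def test_one_hot_partition(self, raw):
        builder = FeatureMatrixBuilder(CFG).fit(raw)
        fm = builder.transform(raw)
        onehot_cols = [c for c in fm.columns if c.startswith("consequence=")]
        unscaled = fm.frame[onehot_cols] * fm.divisors[onehot_cols]
        sums = unscaled.sum(axis=1)
        assert np.allclose(sums, 1.0)
        for cat in builder.categories_:
            col = f"consequence={cat}"
            assert np.isclose(
                unscaled[col].sum(), (raw.consequence == cat).sum()
            )

    def test_scaling_gives_unit_std_on_training_rows(self, raw):
        fm = FeatureMatrixBuilder(CFG).fit(raw).transform(raw)
        stds = fm.frame.std(axis=0, ddof=0)
        nonconst = stds[stds > 1e-12]
        assert np.allclose(nonconst, 1.0)

    def test_no_missing_after_imputation(self, raw):
        fm = FeatureMatrixBuilder(CFG).fit(raw).transform(raw)
        assert np.isfinite(fm.frame.to_numpy()).all()

    def test_half_coverage_missingness_indicators(self, world):
        from caddkit.fixtures import generate_conservation_tracks

        tracks = generate_conservation_tracks(
            world.genome, world.gene_model, seed=9, coverage=0.5
        )
        variants, _ = ck.build_training_variants(world, seed=5)
        raw = annotate_variants(variants, world.gene_model, world.genome,
                                tracks, CFG)
        fm = FeatureMatrixBuilder(CFG).fit(raw).transform(raw)
        for name in tracks:
            frac = fm.missing_mask[f"track_{name}"].mean()
            assert abs(frac - 0.5) < 0.1

    def test_scaling_divisor_halves_values(self):
        raw = pd.DataFrame(dict(
            consequence=["intergenic"] * 8,
            x=[0.0, 2.0, 0.0, 2.0, 0.0, 2.0, 0.0, 2.0],
        ))
        fm = FeatureMatrixBuilder(CFG).fit(raw).transform(raw)
        assert np.isclose(fm.divisors["x"], 1.0)  # std of 0/2 alternation
        raw2 = raw.assign(x=raw.x * 2)
        fm2 = FeatureMatrixBuilder(CFG).fit(raw2).transform(raw2)
        assert np.isclose(fm2.divisors["x"], 2.0)
        assert np.allclose(fm2.frame["x"], raw2.x / 2.0)

    def test_unseen_category_maps_to_zero_with_warning(self, raw):
        builder = FeatureMatrixBuilder(CFG).fit(raw)
        odd = raw.iloc[:2].copy()
        odd["consequence"] = "never_seen"
        with pytest.warns(UserWarning, match="unseen"):
            fm = builder.transform(odd)
        onehot = [c for c in fm.columns if c.startswith("consequence=")]
        assert fm.frame[onehot].to_numpy().sum() == 0.0

    def test_transform_reuses_training_divisors(self, raw):
        builder = FeatureMatrixBuilder(CFG).fit(raw)
        subset = builder.transform(raw.iloc[:10])
        full = builder.transform(raw)
        pd.testing.assert_frame_equal(
            subset.frame, full.frame.iloc[:10], check_like=False
        )

    def test_json_sidecar_round_trip(self, raw, tmp_path):
        builder = FeatureMatrixBuilder(CFG).fit(raw)
        path = str(tmp_path / "catalogue.json")
        builder.to_json(path)
        back = FeatureMatrixBuilder.from_json(path, CFG)
        fm1 = builder.transform(raw)
        fm2 = back.transform(raw)
        pd.testing.assert_frame_equal(fm1.frame, fm2.frame)
        assert fm1.fingerprint == fm2.fingerprint
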