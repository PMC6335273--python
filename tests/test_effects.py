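"""Codon-level effect annotation, SAAC sets, and the NS/S ratio test."""

import numpy as np
import pytest
from Bio.Seq import Seq

from passcan.effects import (Effect, GeneModel, VariantEffect,
                             annotate_variant, load_gene_models,
                             ns_s_ratio_test, saac_sets, _COMPLEMENT)
from passcan.synthetic import SimConfig, simulate_genome, write_gff3


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@pytest.fixture
def plus_gene():
    """Single-exon + strand gene: ATG GGA TAC AAA TAA at offset 10."""
    cds = "ATGGGATACAAATAA"
    ref = {"chr1": "T" * 10 + cds + "T" * 10}
    model = GeneModel("g1", "t1", "chr1", "+", [(10, 25)])
    return ref, model


@pytest.fixture
def minus_gene():
    """Two-exon - strand gene with the same CDS, intron of 5 bp."""
    cds = "ATGGGATACAAATAA"
    genomic = revcomp(cds)  # 15 bp total on the genome
    # split genomic into two exons: first 7, intron 5, last 8
    ref = {"chr1": "C" * 10 + genomic[:7] + "GTGTG" + genomic[7:] + "C" * 10}
    model = GeneModel("g2", "t2", "chr1", "-", [(10, 17), (22, 30)])
    return ref, model


class TestAnnotateSNV:
    def test_third_position_wobble_is_synonymous(self, plus_gene):
        ref, model = plus_gene
        # codon 2 GGA -> GGG (Gly->Gly); genomic pos of its 3rd base = 16(1-based)
        e = annotate_variant("chr1", 16, "A", "G", model, ref)
        assert e.effect is Effect.SYNONYMOUS

    def test_missense_with_notation(self, plus_gene):
        ref, model = plus_gene
        # codon 2 GGA -> GAA: Gly2Glu
        e = annotate_variant("chr1", 15, "G", "A", model, ref)
        assert e.effect is Effect.NONSYNONYMOUS
        assert e.aa_change == "G2E"

    def test_stopgain(self, plus_gene):
        ref, model = plus_gene
        # codon 3 TAC -> TAA (Tyr -> stop); third base at 1-based 19
        e = annotate_variant("chr1", 19, "C", "A", model, ref)
        assert e.effect is Effect.STOPGAIN
        assert e.aa_change == "Y3*"

    def test_stoploss(self, plus_gene):
        ref, model = plus_gene
        # stop codon TAA -> CAA (Gln)
        e = annotate_variant("chr1", 23, "T", "C", model, ref)
        assert e.effect is Effect.STOPLOSS

    def test_stop_retained_counts_synonymous(self, plus_gene):
        ref, model = plus_gene
        # TAA -> TGA is still a stop
        e = annotate_variant("chr1", 24, "A", "G", model, ref)
        assert e.effect is Effect.SYNONYMOUS

    def test_reference_allele_identity_has_no_effect(self, plus_gene):
        ref, model = plus_gene
        e = annotate_variant("chr1", 15, "G", "G", model, ref)
        assert e.effect is Effect.SYNONYMOUS and e.aa_change == ""

    def test_noncoding_and_splice_region(self, minus_gene):
        ref, model = minus_gene
        assert annotate_variant("chr1", 3, "C", "A", model, ref).effect \
            is Effect.NONCODING
        # first intron base after exon1 end (0-based 17 -> 1-based 18)
        assert annotate_variant("chr1", 18, "G", "A", model, ref).effect \
            is Effect.SPLICE_REGION

    def test_reference_mismatch_raises_with_coordinates(self, plus_gene):
        ref, model = plus_gene
        with pytest.raises(ValueError, match="chr1:15"):
            annotate_variant("chr1", 15, "C", "A", model, ref)

    def test_minus_strand_matches_translate_and_diff(self, minus_gene):
        """Every CDS substitution on the minus gene agrees with the
        whole-protein translate-and-diff oracle."""
        ref, model = minus_gene
        seq = ref["chr1"]
        prot_ref = str(Seq(model.cds_sequence(ref)).translate())
        cds_genomic = {p for s, e in model.cds_segments for p in range(s, e)}
        for pos0 in sorted(cds_genomic):
            base = seq[pos0]
            for alt in "ACGT":
                if alt == base:
                    continue
                e = annotate_variant("chr1", pos0 + 1, base, alt, model, ref)
                mutated = {"chr1": seq[:pos0] + alt + seq[pos0 + 1:]}
                prot_alt = str(Seq(model.cds_sequence(mutated)).translate())
                if prot_ref == prot_alt:
                    assert e.effect is Effect.SYNONYMOUS
                elif "*" in prot_alt[:-1]:
                    assert e.effect is Effect.STOPGAIN
                elif prot_alt[-1] != "*" and prot_ref[-1] == "*":
                    assert e.effect is Effect.STOPLOSS
                else:
                    assert e.effect is Effect.NONSYNONYMOUS

    def test_strand_mirror_symmetry(self, plus_gene):
        """Reverse-complementing the genome and model preserves effects."""
        ref, model = plus_gene
        seq = ref["chr1"]
        n = len(seq)
        mirror = {"chr1": revcomp(seq)}
        lo, hi = model.span
        mirror_model = GeneModel("g1", "t1", "chr1", "-", [(n - hi, n - lo)])
        for pos0 in range(lo, hi):
            base = seq[pos0]
            for alt in "ACGT":
                if alt == base:
                    continue
                e1 = annotate_variant("chr1", pos0 + 1, base, alt, model, ref)
                mpos0 = n - 1 - pos0
                e2 = annotate_variant("chr1", mpos0 + 1,
                                      base.translate(_COMPLEMENT),
                                      alt.translate(_COMPLEMENT),
                                      mirror_model, mirror)
                assert e1.effect is e2.effect
                assert e1.aa_change == e2.aa_change


class TestAnnotateIndel:
    def test_frameshift_vs_inframe(self, plus_gene):
        ref, model = plus_gene
        e2 = annotate_variant("chr1", 13, "G", "GAT", model, ref)
        assert e2.effect is Effect.FRAMESHIFT
        e3 = annotate_variant("chr1", 13, "G", "GATT", model, ref)
        assert e3.effect is Effect.NONFRAMESHIFT_INDEL

    def test_deletion_outside_cds_noncoding(self, plus_gene):
        ref, model = plus_gene
        e = annotate_variant("chr1", 2, "TT", "T", model, ref)
        assert e.effect is Effect.NONCODING


class TestGeneModelLoading:
    def test_round_trip_through_gff3(self, tmp_path):
        reference, genes, _ = simulate_genome(
            SimConfig(seed=21, n_chroms=1, chrom_length=300_000, n_genes=12))
        gff = tmp_path / "genes.gff3"
        write_gff3(genes, gff)
        loaded = load_gene_models(gff)
        assert len(loaded) == len(genes)
        by_id = {m.gene_id: m for m in loaded}
        for g in genes:
            m = by_id[g.gene_id]
            assert m.cds_segments == g.cds_segments
            assert m.strand == g.strand
            assert m.cds_length % 3 == 0

    def test_longest_transcript_selected(self, tmp_path):
        gff = tmp_path / "multi.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tx\tgene\t1\t100\t.\t+\t.\tID=g\n"
            "c\tx\tmRNA\t1\t100\t.\t+\t.\tID=t_short;Parent=g\n"
            "c\tx\tCDS\t1\t6\t.\t+\t0\tID=c1;Parent=t_short\n"
            "c\tx\tmRNA\t1\t100\t.\t+\t.\tID=t_long;Parent=g\n"
            "c\tx\tCDS\t1\t12\t.\t+\t0\tID=c2;Parent=t_long\n")
        (model,) = load_gene_models(gff)
        assert model.transcript_id == "t_long"
        assert model.cds_length == 12

    def test_partial_codon_models_skipped(self, tmp_path):
        gff = tmp_path / "partial.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tx\tgene\t1\t100\t.\t+\t.\tID=g\n"
            "c\tx\tmRNA\t1\t100\t.\t+\t.\tID=t;Parent=g\n"
            "c\tx\tCDS\t1\t7\t.\t+\t0\tID=c1;Parent=t\n")
        assert load_gene_models(gff) == []


class TestSaacSets:
    def eff(self, gene, effect):
        return VariantEffect("chr1", 1, "A", "T", gene, gene, effect)

    def test_set_difference(self):
        a = [self.eff("g1", Effect.NONSYNONYMOUS),
             self.eff("g2", Effect.FRAMESHIFT),
             self.eff("g3", Effect.STOPGAIN)]
        b = [self.eff("g2", Effect.NONSYNONYMOUS)]
        s = saac_sets(a, b)
        assert s.saac_a == {"g1", "g3"}
        assert s.saac_b == set()
        assert not (s.saac_a & s.saac_b)

    def test_synonymous_only_gene_excluded(self):
        s = saac_sets([self.eff("g1", Effect.SYNONYMOUS)], [])
        assert s.saac_a == set()

    def test_splice_region_excluded_from_saac(self):
        s = saac_sets([self.eff("g1", Effect.SPLICE_REGION)], [])
        assert s.saac_a == set()

    def test_order_invariance(self, rng):
        effects = [self.eff(f"g{i % 7}", Effect.NONSYNONYMOUS)
                   for i in range(30)]
        shuffled = list(effects)
        rng.shuffle(shuffled)
        assert saac_sets(effects, []).saac_a == saac_sets(shuffled, []).saac_a

    def test_synthetic_noise_free_world_matches_truth(self):
        """With no genotype noise, observed SAAC sets equal planted truth."""
        from passcan.pipeline import classify_stage, effects_stage
        from passcan.synthetic import simulate_world

        world = simulate_world(SimConfig(seed=23, n_chroms=1,
                                         chrom_length=500_000, n_genes=40,
                                         het_residual_prob=0.0,
                                         missing_prob=0.0))
        spec = world.config.population_spec()
        table, _ = classify_stage(world.sites, spec)
        _, _, saac = effects_stage(table, world.genes, world.reference)
        assert set(saac.saac_a) == set(world.truth.saac_a)
        assert set(saac.saac_b) == set(world.truth.saac_b)


class TestNsSRatio:
    def test_published_counts(self):
        ratio_in, ratio_out, p = ns_s_ratio_test(1021, 1553, 2481, 4587)
        assert round(ratio_in, 2) == 0.66
        assert round(ratio_out, 2) == 0.54
        assert p == pytest.approx(4.239e-05, rel=1e-3)

    def test_equal_ratios_not_significant(self):
        ratio_in, ratio_out, p = ns_s_ratio_test(10, 20, 20, 40)
        assert ratio_in == pytest.approx(ratio_out)
        assert p > 0.99

    def test_empty_nonsynonymous_class(self):
        ratio_in, ratio_out, p = ns_s_ratio_test(0, 10, 0, 10)
        assert ratio_in == 0.0 and ratio_out == 0.0 and p == 1.0

    def test_zero_synonymous_stratum_keeps_p(self):
        ratio_in, ratio_out, p = ns_s_ratio_test(5, 0, 3, 10)
        assert np.isnan(ratio_in)
        assert 0.0 < p <= 1.0
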