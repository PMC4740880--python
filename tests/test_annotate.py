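"""Consequence classifier: codon calls, splice logic, indels, aggregation."""

import numpy as np
import pytest

from riphewas import io
from riphewas.annotate import (
    Consequence,
    ReferenceMismatchError,
    VariantRecord,
    annotate_variants,
    classify_indel,
    classify_snv,
    combine_class_counts,
    most_severe,
    normalize_variant,
    platform_fpr,
)
from riphewas.genome import Genome, TranscriptModel
from riphewas.simulate import simulate_variant_catalog

C = Consequence


def snv(pos1, ref, alt, chrom="c"):
    return VariantRecord(chrom, pos1, ref, alt)


# ---------------------------------------------------------------------------
# SNVs on the hand-built '+' strand transcript (see conftest layout)


class TestClassifySnv:
    def test_synonymous_lys_to_lys(self, mini_genome, mini_transcript):
        # codon 2 AAA at genomic 11-13; A->G at third base keeps Lys
        call = classify_snv(snv(14, "A", "G"), mini_transcript, mini_genome)
        assert call.consequence == C.synonymous
        assert call.codon_change == "AAA>AAG"
        assert call.protein_change == "K2K"

    def test_stop_gain_tat_to_taa(self, mini_genome, mini_transcript):
        # codon 3 TAT spans the intron: bases at 14, 15 and 46
        call = classify_snv(snv(47, "T", "A"), mini_transcript, mini_genome)
        assert call.consequence == C.stop_gain
        assert call.codon_change == "TAT>TAA"

    def test_missense(self, mini_genome, mini_transcript):
        # codon 4 CCC (Pro) at 47-49; C->A at first base -> ACC (Thr)
        call = classify_snv(snv(48, "C", "A"), mini_transcript, mini_genome)
        assert call.consequence == C.missense
        assert call.protein_change == "P4T"

    def test_stop_loss(self, mini_genome, mini_transcript):
        # stop codon TAA at 50-52; T->C -> CAA (Gln)
        call = classify_snv(snv(51, "T", "C"), mini_transcript, mini_genome)
        assert call.consequence == C.stop_loss

    def test_splice_donor_first_intron_base(self, mini_genome, mini_transcript):
        call = classify_snv(snv(17, "G", "A"), mini_transcript, mini_genome)
        assert call.consequence == C.splice_donor

    def test_splice_donor_second_intron_base(self, mini_genome, mini_transcript):
        call = classify_snv(snv(18, "T", "C"), mini_transcript, mini_genome)
        assert call.consequence == C.splice_donor

    def test_splice_acceptor_last_two_bases(self, mini_genome, mini_transcript):
        for pos1 in (45, 46):
            call = classify_snv(
                snv(pos1, mini_genome.base("c", pos1 - 1), "C"),
                mini_transcript, mini_genome,
            )
            assert call.consequence == C.splice_acceptor, pos1

    def test_intron_interior(self, mini_genome, mini_transcript):
        call = classify_snv(snv(26, "A", "G"), mini_transcript, mini_genome)
        assert call.consequence == C.intronic

    def test_utrs(self, mini_genome, mini_transcript):
        assert (
            classify_snv(snv(7, "T", "A"), mini_transcript, mini_genome).consequence
            == C.utr5
        )
        assert (
            classify_snv(snv(55, "G", "A"), mini_transcript, mini_genome).consequence
            == C.utr3
        )

    def test_intergenic(self, mini_genome, mini_transcript):
        call = classify_snv(snv(3, "C", "T"), mini_transcript, mini_genome)
        assert call.consequence == C.intergenic

    def test_ref_mismatch_names_position(self, mini_genome, mini_transcript):
        with pytest.raises(ReferenceMismatchError, match="c:14"):
            classify_snv(snv(14, "G", "T"), mini_transcript, mini_genome)

    def test_pure_function(self, mini_genome, mini_transcript):
        v = snv(48, "C", "A")
        a = classify_snv(v, mini_transcript, mini_genome)
        b = classify_snv(v, mini_transcript, mini_genome)
        assert a == b

    def test_incomplete_cds_flagged_noncoding_only(self, mini_genome):
        t = TranscriptModel(
            "txI", "geneI", "c", "+",
            exons=((5, 16), (46, 57)),
            cds=((8, 16), (46, 52)),  # 14 bases: not divisible by 3
        )
        call = classify_snv(snv(12, "A", "G"), t, mini_genome)
        assert "incomplete_cds" in call.flags
        assert call.consequence in {C.utr5, C.utr3, C.intronic}


# ---------------------------------------------------------------------------
# indels


class TestClassifyIndel:
    def test_three_bp_deletion_in_cds_inframe(self, mini_genome, mini_transcript):
        # delete genomic bases 11-13 (AAA codon): anchor at 10
        ref = mini_genome.fetch("c", 10, 14)
        call = classify_indel(
            VariantRecord("c", 11, ref, ref[0]), mini_transcript, mini_genome
        )
        assert call.consequence == C.inframe_indel

    def test_four_bp_insertion_in_cds_frameshift(self, mini_genome, mini_transcript):
        anchor = mini_genome.base("c", 11)
        call = classify_indel(
            VariantRecord("c", 12, anchor, anchor + "GTCA"),
            mini_transcript, mini_genome,
        )
        assert call.consequence == C.frameshift

    def test_intronic_deletion_away_from_splice_sites(
        self, mini_genome, mini_transcript
    ):
        # delete 11 intron bases 25-35; dinucleotides at 16-17 and 44-45
        ref = mini_genome.fetch("c", 24, 36)
        call = classify_indel(
            VariantRecord("c", 25, ref, ref[0]), mini_transcript, mini_genome
        )
        assert call.consequence == C.intronic

    def test_deletion_spanning_exon_boundary_takes_most_severe(
        self, mini_genome, mini_transcript
    ):
        # delete 14-18: last CDS bases of exon1 plus the GT donor
        ref = mini_genome.fetch("c", 13, 19)
        call = classify_indel(
            VariantRecord("c", 14, ref, ref[0]), mini_transcript, mini_genome
        )
        # 5 deleted bases -> frameshift outranks the splice_donor overlap
        assert call.consequence == C.frameshift

    def test_left_normalization(self, mini_genome):
        # intron is A*26: a 2-bp A-deletion anywhere in the run shifts left
        v = VariantRecord("c", 30, "AAA", "A")
        norm = normalize_variant(v, mini_genome)
        assert norm.position < 30
        assert len(norm.ref) == 3 and len(norm.alt) == 1


# ---------------------------------------------------------------------------
# severity and aggregation


def test_severity_order_is_fixed():
    order = [
        C.stop_gain, C.stop_loss, C.frameshift, C.splice_donor, C.missense,
        C.inframe_indel, C.synonymous, C.utr5, C.intronic, C.intergenic,
    ]
    from riphewas.annotate import SEVERITY

    ranks = [SEVERITY[c] for c in order]
    assert ranks == sorted(ranks, reverse=True)
    assert SEVERITY[C.splice_donor] == SEVERITY[C.splice_acceptor]
    assert most_severe([C.intronic, C.missense, C.utr3]) == C.missense


def test_multi_transcript_most_severe_wins(mini_genome, mini_transcript):
    # second transcript whose intron covers the first's missense position
    other = TranscriptModel(
        "txB", "geneB", "c", "+",
        exons=((5, 10), (60, 70)),
        cds=(),
    )
    table, _ = annotate_variants(
        [snv(48, "C", "A")], [mini_transcript, other], mini_genome
    )
    assert table.loc[0, "consequence"] == "missense"
    assert table.loc[0, "transcript_id"] == "txA"


def test_empty_catalog(mini_genome, mini_transcript):
    table, counts = annotate_variants([], [mini_transcript], mini_genome)
    assert table.empty
    assert (counts == 0).all()


def test_generator_truth_agreement(gene_models):
    counts = {
        "synonymous": 15, "missense": 20, "stop_gain": 8, "stop_loss": 5,
        "splice_donor": 10, "splice_acceptor": 10, "utr5": 8, "utr3": 8,
        "intronic": 15, "intergenic": 10, "frameshift": 10,
        "inframe_indel": 8, "intronic_indel": 5,
    }
    cat = simulate_variant_catalog(gene_models, counts, seed=42)
    table, _ = annotate_variants(
        cat.variants, gene_models.transcripts, gene_models.genome
    )
    merged = cat.truth.merge(table, on="variant_id", validate="1:1")
    mismatch = merged[merged["expected_consequence"] != merged["consequence"]]
    assert mismatch.empty, mismatch[["variant_id", "true_class", "consequence"]]


# ---------------------------------------------------------------------------
# strand symmetry property


def _mirror_variant(v, genome):
    from riphewas.genome import revcomp

    length = genome.length(v.chromosome)
    if v.is_snv:
        return VariantRecord(
            v.chromosome, length - v.pos0, revcomp(v.ref), revcomp(v.alt)
        )
    # mirror the affected interval, rebuild with the anchor base to its left
    a, b = v.affected_interval()
    na, nb = length - b, length - a
    anchor_pos = na - 1
    mirrored = genome.reverse_complemented()
    anchor = mirrored.base(v.chromosome, anchor_pos)
    if v.variant_class == "deletion":
        deleted = mirrored.fetch(v.chromosome, na, nb)
        return VariantRecord(v.chromosome, anchor_pos + 1, anchor + deleted, anchor)
    inserted = revcomp(v.alt[len(v.ref):])
    return VariantRecord(v.chromosome, anchor_pos + 1, anchor, anchor + inserted)


def test_strand_symmetry(gene_models):
    counts = {
        "synonymous": 5, "missense": 5, "stop_gain": 3, "stop_loss": 3,
        "splice_donor": 4, "splice_acceptor": 4, "intronic": 5,
        "frameshift": 4, "inframe_indel": 4,
    }
    cat = simulate_variant_catalog(gene_models, counts, seed=77)
    genome = gene_models.genome
    mirrored_genome = genome.reverse_complemented()
    chrom = genome.chromosomes[0]
    length = genome.length(chrom)
    mirrored_tx = [t.mirrored(length) for t in gene_models.transcripts]
    table, _ = annotate_variants(cat.variants, gene_models.transcripts, genome)
    mv = [_mirror_variant(v, genome) for v in cat.variants]
    mtable, _ = annotate_variants(mv, mirrored_tx, mirrored_genome)
    fwd = dict(zip(table["variant_id"], table["consequence"]))
    rev = {
        _mirror_variant(v, genome).variant_id: fwd[v.variant_id]
        for v in cat.variants
    }
    for _, row in mtable.iterrows():
        assert row["consequence"] == rev[row["variant_id"]], row["variant_id"]


# ---------------------------------------------------------------------------
# QC arithmetic


class TestPlatformFpr:
    def test_first_platform(self):
        assert platform_fpr(4_160_570, 3_375_198, 0.0234) == pytest.approx(
            0.0044, abs=5e-5
        )

    def test_second_platform(self):
        assert platform_fpr(4_090_000, 3_375_198, 0.0373) == pytest.approx(
            0.0065, abs=5e-5
        )

    def test_all_shared_is_zero(self):
        assert platform_fpr(100, 100, 0.5) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            platform_fpr(0, 0, 0.1)
        with pytest.raises(ValueError):
            platform_fpr(10, 20, 0.1)
        with pytest.raises(ValueError):
            platform_fpr(10, 5, 1.5)


def test_combine_class_counts():
    assert combine_class_counts({"a": 23_089, "b": 11_979}) == 35_068
    with pytest.raises(ValueError):
        combine_class_counts({"a": -1})
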