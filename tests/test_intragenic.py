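"""Transcript selection, reading-frame arithmetic, and NMD prediction."""

import random

import pytest

from cnvscore.database import load_database
from cnvscore.intragenic import (
    Pvs1Strength,
    TandemStatus,
    evaluate_deletion,
    evaluate_duplication,
    predict_nmd_deletion,
    select_transcript,
)
from cnvscore.models import CnvQuery, Dosage, GenomicInterval

from helpers import brute_force_nmd_deletion, make_gene, random_gene, write_db


def loss(chrom, start, end):
    return CnvQuery(GenomicInterval(chrom, start, end), Dosage.LOSS)


def gain(chrom, start, end):
    return CnvQuery(GenomicInterval(chrom, start, end), Dosage.GAIN)


class TestSelectTranscript:
    def test_canonical_flag_beats_length(self):
        short = make_gene(symbol="G", gene_id="G.short", exon_lens=(100,), utr=10,
                          is_canonical=True)
        long = make_gene(symbol="G", gene_id="G.long", start=20_000)
        assert select_transcript([long, short]) is short

    def test_singleton(self):
        only = make_gene()
        assert select_transcript([only]) is only

    def test_longest_cds_among_unflagged(self):
        cds900 = make_gene(symbol="G", gene_id="G.a", exon_lens=(500, 600), utr=100)
        cds600 = make_gene(symbol="G", gene_id="G.b", start=30_000,
                           exon_lens=(400, 400), utr=100)
        assert cds900.total_cds_bases() == 900
        assert cds600.total_cds_bases() == 600
        assert select_transcript([cds600, cds900]) is cds900

    def test_tie_breaks_deterministic(self):
        a = make_gene(symbol="G", gene_id="G.a")
        b = make_gene(symbol="G", gene_id="G.b")
        assert select_transcript([b, a]).gene_id == "G.a"

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            select_transcript([])


class TestEvaluateDeletion:
    def test_frameshifting_internal_exon_is_pvs1(self):
        # 4 exons; exon 2 has 100 coding bases (100 % 3 != 0) with two
        # downstream junctions -> frameshift, NMD, PVS1
        gene = make_gene(start=10_000, exon_lens=(200, 100, 200, 200))
        call = evaluate_deletion(loss("chr1", 10_950, 11_150), gene)
        assert call.frame_disrupted and call.nmd_predicted
        assert call.strength is Pvs1Strength.PVS1

    def test_in_frame_above_ten_percent_is_strong(self):
        gene = make_gene(start=10_000)  # 600 coding bases
        call = evaluate_deletion(loss("chr1", 11_000, 11_071), gene)  # 72 bases = 12%
        assert not call.frame_disrupted
        assert call.fraction_protein_removed == pytest.approx(0.12)
        assert call.strength is Pvs1Strength.PVS1_STRONG

    def test_in_frame_below_ten_percent_is_moderate(self):
        gene = make_gene(start=10_000)
        call = evaluate_deletion(loss("chr1", 11_000, 11_023), gene)  # 24 bases = 4%
        assert call.strength is Pvs1Strength.PVS1_MODERATE

    def test_last_exon_frameshift_escapes_nmd(self):
        gene = make_gene(start=10_000, exon_lens=(200, 200, 200, 200))
        # delete 100 coding bases of the last exon: PTC downstream of the
        # final junction -> NMD escape, falls to the fraction branch
        call = evaluate_deletion(loss("chr1", 13_000, 13_099), gene)
        assert call.frame_disrupted and not call.nmd_predicted
        assert call.strength in (Pvs1Strength.PVS1_STRONG, Pvs1Strength.PVS1_MODERATE)

    def test_critical_region_forces_strong(self, tmp_path):
        gene = make_gene(symbol="G1", start=10_000)
        db = load_database(
            write_db(tmp_path / "d", genes=[gene],
                     critical_rows=[("G1", "chr1", 11_000, 11_100, "domain")])
        )
        call = evaluate_deletion(loss("chr1", 11_000, 11_023), gene, db)
        assert call.critical_region_hit
        assert call.strength is Pvs1Strength.PVS1_STRONG

    def test_frequent_lof_blocks_fraction_branch(self, tmp_path):
        gene = make_gene(symbol="G1", start=10_000)
        db = load_database(
            write_db(tmp_path / "d", genes=[gene],
                     variant_rows=[("chr1", 11_010, 11_010, "G1", "PATHOGENIC", 0.005)])
        )
        call = evaluate_deletion(loss("chr1", 11_000, 11_023), gene, db)
        assert call.lof_frequent
        assert call.strength is Pvs1Strength.NONE

    def test_intronic_deletion_has_no_strength(self):
        gene = make_gene(start=10_000)
        call = evaluate_deletion(loss("chr1", 10_300, 10_900), gene)
        assert call.fraction_protein_removed == 0.0
        assert call.strength is Pvs1Strength.NONE

    def test_utr_bases_do_not_change_protein_fraction(self):
        gene = make_gene(start=10_000)
        inner = evaluate_deletion(loss("chr1", 11_000, 11_071), gene)
        with_intron = evaluate_deletion(loss("chr1", 10_980, 11_071), gene)
        # same 72 coding bases deleted once intronic padding is added
        assert with_intron.fraction_protein_removed == pytest.approx(0.12)
        assert inner.fraction_protein_removed == with_intron.fraction_protein_removed

    def test_not_contained_is_contract_violation(self):
        gene = make_gene(start=10_000)
        with pytest.raises(ValueError):
            evaluate_deletion(loss("chr1", 9_000, 11_000), gene)

    def test_multiple_of_three_never_frameshifts(self):
        rng = random.Random(5)
        for _ in range(100):
            gene = random_gene(rng)
            span = gene.interval
            a = rng.randint(span.start, span.end)
            b = rng.randint(span.start, span.end)
            q = GenomicInterval("chr1", min(a, b), max(a, b))
            deleted = sum(q.overlap_bp(p) for p in gene.coding_exon_parts())
            call = evaluate_deletion(CnvQuery(q, Dosage.LOSS), gene)
            assert call.frame_disrupted == (deleted % 3 != 0)

    def test_nmd_matches_brute_force_reconstruction(self):
        """200 random intragenic deletions vs base-by-base transcript rebuild."""
        rng = random.Random(17)
        checked = 0
        while checked < 200:
            gene = random_gene(rng)
            span = gene.interval
            a = rng.randint(span.start, span.end)
            b = rng.randint(span.start, span.end)
            q = GenomicInterval("chr1", min(a, b), max(a, b))
            assert predict_nmd_deletion(gene, q) == brute_force_nmd_deletion(gene, q)
            checked += 1


class TestEvaluateDuplication:
    def _hi_gene(self):
        return make_gene(start=10_000, exon_lens=(200, 200, 200, 200))

    def test_tandem_proven_frameshift_is_pvs1(self):
        call = evaluate_duplication(
            gain("chr1", 10_950, 11_250), self._hi_gene(), TandemStatus.PROVEN
        )
        assert call.frame_disrupted and call.nmd_predicted
        assert call.strength is Pvs1Strength.PVS1

    def test_tandem_assumed_is_strong(self):
        call = evaluate_duplication(
            gain("chr1", 10_950, 11_250), self._hi_gene(), TandemStatus.ASSUMED
        )
        assert call.strength is Pvs1Strength.PVS1_STRONG

    def test_in_frame_whole_exon_duplication_is_none(self):
        # duplicate an exon whose coding length is divisible by 3
        gene = make_gene(start=10_000, exon_lens=(200, 201, 200, 200))
        call = evaluate_duplication(
            gain("chr1", 10_950, 11_250), gene, TandemStatus.PROVEN
        )
        assert not call.frame_disrupted
        assert call.strength is Pvs1Strength.NONE

    def test_unknown_tandem_defers_to_manual(self):
        call = evaluate_duplication(
            gain("chr1", 10_950, 11_250), self._hi_gene(), TandemStatus.UNKNOWN
        )
        assert call.strength is Pvs1Strength.NONE

    def test_last_exon_duplication_escapes_nmd(self):
        call = evaluate_duplication(
            gain("chr1", 13_000, 13_100), self._hi_gene(), TandemStatus.PROVEN
        )
        assert not call.nmd_predicted
        assert call.strength is Pvs1Strength.NONE
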