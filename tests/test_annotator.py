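"""Overlap taxonomy, gene content, and common-variant facts."""

import random

import pytest

from cnvscore.annotator import (
    Containment,
    OverlapRelation,
    annotate,
    classify_gene_overlap,
    common_variant_facts,
)
from cnvscore.database import load_database, parse_cnv
from cnvscore.models import CnvQuery, Dosage, GenomicInterval

from helpers import brute_force_overlaps, make_gene, random_gene, write_db


class TestClassifyGeneOverlap:
    def test_intronic_cnv_is_within_no_exons(self):
        gene = make_gene(start=10_000)  # exons at 10000,11000,12000,13000 (+199)
        detail = classify_gene_overlap(GenomicInterval("chr1", 10_300, 10_900), gene)
        assert detail.relation is OverlapRelation.CNV_WITHIN_ELEMENT
        assert detail.exons_involved == ()
        assert not detail.coding_sequence_involved

    def test_minus_strand_genomic_3prime_half_is_transcriptional_5prime(self):
        # 3-exon minus-strand gene: transcription runs right to left, so a
        # CNV covering the genomic right half hits the transcriptional 5' end
        gene = make_gene(strand="-", exon_lens=(200, 200, 200), start=10_000)
        detail = classify_gene_overlap(GenomicInterval("chr1", 11_500, 13_000), gene)
        assert detail.relation is OverlapRelation.PARTIAL_5PRIME
        # exon 1 in transcription order is the genomic-rightmost exon
        assert 1 in detail.exons_involved

    def test_plus_strand_terminal_exon_coding_part(self):
        gene = make_gene(start=10_000)  # last exon 13000-13199, CDS ends 13099
        detail = classify_gene_overlap(GenomicInterval("chr1", 12_500, 13_300), gene)
        assert detail.relation is OverlapRelation.PARTIAL_3PRIME
        assert detail.only_last_exon
        assert detail.coding_sequence_involved
        assert not detail.only_3prime_utr

    def test_3prime_utr_only(self):
        gene = make_gene(start=10_000)
        detail = classify_gene_overlap(GenomicInterval("chr1", 13_100, 13_400), gene)
        assert detail.only_3prime_utr
        assert not detail.coding_sequence_involved
        assert detail.only_last_exon

    def test_5prime_utr_only(self):
        gene = make_gene(start=10_000)
        detail = classify_gene_overlap(GenomicInterval("chr1", 9_500, 10_099), gene)
        assert detail.relation is OverlapRelation.PARTIAL_5PRIME
        assert not detail.coding_sequence_involved

    def test_containment_both_ways(self):
        gene = make_gene(start=10_000)
        assert (
            classify_gene_overlap(GenomicInterval("chr1", 9_000, 14_000), gene).relation
            is OverlapRelation.CNV_CONTAINS_ELEMENT
        )
        assert (
            classify_gene_overlap(GenomicInterval("chr1", 10_500, 12_500), gene).relation
            is OverlapRelation.CNV_WITHIN_ELEMENT
        )

    def test_disjoint_is_contract_violation(self):
        gene = make_gene(start=10_000)
        with pytest.raises(ValueError):
            classify_gene_overlap(GenomicInterval("chr1", 1, 100), gene)

    def test_strand_mirror_symmetry(self):
        """Mirroring all coordinates and flipping strand preserves the relation."""
        rng = random.Random(11)
        mirror_at = 2_000_000
        for _ in range(200):
            gene = random_gene(rng)
            span = gene.interval
            a = rng.randint(span.start - 400, span.end + 400)
            b = rng.randint(span.start - 400, span.end + 400)
            lo, hi = min(a, b), max(a, b)
            query = GenomicInterval("chr1", max(1, lo), max(1, hi))
            if not query.overlaps(span):
                continue
            flipped = "-" if gene.strand.value == "+" else "+"
            from cnvscore.models import GeneModel, Strand

            mirrored_exons = sorted(
                (GenomicInterval("chr1", mirror_at - e.end, mirror_at - e.start)
                 for e in gene.exons),
                key=lambda e: e.start,
            )
            if flipped == "-":
                mirrored_exons = list(reversed(mirrored_exons))
            mirrored_gene = GeneModel(
                gene_id=gene.gene_id,
                symbol=gene.symbol,
                interval=GenomicInterval("chr1", mirror_at - span.end, mirror_at - span.start),
                strand=Strand(flipped),
                exons=tuple(mirrored_exons),
                cds_start=mirror_at - gene.cds_end,
                cds_end=mirror_at - gene.cds_start,
            )
            mirrored_query = GenomicInterval("chr1", mirror_at - query.end, mirror_at - query.start)
            orig = classify_gene_overlap(query, gene)
            mirr = classify_gene_overlap(mirrored_query, mirrored_gene)
            assert orig.relation is mirr.relation
            assert orig.exons_involved == mirr.exons_involved
            assert orig.coding_sequence_involved == mirr.coding_sequence_involved


class TestAnnotate:
    def test_worked_example_region_and_gene_count(self, db):
        """chr22 deletion: 32 coding genes, fully spanned score-3 HI region."""
        query = parse_cnv("chr22:18,761,827-20,307,561", "loss")
        ann = annotate(query, db)
        assert ann.gene_count == 32
        assert ann.functionally_important
        assert any(
            rel is OverlapRelation.CNV_CONTAINS_ELEMENT for _, rel in ann.hi_overlaps
        )

    def test_gene_desert(self, db):
        ann = annotate(parse_cnv("chr20:1-1000", "loss"), db)
        assert ann.gene_count == 0
        assert not ann.functionally_important
        assert ann.common_variant_facts == []

    def test_gene_count_matches_brute_force(self, db):
        rng = random.Random(3)
        records = [g for g in db.genes if g.is_protein_coding]
        chroms = sorted({g.interval.chrom for g in records})
        for _ in range(200):
            chrom = rng.choice(chroms)
            a = rng.randint(1, 60_000_000)
            q = GenomicInterval(chrom, a, a + rng.randint(1_000, 3_000_000))
            ann = annotate(CnvQuery(q, Dosage.LOSS), db)
            expected = len({g.symbol for g in brute_force_overlaps(records, q)})
            assert ann.gene_count == expected

    def test_within_containment_iff_full_fraction(self, db, fixture_dir):
        import csv

        with open(fixture_dir / "suite.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                q = parse_cnv(row["coordinate"], row["dosage"])
                for fact in annotate(q, db).common_variant_facts:
                    assert (fact.overlap_fraction_of_cnv == 1.0) == (
                        fact.containment is Containment.CNV_WITHIN
                    )


class TestCommonVariantFacts:
    @pytest.fixture()
    def popdb(self, tmp_path):
        gene = make_gene(symbol="G1", start=50_000, utr=50)
        rows = [
            ("common_loss", "chr1", 10_000, 100_000, "loss", 0.1245, 1500, "SAMPLE_COUNTED"),
            ("rare_loss", "chr1", 10_000, 100_000, "loss", 0.009, 9000, "SAMPLE_COUNTED"),
            ("small_cohort", "chr1", 10_000, 100_000, "loss", 0.10, 999, "SAMPLE_COUNTED"),
            ("common_gain", "chr1", 10_000, 100_000, "gain", 0.20, 5000, "ALLELE_COUNTED"),
            ("thin_alleles", "chr1", 10_000, 100_000, "gain", 0.20, 1999, "ALLELE_COUNTED"),
        ]
        return load_database(write_db(tmp_path / "d", genes=[gene], popvar_rows=rows))

    def test_filters_and_containment(self, popdb):
        query = parse_cnv("chr1:40000-60000", "loss")
        facts = common_variant_facts(query, popdb)
        assert [f.variant.variant_id for f in facts] == ["common_loss"]
        fact = facts[0]
        assert fact.containment is Containment.CNV_WITHIN
        assert fact.overlap_fraction_of_cnv == 1.0
        assert fact.extra_protein_genes == 0

    def test_dosage_match_and_cohort_kinds(self, popdb):
        gain_facts = common_variant_facts(parse_cnv("chr1:40000-60000", "gain"), popdb)
        assert [f.variant.variant_id for f in gain_facts] == ["common_gain"]

    def test_partial_overlap_fraction_exact(self, popdb):
        # CNV chr1:90001-110000 (20000 bp), variant ends at 100000 -> 10000 bp shared
        facts = common_variant_facts(parse_cnv("chr1:90001-110000", "loss"), popdb)
        assert facts[0].containment is Containment.OVERLAP
        assert facts[0].overlap_fraction_of_cnv == pytest.approx(0.5)
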