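"""Shared sections (1, 3, 4O), the single-winner rule, and both
dosage-specific Section-2 trees exercised through the full pipeline."""

import csv

import pytest

from cnvscore.annotator import (
    AnnotationResult,
    CommonVariantFact,
    Containment,
    annotate,
)
from cnvscore.database import parse_cnv
from cnvscore.evidence import EvidenceItem
from cnvscore.models import (
    CnvQuery,
    Dosage,
    GenomicInterval,
    PopulationVariant,
    SourceKind,
)
from cnvscore.pipeline import interpret, run_automated
from cnvscore.scoring import (
    pick_section2_winner,
    score_section1,
    score_section3,
    score_section4_auto,
)
from cnvscore.scoring_gain import score_section2_gain
from cnvscore.scoring_loss import score_section2_loss


def bare_annotation(dosage: Dosage, gene_count: int = 0,
                    functionally_important: bool = False, facts=()) -> AnnotationResult:
    query = CnvQuery(GenomicInterval("chr1", 1000, 2000), dosage)
    return AnnotationResult(
        query=query,
        protein_coding_genes=[],
        gene_count=gene_count,
        functionally_important=functionally_important,
        hi_overlaps=[],
        ts_overlaps=[],
        benign_overlaps=[],
        gene_overlap_details=[],
        predicted_hi_genes=[],
        common_variant_facts=list(facts),
    )


def make_fact(containment, fraction, extra):
    variant = PopulationVariant(
        "PV1", GenomicInterval("chr1", 500, 5000), Dosage.LOSS, 0.05, 5000,
        SourceKind.SAMPLE_COUNTED,
    )
    return CommonVariantFact(variant, containment, fraction, extra)


class TestSection1:
    def test_genes_present(self, cfg):
        item = score_section1(bare_annotation(Dosage.LOSS, gene_count=32), cfg)
        assert (item.category, item.points) == ("1A", 0.0)

    def test_empty_region(self, cfg):
        item = score_section1(bare_annotation(Dosage.LOSS), cfg)
        assert (item.category, item.points) == ("1B", -0.6)

    def test_functionally_important_element_without_genes(self, cfg):
        item = score_section1(
            bare_annotation(Dosage.GAIN, functionally_important=True), cfg
        )
        assert (item.category, item.points) == ("1A", 0.0)


class TestSection3:
    @pytest.mark.parametrize(
        "dosage,count,category,points",
        [
            (Dosage.LOSS, 0, "3A", 0.0),
            (Dosage.LOSS, 24, "3A", 0.0),
            (Dosage.LOSS, 25, "3B", 0.45),
            (Dosage.LOSS, 32, "3B", 0.45),
            (Dosage.LOSS, 34, "3B", 0.45),
            (Dosage.LOSS, 35, "3C", 0.9),
            (Dosage.LOSS, 49, "3C", 0.9),
            (Dosage.GAIN, 34, "3A", 0.0),
            (Dosage.GAIN, 35, "3B", 0.45),
            (Dosage.GAIN, 49, "3B", 0.45),
            (Dosage.GAIN, 50, "3C", 0.9),
        ],
    )
    def test_band_boundaries(self, cfg, dosage, count, category, points):
        item = score_section3(bare_annotation(dosage, gene_count=count), cfg)
        assert (item.category, item.points) == (category, points)

    def test_monotone_in_gene_count(self, cfg):
        points = [
            score_section3(bare_annotation(Dosage.LOSS, gene_count=n), cfg).points
            for n in range(0, 60)
        ]
        assert points == sorted(points)


class TestSection4:
    def test_containment_fires(self, cfg):
        ann = bare_annotation(
            Dosage.LOSS, facts=[make_fact(Containment.CNV_WITHIN, 1.0, 0)]
        )
        item = score_section4_auto(ann, cfg)
        assert (item.category, item.points) == ("4O", -1.0)

    def test_half_overlap_no_extra_genes_fires(self, cfg):
        ann = bare_annotation(
            Dosage.LOSS, facts=[make_fact(Containment.OVERLAP, 0.5, 0)]
        )
        assert score_section4_auto(ann, cfg).points == -1.0

    def test_just_below_half_does_not_fire(self, cfg):
        ann = bare_annotation(
            Dosage.LOSS, facts=[make_fact(Containment.OVERLAP, 0.49, 0)]
        )
        assert score_section4_auto(ann, cfg) is None

    def test_extra_genes_block_overlap_branch(self, cfg):
        ann = bare_annotation(
            Dosage.LOSS, facts=[make_fact(Containment.OVERLAP, 0.9, 2)]
        )
        assert score_section4_auto(ann, cfg) is None


class TestSingleWinner:
    def test_only_highest_contributes(self):
        items = [
            EvidenceItem("2B", 0.0, 0.0, 0.0),
            EvidenceItem("2C-1", 0.9, 0.45, 1.0),
            EvidenceItem("2E", 0.45, 0.3, 0.9),
        ]
        marked, winner = pick_section2_winner(items)
        assert winner.category == "2C-1"
        assert [i.category for i in marked if i.contributes] == ["2C-1"]
        assert len(marked) == 3  # every candidate stays on record

    def test_tie_goes_to_first_emitted(self):
        items = [EvidenceItem("2A", 1.0, 1.0, 1.0), EvidenceItem("2A", 1.0, 1.0, 1.0)]
        marked, winner = pick_section2_winner(items)
        assert marked[0].contributes and not marked[1].contributes


class TestSection2Dispatch:
    def test_loss_scorer_rejects_gain(self, db, cfg):
        ann = annotate(parse_cnv("chr22:18761827-20307561", "gain"), db)
        with pytest.raises(ValueError):
            score_section2_loss(ann, db, cfg)

    def test_gain_scorer_rejects_loss(self, db, cfg):
        ann = annotate(parse_cnv("chr22:18761827-20307561", "loss"), db)
        with pytest.raises(ValueError):
            score_section2_gain(ann, db, cfg)


class TestTerminalBenign:
    def _suite_query(self, fixture_dir, label):
        with open(fixture_dir / "suite.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                if row["label"] == label:
                    return parse_cnv(row["coordinate"], row["dosage"], label=label)
        raise AssertionError(f"label {label} not in suite")

    def test_loss_benign_containment_fixes_total(self, db, cfg, fixture_dir):
        card = interpret(self._suite_query(fixture_dir, "loss_2f_within"), db, cfg)
        assert card.terminal_benign
        assert card.auto_total == -1.0
        assert card.final_classification.value == "benign"
        assert [i.category for i in card.items if i.contributes] == ["2F"]

    def test_gain_terminal_can_be_disabled(self, db, cfg, fixture_dir):
        query = self._suite_query(fixture_dir, "gain_2c")
        on = interpret(query, db, cfg)
        off = interpret(query, db, cfg, terminal_benign_gain=False)
        assert on.terminal_benign and not off.terminal_benign
        assert off.auto_total == -1.0  # 1A + 2C + 3A still sums to -1
        assert {i.category for i in off.items if i.contributes} >= {"1A", "2C", "3A"}

    def test_gain_never_gets_loss_only_categories(self, db, cfg, fixture_dir):
        loss_only = {"2C-1", "2C-2", "2D-1", "2D-2", "2D-3", "2D-4"}
        with open(fixture_dir / "suite.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                if row["dosage"] != "gain":
                    continue
                card = interpret(parse_cnv(row["coordinate"], "gain"), db, cfg)
                assert not loss_only & {i.category for i in card.items}

    def test_all_emitted_points_within_configured_ranges(self, db, cfg, fixture_dir):
        with open(fixture_dir / "suite.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                card = interpret(parse_cnv(row["coordinate"], row["dosage"]), db, cfg)
                for item in card.items:
                    assert item.range_min <= item.points <= item.range_max


class TestConflictFlags:
    def test_benign_containment_with_positive_evidence_flagged(self, tmp_path, cfg):
        from helpers import make_gene, write_db
        from cnvscore.database import load_database

        hi = make_gene(symbol="HI1", start=20_000, pli=0.99, oe_upper=0.1, hi_index=2.0)
        db = load_database(
            write_db(
                tmp_path / "d",
                genes=[hi],
                dosage_rows=[
                    ("HIG1", "chr1", 20_000, hi.interval.end, "HI_GENE", 3, "HI1"),
                    ("BL1", "chr1", 10_000, 40_000, "BENIGN_LOSS", "", ""),
                ],
            )
        )
        # deletion spans the HI gene and sits inside the benign region
        card = interpret(parse_cnv("chr1:15000-30000", "loss"), db, cfg)
        assert not card.terminal_benign
        assert any(i.category == "2A" and i.contributes for i in card.items)
        assert any(i.category == "2F" and not i.contributes for i in card.items)
        assert any("2F" in flag or "benign" in flag for flag in card.conflicts)
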