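"""Deterministic synthetic annotation database and CNV test suite.

Every automated branch of the scoring metric is exercisable offline: the
generator lays out gene models, dosage-map elements, benign regions,
population CNVs and known variants by explicit geometry, places one or
more CNVs per scoring branch, and records the expected evidence and
classification *constructively* — the expectations are derived from the
construction itself, never by running the scoring engine, so the suite is
an independent oracle for it.

The database also carries replicas of three published worked examples: a
chr22 deletion spanning an established HI region with 32 contained
protein-coding genes, a 49-gene deletion on chr11, and a deletion inside a
12.45 %-frequency population loss on chr1.

Only cosmetic gene attributes (constraint-metric values of genes that must
NOT trip any predictor) are drawn from the seeded RNG; all geometry that
decides a category is fixed, so a given seed always reproduces the same
files byte for byte.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple


@dataclass(frozen=True)
class FixtureParams:
    """Scenario sizes; defaults match the published worked examples."""

    case1_genes: int = 32
    dbvar_3c_genes: int = 49
    loss_3b_genes: int = 25
    loss_3c_genes: int = 35
    gain_3b_genes: int = 35
    gain_3c_genes: int = 50

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _classification(total_cents: int) -> str:
    """Published five-tier bands, on integer hundredths of a point."""
    if total_cents >= 99:
        return "pathogenic"
    if total_cents >= 90:
        return "likely pathogenic"
    if total_cents > -90:
        return "uncertain significance"
    if total_cents > -99:
        return "likely benign"
    return "benign"


class _Builder:
    """Accumulates database rows, suite CNVs and constructive expectations."""

    def __init__(self, seed: int, params: FixtureParams) -> None:
        self.rng = random.Random(seed)
        self.params = params
        self.gene_rows: List[tuple] = []
        self.dosage_rows: List[tuple] = []
        self.popvar_rows: List[tuple] = []
        self.variant_rows: List[tuple] = []
        self.critical_rows: List[tuple] = []
        self.suite_rows: List[tuple] = []
        self.expected: Dict[str, dict] = {}
        self._window = 0
        self._region_n = 0

    # -- allocation ------------------------------------------------------

    def window(self) -> Tuple[str, int]:
        """A fresh (chrom, base) pair; windows never collide."""
        chrom = f"chr{2 + self._window % 9}"
        base = 10_000_000 + self._window * 1_000_000
        self._window += 1
        return chrom, base

    def _region_id(self, prefix: str) -> str:
        self._region_n += 1
        return f"{prefix}{self._region_n:04d}"

    # -- record factories ------------------------------------------------

    def gene(
        self,
        chrom: str,
        start: int,
        symbol: str,
        strand: str = "+",
        n_exons: int = 4,
        exon_len: int = 200,
        intron_len: int = 800,
        utr: int = 100,
        coding: bool = True,
        pli: Optional[float] = None,
        oe_upper: Optional[float] = None,
        hi_index: Optional[float] = None,
        relevant: bool = True,
    ) -> dict:
        """A gene with evenly spaced exons; returns its layout facts.

        Constraint metrics left unset are jittered into the clearly
        unconstrained range so the gene never trips the HI predictors.
        """
        pitch = exon_len + intron_len
        exon_starts = [start + i * pitch for i in range(n_exons)]
        exon_ends = [s + exon_len - 1 for s in exon_starts]
        end = exon_ends[-1]
        cds_start = start + utr if coding else ""
        cds_end = end - utr if coding else ""
        if pli is None:
            pli = round(self.rng.uniform(0.0, 0.3), 3)
        if oe_upper is None:
            oe_upper = round(self.rng.uniform(0.5, 1.5), 3)
        if hi_index is None:
            hi_index = round(self.rng.uniform(25.0, 90.0), 1)
        self.gene_rows.append(
            (
                f"{symbol}.t1", symbol, chrom, start, end, strand,
                cds_start, cds_end,
                ",".join(str(s) for s in exon_starts),
                ",".join(str(e) for e in exon_ends),
                int(coding), 1, pli, oe_upper, hi_index, int(relevant),
            )
        )
        return {
            "symbol": symbol, "chrom": chrom, "start": start, "end": end,
            "exon_starts": exon_starts, "exon_ends": exon_ends,
            "cds_start": cds_start, "cds_end": cds_end,
        }

    def gene_grid(self, chrom: str, start: int, count: int, prefix: str) -> Tuple[int, int]:
        """*count* small 2-exon genes at 3-kb pitch; returns (first, last) bounds."""
        for i in range(count):
            self.gene(
                chrom, start + i * 3000, f"{prefix}{i + 1:03d}",
                n_exons=2, exon_len=200, intron_len=800, utr=50,
            )
        return start, start + (count - 1) * 3000 + 1199

    def dosage(self, chrom: str, start: int, end: int, kind: str,
               score: Optional[int] = None, gene_id: str = "") -> str:
        rid = self._region_id({"HI_GENE": "HIG", "HI_REGION": "HIR",
                               "TS_GENE": "TSG", "TS_REGION": "TSR",
                               "BENIGN_LOSS": "BL", "BENIGN_GAIN": "BG"}[kind])
        self.dosage_rows.append((rid, chrom, start, end, kind,
                                 "" if score is None else score, gene_id))
        return rid

    def hi_gene(self, layout: dict, score: int = 3) -> str:
        return self.dosage(layout["chrom"], layout["start"], layout["end"],
                           "HI_GENE", score, layout["symbol"])

    def popvar(self, chrom: str, start: int, end: int, dosage: str,
               frequency: float, cohort: int, source: str) -> str:
        vid = self._region_id("PV")
        self.popvar_rows.append((vid, chrom, start, end, dosage, frequency, cohort, source))
        return vid

    def known_variant(self, chrom: str, pos: int, gene: str,
                      significance: str, af: float) -> None:
        self.variant_rows.append((chrom, pos, pos, gene, significance, af))

    # -- suite bookkeeping -----------------------------------------------

    def cnv(
        self,
        label: str,
        chrom: str,
        start: int,
        end: int,
        dosage: str,
        items: Dict[str, float],
        terminal: bool = False,
        tandem: str = "unknown",
    ) -> None:
        """Register a suite CNV with its constructively expected evidence.

        *items* lists the contributing categories and their points; the
        expected total, classification and sufficiency flag follow from
        them by the published band arithmetic.
        """
        total_cents = sum(round(p * 100) for p in items.values())
        self.suite_rows.append((label, f"{chrom}:{start}-{end}", dosage, tandem))
        self.expected[label] = {
            "items": dict(items),
            "auto_total": total_cents / 100,
            "classification": _classification(total_cents),
            "terminal": terminal,
            "sufficient_without_manual": abs(total_cents) >= 99 or terminal,
        }


# ---------------------------------------------------------------------------
# Scenario construction


def _build(seed: int, params: FixtureParams) -> _Builder:
    b = _Builder(seed, params)
    p = params

    # ---- published worked-example replicas ------------------------------
    # chr22 deletion spanning an established HI region with 32 coding genes
    cnv_start, cnv_end = 18_761_827, 20_307_561
    b.dosage("chr22", 18_912_231, 20_287_208, "HI_REGION", 3)
    for i in range(p.case1_genes):
        b.gene("chr22", 19_000_000 + i * 40_000, f"C22G{i + 1:03d}",
               n_exons=2, exon_len=200, intron_len=800, utr=50)
    case1_sec3 = "3C" if p.case1_genes >= 35 else ("3B" if p.case1_genes >= 25 else "3A")
    case1_pts = {"3A": 0.0, "3B": 0.45, "3C": 0.9}[case1_sec3]
    b.cnv("case1", "chr22", cnv_start, cnv_end, "loss",
          {"1A": 0.0, "2A": 1.0, case1_sec3: case1_pts})

    # chr11 49-gene deletion scoring 3C
    b.gene_grid("chr11", 55_300_000, p.dbvar_3c_genes, "C11G")
    dbvar_sec3 = "3C" if p.dbvar_3c_genes >= 35 else ("3B" if p.dbvar_3c_genes >= 25 else "3A")
    b.cnv("dbvar_3c", "chr11", 55_213_165, 56_882_257, "loss",
          {"1A": 0.0, dbvar_sec3: {"3A": 0.0, "3B": 0.45, "3C": 0.9}[dbvar_sec3]})

    # chr1 deletion inside a 12.45 %-frequency common population loss
    b.popvar("chr1", 196_757_278, 196_796_716, "loss", 0.1245, 1500, "SAMPLE_COUNTED")
    b.gene("chr1", 196_765_000, "C1G001", n_exons=2, utr=50)
    b.cnv("dbvar_4o", "chr1", 196_760_000, 196_790_000, "loss",
          {"1A": 0.0, "3A": 0.0, "4O": -1.0})

    # ---- loss: Section 1 -------------------------------------------------
    chrom, base = b.window()
    b.gene(chrom, base, "L1A001")
    b.cnv("loss_1a", chrom, base - 500, base + 4000, "loss", {"1A": 0.0, "3A": 0.0})

    chrom, base = b.window()
    b.cnv("loss_1b", chrom, base, base + 50_000, "loss", {"1B": -0.6, "3A": 0.0})

    # ---- loss: established HI (2A-2E) -----------------------------------
    chrom, base = b.window()
    g = b.gene(chrom, base, "HIA001", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("loss_2a_gene", chrom, base - 1000, base + 4200, "loss",
          {"1A": 0.0, "2A": 1.0, "3A": 0.0})

    chrom, base = b.window()
    b.dosage(chrom, base, base + 100_000, "HI_REGION", 3)
    b.gene(chrom, base + 120_000, "L2B001")
    b.cnv("loss_2b", chrom, base + 90_000, base + 150_000, "loss",
          {"1A": 0.0, "2B": 0.0, "3A": 0.0})

    chrom, base = b.window()
    g = b.gene(chrom, base, "HIC001", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("loss_2c1", chrom, base - 500, base + 1500, "loss",
          {"1A": 0.0, "2C-1": 0.9, "3A": 0.0})

    chrom, base = b.window()
    g = b.gene(chrom, base, "HIC002", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("loss_2c2", chrom, base - 500, base + 99, "loss",
          {"1A": 0.0, "2C-2": 0.0, "3A": 0.0})

    chrom, base = b.window()
    g = b.gene(chrom, base, "HID001", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("loss_2d1", chrom, base + 3100, base + 3500, "loss",
          {"1A": 0.0, "2D-1": 0.0, "3A": 0.0})

    chrom, base = b.window()
    g = b.gene(chrom, base, "HID002", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.known_variant(chrom, base + 3010, "HID002", "PATHOGENIC", 0.0001)
    b.cnv("loss_2d2", chrom, base + 2500, base + 3500, "loss",
          {"1A": 0.0, "2D-2": 0.9, "3A": 0.0})

    chrom, base = b.window()
    g = b.gene(chrom, base, "HID003", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("loss_2d3", chrom, base + 2500, base + 3500, "loss",
          {"1A": 0.0, "2D-3": 0.3, "3A": 0.0})

    chrom, base = b.window()
    g = b.gene(chrom, base, "HID004", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("loss_2d4", chrom, base + 1500, base + 3500, "loss",
          {"1A": 0.0, "2D-4": 0.9, "3A": 0.0})

    # intragenic deletions: whole frameshifting exon / in-frame 12 % / 4 %
    chrom, base = b.window()
    g = b.gene(chrom, base, "HIE001", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("loss_2e_pvs1", chrom, base + 950, base + 1250, "loss",
          {"1A": 0.0, "2E": 0.9, "3A": 0.0})

    chrom, base = b.window()
    g = b.gene(chrom, base, "HIE002", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("loss_2e_strong", chrom, base + 1000, base + 1071, "loss",
          {"1A": 0.0, "2E": 0.45, "3A": 0.0})

    chrom, base = b.window()
    g = b.gene(chrom, base, "HIE003", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("loss_2e_moderate", chrom, base + 1000, base + 1023, "loss",
          {"1A": 0.0, "2E": 0.3, "3A": 0.0})

    # ---- loss: benign (2F/2G) and predicted HI (2H) ----------------------
    chrom, base = b.window()
    b.dosage(chrom, base, base + 50_000, "BENIGN_LOSS")
    b.gene(chrom, base + 10_000, "BF1001", n_exons=2, utr=50)
    b.gene(chrom, base + 20_000, "BF1002", n_exons=2, utr=50)
    b.cnv("loss_2f_within", chrom, base + 5000, base + 25_000, "loss",
          {"2F": -1.0}, terminal=True)

    chrom, base = b.window()
    b.dosage(chrom, base + 10_000, base + 30_000, "BENIGN_LOSS")
    b.gene(chrom, base + 12_000, "BF2001", n_exons=2, utr=50)
    b.gene(chrom, base + 20_000, "BF2002", n_exons=2, utr=50)
    b.cnv("loss_2f_identical", chrom, base + 5000, base + 35_000, "loss",
          {"2F": -1.0}, terminal=True)

    chrom, base = b.window()
    b.dosage(chrom, base, base + 20_000, "BENIGN_LOSS")
    b.gene(chrom, base + 5000, "BG1001", n_exons=2, utr=50)
    b.gene(chrom, base + 30_000, "BG1002", n_exons=2, utr=50)
    b.cnv("loss_2g", chrom, base + 15_000, base + 40_000, "loss",
          {"1A": 0.0, "2G": 0.0, "3A": 0.0})

    chrom, base = b.window()
    b.gene(chrom, base, "PHI001", pli=0.95, oe_upper=0.2, hi_index=5.0)
    b.cnv("loss_2h", chrom, base - 500, base + 4000, "loss",
          {"1A": 0.0, "2H": 0.15, "3A": 0.0})

    # ---- loss: Section 3 bands ------------------------------------------
    chrom, base = b.window()
    b.gene_grid(chrom, base, p.loss_3b_genes, "N3B")
    b.cnv("loss_3b", chrom, base - 500, base + p.loss_3b_genes * 3000 + 500,
          "loss", {"1A": 0.0, "3B": 0.45})

    chrom, base = b.window()
    b.gene_grid(chrom, base, p.loss_3c_genes, "N3C")
    b.cnv("loss_3c", chrom, base - 500, base + p.loss_3c_genes * 3000 + 500,
          "loss", {"1A": 0.0, "3C": 0.9})

    # ---- loss: 4O fractional-overlap branches ---------------------------
    chrom, base = b.window()
    b.popvar(chrom, base, base + 60_000, "loss", 0.05, 5000, "SAMPLE_COUNTED")
    b.gene(chrom, base + 40_000, "PO1001", n_exons=2, utr=50)
    b.cnv("loss_4o_frac", chrom, base + 30_000, base + 79_999, "loss",
          {"1A": 0.0, "3A": 0.0, "4O": -1.0})

    chrom, base = b.window()
    b.popvar(chrom, base, base + 50_000, "loss", 0.05, 5000, "SAMPLE_COUNTED")
    b.gene(chrom, base + 30_000, "PO2001", n_exons=2, utr=50)
    b.cnv("loss_4o_below", chrom, base + 25_500, base + 75_499, "loss",
          {"1A": 0.0, "3A": 0.0})

    # ---- gain: Sections 1 and 2L ----------------------------------------
    chrom, base = b.window()
    b.gene(chrom, base, "G1A001")
    b.cnv("gain_2l", chrom, base - 500, base + 4000, "gain",
          {"1A": 0.0, "2L": 0.0, "3A": 0.0})

    chrom, base = b.window()
    b.cnv("gain_1b", chrom, base, base + 50_000, "gain", {"1B": -0.6, "3A": 0.0})

    # ---- gain: TS (2A/2B) ------------------------------------------------
    chrom, base = b.window()
    b.dosage(chrom, base, base + 30_000, "TS_REGION", 3)
    b.gene(chrom, base + 10_000, "TSA001", n_exons=2, utr=50)
    b.cnv("gain_2a", chrom, base - 1000, base + 40_000, "gain",
          {"1A": 0.0, "2A": 1.0, "3A": 0.0})

    chrom, base = b.window()
    b.dosage(chrom, base, base + 30_000, "TS_REGION", 3)
    b.gene(chrom, base + 25_000, "TSB001", n_exons=2, utr=50)
    b.cnv("gain_2b", chrom, base + 20_000, base + 50_000, "gain",
          {"1A": 0.0, "2B": 0.0, "3A": 0.0})

    # ---- gain: benign relations (2C-2G) ---------------------------------
    chrom, base = b.window()
    b.dosage(chrom, base, base + 30_000, "BENIGN_GAIN")
    b.gene(chrom, base + 5000, "GBC001", n_exons=2, utr=50)
    b.gene(chrom, base + 15_000, "GBC002", n_exons=2, utr=50)
    b.cnv("gain_2c", chrom, base + 2000, base + 28_000, "gain",
          {"2C": -1.0}, terminal=True)

    chrom, base = b.window()
    b.dosage(chrom, base, base + 40_000, "BENIGN_GAIN")
    b.gene(chrom, base + 10_000, "GBD001", n_exons=2, utr=50)
    b.gene(chrom, base + 30_000, "GBD002", n_exons=2, utr=50)
    b.cnv("gain_2d", chrom, base + 5000, base + 20_000, "gain",
          {"2D": -1.0}, terminal=True)

    chrom, base = b.window()
    b.dosage(chrom, base, base + 40_000, "BENIGN_GAIN")
    b.gene(chrom, base + 19_500, "GBE001", n_exons=2, utr=50)
    b.gene(chrom, base + 30_000, "GBE002", n_exons=2, utr=50)
    b.cnv("gain_2e", chrom, base + 5000, base + 20_000, "gain",
          {"1A": 0.0, "2E": 0.0, "3A": 0.0})

    chrom, base = b.window()
    b.dosage(chrom, base, base + 30_000, "BENIGN_GAIN")
    b.gene(chrom, base + 5000, "GBF001", n_exons=2, utr=50)
    b.gene(chrom, base + 20_000, "GBF002", n_exons=2, utr=50)
    b.cnv("gain_2f", chrom, base + 15_000, base + 45_000, "gain",
          {"1A": 0.0, "2F": -1.0, "3A": 0.0})

    chrom, base = b.window()
    b.dosage(chrom, base, base + 20_000, "BENIGN_GAIN")
    b.gene(chrom, base + 5000, "GBG001", n_exons=2, utr=50)
    b.gene(chrom, base + 35_000, "GBG002", n_exons=2, utr=50)
    b.cnv("gain_2g", chrom, base + 15_000, base + 45_000, "gain",
          {"1A": 0.0, "2G": 0.0, "3A": 0.0})

    # ---- gain: HI genes (2H/2I) -----------------------------------------
    chrom, base = b.window()
    g = b.gene(chrom, base, "GHH001", pli=0.99, oe_upper=0.1, hi_index=2.0)
    b.hi_gene(g)
    b.cnv("gain_2h", chrom, base - 1000, base + 5000, "gain",
          {"1A": 0.0, "2H": 0.0, "3A": 0.0})

    for label, tandem, points in (
        ("gain_2i_proven", "proven", 0.9),
        ("gain_2i_assumed", "assumed", 0.45),
        ("gain_2i_unknown", "unknown", 0.0),
    ):
        chrom, base = b.window()
        g = b.gene(chrom, base, f"GHI{label[-3:].upper()}",
                   pli=0.99, oe_upper=0.1, hi_index=2.0)
        b.hi_gene(g)
        b.cnv(label, chrom, base + 950, base + 1250, "gain",
              {"1A": 0.0, "2I": points, "3A": 0.0}, tandem=tandem)

    # ---- gain: Section 3 bands ------------------------------------------
    chrom, base = b.window()
    b.gene_grid(chrom, base, p.gain_3b_genes, "GN3B")
    b.cnv("gain_3b", chrom, base - 500, base + p.gain_3b_genes * 3000 + 500,
          "gain", {"1A": 0.0, "2L": 0.0, "3B": 0.45})

    chrom, base = b.window()
    b.gene_grid(chrom, base, p.gain_3c_genes, "GN3C")
    b.cnv("gain_3c", chrom, base - 500, base + p.gain_3c_genes * 3000 + 500,
          "gain", {"1A": 0.0, "2L": 0.0, "3C": 0.9})

    # ---- gain: 4O --------------------------------------------------------
    chrom, base = b.window()
    b.popvar(chrom, base, base + 40_000, "gain", 0.08, 3000, "ALLELE_COUNTED")
    b.gene(chrom, base + 12_000, "GPO001", n_exons=2, utr=50)
    b.cnv("gain_4o", chrom, base + 10_000, base + 20_000, "gain",
          {"1A": 0.0, "2L": 0.0, "3A": 0.0, "4O": -1.0})

    return b


# ---------------------------------------------------------------------------
# File emission


def _write_tsv(path: Path, header: tuple, rows: List[tuple]) -> None:
    with open(path, "w", newline="") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(v) for v in row) + "\n")


def generate_fixture_db(
    out_dir: str | Path,
    seed: int = 0,
    params: Optional[FixtureParams] = None,
) -> Path:
    """Write the complete annotation database under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b = _build(seed, params or FixtureParams())
    _write_tsv(out_dir / "genes.tsv",
               ("gene_id", "symbol", "chrom", "start", "end", "strand",
                "cds_start", "cds_end", "exon_starts", "exon_ends",
                "coding", "canonical", "pli", "oe_upper", "hi_index", "relevant"),
               b.gene_rows)
    _write_tsv(out_dir / "dosage.tsv",
               ("region_id", "chrom", "start", "end", "kind", "score", "gene_id"),
               b.dosage_rows)
    _write_tsv(out_dir / "popvar.tsv",
               ("variant_id", "chrom", "start", "end", "dosage", "frequency",
                "cohort_size", "source_kind"),
               b.popvar_rows)
    _write_tsv(out_dir / "variants.tsv",
               ("chrom", "start", "end", "gene_id", "significance", "allele_frequency"),
               b.variant_rows)
    _write_tsv(out_dir / "critical.tsv",
               ("gene_id", "chrom", "start", "end", "note"),
               b.critical_rows)
    return out_dir


def generate_cnv_suite(
    out_dir: str | Path,
    seed: int = 0,
    params: Optional[FixtureParams] = None,
) -> Tuple[Path, Path]:
    """Write ``suite.tsv`` (CNVs to score) and ``expected.json`` (oracle).

    Must be paired with :func:`generate_fixture_db` called with the same
    seed and params.  Returns the two file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b = _build(seed, params or FixtureParams())
    suite_path = out_dir / "suite.tsv"
    _write_tsv(suite_path, ("label", "coordinate", "dosage", "tandem"), b.suite_rows)
    expected_path = out_dir / "expected.json"
    with open(expected_path, "w") as handle:
        json.dump(b.expected, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return suite_path, expected_path


def expected_scorecards(seed: int = 0, params: Optional[FixtureParams] = None) -> Dict[str, dict]:
    """The constructive oracle as an in-memory mapping (label -> expectation)."""
    return _build(seed, params or FixtureParams()).expected
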