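"""Core domain types shared by every stage of the pipeline.

Coordinates are 1-based and fully closed on both ends (the convention used
in clinical CNV reports and in the ClinGen dosage map): a record with
``start == end`` covers exactly one base.  BED-style inputs are converted on
load, never stored half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Dosage(str, enum.Enum):
    """Direction of the copy-number change."""

    LOSS = "loss"
    GAIN = "gain"


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"


class RegionKind(str, enum.Enum):
    """Curated dosage-map element classes (ClinGen-style)."""

    HI_GENE = "HI_GENE"
    HI_REGION = "HI_REGION"
    TS_GENE = "TS_GENE"
    TS_REGION = "TS_REGION"
    BENIGN_LOSS = "BENIGN_LOSS"
    BENIGN_GAIN = "BENIGN_GAIN"


class Significance(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    OTHER = "OTHER"


class SourceKind(str, enum.Enum):
    """How a population-CNV cohort size is counted.

    DGV-style sources report the number of tested samples; gnomAD-style
    sources report a total allele count.  The commonness thresholds differ
    (>= 1000 samples vs >= 2000 alleles).
    """

    SAMPLE_COUNTED = "SAMPLE_COUNTED"
    ALLELE_COUNTED = "ALLELE_COUNTED"


#: Dosage-map curation scores that mark an element as functionally important
#: (1 = little evidence, 2 = emerging, 3 = sufficient).  30/40 encode
#: "unlikely"/"dosage-insensitive" and do not count.
FUNCTIONALLY_IMPORTANT_SCORES = frozenset({1, 2, 3})


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label to the ``chr``-prefixed form.

    ``"22"`` and ``"chr22"`` compare equal after normalization.
    """
    chrom = chrom.strip()
    if not chrom:
        raise ValueError("empty chromosome label")
    if not chrom.lower().startswith("chr"):
        return "chr" + chrom
    return "chr" + chrom[3:]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates must be positive: {self.start}-{self.end}")
        if self.start > self.end:
            raise ValueError(f"inverted interval: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        """True when *other* lies fully inside this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CnvQuery:
    """A single CNV under interpretation."""

    interval: GenomicInterval
    dosage: Dosage
    label: Optional[str] = None


@dataclass(frozen=True)
class GeneModel:
    """One transcript of a protein-coding (or non-coding) gene.

    ``gene_id`` identifies the transcript record (RefSeq-accession style);
    ``symbol`` groups transcripts of the same locus.  Exons are stored in
    transcription order, so exon 1 is always the 5'-most exon regardless of
    strand and "last exon" is well defined on both strands.
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval
    strand: Strand
    exons: tuple  # tuple[GenomicInterval, ...] in transcription order
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    is_protein_coding: bool = True
    is_canonical: bool = False
    pli: Optional[float] = None
    oe_upper: Optional[float] = None
    hi_index: Optional[float] = None
    biologically_relevant: bool = True

    def __post_init__(self) -> None:
        genomic = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for exon in genomic:
            if not self.interval.contains(exon):
                raise ValueError(
                    f"{self.gene_id}: exon {exon} outside transcript span {self.interval}"
                )
            if prev_end is not None and exon.start <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = exon.end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: cds_start/cds_end must both be set or absent")
        if self.cds_start is not None:
            if not (self.interval.start <= self.cds_start <= self.cds_end <= self.interval.end):
                raise ValueError(f"{self.gene_id}: CDS bounds outside transcript span")
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"{self.gene_id}: pli {self.pli} outside [0, 1]")
        if self.hi_index is not None and not 0.0 <= self.hi_index <= 100.0:
            raise ValueError(f"{self.gene_id}: hi_index {self.hi_index} outside [0, 100]")

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    @property
    def cds_interval(self) -> Optional[GenomicInterval]:
        if self.cds_start is None:
            return None
        return GenomicInterval(self.interval.chrom, self.cds_start, self.cds_end)

    def coding_exon_parts(self) -> list:
        """Coding portion of each exon, transcription order, empty if non-coding."""
        cds = self.cds_interval
        if cds is None:
            return []
        parts = []
        for exon in self.exons:
            lo = max(exon.start, cds.start)
            hi = min(exon.end, cds.end)
            if lo <= hi:
                parts.append(GenomicInterval(exon.chrom, lo, hi))
        return parts

    def total_cds_bases(self) -> int:
        return sum(p.length for p in self.coding_exon_parts())

    def is_predicted_hi(
        self,
        min_pli: float = 0.9,
        max_oe_upper: float = 0.35,
        max_hi_index: float = 10.0,
    ) -> bool:
        """Gene-level haploinsufficiency prediction.

        Requires all three constraint metrics to be present and to pass:
        gnomAD pLI >= 0.9, observed/expected LoF upper bound < 0.35, and a
        DECIPHER-style HI percentile <= 10.
        """
        return (
            self.pli is not None
            and self.oe_upper is not None
            and self.hi_index is not None
            and self.pli >= min_pli
            and self.oe_upper < max_oe_upper
            and self.hi_index <= max_hi_index
        )


@dataclass(frozen=True)
class DosageRegion:
    region_id: str
    interval: GenomicInterval
    kind: RegionKind
    dosage_score: Optional[int] = None
    gene_id: Optional[str] = None  # gene symbol link for *_GENE entries

    def __post_init__(self) -> None:
        if self.kind in (
            RegionKind.HI_GENE,
            RegionKind.HI_REGION,
            RegionKind.TS_GENE,
            RegionKind.TS_REGION,
        ):
            if self.dosage_score is None:
                raise ValueError(f"{self.region_id}: HI/TS entry requires a dosage score")
            if self.dosage_score not in (0, 1, 2, 3, 30, 40):
                raise ValueError(
                    f"{self.region_id}: dosage score {self.dosage_score} not in {{0,1,2,3,30,40}}"
                )

    @property
    def functionally_important(self) -> bool:
        return self.dosage_score in FUNCTIONALLY_IMPORTANT_SCORES


@dataclass(frozen=True)
class PopulationVariant:
    variant_id: str
    interval: GenomicInterval
    dosage: Dosage
    frequency: float
    cohort_size: int
    source_kind: SourceKind

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"{self.variant_id}: frequency {self.frequency} outside [0, 1]")
        if self.cohort_size < 0:
            raise ValueError(f"{self.variant_id}: negative cohort size")


@dataclass(frozen=True)
class KnownVariant:
    interval: GenomicInterval
    gene_id: str
    significance: Significance
    allele_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele frequency {self.allele_frequency} outside [0, 1]")

    @property
    def is_pathogenic(self) -> bool:
        return self.significance in (
            Significance.PATHOGENIC,
            Significance.LIKELY_PATHOGENIC,
        )


@dataclass(frozen=True)
class CriticalRegion:
    gene_id: str
    interval: GenomicInterval
    note: str = ""
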