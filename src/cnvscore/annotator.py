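"""Turn a CNV query plus the annotation database into overlap facts.

The scorers never touch the database directly: everything they need — gene
content, the overlap taxonomy against dosage-map elements, benign-region
relations, predicted-HI genes and common population-variant containment —
is assembled here into one :class:`AnnotationResult`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .database import AnnotationDatabase
from .models import (
    CnvQuery,
    Dosage,
    GenomicInterval,
    GeneModel,
    PopulationVariant,
    DosageRegion,
    RegionKind,
    SourceKind,
    Strand,
)
from .intragenic import select_transcript


class OverlapRelation(str, enum.Enum):
    """Geometric relation between a CNV and one annotated element."""

    CNV_CONTAINS_ELEMENT = "CNV_CONTAINS_ELEMENT"
    CNV_WITHIN_ELEMENT = "CNV_WITHIN_ELEMENT"
    PARTIAL_5PRIME = "PARTIAL_5PRIME"
    PARTIAL_3PRIME = "PARTIAL_3PRIME"
    IDENTICAL_GENE_CONTENT = "IDENTICAL_GENE_CONTENT"
    OTHER_PARTIAL = "OTHER_PARTIAL"


class Containment(str, enum.Enum):
    CNV_WITHIN = "CNV_WITHIN"
    OVERLAP = "OVERLAP"


@dataclass(frozen=True)
class GeneOverlapDetail:
    """How a CNV hits one gene (selected transcript), strand-aware."""

    gene: GeneModel
    relation: OverlapRelation
    coding_sequence_involved: bool
    exons_involved: Tuple[int, ...]  # 1-based ordinals, transcription order
    only_last_exon: bool
    only_3prime_utr: bool


@dataclass(frozen=True)
class CommonVariantFact:
    """A common population CNV of the same dosage overlapping the query."""

    variant: PopulationVariant
    containment: Containment
    overlap_fraction_of_cnv: float
    extra_protein_genes: int


@dataclass(frozen=True)
class CommonnessThresholds:
    """What counts as a common population variant.

    Defaults follow the DGV/gnomAD convention: frequency >= 1 % backed by
    >= 1,000 tested samples (sample-counted sources) or >= 2,000 total
    alleles (allele-counted sources).
    """

    min_frequency: float = 0.01
    min_samples: int = 1000
    min_alleles: int = 2000

    def is_common(self, variant: PopulationVariant) -> bool:
        if variant.frequency < self.min_frequency:
            return False
        if variant.source_kind is SourceKind.SAMPLE_COUNTED:
            return variant.cohort_size >= self.min_samples
        return variant.cohort_size >= self.min_alleles


@dataclass
class AnnotationResult:
    query: CnvQuery
    protein_coding_genes: List[GeneModel]  # one selected transcript per locus
    gene_count: int
    functionally_important: bool
    hi_overlaps: List[Tuple[DosageRegion, OverlapRelation]]
    ts_overlaps: List[Tuple[DosageRegion, OverlapRelation]]
    benign_overlaps: List[Tuple[DosageRegion, OverlapRelation]]
    gene_overlap_details: List[GeneOverlapDetail]
    predicted_hi_genes: List[GeneModel]
    common_variant_facts: List[CommonVariantFact]

    def detail_for_symbol(self, symbol: str) -> Optional[GeneOverlapDetail]:
        for detail in self.gene_overlap_details:
            if detail.gene.symbol == symbol:
                return detail
        return None


# ---------------------------------------------------------------------------
# Overlap classification


def _covers(query: GenomicInterval, pos: int) -> bool:
    return query.start <= pos <= query.end


def classify_region_overlap(query: GenomicInterval, region: GenomicInterval) -> OverlapRelation:
    """Strand-free relation for curated regions (no 5'/3' sense)."""
    if not query.overlaps(region):
        raise ValueError(f"{query} does not overlap {region}")
    if query.contains(region):
        return OverlapRelation.CNV_CONTAINS_ELEMENT
    if region.contains(query):
        return OverlapRelation.CNV_WITHIN_ELEMENT
    return OverlapRelation.OTHER_PARTIAL


def classify_gene_overlap(query: GenomicInterval, gene: GeneModel) -> GeneOverlapDetail:
    """Classify how *query* hits *gene*, in transcription sense.

    A partial overlap that covers the transcription start (genomic start on
    '+', genomic end on '-') but not the transcription end is PARTIAL_5PRIME,
    and vice versa.  Exon ordinals are reported in transcription order so
    "last exon" means the 3'-most exon on either strand.
    """
    span = gene.interval
    if not query.overlaps(span):
        raise ValueError(f"query {query} does not overlap gene {gene.gene_id}")
    if query.contains(span):
        relation = OverlapRelation.CNV_CONTAINS_ELEMENT
    elif span.contains(query):
        relation = OverlapRelation.CNV_WITHIN_ELEMENT
    else:
        tss = span.start if gene.strand is Strand.PLUS else span.end
        tes = span.end if gene.strand is Strand.PLUS else span.start
        covers_tss = _covers(query, tss)
        covers_tes = _covers(query, tes)
        if covers_tss and not covers_tes:
            relation = OverlapRelation.PARTIAL_5PRIME
        elif covers_tes and not covers_tss:
            relation = OverlapRelation.PARTIAL_3PRIME
        else:  # unreachable for a genuine partial overlap; kept as a guard
            relation = OverlapRelation.OTHER_PARTIAL

    exons_involved = tuple(
        ordinal
        for ordinal, exon in enumerate(gene.exons, start=1)
        if query.overlaps(exon)
    )
    coding_involved = any(query.overlaps(part) for part in gene.coding_exon_parts())
    n_exons = len(gene.exons)
    only_last_exon = exons_involved == (n_exons,) if n_exons else False

    only_3prime_utr = False
    if gene.has_cds and not coding_involved:
        # intersection of query with the transcript span, genomic sense
        lo = max(query.start, span.start)
        hi = min(query.end, span.end)
        if gene.strand is Strand.PLUS:
            only_3prime_utr = lo > gene.cds_end
        else:
            only_3prime_utr = hi < gene.cds_start

    return GeneOverlapDetail(
        gene=gene,
        relation=relation,
        coding_sequence_involved=coding_involved,
        exons_involved=exons_involved,
        only_last_exon=only_last_exon,
        only_3prime_utr=only_3prime_utr,
    )


# ---------------------------------------------------------------------------
# Gene content helpers


def select_overlapping_genes(db: AnnotationDatabase, interval: GenomicInterval) -> List[GeneModel]:
    """One selected transcript per protein-coding locus overlapping *interval*."""
    by_symbol: Dict[str, List[GeneModel]] = {}
    for gene in db.query(interval, "genes"):
        if gene.is_protein_coding:
            by_symbol.setdefault(gene.symbol, []).append(gene)
    selected = [select_transcript(txs) for txs in by_symbol.values()]
    selected.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.interval.end, g.gene_id))
    return selected


def coding_symbols(db: AnnotationDatabase, interval: GenomicInterval) -> frozenset:
    """Set of protein-coding gene symbols with >= 1 bp overlap."""
    return frozenset(
        g.symbol for g in db.query(interval, "genes") if g.is_protein_coding
    )


# ---------------------------------------------------------------------------
# Main entry points


def _classify_dosage_overlap(
    query: GenomicInterval, region: DosageRegion, db: AnnotationDatabase
) -> OverlapRelation:
    """Relation for a dosage-map element; gene entries use the gene geometry."""
    if region.kind in (RegionKind.HI_GENE, RegionKind.TS_GENE) and region.gene_id:
        txs = [
            g for g in db.query(region.interval, "genes") if g.symbol == region.gene_id
        ]
        if txs:
            return classify_gene_overlap(query, select_transcript(txs)).relation
    relation = classify_region_overlap(query, region.interval)
    if relation is OverlapRelation.OTHER_PARTIAL and region.kind in (
        RegionKind.BENIGN_LOSS,
        RegionKind.BENIGN_GAIN,
    ):
        # benign comparisons are on gene content, not coordinates
        if coding_symbols(db, query) == coding_symbols(db, region.interval):
            return OverlapRelation.IDENTICAL_GENE_CONTENT
    return relation


def common_variant_facts(
    query: CnvQuery,
    db: AnnotationDatabase,
    thresholds: CommonnessThresholds | None = None,
) -> List[CommonVariantFact]:
    """Common population variants of the query's dosage overlapping it.

    Rare variants and dosage-mismatched variants are dropped.  For each
    survivor the containment status, the fraction of the CNV covered, and
    the number of protein-coding genes in the CNV but outside the variant
    are computed exactly.
    """
    thresholds = thresholds or CommonnessThresholds()
    qiv = query.interval
    cnv_genes = select_overlapping_genes(db, qiv)
    facts = []
    for variant in db.query(qiv, "population_variants"):
        if variant.dosage is not query.dosage or not thresholds.is_common(variant):
            continue
        shared = qiv.overlap_bp(variant.interval)
        containment = (
            Containment.CNV_WITHIN
            if variant.interval.contains(qiv)
            else Containment.OVERLAP
        )
        extra = sum(
            1 for g in cnv_genes if not g.interval.overlaps(variant.interval)
        )
        facts.append(
            CommonVariantFact(
                variant=variant,
                containment=containment,
                overlap_fraction_of_cnv=shared / qiv.length,
                extra_protein_genes=extra,
            )
        )
    return facts


def annotate(
    query: CnvQuery,
    db: AnnotationDatabase,
    thresholds: CommonnessThresholds | None = None,
) -> AnnotationResult:
    """Compute every overlap fact the scoring trees consume."""
    qiv = query.interval
    genes = select_overlapping_genes(db, qiv)
    details = [classify_gene_overlap(qiv, g) for g in genes]

    hi, ts, benign = [], [], []
    functionally_important = False
    for region in db.query(qiv, "dosage_regions"):
        relation = _classify_dosage_overlap(qiv, region, db)
        pair = (region, relation)
        if region.kind in (RegionKind.HI_GENE, RegionKind.HI_REGION):
            hi.append(pair)
        elif region.kind in (RegionKind.TS_GENE, RegionKind.TS_REGION):
            ts.append(pair)
        else:
            benign.append(pair)
        if region.functionally_important:
            functionally_important = True

    predicted = [g for g in genes if g.is_predicted_hi()]

    return AnnotationResult(
        query=query,
        protein_coding_genes=genes,
        gene_count=len(genes),
        functionally_important=functionally_important,
        hi_overlaps=hi,
        ts_overlaps=ts,
        benign_overlaps=benign,
        gene_overlap_details=details,
        predicted_hi_genes=predicted,
        common_variant_facts=common_variant_facts(query, db, thresholds),
    )
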