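"""Loss-of-function effect prediction for CNVs fully inside a gene.

Implements the graded PVS1 logic used for intragenic deletions (and tandem
duplications) of established haploinsufficient genes: reading-frame
arithmetic on the affected coding bases, nonsense-mediated-decay (NMD)
prediction via the 50-nt junction rule, fraction of protein removed, and
curated critical-region / LoF-frequency context.

No nucleotide sequence is available at CNV scale, so the premature
termination codon is approximated as arising at the CNV junction itself:
for a frameshifting deletion the PTC is placed at the splice-corrected
position where deleted sequence was removed; for a tandem duplication, at
the junction between the duplicated copy and the downstream original
sequence.  The 50-nt rule then asks whether that position lies at least
50 nt upstream of the last exon-exon junction of the selected transcript.
Single-exon genes never trigger NMD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .models import CnvQuery, GenomicInterval, GeneModel, Strand

NMD_JUNCTION_DISTANCE_NT = 50


class Pvs1Strength(str, enum.Enum):
    PVS1 = "PVS1"
    PVS1_STRONG = "PVS1_STRONG"
    PVS1_MODERATE = "PVS1_MODERATE"
    NONE = "NONE"


class TandemStatus(str, enum.Enum):
    PROVEN = "proven"
    ASSUMED = "assumed"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class EffectCall:
    strength: Pvs1Strength
    frame_disrupted: bool
    nmd_predicted: bool
    fraction_protein_removed: float
    critical_region_hit: bool = False
    lof_frequent: bool = False
    relevant_transcript: bool = True
    tandem_status: Optional[TandemStatus] = None
    rationale: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Transcript selection


def select_transcript(transcripts: Sequence[GeneModel]) -> GeneModel:
    """Pick the transcript to score for a locus with several.

    Preference order: the canonical-flagged transcript, then the longest
    CDS, then the longest transcript span, then lexicographically smallest
    transcript id (for full determinism).
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    pool = [t for t in transcripts if t.is_canonical] or list(transcripts)
    return min(
        pool,
        key=lambda t: (-t.total_cds_bases(), -t.interval.length, t.gene_id),
    )


# ---------------------------------------------------------------------------
# Spliced-coordinate arithmetic


def _exonic_overlap(gene: GeneModel, query: GenomicInterval, coding_only: bool) -> int:
    parts = gene.coding_exon_parts() if coding_only else list(gene.exons)
    return sum(query.overlap_bp(p) for p in parts)


def _upstream_downstream_exonic(gene: GeneModel, query: GenomicInterval) -> Tuple[int, int]:
    """Exonic bases strictly 5' / strictly 3' of *query* in transcription sense."""
    up = down = 0
    for exon in gene.exons:
        if gene.strand is Strand.PLUS:
            up += max(0, min(exon.end, query.start - 1) - exon.start + 1)
            down += max(0, exon.end - max(exon.start, query.end + 1) + 1)
        else:
            up += max(0, exon.end - max(exon.start, query.end + 1) + 1)
            down += max(0, min(exon.end, query.start - 1) - exon.start + 1)
    return up, down


def predict_nmd_deletion(gene: GeneModel, query: GenomicInterval) -> bool:
    """50-nt rule for a frameshifting intragenic deletion.

    The post-deletion transcript keeps every exon with surviving bases; the
    PTC sits at the deletion junction, whose spliced position equals the
    exonic bases retained upstream of the deletion.  NMD is predicted when
    that position is >= 50 nt upstream of the last exon-exon junction of
    the post-deletion transcript.
    """
    surviving = [e.length - query.overlap_bp(e) for e in gene.exons]
    surviving = [s for s in surviving if s > 0]
    if len(surviving) < 2:
        return False
    upstream, _ = _upstream_downstream_exonic(gene, query)
    last_junction = sum(surviving) - surviving[-1]
    return last_junction - upstream >= NMD_JUNCTION_DISTANCE_NT


def predict_nmd_duplication(gene: GeneModel, query: GenomicInterval) -> bool:
    """50-nt rule for a frameshifting tandem duplication.

    With the duplicate inserted in tandem, both the PTC (just downstream of
    the duplicated copy) and the last junction shift by the duplicated
    exonic length, so their distance reduces to the exonic bases between
    the duplication end and the start of the last exon of the original
    transcript.  A duplication touching the last exon places the PTC in it
    and escapes NMD.
    """
    if len(gene.exons) < 2:
        return False
    if query.overlaps(gene.exons[-1]):
        return False
    _, downstream = _upstream_downstream_exonic(gene, query)
    return downstream - gene.exons[-1].length >= NMD_JUNCTION_DISTANCE_NT


# ---------------------------------------------------------------------------
# Effect evaluation

#: fraction of protein above which an in-frame removal is still strong evidence
PROTEIN_FRACTION_THRESHOLD = 0.10
#: known pathogenic LoF variants at or above this allele frequency mark the
#: region as LoF-tolerated in the general population
LOF_FREQUENT_AF = 0.001


def _require_contained(query: CnvQuery, gene: GeneModel) -> None:
    if not gene.interval.contains(query.interval):
        raise ValueError(
            f"CNV {query.interval} is not fully within gene {gene.symbol} span {gene.interval}"
        )


def _critical_region_hit(query: GenomicInterval, gene: GeneModel, db) -> bool:
    if db is None:
        return False
    return any(
        region.gene_id == gene.symbol
        for region in db.query(query, "critical_regions")
    )


def _lof_frequent(query: GenomicInterval, gene: GeneModel, db, af_threshold: float) -> bool:
    if db is None:
        return False
    return any(
        kv.gene_id == gene.symbol and kv.is_pathogenic and kv.allele_frequency >= af_threshold
        for kv in db.query(query, "known_variants")
    )


def evaluate_deletion(
    query: CnvQuery,
    gene: GeneModel,
    db=None,
    lof_frequent_af: float = LOF_FREQUENT_AF,
) -> EffectCall:
    """PVS1 strength for a deletion fully inside *gene*.

    Frameshift plus predicted NMD on a biologically relevant transcript is
    full PVS1.  Otherwise a curated critical-region hit gives PVS1_Strong;
    failing that, an in-frame/NMD-escaping removal of more than 10 % of the
    protein gives PVS1_Strong and of less, PVS1_Moderate — provided LoF
    variants in the region are not frequent in the population.
    """
    _require_contained(query, gene)
    if not gene.is_protein_coding or not gene.has_cds:
        raise ValueError(f"gene {gene.symbol} is not protein-coding")
    qiv = query.interval
    deleted_coding = _exonic_overlap(gene, qiv, coding_only=True)
    total_cds = gene.total_cds_bases()
    frame_disrupted = deleted_coding % 3 != 0
    nmd = frame_disrupted and predict_nmd_deletion(gene, qiv)
    fraction = deleted_coding / total_cds if total_cds else 0.0
    critical = _critical_region_hit(qiv, gene, db)
    lof_frequent = _lof_frequent(qiv, gene, db, lof_frequent_af)
    relevant = gene.biologically_relevant

    rationale: List[str] = [
        f"deleted {deleted_coding} of {total_cds} coding bases ({fraction:.1%})",
        "reading frame disrupted" if frame_disrupted else "reading frame preserved",
    ]
    if frame_disrupted:
        rationale.append("NMD predicted (50-nt rule)" if nmd else "predicted to escape NMD")

    if deleted_coding == 0:
        strength = Pvs1Strength.NONE
        rationale.append("no coding sequence removed")
    elif frame_disrupted and nmd and relevant:
        strength = Pvs1Strength.PVS1
    elif critical:
        strength = Pvs1Strength.PVS1_STRONG
        rationale.append("curated critical protein region altered")
    elif not lof_frequent and relevant:
        if fraction > PROTEIN_FRACTION_THRESHOLD:
            strength = Pvs1Strength.PVS1_STRONG
            rationale.append("removes > 10% of the protein")
        else:
            strength = Pvs1Strength.PVS1_MODERATE
            rationale.append("removes < 10% of the protein")
    else:
        strength = Pvs1Strength.NONE
        if lof_frequent:
            rationale.append("LoF variants frequent in the general population")
        if not relevant:
            rationale.append("transcript not biologically relevant")

    return EffectCall(
        strength=strength,
        frame_disrupted=frame_disrupted,
        nmd_predicted=nmd,
        fraction_protein_removed=fraction,
        critical_region_hit=critical,
        lof_frequent=lof_frequent,
        relevant_transcript=relevant,
        rationale=tuple(rationale),
    )


def evaluate_duplication(
    query: CnvQuery,
    gene: GeneModel,
    tandem_status: TandemStatus = TandemStatus.UNKNOWN,
) -> EffectCall:
    """PVS1 strength for a duplication fully inside *gene*.

    Assumes a tandem insertion of the duplicated segment on the selected
    transcript.  Frameshift with predicted NMD gives PVS1 when tandem state
    is proven and PVS1_Strong when assumed; an unknown tandem state (or an
    in-frame / NMD-escaping event) yields no automated strength and is left
    to manual review.
    """
    _require_contained(query, gene)
    if not gene.is_protein_coding or not gene.has_cds:
        raise ValueError(f"gene {gene.symbol} is not protein-coding")
    qiv = query.interval
    dup_coding = _exonic_overlap(gene, qiv, coding_only=True)
    frame_disrupted = dup_coding % 3 != 0
    nmd = frame_disrupted and predict_nmd_duplication(gene, qiv)
    fraction = dup_coding / gene.total_cds_bases() if gene.total_cds_bases() else 0.0

    rationale: List[str] = [
        f"duplicates {dup_coding} coding bases in tandem ({tandem_status.value})",
        "reading frame disrupted" if frame_disrupted else "reading frame preserved",
    ]
    if frame_disrupted:
        rationale.append("NMD predicted (50-nt rule)" if nmd else "predicted to escape NMD")

    if frame_disrupted and nmd and tandem_status is TandemStatus.PROVEN:
        strength = Pvs1Strength.PVS1
    elif frame_disrupted and nmd and tandem_status is TandemStatus.ASSUMED:
        strength = Pvs1Strength.PVS1_STRONG
    else:
        strength = Pvs1Strength.NONE
        if tandem_status is TandemStatus.UNKNOWN:
            rationale.append("tandem status unknown; deferred to manual review")

    return EffectCall(
        strength=strength,
        frame_disrupted=frame_disrupted,
        nmd_predicted=nmd,
        fraction_protein_removed=fraction,
        relevant_transcript=gene.biologically_relevant,
        tandem_status=tandem_status,
        rationale=tuple(rationale),
    )
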