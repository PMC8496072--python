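"""Section-2 decision tree for copy-number losses.

Order of evaluation follows the loss metric: established HI genes/regions
first (2A-2E), then the gene-level HI predictors (2H) when no established
element is hit, then established benign regions (2F/2G).  When several
2-series categories apply, every candidate is recorded but only the
highest-scoring one contributes points.  A benign 2F hit is terminal — the
final automated total is fixed at -1.0 — unless positive dosage evidence
fired, in which case the conflict is flagged for review instead.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from .annotator import (
    AnnotationResult,
    OverlapRelation,
    coding_symbols,
)
from .database import AnnotationDatabase
from .evidence import EvidenceItem, MetricConfig
from .intragenic import Pvs1Strength, evaluate_deletion, select_transcript
from .models import Dosage, GeneModel, GenomicInterval, RegionKind
from .scoring import pick_section2_winner

#: points and per-strength ranges for category 2E (intragenic deletion of an
#: established HI gene), keyed by the graded PVS1 call
SECTION2E_POINTS = {
    Pvs1Strength.PVS1: (0.9, 0.45, 0.9),
    Pvs1Strength.PVS1_STRONG: (0.45, 0.3, 0.9),
    Pvs1Strength.PVS1_MODERATE: (0.3, 0.15, 0.45),
    Pvs1Strength.NONE: (0.0, 0.0, 0.0),
}

#: established pathogenic variants (for 2D-2) must be rarer than this
PATHOGENIC_VARIANT_MAX_AF = 0.01


def _transcript_for_symbol(
    db: AnnotationDatabase, interval: GenomicInterval, symbol: str
) -> Optional[GeneModel]:
    txs = [g for g in db.query(interval, "genes") if g.symbol == symbol]
    return select_transcript(txs) if txs else None


def _pathogenic_variant_in_exon(
    db: AnnotationDatabase, gene: GeneModel, exon: GenomicInterval
) -> bool:
    return any(
        kv.gene_id == gene.symbol
        and kv.is_pathogenic
        and kv.allele_frequency < PATHOGENIC_VARIANT_MAX_AF
        for kv in db.query(exon, "known_variants")
    )


def score_section2_loss(
    ann: AnnotationResult,
    db: AnnotationDatabase,
    cfg: MetricConfig,
) -> Tuple[List[EvidenceItem], bool, List[str]]:
    """Score Section 2 for a loss; returns (items, terminal_benign, conflicts)."""
    if ann.query.dosage is not Dosage.LOSS:
        raise ValueError("score_section2_loss requires a LOSS query")
    qiv = ann.query.interval
    candidates: List[EvidenceItem] = []
    conflicts: List[str] = []

    # --- established HI genes and regions -------------------------------
    hi_gene_symbols = {
        region.gene_id
        for region, _ in ann.hi_overlaps
        if region.kind is RegionKind.HI_GENE and region.gene_id
    }
    for region, relation in ann.hi_overlaps:
        refs = (region.region_id,)
        if relation is OverlapRelation.CNV_CONTAINS_ELEMENT:
            candidates.append(
                cfg.default_item(
                    Dosage.LOSS,
                    "2A",
                    rationale=f"completely spans established HI element {region.region_id}",
                    element_refs=refs,
                )
            )
            continue
        if region.kind is RegionKind.HI_REGION:
            # partial region overlap scores 2B only when no known HI gene of
            # the region is itself involved by the CNV
            if not hi_gene_symbols:
                candidates.append(
                    cfg.default_item(
                        Dosage.LOSS,
                        "2B",
                        rationale=(
                            f"partial overlap of HI region {region.region_id} "
                            "without involving known HI genes"
                        ),
                        element_refs=refs,
                    )
                )
            continue
        # HI gene, partially overlapped or containing the CNV
        gene = _transcript_for_symbol(db, region.interval, region.gene_id)
        if gene is None:
            continue
        detail = ann.detail_for_symbol(gene.symbol)
        if detail is None:
            continue
        if relation is OverlapRelation.PARTIAL_5PRIME:
            category = "2C-1" if detail.coding_sequence_involved else "2C-2"
            candidates.append(
                cfg.default_item(
                    Dosage.LOSS,
                    category,
                    rationale=(
                        f"5' overlap of HI gene {gene.symbol}"
                        + (
                            " involving coding sequence"
                            if detail.coding_sequence_involved
                            else ", 5' UTR only"
                        )
                    ),
                    element_refs=refs,
                )
            )
        elif relation is OverlapRelation.PARTIAL_3PRIME:
            if detail.only_3prime_utr or not detail.exons_involved:
                candidates.append(
                    cfg.default_item(
                        Dosage.LOSS,
                        "2D-1",
                        rationale=f"3' overlap of HI gene {gene.symbol}, 3' UTR only",
                        element_refs=refs,
                    )
                )
            elif detail.only_last_exon:
                last_exon = gene.exons[-1]
                if _pathogenic_variant_in_exon(db, gene, last_exon):
                    candidates.append(
                        cfg.default_item(
                            Dosage.LOSS,
                            "2D-2",
                            rationale=(
                                f"only the last exon of HI gene {gene.symbol} deleted; "
                                "established pathogenic variants documented in that exon"
                            ),
                            element_refs=refs,
                        )
                    )
                else:
                    candidates.append(
                        cfg.default_item(
                            Dosage.LOSS,
                            "2D-3",
                            rationale=(
                                f"only the last exon of HI gene {gene.symbol} deleted; "
                                "no established pathogenic variants in that exon"
                            ),
                            element_refs=refs,
                        )
                    )
            else:
                candidates.append(
                    cfg.default_item(
                        Dosage.LOSS,
                        "2D-4",
                        rationale=(
                            f"3' deletion of HI gene {gene.symbol} involving the last "
                            "exon and other exons"
                        ),
                        element_refs=refs,
                    )
                )
        elif relation is OverlapRelation.CNV_WITHIN_ELEMENT:
            effect = evaluate_deletion(ann.query, gene, db)
            points, lo, hi = SECTION2E_POINTS[effect.strength]
            candidates.append(
                EvidenceItem(
                    category="2E",
                    points=points,
                    range_min=lo,
                    range_max=hi,
                    rationale=(
                        f"intragenic deletion in HI gene {gene.symbol}: "
                        f"{effect.strength.value} ({'; '.join(effect.rationale)})"
                    ),
                    element_refs=refs,
                )
            )

    # --- predicted HI genes (2H) ----------------------------------------
    if not ann.hi_overlaps and ann.predicted_hi_genes:
        symbols = ", ".join(g.symbol for g in ann.predicted_hi_genes)
        candidates.append(
            cfg.default_item(
                Dosage.LOSS,
                "2H",
                rationale=(
                    f"predicted HI gene(s) {symbols}: pLI >= 0.9, o/e upper < 0.35, "
                    "HI index <= 10"
                ),
                element_refs=tuple(g.symbol for g in ann.predicted_hi_genes),
            )
        )

    # --- established benign regions (2F/2G) ------------------------------
    benign_terminal_candidate = None
    for region, relation in ann.benign_overlaps:
        if region.kind is not RegionKind.BENIGN_LOSS:
            continue
        refs = (region.region_id,)
        identical = (
            relation is OverlapRelation.IDENTICAL_GENE_CONTENT
            or coding_symbols(db, qiv) == coding_symbols(db, region.interval)
        )
        if relation is OverlapRelation.CNV_WITHIN_ELEMENT or identical:
            item = cfg.default_item(
                Dosage.LOSS,
                "2F",
                rationale=(
                    f"completely within benign region {region.region_id}"
                    if relation is OverlapRelation.CNV_WITHIN_ELEMENT
                    else f"protein-coding gene content identical to benign region {region.region_id}"
                ),
                element_refs=refs,
            )
            candidates.append(item)
            benign_terminal_candidate = item
        else:
            candidates.append(
                cfg.default_item(
                    Dosage.LOSS,
                    "2G",
                    rationale=(
                        f"overlaps benign region {region.region_id} but includes "
                        "additional genomic material"
                    ),
                    element_refs=refs,
                )
            )

    positive_evidence = any(c.points > 0 for c in candidates)
    terminal = benign_terminal_candidate is not None and not positive_evidence
    if benign_terminal_candidate is not None and positive_evidence:
        conflicts.append(
            "benign containment (2F) suppressed by positive Section-2 evidence; review"
        )

    if terminal:
        from dataclasses import replace

        items = [
            replace(c, contributes=(c is benign_terminal_candidate)) for c in candidates
        ]
        return items, True, conflicts

    items, _ = pick_section2_winner(candidates)
    return items, False, conflicts
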