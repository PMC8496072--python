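"""Section-2 decision tree for copy-number gains.

Order of evaluation: established triplosensitive (TS) genes/regions first
(2A/2B), then established benign-gain relations (2C-2G), then
haploinsufficient genes caught up in the duplication (2H-2K) and finally
the no-established-significance fallback (2L).  Benign relations are
compared on protein-coding gene content, not raw coordinates; the two
boundary scenarios where a gain neither adds genes nor matches the benign
element exactly collapse onto 2E (breakpoints potentially interrupting a
gene) and 2F (no interruption).

A gain that is gene-content-identical to (2C) or contained in (2D) an
established benign gain is treated as terminal benign, mirroring the loss
2F rule, unless positive dosage evidence fired first; this behaviour can
be disabled with ``terminal_benign=False``.
"""

from __future__ import annotations

from dataclasses import replace
from typing import List, Optional, Tuple

from .annotator import (
    AnnotationResult,
    OverlapRelation,
    coding_symbols,
)
from .database import AnnotationDatabase
from .evidence import EvidenceItem, MetricConfig
from .intragenic import (
    Pvs1Strength,
    TandemStatus,
    evaluate_duplication,
    select_transcript,
)
from .models import Dosage, GeneModel, GenomicInterval, RegionKind
from .scoring import pick_section2_winner

#: points for category 2I (intragenic duplication of an established HI
#: gene), keyed by the graded PVS1 call driven by tandem status
SECTION2I_POINTS = {
    Pvs1Strength.PVS1: 0.9,
    Pvs1Strength.PVS1_STRONG: 0.45,
    Pvs1Strength.PVS1_MODERATE: 0.0,
    Pvs1Strength.NONE: 0.0,
}


def _transcript_for_symbol(
    db: AnnotationDatabase, interval: GenomicInterval, symbol: str
) -> Optional[GeneModel]:
    txs = [g for g in db.query(interval, "genes") if g.symbol == symbol]
    return select_transcript(txs) if txs else None


def _interrupts_coding_gene(ann: AnnotationResult) -> bool:
    """True when a CNV breakpoint falls inside some protein-coding gene."""
    return any(
        d.relation is not OverlapRelation.CNV_CONTAINS_ELEMENT
        for d in ann.gene_overlap_details
    )


def score_section2_gain(
    ann: AnnotationResult,
    db: AnnotationDatabase,
    cfg: MetricConfig,
    tandem_status: TandemStatus = TandemStatus.UNKNOWN,
    terminal_benign: bool = True,
) -> Tuple[List[EvidenceItem], bool, List[str]]:
    """Score Section 2 for a gain; returns (items, terminal_benign, conflicts)."""
    if ann.query.dosage is not Dosage.GAIN:
        raise ValueError("score_section2_gain requires a GAIN query")
    qiv = ann.query.interval
    candidates: List[EvidenceItem] = []
    conflicts: List[str] = []

    # --- established TS genes and regions -------------------------------
    for region, relation in ann.ts_overlaps:
        refs = (region.region_id,)
        if relation is OverlapRelation.CNV_CONTAINS_ELEMENT:
            candidates.append(
                cfg.default_item(
                    Dosage.GAIN,
                    "2A",
                    rationale=f"completely spans established TS element {region.region_id}",
                    element_refs=refs,
                )
            )
        else:
            candidates.append(
                cfg.default_item(
                    Dosage.GAIN,
                    "2B",
                    rationale=f"partial overlap of TS element {region.region_id}",
                    element_refs=refs,
                )
            )

    # --- established benign-gain relations -------------------------------
    terminal_candidate = None
    for region, relation in ann.benign_overlaps:
        if region.kind is not RegionKind.BENIGN_GAIN:
            continue
        refs = (region.region_id,)
        cnv_genes = coding_symbols(db, qiv)
        region_genes = coding_symbols(db, region.interval)
        interrupts = _interrupts_coding_gene(ann)
        if cnv_genes == region_genes and not interrupts:
            item = cfg.default_item(
                Dosage.GAIN,
                "2C",
                rationale=(
                    f"identical protein-coding gene content to benign gain {region.region_id}"
                ),
                element_refs=refs,
            )
            candidates.append(item)
            terminal_candidate = terminal_candidate or item
        elif relation is OverlapRelation.CNV_WITHIN_ELEMENT:
            if interrupts:
                candidates.append(
                    cfg.default_item(
                        Dosage.GAIN,
                        "2E",
                        rationale=(
                            f"within benign gain {region.region_id} but breakpoints "
                            "potentially interrupt protein-coding gene(s)"
                        ),
                        element_refs=refs,
                    )
                )
            else:
                item = cfg.default_item(
                    Dosage.GAIN,
                    "2D",
                    rationale=(
                        f"smaller than benign gain {region.region_id}; breakpoints do "
                        "not interrupt protein-coding genes"
                    ),
                    element_refs=refs,
                )
                candidates.append(item)
                terminal_candidate = terminal_candidate or item
        elif not (cnv_genes - region_genes):
            # no additional protein-coding genes beyond the benign element
            if interrupts:
                candidates.append(
                    cfg.default_item(
                        Dosage.GAIN,
                        "2E",
                        rationale=(
                            f"no genes beyond benign gain {region.region_id} but "
                            "breakpoints potentially interrupt protein-coding gene(s)"
                        ),
                        element_refs=refs,
                    )
                )
            else:
                candidates.append(
                    cfg.default_item(
                        Dosage.GAIN,
                        "2F",
                        rationale=(
                            f"larger than benign gain {region.region_id} with no "
                            "additional protein-coding genes"
                        ),
                        element_refs=refs,
                    )
                )
        else:
            candidates.append(
                cfg.default_item(
                    Dosage.GAIN,
                    "2G",
                    rationale=(
                        f"overlaps benign gain {region.region_id} but includes "
                        "additional genomic material"
                    ),
                    element_refs=refs,
                )
            )

    # --- HI genes under a duplication ------------------------------------
    for region, relation in ann.hi_overlaps:
        if region.kind is not RegionKind.HI_GENE or not region.gene_id:
            continue
        refs = (region.region_id,)
        if relation is OverlapRelation.CNV_CONTAINS_ELEMENT:
            candidates.append(
                cfg.default_item(
                    Dosage.GAIN,
                    "2H",
                    rationale=f"HI gene {region.gene_id} fully contained within the gain",
                    element_refs=refs,
                )
            )
        elif relation is OverlapRelation.CNV_WITHIN_ELEMENT:
            gene = _transcript_for_symbol(db, region.interval, region.gene_id)
            if gene is None:
                continue
            effect = evaluate_duplication(ann.query, gene, tandem_status)
            points = SECTION2I_POINTS[effect.strength]
            spec = cfg.spec(Dosage.GAIN, "2I")
            candidates.append(
                EvidenceItem(
                    category="2I",
                    points=points,
                    range_min=spec.range_min,
                    range_max=spec.range_max,
                    rationale=(
                        f"intragenic duplication in HI gene {gene.symbol}: "
                        f"{effect.strength.value} ({'; '.join(effect.rationale)})"
                    ),
                    element_refs=refs,
                )
            )
        else:
            # one breakpoint inside an established HI gene: phenotype-dependent,
            # solicit user input under 2J/2K
            for category in ("2J", "2K"):
                spec = cfg.spec(Dosage.GAIN, category)
                candidates.append(
                    EvidenceItem(
                        category=category,
                        points=0.0,
                        range_min=spec.range_min,
                        range_max=spec.range_max,
                        rationale=(
                            f"breakpoint within HI gene {region.gene_id}; pending "
                            "manual phenotype assessment"
                        ),
                        element_refs=refs,
                    )
                )

    # --- fallback: genes of no established clinical significance ---------
    if not candidates and ann.gene_count > 0:
        candidates.append(
            cfg.default_item(
                Dosage.GAIN,
                "2L",
                rationale=(
                    "overlapping gene(s) without dosage-sensitivity curation or "
                    "established clinical significance"
                ),
            )
        )

    positive_evidence = any(c.points > 0 for c in candidates)
    terminal = (
        terminal_benign and terminal_candidate is not None and not positive_evidence
    )
    if terminal_candidate is not None and positive_evidence:
        conflicts.append(
            "benign-gain containment (2C/2D) suppressed by positive Section-2 evidence; review"
        )

    if terminal:
        items = [replace(c, contributes=(c is terminal_candidate)) for c in candidates]
        return items, True, conflicts

    items, _ = pick_section2_winner(candidates)
    return items, False, conflicts
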