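"""Evidence sections shared by both dosage directions.

Section 1 (genomic content), Section 3 (protein-coding gene count) and the
automatable part of Section 4 (category 4O, common population variation)
score identically for losses and gains apart from the Section-3 band
boundaries.  The dosage-specific Section-2 decision trees live in
:mod:`cnvscore.scoring_loss` and :mod:`cnvscore.scoring_gain`.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from .annotator import AnnotationResult, Containment
from .evidence import EvidenceItem, MetricConfig
from .models import Dosage

#: Section-3 gene-count bands: (3B lower bound, 3C lower bound) per dosage.
#: For losses 25-34 genes is 3B and >= 35 is 3C; gains use 35-49 and >= 50.
SECTION3_BANDS = {
    Dosage.LOSS: (25, 35),
    Dosage.GAIN: (35, 50),
}

#: minimum fraction of the CNV covered by a common variant for 4O without
#: full containment
SECTION4_OVERLAP_FRACTION = 0.5


def score_section1(ann: AnnotationResult, cfg: MetricConfig) -> EvidenceItem:
    """1A (0) when the CNV holds coding genes or functionally important
    elements; 1B (-0.60) for empty genomic content."""
    dosage = ann.query.dosage
    if ann.gene_count > 0 or ann.functionally_important:
        reasons = []
        if ann.gene_count:
            reasons.append(f"contains {ann.gene_count} protein-coding gene(s)")
        if ann.functionally_important:
            reasons.append("overlaps functionally important element (dosage score 1-3)")
        return cfg.default_item(dosage, "1A", rationale="; ".join(reasons))
    return cfg.default_item(
        dosage,
        "1B",
        rationale="no protein-coding genes or known functionally important elements",
    )


def score_section3(ann: AnnotationResult, cfg: MetricConfig) -> EvidenceItem:
    """Gene-count bands: 3A / 3B (0.45) / 3C (0.9), dosage-specific cuts."""
    dosage = ann.query.dosage
    b_lo, c_lo = SECTION3_BANDS[dosage]
    count = ann.gene_count
    if count >= c_lo:
        category = "3C"
    elif count >= b_lo:
        category = "3B"
    else:
        category = "3A"
    return cfg.default_item(
        dosage, category, rationale=f"{count} protein-coding gene(s)"
    )


def score_section4_auto(
    ann: AnnotationResult, cfg: MetricConfig
) -> Optional[EvidenceItem]:
    """Category 4O for overlap with common population variation.

    -1.0 when the CNV is completely within a common variant of the same
    dosage, or when a common variant covers >= 50 % of the CNV and the CNV
    adds no protein-coding genes beyond it.  Otherwise 4O does not apply.
    """
    dosage = ann.query.dosage
    for fact in ann.common_variant_facts:
        if fact.containment is Containment.CNV_WITHIN:
            return cfg.default_item(
                dosage,
                "4O",
                rationale=(
                    f"completely within common {dosage.value} variant "
                    f"{fact.variant.variant_id} (frequency {fact.variant.frequency:.2%})"
                ),
                element_refs=(fact.variant.variant_id,),
            )
    for fact in ann.common_variant_facts:
        if (
            fact.extra_protein_genes == 0
            and fact.overlap_fraction_of_cnv >= SECTION4_OVERLAP_FRACTION
        ):
            return cfg.default_item(
                dosage,
                "4O",
                rationale=(
                    f"common variant {fact.variant.variant_id} covers "
                    f"{fact.overlap_fraction_of_cnv:.0%} of the CNV with no additional "
                    "protein-coding genes"
                ),
                element_refs=(fact.variant.variant_id,),
            )
    return None


def pick_section2_winner(
    candidates: List[EvidenceItem],
) -> Tuple[List[EvidenceItem], Optional[EvidenceItem]]:
    """Apply the single-winner rule to Section-2 candidates.

    All candidates remain in the report, but only the highest-scoring one
    contributes points; ties go to the earliest-emitted candidate.
    """
    if not candidates:
        return [], None
    winner = max(range(len(candidates)), key=lambda i: (candidates[i].points, -i))
    items = []
    for i, item in enumerate(candidates):
        from dataclasses import replace

        items.append(replace(item, contributes=(i == winner)))
    return items, items[winner]
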