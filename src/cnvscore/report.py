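"""Point aggregation, five-tier classification, and report serialization.

Totals are accumulated in integer hundredths of a point so that band
boundaries (0.99, 0.90, ...) are compared exactly, free of binary-float
drift; every point value in the metric is a multiple of 0.01.
"""

from __future__ import annotations

import enum
import io
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .evidence import EvidenceItem
from .models import CnvQuery, Dosage, GenomicInterval


class Classification(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely pathogenic"
    VUS = "uncertain significance"
    LIKELY_BENIGN = "likely benign"
    BENIGN = "benign"


def _cents(points: float) -> int:
    if not math.isfinite(points):
        raise ValueError(f"non-finite point total: {points}")
    return round(points * 100)


def classify(total: float) -> Classification:
    """Map a point total onto the five-tier classification.

    Thresholds: >= 0.99 pathogenic; >= 0.90 likely pathogenic; <= -0.99
    benign; <= -0.90 likely benign; everything in (-0.90, 0.90) uncertain.
    This reproduces the published bands (0.99+, 0.90..0.98, -0.89..0.89,
    -0.90..-0.98, -0.99 and below) and is total over the reals.
    """
    c = _cents(total)
    if c >= 99:
        return Classification.PATHOGENIC
    if c >= 90:
        return Classification.LIKELY_PATHOGENIC
    if c > -90:
        return Classification.VUS
    if c > -99:
        return Classification.LIKELY_BENIGN
    return Classification.BENIGN


def sum_points(items: Sequence[EvidenceItem]) -> float:
    return sum(_cents(i.points) for i in items if i.contributes) / 100


#: automated total at or beyond which no manual evidence is needed to reach
#: a pathogenic/benign call
SUFFICIENCY_THRESHOLD = 0.99


@dataclass
class ScoreCard:
    """Full interpretation result for one CNV."""

    query: CnvQuery
    items: List[EvidenceItem]
    auto_total: float
    final_total: float
    pre_classification: Classification
    final_classification: Classification
    sufficient_without_manual: bool
    terminal_benign: bool = False
    conflicts: List[str] = field(default_factory=list)
    build_label: str = "GRCh37"


def build_scorecard(
    auto_items: Sequence[EvidenceItem],
    merged_items: Sequence[EvidenceItem],
    query: CnvQuery,
    terminal_benign: bool = False,
    conflicts: Optional[Sequence[str]] = None,
    build_label: str = "GRCh37",
) -> ScoreCard:
    """Assemble totals and classifications from scored evidence.

    ``auto_items`` are the engine's items alone; ``merged_items`` include
    any manual evidence.  Contribution flags (single-winner rule, terminal
    benign short-circuit) are expected to be already set by the scorers.
    """
    conflicts = list(conflicts or [])
    auto_total = sum_points(auto_items)
    final_total = sum_points(merged_items)
    pre = classify(auto_total)
    final = classify(final_total)

    positive_sec2 = any(
        i.contributes and i.category.startswith("2") and i.points > 0
        for i in merged_items
    )
    if positive_sec2 and any(
        i.contributes and i.category == "4O" for i in merged_items
    ):
        conflicts.append(
            "common-variant evidence (4O) fired alongside positive Section-2 evidence; review"
        )

    sufficient = (
        auto_total >= SUFFICIENCY_THRESHOLD
        or auto_total <= -SUFFICIENCY_THRESHOLD
        or terminal_benign
    )
    return ScoreCard(
        query=query,
        items=list(merged_items),
        auto_total=auto_total,
        final_total=final_total,
        pre_classification=pre,
        final_classification=final,
        sufficient_without_manual=sufficient,
        terminal_benign=terminal_benign,
        conflicts=conflicts,
        build_label=build_label,
    )


# ---------------------------------------------------------------------------
# Serialization

_SECTION_ORDER = "12345"


def _item_sort_key(item: EvidenceItem) -> Tuple:
    section = item.category[0]
    return (
        _SECTION_ORDER.index(section) if section in _SECTION_ORDER else 9,
        item.category,
    )


def card_to_dict(card: ScoreCard) -> dict:
    return {
        "query": {
            "label": card.query.label,
            "chrom": card.query.interval.chrom,
            "start": card.query.interval.start,
            "end": card.query.interval.end,
            "dosage": card.query.dosage.value,
        },
        "build": card.build_label,
        "auto_total": card.auto_total,
        "final_total": card.final_total,
        "pre_classification": card.pre_classification.value,
        "final_classification": card.final_classification.value,
        "sufficient_without_manual": card.sufficient_without_manual,
        "terminal_benign": card.terminal_benign,
        "conflicts": list(card.conflicts),
        "evidence": [
            {
                "category": i.category,
                "points": i.points,
                "range_min": i.range_min,
                "range_max": i.range_max,
                "source": i.source,
                "contributes": i.contributes,
                "rationale": i.rationale,
                "element_refs": list(i.element_refs),
            }
            for i in sorted(card.items, key=_item_sort_key)
        ],
    }


def card_from_dict(data: dict) -> ScoreCard:
    q = data["query"]
    query = CnvQuery(
        interval=GenomicInterval(q["chrom"], q["start"], q["end"]),
        dosage=Dosage(q["dosage"]),
        label=q.get("label"),
    )
    items = [
        EvidenceItem(
            category=e["category"],
            points=e["points"],
            range_min=e["range_min"],
            range_max=e["range_max"],
            source=e["source"],
            rationale=e["rationale"],
            element_refs=tuple(e["element_refs"]),
            contributes=e["contributes"],
        )
        for e in data["evidence"]
    ]
    return ScoreCard(
        query=query,
        items=items,
        auto_total=data["auto_total"],
        final_total=data["final_total"],
        pre_classification=Classification(data["pre_classification"]),
        final_classification=Classification(data["final_classification"]),
        sufficient_without_manual=data["sufficient_without_manual"],
        terminal_benign=data["terminal_benign"],
        conflicts=list(data["conflicts"]),
        build_label=data.get("build", "GRCh37"),
    )


TSV_COLUMNS = (
    "label", "chrom", "start", "end", "dosage", "auto_total", "final_total",
    "pre_class", "final_class", "categories", "flags",
)


def card_to_tsv_row(card: ScoreCard) -> str:
    cats = ";".join(
        f"{i.category}:{i.points:g}"
        for i in sorted(card.items, key=_item_sort_key)
        if i.contributes
    )
    fields = (
        card.query.label or "",
        card.query.interval.chrom,
        str(card.query.interval.start),
        str(card.query.interval.end),
        card.query.dosage.value,
        f"{card.auto_total:g}",
        f"{card.final_total:g}",
        card.pre_classification.value,
        card.final_classification.value,
        cats,
        "|".join(card.conflicts),
    )
    return "\t".join(fields)


def card_to_text(card: ScoreCard) -> str:
    """Narrative report mirroring the section order of the scoring metric."""
    out = io.StringIO()
    q = card.query
    out.write(f"CNV: {q.interval} ({q.dosage.value})")
    if q.label:
        out.write(f"  [{q.label}]")
    out.write(f"\nGenome build: {card.build_label}\n\n")
    out.write("Evidence (sections 1-5):\n")
    for item in sorted(card.items, key=_item_sort_key):
        marker = "*" if item.contributes else " "
        out.write(
            f"  {marker} {item.category:<5} {item.points:+.2f} "
            f"[{item.range_min:g}..{item.range_max:g}] ({item.source.lower()}) "
            f"{item.rationale}\n"
        )
    out.write("  (* = contributes to the total)\n\n")
    out.write(f"Automated total: {card.auto_total:.2f} -> {card.pre_classification.value}\n")
    out.write(f"Final total:     {card.final_total:.2f} -> {card.final_classification.value}\n")
    if card.terminal_benign:
        out.write("Terminal benign rule applied: final point fixed at -1.0.\n")
    if card.sufficient_without_manual:
        out.write("Classification reached without manual evidence.\n")
    for flag in card.conflicts:
        out.write(f"CONFLICT: {flag}\n")
    return out.getvalue()


def write_report(card: ScoreCard, fmt: str = "json") -> str:
    """Serialize a scorecard as ``json``, ``tsv`` (header + row) or ``text``."""
    if fmt == "json":
        return json.dumps(card_to_dict(card), indent=2)
    if fmt == "tsv":
        return "\t".join(TSV_COLUMNS) + "\n" + card_to_tsv_row(card) + "\n"
    if fmt == "text":
        return card_to_text(card)
    raise ValueError(f"unknown report format {fmt!r}; expected json, tsv or text")
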