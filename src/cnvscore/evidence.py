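"""Evidence items, the scoring-metric configuration, and manual merge.

The 2019 ACMG/ClinGen CNV scoring metric defines 40 evidence categories per
dosage direction (80 in total), each with a suggested default point value
and an allowed range.  The engine automates 18 of the loss and 16 of the
gain categories; the rest (case evidence 4A-4N, family history 5A-5H, and
the gain breakpoint categories 2J/2K) take user-supplied points that are
validated here against the configured ranges before merging.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import yaml

from .models import Dosage


class MetricConfigError(Exception):
    """Invalid or incomplete scoring-metric configuration."""


class ManualEvidenceError(Exception):
    """User-supplied evidence failed validation against the metric."""


#: number of evidence categories per dosage in the scoring metric
CATEGORIES_PER_DOSAGE = 40


@dataclass(frozen=True)
class EvidenceItem:
    """Points assigned under one metric category, with provenance."""

    category: str
    points: float
    range_min: float
    range_max: float
    source: str = "AUTOMATED"  # AUTOMATED | MANUAL
    rationale: str = ""
    element_refs: Tuple[str, ...] = ()
    contributes: bool = True  # False for recorded-but-not-counted candidates

    def __post_init__(self) -> None:
        if not (self.range_min - 1e-9 <= self.points <= self.range_max + 1e-9):
            raise ValueError(
                f"{self.category}: points {self.points} outside range "
                f"[{self.range_min}, {self.range_max}]"
            )


@dataclass(frozen=True)
class CategorySpec:
    category: str
    default_points: float
    range_min: float
    range_max: float
    automated: bool
    description: str = ""


@dataclass(frozen=True)
class ManualEvidence:
    category: str
    points: float
    note: str = ""


@dataclass
class MetricConfig:
    """Per-dosage category table plus the manual adjustment step size."""

    loss: Dict[str, CategorySpec]
    gain: Dict[str, CategorySpec]
    adjustment_step: float = 0.05

    def table(self, dosage: Dosage) -> Dict[str, CategorySpec]:
        return self.loss if dosage is Dosage.LOSS else self.gain

    def spec(self, dosage: Dosage, category: str) -> CategorySpec:
        try:
            return self.table(dosage)[category]
        except KeyError:
            raise MetricConfigError(
                f"category {category!r} not defined for {dosage.value}"
            ) from None

    def automated_categories(self, dosage: Dosage) -> List[str]:
        return [c for c, s in self.table(dosage).items() if s.automated]

    def default_item(self, dosage: Dosage, category: str, **kwargs) -> EvidenceItem:
        spec = self.spec(dosage, category)
        return EvidenceItem(
            category=category,
            points=spec.default_points,
            range_min=spec.range_min,
            range_max=spec.range_max,
            **kwargs,
        )


def _parse_table(entries: Sequence[dict], dosage_name: str) -> Dict[str, CategorySpec]:
    table: Dict[str, CategorySpec] = {}
    for entry in entries:
        cat = str(entry["category"])
        if cat in table:
            raise MetricConfigError(f"duplicate category {cat!r} for {dosage_name}")
        spec = CategorySpec(
            category=cat,
            default_points=float(entry["default"]),
            range_min=float(entry["min"]),
            range_max=float(entry["max"]),
            automated=bool(entry["automated"]),
            description=str(entry.get("description", "")),
        )
        if not spec.range_min <= spec.default_points <= spec.range_max:
            raise MetricConfigError(
                f"{dosage_name} category {cat}: default {spec.default_points} outside "
                f"range [{spec.range_min}, {spec.range_max}]"
            )
        table[cat] = spec
    if len(table) != CATEGORIES_PER_DOSAGE:
        raise MetricConfigError(
            f"{dosage_name}: expected {CATEGORIES_PER_DOSAGE} categories, found {len(table)}"
        )
    return table


def load_metric_config(path: Optional[str | Path] = None) -> MetricConfig:
    """Load the metric from YAML/JSON; without *path*, the shipped default."""
    if path is None:
        text = resources.files("cnvscore.data").joinpath("metric_config.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        text = Path(path).read_text()
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    try:
        categories = raw["categories"]
        loss = _parse_table(categories["loss"], "loss")
        gain = _parse_table(categories["gain"], "gain")
    except (KeyError, TypeError) as exc:
        raise MetricConfigError(f"malformed metric config: {exc}") from exc
    return MetricConfig(
        loss=loss,
        gain=gain,
        adjustment_step=float(raw.get("adjustment_step", 0.05)),
    )


# ---------------------------------------------------------------------------
# Manual evidence


def load_manual_evidence(path: str | Path) -> List[ManualEvidence]:
    """Read manual evidence from a JSON array or a TSV (category, points, note)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
        if not isinstance(entries, list):
            raise ManualEvidenceError(f"{path.name}: expected a JSON array")
        return [
            ManualEvidence(
                category=str(e["category"]),
                points=float(e["points"]),
                note=str(e.get("note", "")),
            )
            for e in entries
        ]
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "category" not in reader.fieldnames:
            raise ManualEvidenceError(f"{path.name}: missing 'category' column")
        return [
            ManualEvidence(
                category=row["category"].strip(),
                points=float(row["points"]),
                note=(row.get("note") or "").strip(),
            )
            for row in reader
        ]


def _is_step_multiple(offset: float, step: float) -> bool:
    # work in integer hundredths to dodge binary-float drift
    return round(offset * 100) % round(step * 100) == 0


def validate_manual(
    manual: Sequence[ManualEvidence],
    dosage: Dosage,
    cfg: MetricConfig,
    strict_step: bool = True,
) -> None:
    """Range-, dosage- and step-validate manual entries; raise on the first violation."""
    seen = set()
    for entry in manual:
        if entry.category in seen:
            raise ManualEvidenceError(f"duplicate manual category {entry.category!r}")
        seen.add(entry.category)
        spec = cfg.spec(dosage, entry.category)  # raises for wrong-dosage categories
        if not spec.range_min - 1e-9 <= entry.points <= spec.range_max + 1e-9:
            raise ManualEvidenceError(
                f"category {entry.category}: points {entry.points} outside allowed "
                f"range [{spec.range_min}, {spec.range_max}]"
            )
        if strict_step and not _is_step_multiple(
            entry.points - spec.default_points, cfg.adjustment_step
        ):
            raise ManualEvidenceError(
                f"category {entry.category}: points {entry.points} is not default "
                f"{spec.default_points} plus a multiple of {cfg.adjustment_step}"
            )


def merge_manual(
    auto_items: Sequence[EvidenceItem],
    manual: Sequence[ManualEvidence],
    dosage: Dosage,
    cfg: MetricConfig,
    strict_step: bool = True,
) -> List[EvidenceItem]:
    """Merge validated manual evidence into the automated item list.

    A manual entry for a category the engine already scored replaces the
    automated points (flagged as user-adjusted); other entries are appended
    as MANUAL items.  The merge is order-independent over the manual list
    and never counts a category twice.
    """
    validate_manual(manual, dosage, cfg, strict_step=strict_step)
    by_category = {e.category: e for e in manual}
    merged: List[EvidenceItem] = []
    for item in auto_items:
        override = by_category.pop(item.category, None)
        if override is None:
            merged.append(item)
        else:
            spec = cfg.spec(dosage, item.category)
            merged.append(
                replace(
                    item,
                    points=override.points,
                    range_min=spec.range_min,
                    range_max=spec.range_max,
                    source="MANUAL",
                    rationale=(
                        f"user-adjusted from automated {item.points:g}: {override.note}"
                        if override.note
                        else f"user-adjusted from automated {item.points:g}"
                    ),
                )
            )
    for category in sorted(by_category):
        entry = by_category[category]
        spec = cfg.spec(dosage, category)
        merged.append(
            EvidenceItem(
                category=category,
                points=entry.points,
                range_min=spec.range_min,
                range_max=spec.range_max,
                source="MANUAL",
                rationale=entry.note,
            )
        )
    return merged
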