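"""End-to-end interpretation: annotate, score, merge, classify.

``interpret`` is the single entry point the CLI and batch runner use; it
walks the evidence sections in ascending order (1 through 4O), honours the
terminal-benign short-circuit, merges validated manual evidence and
returns a complete :class:`~cnvscore.report.ScoreCard`.
"""

from __future__ import annotations

from dataclasses import replace
from typing import List, Optional, Sequence, Tuple

from .annotator import AnnotationResult, CommonnessThresholds, annotate
from .database import AnnotationDatabase
from .evidence import EvidenceItem, ManualEvidence, MetricConfig, load_metric_config, merge_manual
from .intragenic import TandemStatus
from .models import CnvQuery, Dosage
from .report import ScoreCard, build_scorecard
from .scoring import score_section1, score_section3, score_section4_auto
from .scoring_gain import score_section2_gain
from .scoring_loss import score_section2_loss


def run_automated(
    query: CnvQuery,
    db: AnnotationDatabase,
    cfg: Optional[MetricConfig] = None,
    tandem_status: TandemStatus = TandemStatus.UNKNOWN,
    thresholds: Optional[CommonnessThresholds] = None,
    terminal_benign_gain: bool = True,
) -> Tuple[AnnotationResult, List[EvidenceItem], bool, List[str]]:
    """Run every automated section; returns (annotation, items, terminal, conflicts).

    When a terminal benign category fires in Section 2 (loss 2F, gain
    2C/2D), later sections are not evaluated and the Section-1 item is
    demoted to a recorded-only entry so the automated total is exactly the
    benign -1.0.
    """
    cfg = cfg or load_metric_config()
    ann = annotate(query, db, thresholds)
    items: List[EvidenceItem] = [score_section1(ann, cfg)]

    if query.dosage is Dosage.LOSS:
        sec2, terminal, conflicts = score_section2_loss(ann, db, cfg)
    else:
        sec2, terminal, conflicts = score_section2_gain(
            ann, db, cfg, tandem_status, terminal_benign=terminal_benign_gain
        )
    items.extend(sec2)

    if terminal:
        items = [
            i if i.category.startswith("2") else replace(i, contributes=False)
            for i in items
        ]
        return ann, items, True, conflicts

    items.append(score_section3(ann, cfg))
    sec4 = score_section4_auto(ann, cfg)
    if sec4 is not None:
        items.append(sec4)
    return ann, items, False, conflicts


def interpret(
    query: CnvQuery,
    db: AnnotationDatabase,
    cfg: Optional[MetricConfig] = None,
    manual: Sequence[ManualEvidence] = (),
    tandem_status: TandemStatus = TandemStatus.UNKNOWN,
    thresholds: Optional[CommonnessThresholds] = None,
    strict_step: bool = True,
    terminal_benign_gain: bool = True,
) -> ScoreCard:
    """Interpret one CNV, optionally merging manual evidence."""
    cfg = cfg or load_metric_config()
    ann, auto_items, terminal, conflicts = run_automated(
        query,
        db,
        cfg,
        tandem_status=tandem_status,
        thresholds=thresholds,
        terminal_benign_gain=terminal_benign_gain,
    )
    if manual:
        merged = merge_manual(
            auto_items, manual, query.dosage, cfg, strict_step=strict_step
        )
        overridden = [
            i.category
            for i in merged
            if i.source == "MANUAL" and any(a.category == i.category for a in auto_items)
        ]
        for category in overridden:
            conflicts = list(conflicts) + [
                f"automated category {category} overridden by manual evidence"
            ]
    else:
        merged = list(auto_items)
    return build_scorecard(
        auto_items,
        merged,
        query,
        terminal_benign=terminal,
        conflicts=conflicts,
        build_label=db.build_label,
    )
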