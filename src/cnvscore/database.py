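"""Local annotation databases: loading, validation, and interval queries.

The engine runs entirely from a directory of tab-delimited files (one per
database), mirroring the six sources a CNV interpretation workflow draws on:
gene models with exon/CDS structure, the curated dosage-sensitivity map
(HI/TS plus established-benign tracks), population CNVs with cohort sizes,
a known-variant table, and an optional curated critical-region table.
Each collection is indexed per chromosome with an interval tree; a query
returns every record sharing >= 1 bp with the query interval, in
deterministic (coordinate, id) order.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from intervaltree import IntervalTree

from .models import (
    CnvQuery,
    CriticalRegion,
    Dosage,
    GenomicInterval,
    GeneModel,
    KnownVariant,
    PopulationVariant,
    DosageRegion,
    RegionKind,
    Significance,
    SourceKind,
    Strand,
    normalize_chrom,
)

log = logging.getLogger(__name__)

_CNV_RE = re.compile(r"^\s*(?P<chrom>[A-Za-z0-9_.]+)\s*:\s*(?P<start>[\d,\s]+?)\s*-\s*(?P<end>[\d,\s]+?)\s*$")


class DatabaseError(Exception):
    """Schema or record-level validation failure while loading a database."""


def parse_cnv(text: str, dosage: Dosage | str, label: Optional[str] = None) -> CnvQuery:
    """Parse a ``chrom:start-end`` coordinate string into a :class:`CnvQuery`.

    Commas and internal whitespace in the numbers are ignored, so printed
    clinical coordinates such as ``chr22:18,761,827-20,307,561`` parse
    directly.  A missing ``chr`` prefix is added.
    """
    if isinstance(dosage, str):
        dosage = Dosage(dosage.lower())
    m = _CNV_RE.match(text)
    if not m:
        raise ValueError(f"malformed CNV coordinate {text!r}; expected chrom:start-end")
    start = int(re.sub(r"[,\s]", "", m.group("start")))
    end = int(re.sub(r"[,\s]", "", m.group("end")))
    interval = GenomicInterval(m.group("chrom"), start, end)  # validates start <= end
    return CnvQuery(interval=interval, dosage=dosage, label=label)


def format_cnv(query: CnvQuery) -> str:
    """Inverse of :func:`parse_cnv` (canonical form, no thousands separators)."""
    return str(query.interval)


class _IntervalIndex:
    """Per-chromosome interval trees over records carrying ``.interval``.

    Internally converts the 1-based closed intervals to half-open ones
    (end + 1) as required by :mod:`intervaltree`; callers never see that.
    """

    def __init__(self, records: Sequence, sort_key) -> None:
        self.records: List = sorted(records, key=sort_key)
        self._trees: Dict[str, IntervalTree] = {}
        for idx, rec in enumerate(self.records):
            iv = rec.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, idx)
        self._warned_chroms: set = set()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def overlapping(self, interval: GenomicInterval) -> List:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            if interval.chrom not in self._warned_chroms:
                log.info("no records on %s; returning empty result", interval.chrom)
                self._warned_chroms.add(interval.chrom)
            return []
        hits = sorted(hit.data for hit in tree.overlap(interval.start, interval.end + 1))
        return [self.records[i] for i in hits]


def _record_key(rec):
    iv = rec.interval
    ident = getattr(rec, "gene_id", None) or getattr(rec, "region_id", None) or getattr(
        rec, "variant_id", ""
    )
    return (iv.chrom, iv.start, iv.end, str(ident))


@dataclass
class AnnotationDatabase:
    """All loaded annotation collections plus their interval indexes."""

    genes: _IntervalIndex
    dosage_regions: _IntervalIndex
    population_variants: _IntervalIndex
    known_variants: _IntervalIndex
    critical_regions: _IntervalIndex
    build_label: str = "GRCh37"

    _COLLECTIONS = ("genes", "dosage_regions", "population_variants", "known_variants", "critical_regions")

    def query(self, interval: GenomicInterval, collection: str) -> List:
        """Every record of *collection* sharing >= 1 bp with *interval*."""
        if collection not in self._COLLECTIONS:
            raise KeyError(f"unknown collection {collection!r}; expected one of {self._COLLECTIONS}")
        index: _IntervalIndex = getattr(self, collection)
        return index.overlapping(interval)


# ---------------------------------------------------------------------------
# TSV readers


def _read_tsv(path: Path, required: Sequence[str]) -> List[dict]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        missing = [col for col in required if col not in header]
        if missing:
            raise DatabaseError(f"{path.name}: missing required column(s) {', '.join(missing)}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            row["_line"] = lineno
            rows.append(row)
    return rows


def _opt_float(value: str) -> Optional[float]:
    value = (value or "").strip()
    if value in ("", ".", "NA", "na", "None"):
        return None
    return float(value)


def _opt_int(value: str) -> Optional[int]:
    value = (value or "").strip()
    if value in ("", ".", "NA", "na", "None"):
        return None
    return int(value)


def _row_error(path: Path, row: dict, exc: Exception) -> DatabaseError:
    return DatabaseError(f"{path.name}, line {row.get('_line', '?')}: {exc}")


GENE_COLUMNS = (
    "gene_id", "symbol", "chrom", "start", "end", "strand", "cds_start", "cds_end",
    "exon_starts", "exon_ends", "coding", "canonical", "pli", "oe_upper", "hi_index", "relevant",
)


def _parse_gene_row(row: dict, path: Path) -> GeneModel:
    try:
        chrom = row["chrom"]
        strand = Strand(row["strand"])
        exon_starts = [int(s) for s in row["exon_starts"].rstrip(",").split(",")]
        exon_ends = [int(s) for s in row["exon_ends"].rstrip(",").split(",")]
        if len(exon_starts) != len(exon_ends):
            raise ValueError("exon_starts/exon_ends length mismatch")
        exons = [GenomicInterval(chrom, s, e) for s, e in zip(exon_starts, exon_ends)]
        exons.sort(key=lambda iv: iv.start)
        if strand is Strand.MINUS:
            exons.reverse()  # store in transcription order
        return GeneModel(
            gene_id=row["gene_id"],
            symbol=row["symbol"],
            interval=GenomicInterval(chrom, int(row["start"]), int(row["end"])),
            strand=strand,
            exons=tuple(exons),
            cds_start=_opt_int(row["cds_start"]),
            cds_end=_opt_int(row["cds_end"]),
            is_protein_coding=row["coding"].strip() == "1",
            is_canonical=row["canonical"].strip() == "1",
            pli=_opt_float(row["pli"]),
            oe_upper=_opt_float(row["oe_upper"]),
            hi_index=_opt_float(row["hi_index"]),
            biologically_relevant=row["relevant"].strip() != "0",
        )
    except (ValueError, KeyError) as exc:
        raise _row_error(path, row, exc) from exc


DOSAGE_COLUMNS = ("region_id", "chrom", "start", "end", "kind", "score", "gene_id")


def _parse_dosage_row(row: dict, path: Path) -> DosageRegion:
    try:
        return DosageRegion(
            region_id=row["region_id"],
            interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            kind=RegionKind(row["kind"]),
            dosage_score=_opt_int(row["score"]),
            gene_id=(row["gene_id"].strip() or None),
        )
    except (ValueError, KeyError) as exc:
        raise _row_error(path, row, exc) from exc


POPVAR_COLUMNS = ("variant_id", "chrom", "start", "end", "dosage", "frequency", "cohort_size", "source_kind")


def _parse_popvar_row(row: dict, path: Path) -> PopulationVariant:
    try:
        return PopulationVariant(
            variant_id=row["variant_id"],
            interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            dosage=Dosage(row["dosage"].lower()),
            frequency=float(row["frequency"]),
            cohort_size=int(row["cohort_size"]),
            source_kind=SourceKind(row["source_kind"]),
        )
    except (ValueError, KeyError) as exc:
        raise _row_error(path, row, exc) from exc


VARIANT_COLUMNS = ("chrom", "start", "end", "gene_id", "significance", "allele_frequency")


def _parse_variant_row(row: dict, path: Path) -> KnownVariant:
    try:
        return KnownVariant(
            interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            gene_id=row["gene_id"],
            significance=Significance(row["significance"]),
            allele_frequency=float(row["allele_frequency"]),
        )
    except (ValueError, KeyError) as exc:
        raise _row_error(path, row, exc) from exc


CRITICAL_COLUMNS = ("gene_id", "chrom", "start", "end", "note")


def _parse_critical_row(row: dict, path: Path) -> CriticalRegion:
    try:
        return CriticalRegion(
            gene_id=row["gene_id"],
            interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            note=row.get("note", "") or "",
        )
    except (ValueError, KeyError) as exc:
        raise _row_error(path, row, exc) from exc


_FILES = {
    "genes": ("genes.tsv", GENE_COLUMNS, _parse_gene_row, True),
    "dosage_regions": ("dosage.tsv", DOSAGE_COLUMNS, _parse_dosage_row, False),
    "population_variants": ("popvar.tsv", POPVAR_COLUMNS, _parse_popvar_row, False),
    "known_variants": ("variants.tsv", VARIANT_COLUMNS, _parse_variant_row, False),
    "critical_regions": ("critical.tsv", CRITICAL_COLUMNS, _parse_critical_row, False),
}


def load_database(directory: str | Path, build_label: str = "GRCh37") -> AnnotationDatabase:
    """Load and index every annotation file found under *directory*.

    ``genes.tsv`` is required; every other file is optional and a missing
    one yields an empty (but queryable) collection with a logged warning.
    Row-level invariant violations raise :class:`DatabaseError` naming the
    file and line.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DatabaseError(f"annotation database directory not found: {directory}")
    collections = {}
    for name, (fname, columns, parser, required) in _FILES.items():
        path = directory / fname
        if not path.exists():
            if required:
                raise DatabaseError(f"required database file missing: {path}")
            log.warning("optional database file %s missing; %s collection empty", fname, name)
            collections[name] = _IntervalIndex([], _record_key)
            continue
        records = [parser(row, path) for row in _read_tsv(path, columns)]
        collections[name] = _IntervalIndex(records, _record_key)
        log.info("loaded %d records from %s", len(records), fname)
    # cross-file invariant: critical regions must lie inside their gene's span
    gene_spans: Dict[str, List[GeneModel]] = {}
    for gene in collections["genes"]:
        gene_spans.setdefault(gene.symbol, []).append(gene)
    for region in collections["critical_regions"]:
        carriers = gene_spans.get(region.gene_id, [])
        if carriers and not any(g.interval.contains(region.interval) for g in carriers):
            raise DatabaseError(
                f"critical.tsv: region {region.interval} outside span of gene {region.gene_id}"
            )
    return AnnotationDatabase(build_label=build_label, **collections)


def load_bed_track(path: str | Path, kind: RegionKind, score: Optional[int] = None) -> List[DosageRegion]:
    """Read a minimal BED3+ file as dosage/benign regions.

    BED is 0-based half-open; records are converted to the internal 1-based
    closed convention (start + 1, end unchanged).
    """
    path = Path(path)
    regions = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DatabaseError(f"{path.name}, line {lineno}: fewer than 3 BED columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{path.stem}_{lineno}"
            regions.append(
                DosageRegion(
                    region_id=name,
                    interval=GenomicInterval(chrom, start0 + 1, end0),
                    kind=kind,
                    dosage_score=score,
                )
            )
    return regions
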