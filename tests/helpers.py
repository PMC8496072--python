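"""Shared test utilities: gene-model builders, tiny database writers, and
brute-force oracles kept independent of the library's own arithmetic."""

from __future__ import annotations

import random
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from cnvscore.models import GenomicInterval, GeneModel, Strand


def make_gene(
    symbol: str = "GENE1",
    chrom: str = "chr1",
    start: int = 10_000,
    exon_lens: Sequence[int] = (200, 200, 200, 200),
    intron_len: int = 800,
    strand: str = "+",
    utr: int = 100,
    coding: bool = True,
    gene_id: Optional[str] = None,
    **kwargs,
) -> GeneModel:
    """Gene with the given exon lengths laid out left to right genomically."""
    exons = []
    pos = start
    for length in exon_lens:
        exons.append(GenomicInterval(chrom, pos, pos + length - 1))
        pos += length + intron_len
    end = exons[-1].end
    if strand == "-":
        exons = list(reversed(exons))  # transcription order
    return GeneModel(
        gene_id=gene_id or f"{symbol}.t1",
        symbol=symbol,
        interval=GenomicInterval(chrom, start, end),
        strand=Strand(strand),
        exons=tuple(exons),
        cds_start=start + utr if coding else None,
        cds_end=end - utr if coding else None,
        is_protein_coding=coding,
        **kwargs,
    )


def write_db(
    directory: Path,
    genes: Sequence[GeneModel] = (),
    dosage_rows: Sequence[tuple] = (),
    popvar_rows: Sequence[tuple] = (),
    variant_rows: Sequence[tuple] = (),
    critical_rows: Sequence[tuple] = (),
) -> Path:
    """Write a minimal annotation-database directory from in-memory records."""
    directory.mkdir(parents=True, exist_ok=True)

    def dump(name: str, header: Tuple[str, ...], rows) -> None:
        with open(directory / name, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(v) for v in row) + "\n")

    gene_rows = []
    for g in genes:
        genomic = sorted(g.exons, key=lambda e: e.start)
        gene_rows.append(
            (
                g.gene_id, g.symbol, g.interval.chrom, g.interval.start,
                g.interval.end, g.strand.value,
                g.cds_start if g.cds_start is not None else "",
                g.cds_end if g.cds_end is not None else "",
                ",".join(str(e.start) for e in genomic),
                ",".join(str(e.end) for e in genomic),
                int(g.is_protein_coding), int(g.is_canonical),
                g.pli if g.pli is not None else "",
                g.oe_upper if g.oe_upper is not None else "",
                g.hi_index if g.hi_index is not None else "",
                int(g.biologically_relevant),
            )
        )
    dump("genes.tsv",
         ("gene_id", "symbol", "chrom", "start", "end", "strand", "cds_start",
          "cds_end", "exon_starts", "exon_ends", "coding", "canonical", "pli",
          "oe_upper", "hi_index", "relevant"), gene_rows)
    dump("dosage.tsv",
         ("region_id", "chrom", "start", "end", "kind", "score", "gene_id"),
         dosage_rows)
    dump("popvar.tsv",
         ("variant_id", "chrom", "start", "end", "dosage", "frequency",
          "cohort_size", "source_kind"), popvar_rows)
    dump("variants.tsv",
         ("chrom", "start", "end", "gene_id", "significance", "allele_frequency"),
         variant_rows)
    dump("critical.tsv", ("gene_id", "chrom", "start", "end", "note"), critical_rows)
    return directory


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_overlaps(records, interval: GenomicInterval) -> list:
    """O(n) scan with the >= 1 bp closed-coordinate overlap predicate."""
    hits = [
        r
        for r in records
        if r.interval.chrom == interval.chrom
        and r.interval.start <= interval.end
        and interval.start <= r.interval.end
    ]

    def key(rec):
        ident = getattr(rec, "gene_id", None) or getattr(rec, "region_id", None) \
            or getattr(rec, "variant_id", "")
        return (rec.interval.chrom, rec.interval.start, rec.interval.end, str(ident))

    return sorted(hits, key=key)


def brute_force_nmd_deletion(gene: GeneModel, query: GenomicInterval) -> bool:
    """Base-by-base transcript reconstruction of the 50-nt NMD rule.

    Enumerates every surviving exonic base in transcription order, places
    the premature termination codon at the deletion junction, and measures
    its distance to the last exon-exon junction of the reconstructed
    transcript.
    """
    bases: List[Tuple[int, int]] = []  # (genomic pos, exon ordinal)
    for ordinal, exon in enumerate(gene.exons, start=1):
        positions = (
            range(exon.start, exon.end + 1)
            if gene.strand is Strand.PLUS
            else range(exon.end, exon.start - 1, -1)
        )
        for pos in positions:
            if not (query.start <= pos <= query.end):
                bases.append((pos, ordinal))
    if not bases:
        return False
    surviving_exons = {o for _, o in bases}
    if len(surviving_exons) < 2:
        return False
    last_ordinal = bases[-1][1]
    last_junction = min(i for i, (_, o) in enumerate(bases) if o == last_ordinal)

    def is_downstream(pos: int) -> bool:
        return pos > query.end if gene.strand is Strand.PLUS else pos < query.start

    ptc = next((i for i, (p, _) in enumerate(bases) if is_downstream(p)), len(bases))
    return last_junction - ptc >= 50


def random_gene(rng: random.Random, chrom: str = "chr1") -> GeneModel:
    n_exons = rng.randint(1, 6)
    exon_lens = [rng.randint(30, 300) for _ in range(n_exons)]
    max_utr = min(25, (exon_lens[0] - 1) // 2, (exon_lens[-1] - 1) // 2)
    return make_gene(
        symbol=f"R{rng.randint(0, 10**6)}",
        chrom=chrom,
        start=rng.randint(1_000, 500_000),
        exon_lens=exon_lens,
        intron_len=rng.randint(60, 500),
        strand=rng.choice("+-"),
        utr=rng.randint(0, max_utr),
    )
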