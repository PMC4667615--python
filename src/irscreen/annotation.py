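"""Gene annotation model: transcripts, exons and derived introns.

All internal coordinates are 0-based, half-open ``[start, end)``; the GTF
reader/writer converts to and from GTF's 1-based closed convention at the
boundary, so interval arithmetic downstream matches BED semantics.

The intron universe used by the retention screen is the set of *unique*
genomic intervals ``(chrom, start, end, strand)`` derived from the gaps
between consecutive exons, collapsed across transcripts.  Introns are not
masked against exons of other isoforms: retention is quantified over the
raw intronic interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap (>= 1 bp) test, strand-agnostic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and self.end > other.start
        )


@dataclass
class Transcript:
    """A transcript: ordered exons plus an optional genomic CDS span."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple chromosomes/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be given together")
        if self.cds_start is not None:
            if not (self.span.start <= self.cds_start < self.cds_end <= self.span.end):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS outside exon span"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals into a disjoint sorted union."""
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing a gene_id."""

    gene_id: str
    transcripts: list[Transcript]
    union_exonic_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        self.union_exonic_length = sum(iv.length for iv in self.exon_union())

    def exon_union(self) -> list[GenomicInterval]:
        """Disjoint merged union of all exons across transcripts."""
        return merge_intervals(e for t in self.transcripts for e in t.exons)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand


@dataclass(frozen=True)
class Intron:
    """An intron interval with its source gene and 1-based ordinal.

    The ordinal counts introns in 5'->3' *transcript* orientation of the
    transcript the intron was first derived from, so ordinal 1 on a minus
    strand transcript is the gap nearest the 3' genomic end.
    """

    interval: GenomicInterval
    gene_id: str
    ordinal: int

    @property
    def key(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"

    @property
    def name(self) -> str:
        return f"{self.gene_id}:{self.ordinal}"


def derive_introns(t: Transcript) -> list[Intron]:
    """Introns of one transcript, ordered 5'->3' in transcript orientation."""
    gaps: list[GenomicInterval] = []
    for a, b in zip(t.exons, t.exons[1:]):
        if a.end == b.start:
            raise ValueError(
                f"transcript {t.transcript_id}: zero-length intron at {a.end}"
            )
        gaps.append(GenomicInterval(t.chrom, a.end, b.start, t.strand))
    if t.strand == "-":
        gaps.reverse()
    return [Intron(iv, t.gene_id, i + 1) for i, iv in enumerate(gaps)]


def collapse_introns(genes: Iterable[GeneModel]) -> list[Intron]:
    """Unique introns by (chrom, start, end, strand) across all transcripts.

    gene_id and ordinal come from the first transcript (in input order)
    contributing each interval; the result is coordinate-sorted.
    """
    seen: dict[tuple[str, int, int, str], Intron] = {}
    for gene in genes:
        for t in gene.transcripts:
            for intron in derive_introns(t):
                iv = intron.interval
                key = (iv.chrom, iv.start, iv.end, iv.strand)
                if key not in seen:
                    seen[key] = intron
    return sorted(seen.values(), key=lambda i: (i.interval.chrom, i.interval.start,
                                                i.interval.end, i.interval.strand))


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF file into GeneModels (exon and CDS features only).

    GTF coordinates (1-based, closed) are converted to 0-based half-open.
    Raises ``ValueError`` naming the offending line on malformed input.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    tx_gene: dict[str, str] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise ValueError(f"{path}: line {lineno}: end < start")
            if strand not in VALID_STRANDS:
                raise ValueError(f"{path}: line {lineno}: invalid strand {strand!r}")
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise ValueError(
                    f"{path}: line {lineno}: missing gene_id/transcript_id attribute"
                )
            tid, gid = attr["transcript_id"], attr["gene_id"]
            if tid not in tx_gene:
                tx_gene[tid] = gid
                order.append(tid)
            iv = (start1 - 1, end1)
            if feature == "exon":
                exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, iv[0], iv[1], strand)
                )
            else:
                cds.setdefault(tid, []).append(iv)

    genes: dict[str, list[Transcript]] = {}
    gene_order: list[str] = []
    for tid in order:
        if tid not in exons:
            continue
        gid = tx_gene[tid]
        cds_iv = cds.get(tid)
        t = Transcript(
            transcript_id=tid,
            gene_id=gid,
            exons=exons[tid],
            cds_start=min(s for s, _ in cds_iv) if cds_iv else None,
            cds_end=max(e for _, e in cds_iv) if cds_iv else None,
        )
        if gid not in genes:
            genes[gid] = []
            gene_order.append(gid)
        genes[gid].append(t)
    return [GeneModel(gid, genes[gid]) for gid in gene_order]


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "irscreen") -> None:
    """Write GeneModels back to GTF (exon features plus per-exon CDS segments)."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                    )
                    if t.has_cds:
                        s = max(e.start, t.cds_start)
                        x = min(e.end, t.cds_end)
                        if s < x:
                            fh.write(
                                f"{e.chrom}\t{source}\tCDS\t{s + 1}\t{x}\t.\t{e.strand}\t.\t{attrs}\n"
                            )


def write_introns_bed(introns: Iterable[Intron], path: str | Path) -> None:
    """BED6 intron set: name = gene_id:ordinal, score = 0."""
    with open(path, "w") as fh:
        for i in introns:
            iv = i.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{i.name}\t0\t{iv.strand}\n")


def read_introns_bed(path: str | Path) -> list[Intron]:
    """Read a BED6 intron set written by :func:`write_introns_bed`."""
    introns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            gene_id, _, ordinal = name.rpartition(":")
            introns.append(
                Intron(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    gene_id or name,
                    int(ordinal) if ordinal.isdigit() else 0,
                )
            )
    return introns
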