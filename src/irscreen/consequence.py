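"""Intron-retaining transcript construction and PTC consequence calling.

A retained intron inserts its genomic sequence between two exons of the
mRNA.  Translating the retained transcript from the annotated CDS start
usually hits a stop codon inside the intron (or downstream, after a
frameshift): a premature termination codon.  The consequence is summarised
as the number of leading residues identical to the reference protein (the
"intact" N-terminal prefix), any novel residues translated before the
stop, and the genomic origin of the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .annotation import GeneModel, Intron, Transcript, derive_introns
from .splice import _fetch, reverse_complement


@dataclass
class ConsequenceResult:
    transcript_id: str
    retained_ordinals: tuple[int, ...]
    ptc_found: bool
    intact_prefix_aa: int
    novel_aa: int
    stop_source: str  # retained_intron | downstream_exon | none


def build_retained_mrna(
    t: Transcript,
    retained: set[int] | frozenset[int],
    genome,
) -> tuple[str, int, list[tuple[int, int, str]]]:
    """Assemble the mRNA of ``t`` with the given intron ordinals retained.

    Returns the mRNA sequence (5'->3' in transcript orientation), the CDS
    start offset within it, and a block map ``(start, end, kind)`` in mRNA
    coordinates with kind "exon" or "retained_intron".
    """
    if not t.has_cds:
        raise ValueError(f"transcript {t.transcript_id} has no annotated CDS")
    introns = derive_introns(t)
    n = len(introns)
    bad = [o for o in retained if not 1 <= o <= n]
    if bad:
        raise ValueError(
            f"transcript {t.transcript_id}: retained ordinal(s) {bad} out of range 1..{n}"
        )
    by_ordinal = {i.ordinal: i for i in introns}

    minus = t.strand == "-"
    exons_t = list(reversed(t.exons)) if minus else list(t.exons)

    # blocks in transcript order: exon 1, (intron 1), exon 2, (intron 2), ...
    parts: list[tuple[object, str]] = []
    for i, exon in enumerate(exons_t):
        parts.append((exon, "exon"))
        if i + 1 in by_ordinal and i + 1 in retained:
            parts.append((by_ordinal[i + 1].interval, "retained_intron"))

    seq_parts: list[str] = []
    blocks: list[tuple[int, int, str]] = []
    gmap: list[tuple[int, int, int]] = []  # (t_start, g_start, length), transcript order
    offset = 0
    for iv, kind in parts:
        s = _fetch(genome, iv.chrom, iv.start, iv.end)
        if minus:
            s = reverse_complement(s)
        seq_parts.append(s)
        blocks.append((offset, offset + iv.length, kind))
        gmap.append((offset, iv.start, iv.length))
        offset += iv.length

    mrna = "".join(seq_parts)

    # transcript coordinate of the CDS start (genomic cds_start on '+',
    # cds_end - 1 on '-')
    g_target = t.cds_start if not minus else t.cds_end - 1
    cds_offset = None
    for (t_start, g_start, length), (iv, _kind) in zip(gmap, parts):
        if g_start <= g_target < g_start + length:
            within = g_target - g_start
            cds_offset = t_start + (length - 1 - within if minus else within)
            break
    if cds_offset is None:
        raise ValueError(
            f"transcript {t.transcript_id}: CDS start falls outside exons"
        )
    return mrna, cds_offset, blocks


def reference_protein(t: Transcript, genome) -> str:
    """Protein of the mature (no retention) transcript, translated to the
    first stop with the standard nuclear code."""
    mrna, cds_offset, _ = build_retained_mrna(t, frozenset(), genome)
    return translate_to_stop(mrna, cds_offset)


def translate_to_stop(mrna: str, cds_offset: int) -> str:
    coding = mrna[cds_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate(to_stop=True))


def find_ptc(
    mrna: str,
    cds_offset: int,
    ref_protein: str,
    blocks: list[tuple[int, int, str]] | None = None,
    transcript_id: str = "",
    retained_ordinals: tuple[int, ...] = (),
) -> ConsequenceResult:
    """Translate from ``cds_offset`` and classify the first stop codon.

    ``intact_prefix_aa`` is the longest common prefix with the reference
    protein; a stop strictly before the reference's natural end is a PTC.
    ``blocks`` (from :func:`build_retained_mrna`) locates the genomic
    origin of the stop codon's first base; without it every position is
    treated as exonic.
    """
    if not 0 <= cds_offset < len(mrna):
        raise ValueError("cds_offset out of range")
    coding = mrna[cds_offset:]
    n_codons = len(coding) // 3
    translated = []
    stop_codon_index = None
    for k in range(n_codons):
        aa = str(Seq(coding[3 * k : 3 * k + 3]).translate())
        if aa == "*":
            stop_codon_index = k
            break
        translated.append(aa)
    protein = "".join(translated)

    intact = 0
    for a, b in zip(protein, ref_protein):
        if a != b:
            break
        intact += 1
    novel = len(protein) - intact

    if stop_codon_index is None:
        return ConsequenceResult(
            transcript_id, tuple(retained_ordinals), False, intact, novel, "none"
        )

    ptc_found = stop_codon_index < len(ref_protein)
    stop_pos = cds_offset + 3 * stop_codon_index
    source = "downstream_exon"
    if blocks is not None:
        for b_start, b_end, kind in blocks:
            if b_start <= stop_pos < b_end:
                source = "retained_intron" if kind == "retained_intron" else "downstream_exon"
                break
    return ConsequenceResult(
        transcript_id, tuple(retained_ordinals), ptc_found, intact, novel, source
    )


def consequence_for_intron(gene: GeneModel, intron: Intron, genome) -> ConsequenceResult | None:
    """Consequence of retaining one collapsed intron in its gene.

    Uses the first transcript of the gene whose derived introns contain the
    interval; returns None when no CDS-bearing transcript carries it.
    """
    for t in gene.transcripts:
        if not t.has_cds:
            continue
        for cand in derive_introns(t):
            if cand.interval == intron.interval:
                mrna, off, blocks = build_retained_mrna(t, {cand.ordinal}, genome)
                ref = reference_protein(t, genome)
                return find_ptc(
                    mrna,
                    off,
                    ref,
                    blocks,
                    transcript_id=t.transcript_id,
                    retained_ordinals=(cand.ordinal,),
                )
    return None
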