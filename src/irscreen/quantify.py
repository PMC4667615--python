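"""Fragment counting and FPKM / intronic-FPKM / IR-value quantification.

Counting follows interval-intersection semantics (``intersectBed -c``): a
fragment counts for an interval if it overlaps it by at least one base;
a fragment overlapping several intervals increments each of them.  The
unit throughout is the *fragment* (one BED record per sequenced fragment,
or one properly paired read pair), matching the FPKM denominator
"per million mapped fragments".

Gene expression is union-exon FPKM: fragments overlapping the merged exon
union of a gene, normalised by the union's length.  The IR value of an
intron in a sample is intronic FPKM divided by the gene's FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, Intron

GENOTYPES = ("WT", "KO")
STIMULATIONS = ("none", "RANKL")


@dataclass(frozen=True)
class SampleInfo:
    """One RNA-seq sample in the two-factor (genotype x stimulation) design."""

    sample_id: str
    genotype: str
    stimulation: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.stimulation not in STIMULATIONS:
            raise ValueError(f"stimulation must be one of {STIMULATIONS}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


class _ChromIndex:
    """Sorted fragment coordinates for one chromosome (and optional strand)."""

    __slots__ = ("starts", "ends", "starts_sorted", "ends_sorted", "max_len")

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]          # sorted by start
        self.ends = ends[order]              # aligned with starts
        self.starts_sorted = self.starts     # alias, already sorted
        self.ends_sorted = np.sort(ends)
        self.max_len = int((ends - starts).max()) if len(starts) else 0


class FragmentSet:
    """One sample's aligned fragments as genomic intervals.

    ``total_mapped`` defaults to the number of loaded fragments; it may be
    overridden (e.g. from a design table) when the file holds only a subset
    of the mapped fragments.
    """

    def __init__(
        self,
        sample: SampleInfo,
        chrom_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_mapped: int | None = None,
    ):
        # chrom_arrays: chrom -> (starts, ends, strands) with strands as
        # int8 (+1 / -1); arrays need not be sorted.
        self.sample = sample
        self._by_chrom: dict[str, _ChromIndex] = {}
        self._by_chrom_strand: dict[tuple[str, str], _ChromIndex] = {}
        n = 0
        for chrom, (starts, ends, strands) in chrom_arrays.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            strands = np.asarray(strands, dtype=np.int8)
            if np.any(ends <= starts):
                raise ValueError(f"fragment with end <= start on {chrom}")
            n += len(starts)
            self._by_chrom[chrom] = _ChromIndex(starts, ends)
            for sym, code in (("+", 1), ("-", -1)):
                m = strands == code
                if m.any():
                    self._by_chrom_strand[(chrom, sym)] = _ChromIndex(
                        starts[m], ends[m]
                    )
        self.n_fragments = n
        if total_mapped is None:
            total_mapped = n
        if total_mapped < n:
            raise ValueError("total_mapped cannot be below the number of loaded fragments")
        self.total_mapped = int(total_mapped)

    @classmethod
    def from_bed(
        cls, path: str | Path, sample: SampleInfo, total_mapped: int | None = None
    ) -> "FragmentSet":
        """Load fragments from BED6 (one record per fragment)."""
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                usecols=[0, 1, 2, 5],
                names=["chrom", "start", "end", "strand"],
                dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
            )
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        arrays = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            strands = np.where(sub["strand"].to_numpy() == "-", -1, 1).astype(np.int8)
            arrays[str(chrom)] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                strands,
            )
        return cls(sample, arrays, total_mapped=total_mapped)

    @classmethod
    def from_bam(
        cls, path: str | Path, sample: SampleInfo, total_mapped: int | None = None
    ) -> "FragmentSet":
        """Adapter: proper read pairs collapsed to outer-coordinate fragments.

        Each properly paired alignment is counted once (via read1, template
        length > 0); unpaired primary alignments contribute their own span.
        """
        import pysam  # deferred: only needed for BAM input

        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        with pysam.AlignmentFile(str(path), "rb") as bam:
            for read in bam.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.is_proper_pair:
                    if read.template_length <= 0:
                        continue
                    start = read.reference_start
                    end = start + read.template_length
                elif read.is_paired:
                    continue
                else:
                    start, end = read.reference_start, read.reference_end
                strand = -1 if read.is_reverse else 1
                per_chrom.setdefault(read.reference_name, []).append((start, end, strand))
        arrays = {
            chrom: (
                np.array([r[0] for r in recs], dtype=np.int64),
                np.array([r[1] for r in recs], dtype=np.int64),
                np.array([r[2] for r in recs], dtype=np.int8),
            )
            for chrom, recs in per_chrom.items()
        }
        return cls(sample, arrays, total_mapped=total_mapped)

    def _index(self, chrom: str, strand: str | None) -> _ChromIndex | None:
        if strand is None:
            return self._by_chrom.get(chrom)
        return self._by_chrom_strand.get((chrom, strand))


def count_overlaps(
    intervals: Sequence[GenomicInterval],
    frags: FragmentSet,
    respect_strand: bool = False,
) -> np.ndarray:
    """Number of fragments overlapping each interval by >= 1 bp.

    Strand is ignored unless ``respect_strand``; intervals on chromosomes
    absent from the fragment set count 0.
    """
    out = np.zeros(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        idx = frags._index(iv.chrom, iv.strand if respect_strand else None)
        if idx is None:
            continue
        n_start_before_end = np.searchsorted(idx.starts_sorted, iv.end, side="left")
        n_end_before_start = np.searchsorted(idx.ends_sorted, iv.start, side="right")
        out[i] = n_start_before_end - n_end_before_start
    return out


def count_union_overlaps(
    union: Sequence[GenomicInterval],
    frags: FragmentSet,
    respect_strand: bool = False,
) -> int:
    """Number of distinct fragments overlapping a disjoint sorted interval union.

    Used for gene-level counting over the merged exon union: a fragment
    spanning two exons of the same gene is counted once.
    """
    if not union:
        return 0
    chrom = union[0].chrom
    idx = frags._index(chrom, union[0].strand if respect_strand else None)
    if idx is None:
        return 0
    u_starts = np.array([u.start for u in union], dtype=np.int64)
    u_ends = np.array([u.end for u in union], dtype=np.int64)
    span_start, span_end = int(u_starts[0]), int(u_ends[-1])
    # candidate fragments: start in [span_start - max_len, span_end)
    lo = np.searchsorted(idx.starts, span_start - idx.max_len, side="left")
    hi = np.searchsorted(idx.starts, span_end, side="left")
    fs = idx.starts[lo:hi]
    fe = idx.ends[lo:hi]
    # fragment overlaps the union iff the last union block starting before
    # its end also ends after its start (blocks are disjoint and sorted)
    j = np.searchsorted(u_starts, fe, side="left") - 1
    valid = j >= 0
    hit = np.zeros(len(fs), dtype=bool)
    hit[valid] = u_ends[j[valid]] > fs[valid]
    return int(hit.sum())


def fpkm(count, length, total_mapped):
    """Fragments per kilobase per million mapped fragments.

    fpkm = count * 1e9 / (length * total_mapped); accepts scalars or arrays
    for ``count``.
    """
    length = np.asarray(length, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length must be > 0")
    if np.any(total <= 0):
        raise ValueError("total_mapped must be > 0")
    result = np.asarray(count, dtype=float) * 1e9 / (length * total)
    return result if result.ndim else float(result)


def ir_value(intronic_fpkm: float, gene_fpkm: float) -> float:
    """IR value: intronic FPKM / gene FPKM; NaN (undefined) when gene FPKM is 0."""
    if intronic_fpkm < 0 or gene_fpkm < 0:
        raise ValueError("FPKM values must be non-negative")
    if gene_fpkm == 0:
        return float("nan")
    return intronic_fpkm / gene_fpkm


def gene_fpkm_matrix(
    genes: Sequence[GeneModel],
    samples: Sequence[FragmentSet],
    respect_strand: bool = False,
) -> pd.DataFrame:
    """Union-exon gene FPKM matrix (rows: gene_id, columns: sample_id)."""
    if not genes or not samples:
        raise ValueError("need at least one gene and one sample")
    gene_ids = [g.gene_id for g in genes]
    lengths = np.array([g.union_exonic_length for g in genes], dtype=float)
    if np.any(lengths <= 0):
        bad = gene_ids[int(np.argmin(lengths))]
        raise ValueError(f"gene {bad} has zero union exonic length")
    unions = [g.exon_union() for g in genes]
    data = {}
    for fs in samples:
        counts = np.array(
            [count_union_overlaps(u, fs, respect_strand) for u in unions],
            dtype=np.int64,
        )
        data[fs.sample.sample_id] = fpkm(counts, lengths, fs.total_mapped)
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


@dataclass
class IntronQuantResult:
    """Per-intron per-sample quantification.

    ``introns`` carries one metadata row per intron (indexed by intron key);
    ``counts``, ``intronic_fpkm`` and ``ir`` are wide matrices with sample
    columns; ``ir`` is NaN where the gene's FPKM is zero.
    """

    introns: pd.DataFrame
    counts: pd.DataFrame
    intronic_fpkm: pd.DataFrame
    ir: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for sample_id in self.counts.columns:
            df = self.introns.copy()
            df["sample_id"] = sample_id
            df["count"] = self.counts[sample_id].to_numpy()
            df["intronic_fpkm"] = self.intronic_fpkm[sample_id].to_numpy()
            df["ir_value"] = self.ir[sample_id].to_numpy()
            rows.append(df.reset_index())
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "IntronQuantResult":
        meta_cols = ["intron", "gene_id", "ordinal", "chrom", "start", "end", "strand", "length"]
        meta = df[meta_cols].drop_duplicates("intron").set_index("intron")
        counts = df.pivot(index="intron", columns="sample_id", values="count").loc[meta.index]
        ifpkm = df.pivot(index="intron", columns="sample_id", values="intronic_fpkm").loc[meta.index]
        ir = df.pivot(index="intron", columns="sample_id", values="ir_value").loc[meta.index]
        counts.columns.name = ifpkm.columns.name = ir.columns.name = None
        return cls(meta, counts, ifpkm, ir)


def quantify_introns(
    introns: Sequence[Intron],
    samples: Sequence[FragmentSet],
    gene_fpkm: pd.DataFrame,
    respect_strand: bool = False,
) -> IntronQuantResult:
    """Count fragments per intron and derive intronic FPKM and IR values."""
    keys = [i.key for i in introns]
    meta = pd.DataFrame(
        {
            "gene_id": [i.gene_id for i in introns],
            "ordinal": [i.ordinal for i in introns],
            "chrom": [i.interval.chrom for i in introns],
            "start": [i.interval.start for i in introns],
            "end": [i.interval.end for i in introns],
            "strand": [i.interval.strand for i in introns],
            "length": [i.interval.length for i in introns],
        },
        index=pd.Index(keys, name="intron"),
    )
    lengths = meta["length"].to_numpy(float)
    intervals = [i.interval for i in introns]
    counts = {}
    ifpkm = {}
    ir = {}
    for fs in samples:
        c = count_overlaps(intervals, fs, respect_strand)
        f = fpkm(c, lengths, fs.total_mapped)
        g = gene_fpkm.loc[meta["gene_id"], fs.sample.sample_id].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(g > 0, f / np.where(g > 0, g, 1.0), np.nan)
        sid = fs.sample.sample_id
        counts[sid], ifpkm[sid], ir[sid] = c, f, r
    return IntronQuantResult(
        introns=meta,
        counts=pd.DataFrame(counts, index=meta.index),
        intronic_fpkm=pd.DataFrame(ifpkm, index=meta.index),
        ir=pd.DataFrame(ir, index=meta.index),
    )


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design table (TSV).

    Required columns: sample_id, genotype, stimulation, replicate; optional:
    fragment_path, total_mapped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "genotype", "stimulation", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    seen = set()
    for _, row in df.iterrows():
        key = (row["genotype"], row["stimulation"], int(row["replicate"]))
        if key in seen:
            raise ValueError(f"duplicate design entry {key}")
        seen.add(key)
    return df


def design_samples(df: pd.DataFrame) -> list[SampleInfo]:
    return [
        SampleInfo(str(r["sample_id"]), str(r["genotype"]), str(r["stimulation"]), int(r["replicate"]))
        for _, r in df.iterrows()
    ]


def load_fragments(design: pd.DataFrame, base_dir: str | Path | None = None) -> list[FragmentSet]:
    """Load one FragmentSet per design row from BED (``fragment_path`` column)."""
    if "fragment_path" not in design.columns:
        raise ValueError("design table has no fragment_path column")
    out = []
    for sample, (_, row) in zip(design_samples(design), design.iterrows()):
        p = Path(row["fragment_path"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        total = row.get("total_mapped")
        total = int(total) if pd.notna(total) else None
        out.append(FragmentSet.from_bed(p, sample, total_mapped=total))
    return out
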