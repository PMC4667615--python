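"""Synthetic genome, annotation and RNA-seq fragment simulator.

The simulator emulates the study design the pipeline targets: six samples
(WT and KO fetal thymic stroma, one unstimulated sample per genotype and
two RANKL-stimulated replicates per genotype), paired-end fragments
represented by their outer genomic span (~300 bp for a 101-bp paired-end
library), a subset of stimulation-induced genes, and KO-specific
retention concentrated in introns with weak (GAG-at-PPT) acceptors.

Every intron carries a planted acceptor 15-mer: "strong" introns end in a
pyrimidine-rich ...TTTCAG context, "weak" introns in ...GAGCAG (GAG in
place of the polypyrimidine tract, the hallmark of the retention-prone
acceptor).  Retention is modelled at the molecule level: a fraction rho
of a gene's transcripts retain one given intron (single-intron isoforms
by default), and fragments are allocated to isoforms in proportion to
molar fraction times isoform length, so the expected measured IR value
equals rho up to the junction-fragment edge term.

All randomness flows from ``SimConfig.seed``; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, Transcript, write_gtf
from .quantify import FragmentSet, SampleInfo

_SENSE_CODONS = [
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the emulated study conditions."""

    seed: int
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (150, 450)
    intron_length: tuple[int, int] = (1500, 8000)
    frac_induced: float = 0.3
    induction_fold: float = 8.0
    frac_weak: float = 0.10
    rho_wt: float = 0.05
    rho_ko_weak: float = 0.25
    rho_ko_strong: float = 0.05
    depth: int = 1_000_000
    fragment_length: int = 300          # outer span of a 101-bp read pair
    multi_intron: bool = False
    overdispersion: float | None = None
    intergenic: int = 500
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        for name in ("frac_induced", "frac_weak", "rho_wt", "rho_ko_weak", "rho_ko_strong"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("exon_length", "intron_length", "exons_per_gene"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"infeasible range for {name}: ({lo}, {hi})")
        if self.intron_length[0] < 20:
            raise ValueError("intron length must be >= 20 bp for acceptor extraction")
        if self.exons_per_gene[0] < 1:
            raise ValueError("genes need at least one exon")
        if self.n_genes < 1 or self.depth < 0 or self.fragment_length < 1:
            raise ValueError("n_genes, depth and fragment_length must be sensible")


def default_design() -> list[SampleInfo]:
    """The six-sample two-factor design."""
    return [
        SampleInfo("WT_none_1", "WT", "none", 1),
        SampleInfo("KO_none_1", "KO", "none", 1),
        SampleInfo("WT_RANKL_1", "WT", "RANKL", 1),
        SampleInfo("WT_RANKL_2", "WT", "RANKL", 2),
        SampleInfo("KO_RANKL_1", "KO", "RANKL", 1),
        SampleInfo("KO_RANKL_2", "KO", "RANKL", 2),
    ]


@dataclass
class _GeneSim:
    """Internal per-gene layout in transcript order (genomic coordinates)."""

    gene_id: str
    chrom: str
    strand: str
    exons_t: list[tuple[int, int]]      # transcript-order genomic blocks
    introns_t: list[tuple[int, int]]
    intron_keys: list[str]
    exon_total: int
    intron_lens: list[int]


@dataclass
class Simulation:
    """Genome, annotation and ground truth produced by :func:`make_genome`."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth_genes: pd.DataFrame
    truth_introns: pd.DataFrame
    _layout: list[_GeneSim] = field(repr=False, default_factory=list)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _acceptor14(rng: np.random.Generator, weak: bool) -> str:
    """Planted 14 intronic acceptor bases: PPT + (TTT | GAG) + CAG.

    The polypyrimidine tract is T-rich with at most two C substitutions,
    which keeps the two acceptor classes separated: under the default
    scoring matrix every strong (TTT-core) acceptor outscores every
    GAG-core acceptor regardless of the sampled tract and exonic base.
    """
    ppt = ["T"] * 6
    n_c = int(rng.choice([0, 1, 2], p=[0.5, 0.3, 0.2]))
    for pos in rng.choice(6, size=n_c, replace=False):
        ppt[pos] = "C"
    core = "GAG" if weak else "TTT"
    return "".join(ppt) + "TT" + core + "CAG"


def make_genome(cfg: SimConfig) -> Simulation:
    """Build a genome FASTA-equivalent, gene models and ground truth.

    Each gene is a single-transcript protein-coding model whose CDS spans
    all exons (ATG ... single natural stop); intron acceptors are planted
    verbatim, so extracting the last 14 intronic bases plus the first
    exonic base recovers the recorded 15-mer exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    chrom_parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    layout: list[_GeneSim] = []
    gene_rows = []
    intron_rows = []

    for gi in range(cfg.n_genes):
        gene_id = f"g{gi:04d}"
        spacer = _random_seq(rng, cfg.intergenic)
        chrom_parts.append(spacer)
        cursor += cfg.intergenic

        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, n_ex)
        exon_lens[-1] += (3 - int(exon_lens.sum()) % 3) % 3
        total_cds = int(exon_lens.sum())

        codons = ["ATG"] + [
            _SENSE_CODONS[k] for k in rng.integers(0, len(_SENSE_CODONS), total_cds // 3 - 2)
        ] + ["TAA"]
        cds = "".join(codons)
        protein = cds_to_protein(cds)

        exon_seqs = []
        off = 0
        for L in exon_lens:
            exon_seqs.append(cds[off : off + int(L)])
            off += int(L)

        intron_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, n_ex - 1)
        weak_flags = rng.random(n_ex - 1) < cfg.frac_weak
        if not cfg.multi_intron:
            # single-intron isoform mode: the per-gene molar retention
            # fractions must sum to <= 1, so demote surplus weak introns
            def _ko_sum(flags):
                return float(
                    np.where(flags, cfg.rho_ko_weak, cfg.rho_ko_strong).sum()
                )
            while _ko_sum(weak_flags) > 1.0 and weak_flags.any():
                weak_flags[np.nonzero(weak_flags)[0][-1]] = False
        intron_seqs = []
        acceptors = []
        for j, L in enumerate(intron_lens):
            body = _random_seq(rng, int(L))
            acc = _acceptor14(rng, bool(weak_flags[j]))
            seq = "GT" + body[2 : int(L) - 14] + acc
            intron_seqs.append(seq)
            acceptors.append(acc + exon_seqs[j + 1][0])

        # transcript-oriented pre-mRNA, then place on the chromosome
        blocks: list[tuple[str, str]] = []
        for i in range(n_ex):
            blocks.append((exon_seqs[i], "exon"))
            if i < n_ex - 1:
                blocks.append((intron_seqs[i], "intron"))
        pre = "".join(s for s, _ in blocks)
        locus_len = len(pre)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom_parts.append(pre if strand == "+" else _revcomp(pre))

        exons_t: list[tuple[int, int]] = []
        introns_t: list[tuple[int, int]] = []
        off = 0
        for s, kind in blocks:
            if strand == "+":
                g = (cursor + off, cursor + off + len(s))
            else:
                g = (cursor + locus_len - off - len(s), cursor + locus_len - off)
            (exons_t if kind == "exon" else introns_t).append(g)
            off += len(s)
        cursor += locus_len

        exon_ivs = [GenomicInterval(cfg.chrom, s, e, strand) for s, e in exons_t]
        t = Transcript(
            transcript_id=f"{gene_id}.t1",
            gene_id=gene_id,
            exons=exon_ivs,
            cds_start=min(s for s, _ in exons_t),
            cds_end=max(e for _, e in exons_t),
        )
        genes.append(GeneModel(gene_id, [t]))

        intron_keys = [
            f"{cfg.chrom}:{s}-{e}({strand})" for s, e in introns_t
        ]
        layout.append(
            _GeneSim(
                gene_id,
                cfg.chrom,
                strand,
                exons_t,
                introns_t,
                intron_keys,
                total_cds,
                [int(L) for L in intron_lens],
            )
        )

        base_expr = float(rng.lognormal(0.0, 0.6))
        induced = bool(rng.random() < cfg.frac_induced)
        gene_rows.append(
            {
                "gene_id": gene_id,
                "base_expr": base_expr,
                "induced": induced,
                "protein": protein,
                "strand": strand,
            }
        )
        for j, key in enumerate(intron_keys):
            weak = bool(weak_flags[j])
            intron_rows.append(
                {
                    "intron": key,
                    "gene_id": gene_id,
                    "ordinal": j + 1,
                    "acceptor_class": "weak" if weak else "strong",
                    "acceptor": acceptors[j],
                    "rho_wt": cfg.rho_wt,
                    "rho_ko": cfg.rho_ko_weak if weak else cfg.rho_ko_strong,
                }
            )

    chrom_parts.append(_random_seq(rng, cfg.intergenic))
    genome = {cfg.chrom: "".join(chrom_parts)}
    return Simulation(
        config=cfg,
        genome=genome,
        genes=genes,
        truth_genes=pd.DataFrame(gene_rows).set_index("gene_id"),
        truth_introns=pd.DataFrame(intron_rows).set_index("intron"),
        _layout=layout,
    )


def cds_to_protein(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate(to_stop=True))


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _isoform_blocks(g: _GeneSim, retained: int | None):
    """Block arrays (transcript-coordinate starts, genomic starts/ends) for
    the mature isoform or the isoform retaining intron ``retained`` (0-based)."""
    blocks: list[tuple[int, int]] = []
    for i, exon in enumerate(g.exons_t):
        blocks.append(exon)
        if retained is not None and i == retained:
            blocks.append(g.introns_t[i])
    lens = np.array([e - s for s, e in blocks], dtype=np.int64)
    t_starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    g_starts = np.array([s for s, _ in blocks], dtype=np.int64)
    g_ends = np.array([e for _, e in blocks], dtype=np.int64)
    return t_starts, g_starts, g_ends, int(lens.sum())


def _project_outer(
    t_starts: np.ndarray,
    g_starts: np.ndarray,
    g_ends: np.ndarray,
    strand: str,
    pos: np.ndarray,
) -> np.ndarray:
    b = np.searchsorted(t_starts, pos, side="right") - 1
    off = pos - t_starts[b]
    if strand == "+":
        return g_starts[b] + off
    return g_ends[b] - 1 - off


def simulate_fragments(
    sim: Simulation,
    design: list[SampleInfo] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[FragmentSet], pd.DataFrame]:
    """Draw per-sample fragments and return FragmentSets plus realized
    per-gene fragment counts.

    Per gene and sample the fragment count is Poisson with mean
    depth x relative expression (induction fold applied to induced genes
    in stimulated samples; optional gamma overdispersion).  Fragments are
    projected to their outer genomic span and, when ``out_dir`` is given,
    written as one BED6 record each.
    """
    cfg = sim.config
    design = design if design is not None else default_design()
    if not any(s.stimulation == "RANKL" and s.genotype == "WT" for s in design) or not any(
        s.stimulation == "RANKL" and s.genotype == "KO" for s in design
    ):
        raise ValueError("design must include a stimulated sample of each genotype")

    base = sim.truth_genes["base_expr"].to_numpy(float)
    induced = sim.truth_genes["induced"].to_numpy(bool)
    rho_by_key = {
        "WT": sim.truth_introns["rho_wt"].to_dict(),
        "KO": sim.truth_introns["rho_ko"].to_dict(),
    }

    fragsets: list[FragmentSet] = []
    count_rows = {}
    for si, sample in enumerate(design):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1, si]))
        w = base.copy()
        if sample.stimulation == "RANKL":
            w[induced] *= cfg.induction_fold
        lam = cfg.depth * w / w.sum() if cfg.depth > 0 else np.zeros_like(w)
        if cfg.overdispersion:
            shape = 1.0 / cfg.overdispersion
            lam = rng.gamma(shape, lam * cfg.overdispersion)
        n_per_gene = rng.poisson(lam)
        count_rows[sample.sample_id] = n_per_gene

        starts_all: list[np.ndarray] = []
        ends_all: list[np.ndarray] = []
        strands_all: list[np.ndarray] = []
        for g, n in zip(sim._layout, n_per_gene):
            if n == 0:
                continue
            rhos = np.array([rho_by_key[sample.genotype][k] for k in g.intron_keys])
            if rhos.sum() > 1.0 + 1e-9 and not cfg.multi_intron:
                raise ValueError(
                    f"gene {g.gene_id}: per-intron retention fractions sum to "
                    f"{rhos.sum():.3f} > 1 (single-intron isoform mode)"
                )
            if cfg.multi_intron:
                iso_counts = _multi_intron_counts(rng, n, rhos)
            else:
                iso_lens = np.array(
                    [g.exon_total] + [g.exon_total + L for L in g.intron_lens], dtype=float
                )
                molar = np.concatenate([[1.0 - rhos.sum()], rhos])
                weights = molar * iso_lens
                iso_counts = [
                    (None if k == 0 else frozenset([k - 1]), int(c))
                    for k, c in enumerate(rng.multinomial(n, weights / weights.sum()))
                ]
            for retained_set, c in iso_counts:
                if c == 0:
                    continue
                if retained_set is None or len(retained_set) == 0:
                    t_starts, g_s, g_e, L = _isoform_blocks(g, None)
                elif len(retained_set) == 1:
                    t_starts, g_s, g_e, L = _isoform_blocks(g, next(iter(retained_set)))
                else:
                    t_starts, g_s, g_e, L = _multi_blocks(g, retained_set)
                flen = min(cfg.fragment_length, L)
                pos = rng.integers(0, L - flen + 1, c)
                a = _project_outer(t_starts, g_s, g_e, g.strand, pos)
                b = _project_outer(t_starts, g_s, g_e, g.strand, pos + flen - 1)
                starts_all.append(np.minimum(a, b))
                ends_all.append(np.maximum(a, b) + 1)
                strands_all.append(
                    np.full(c, 1 if g.strand == "+" else -1, dtype=np.int8)
                )

        if starts_all:
            starts = np.concatenate(starts_all)
            ends = np.concatenate(ends_all)
            strands = np.concatenate(strands_all)
        else:
            starts = np.empty(0, dtype=np.int64)
            ends = np.empty(0, dtype=np.int64)
            strands = np.empty(0, dtype=np.int8)

        if out_dir is not None:
            _write_bed(Path(out_dir) / f"{sample.sample_id}.bed", cfg.chrom, starts, ends,
                       strands, sample.sample_id)
        arrays = {cfg.chrom: (starts, ends, strands)} if len(starts) else {}
        fragsets.append(FragmentSet(sample, arrays, total_mapped=len(starts) or None))

    realized = pd.DataFrame(count_rows, index=sim.truth_genes.index)
    return fragsets, realized


def _multi_intron_counts(rng, n, rhos):
    """Independent per-intron retention (no length weighting): group
    fragments by retention mask."""
    masks = rng.random((n, len(rhos))) < rhos
    out: dict[frozenset, int] = {}
    for row in masks:
        key = frozenset(np.nonzero(row)[0].tolist())
        out[key] = out.get(key, 0) + 1
    return list(out.items())


def _multi_blocks(g: _GeneSim, retained: frozenset):
    blocks: list[tuple[int, int]] = []
    for i, exon in enumerate(g.exons_t):
        blocks.append(exon)
        if i in retained:
            blocks.append(g.introns_t[i])
    lens = np.array([e - s for s, e in blocks], dtype=np.int64)
    t_starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    return (
        t_starts,
        np.array([s for s, _ in blocks], dtype=np.int64),
        np.array([e for _, e in blocks], dtype=np.int64),
        int(lens.sum()),
    )


def _write_bed(path, chrom, starts, ends, strands, sample_id):
    with open(path, "w") as fh:
        for i, (s, e, st) in enumerate(zip(starts, ends, strands)):
            sym = "+" if st > 0 else "-"
            fh.write(f"{chrom}\t{s}\t{e}\t{sample_id}_{i}\t0\t{sym}\n")


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_simulation(
    sim: Simulation,
    out_dir: str | Path,
    design: list[SampleInfo] | None = None,
) -> dict[str, Path]:
    """Write genome.fa, annotation.gtf, design.tsv, per-sample BEDs and the
    truth tables; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = design if design is not None else default_design()
    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "annotation.gtf",
        "design": out / "design.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "truth_introns": out / "truth_introns.tsv",
    }
    write_fasta(sim.genome, paths["genome"])
    write_gtf(sim.genes, paths["annotation"])
    sim.truth_genes.to_csv(paths["truth_genes"], sep="\t")
    sim.truth_introns.to_csv(paths["truth_introns"], sep="\t")
    fragsets, realized = simulate_fragments(sim, design, out_dir=out)
    realized.to_csv(out / "truth_counts.tsv", sep="\t")
    rows = []
    for s, fs in zip(design, fragsets):
        rows.append(
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "stimulation": s.stimulation,
                "replicate": s.replicate,
                "fragment_path": f"{s.sample_id}.bed",
                "total_mapped": fs.total_mapped,
            }
        )
    pd.DataFrame(rows).to_csv(paths["design"], sep="\t", index=False)
    return paths
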