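"""End-to-end driver chaining simulation, quantification, screening,
acceptor scoring, association and consequence calling."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import collapse_introns, parse_gtf, write_introns_bed
from .consequence import consequence_for_intron
from .quantify import (
    FragmentSet,
    design_samples,
    gene_fpkm_matrix,
    load_fragments,
    quantify_introns,
    read_design,
)
from .screen import ScreenThresholds, screen_retained_introns
from .simulate import SimConfig, default_design, make_genome, write_simulation
from .splice import AcceptorMatrix, retention_association, score_all

log = logging.getLogger("irscreen")

FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline run configuration (flat key=value file, CLI flags win)."""

    out_dir: Path
    annotation: Path | None = None
    genome: Path | None = None
    design: Path | None = None
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    matrix: Path | None = None          # acceptor matrix TSV, or None for default
    respect_strand: bool = False
    simulate: SimConfig | None = None   # when set, inputs are generated first
    seed: int | None = None

    def digest(self) -> str:
        raw = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(raw.encode()).hexdigest()[:12]


def _load_genome(path: Path):
    import pyfaidx

    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; writes the report bundle into ``cfg.out_dir``.

    Outputs: gene_fpkm.tsv, intron_quant.tsv, retention_calls.tsv,
    selected_introns.bed, splice_scores.tsv, association.tsv,
    consequence.tsv, plus a funnel summary in the log.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("irscreen %s | config %s | seed %s", __version__, cfg.digest(), cfg.seed)

    stage = "simulate"
    try:
        if cfg.simulate is not None:
            sim_cfg = cfg.simulate
            if cfg.seed is not None:
                sim_cfg = SimConfig(**{**sim_cfg.__dict__, "seed": cfg.seed})
            sim = make_genome(sim_cfg)
            write_simulation(sim, out / "sim")
            cfg.annotation = out / "sim" / "annotation.gtf"
            cfg.genome = out / "sim" / "genome.fa"
            cfg.design = out / "sim" / "design.tsv"
            log.info("simulated %d genes into %s", sim_cfg.n_genes, out / "sim")
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError(stage, exc) from exc

    stage = "annotation_model"
    try:
        genes = parse_gtf(cfg.annotation)
        introns = collapse_introns(genes)
        gene_by_id = {g.gene_id: g for g in genes}
        log.info("parsed %d genes, %d unique introns", len(genes), len(introns))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "quantify"
    try:
        design_df = read_design(cfg.design)
        design = design_samples(design_df)
        samples = load_fragments(design_df, base_dir=Path(cfg.design).parent)
        fpkm_m = gene_fpkm_matrix(genes, samples, cfg.respect_strand)
        quant = quantify_introns(introns, samples, fpkm_m, cfg.respect_strand)
        fpkm_m.to_csv(out / "gene_fpkm.tsv", sep="\t", float_format=FLOAT_FMT)
        quant.to_long().to_csv(
            out / "intron_quant.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "retention_screen"
    try:
        calls, funnel = screen_retained_introns(quant, fpkm_m, design, cfg.thresholds)
        calls.to_csv(out / "retention_calls.tsv", sep="\t", float_format=FLOAT_FMT)
        selected_keys = list(calls.index[calls["selected"]])
        selected = [i for i in introns if i.key in set(selected_keys)]
        write_introns_bed(selected, out / "selected_introns.bed")
        log.info(
            "funnel: %d introns -> %d gene-FPKM pass -> %d intronic-FPKM pass -> %d selected",
            funnel["introns_total"],
            funnel["pass_gene_fpkm"],
            funnel["pass_intronic_fpkm"],
            funnel["selected"],
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "splice_site"
    try:
        genome = _load_genome(cfg.genome)
        matrix = AcceptorMatrix.from_tsv(cfg.matrix) if cfg.matrix else AcceptorMatrix.default()
        scores = score_all(genome, introns, matrix)
        scores.to_csv(out / "splice_scores.tsv", sep="\t", float_format=FLOAT_FMT)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "association"
    assoc: dict | None = None
    try:
        if selected_keys and len(selected_keys) < scores["score"].notna().sum():
            assoc = retention_association(scores, selected_keys)
            bins = assoc["bins"].copy()
            bins.to_csv(out / "association.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
            log.info(
                "retention vs acceptor score: one-sided rank-sum p = %.3g "
                "(%d retained vs %d unretained)",
                assoc["rank_sum_p"], assoc["n_retained"], assoc["n_unretained"],
            )
        else:
            pd.DataFrame(
                columns=["bin_low", "bin_high", "n", "n_retained", "retained_fraction"]
            ).to_csv(out / "association.tsv", sep="\t", index=False)
            log.info("association skipped: no selected introns")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "consequence"
    try:
        rows = []
        for intron in selected:
            res = consequence_for_intron(gene_by_id[intron.gene_id], intron, genome)
            if res is None:
                continue
            rows.append(
                {
                    "intron": intron.key,
                    "gene_id": intron.gene_id,
                    "transcript_id": res.transcript_id,
                    "retained_ordinals": ",".join(map(str, res.retained_ordinals)),
                    "ptc_found": res.ptc_found,
                    "intact_prefix_aa": res.intact_prefix_aa,
                    "novel_aa": res.novel_aa,
                    "stop_source": res.stop_source,
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "intron", "gene_id", "transcript_id", "retained_ordinals",
                "ptc_found", "intact_prefix_aa", "novel_aa", "stop_source",
            ],
        ).to_csv(out / "consequence.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return {
        "funnel": funnel,
        "selected": selected_keys,
        "association_p": assoc["rank_sum_p"] if assoc else None,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
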