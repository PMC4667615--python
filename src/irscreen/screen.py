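"""Differential-expression filters and the retained-intron selection cascade.

The screen reproduces a three-step funnel over the intron universe:

1. keep introns of genes whose maximum FPKM across samples exceeds
   ``gene_fpkm_min`` (default 10);
2. keep introns whose intronic FPKM exceeds ``intronic_fpkm_min``
   (default 10) in at least one sample;
3. compute each genotype's mean IR value over the RANKL-stimulated
   replicates, with the pseudocount added to both FPKM terms of each IR,
   and select introns with KO/WT IR ratio strictly above ``ir_ratio_min``
   (default 1.5).

All inequalities are strict ("more than").  Gene-level differential
expression uses the max/min FPKM ratio with a 0.1 pseudocount and a
condition-association test at alpha = 0.05; no multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import IntronQuantResult, SampleInfo


@dataclass
class ScreenThresholds:
    """Filter thresholds; defaults are the screen's reference values."""

    pseudocount: float = 0.1       # FPKM units, guards divisions by zero
    de_ratio: float = 3.0          # max/min FPKM ratio for differential expression
    alpha: float = 0.05            # association test level
    gene_fpkm_min: float = 10.0    # gene max-FPKM filter
    intronic_fpkm_min: float = 10.0
    ir_ratio_min: float = 1.5      # KO/WT IR ratio

    def __post_init__(self) -> None:
        for name in ("pseudocount", "de_ratio", "alpha", "gene_fpkm_min",
                     "intronic_fpkm_min", "ir_ratio_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "ScreenThresholds":
        """Flat key=value file; unknown keys rejected."""
        kwargs = {}
        fields = set(cls.__dataclass_fields__)
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in fields:
                    raise ValueError(f"unknown threshold {key!r}")
                kwargs[key] = float(value)
        return cls(**kwargs)


def de_ratio_filter(m: pd.DataFrame, th: ScreenThresholds) -> list[str]:
    """Genes whose pseudocounted max/min FPKM ratio strictly exceeds de_ratio."""
    if m.shape[1] < 2:
        raise ValueError("need at least two samples")
    vmax = m.max(axis=1) + th.pseudocount
    vmin = m.min(axis=1) + th.pseudocount
    return list(m.index[(vmax / vmin) > th.de_ratio])


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value with degenerate-variance handling.

    Zero pooled standard error (constant groups): p = 1 for equal means,
    p = 0 otherwise.  Single-observation groups contribute zero variance.
    """
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / np.sqrt(se2)
    df_num = se2 ** 2
    df_den = 0.0
    if va > 0 and na > 1:
        df_den += (va / na) ** 2 / (na - 1)
    if vb > 0 and nb > 1:
        df_den += (vb / nb) ** 2 / (nb - 1)
    df = df_num / df_den if df_den > 0 else max(na + nb - 2, 1)
    return float(2 * stats.t.sf(abs(t), df))


def condition_association(
    values: Sequence[float],
    design: Sequence[SampleInfo],
    th: ScreenThresholds,
) -> dict:
    """Association of one gene's FPKM row with stimulation and genotype.

    Welch tests on log2(FPKM + pseudocount): RANKL vs unstimulated, and
    WT vs KO; ``associated`` is true when either p-value is below alpha.
    """
    v = np.asarray(values, dtype=float)
    if len(v) != len(design):
        raise ValueError("values and design length mismatch")
    x = np.log2(v + th.pseudocount)
    stim = np.array([s.stimulation == "RANKL" for s in design])
    geno = np.array([s.genotype == "WT" for s in design])
    for mask, factor in ((stim, "stimulation"), (geno, "genotype")):
        if mask.all() or not mask.any():
            raise ValueError(f"factor {factor} has an empty level in the design")
    p_rankl = _welch(x[stim], x[~stim])
    p_genotype = _welch(x[geno], x[~geno])
    return {
        "p_rankl": p_rankl,
        "p_genotype": p_genotype,
        "associated": (p_rankl < th.alpha) or (p_genotype < th.alpha),
    }


def association_table(
    m: pd.DataFrame, design: Sequence[SampleInfo], th: ScreenThresholds
) -> pd.DataFrame:
    """condition_association applied to every gene row of the FPKM matrix."""
    cols = [s.sample_id for s in design]
    rows = [condition_association(m.loc[g, cols].to_numpy(), design, th) for g in m.index]
    return pd.DataFrame(rows, index=m.index)


def rankl_induced_partition(
    m: pd.DataFrame,
    design: Sequence[SampleInfo],
    de_genes: Sequence[str],
    th: ScreenThresholds,
    assoc: pd.DataFrame | None = None,
) -> dict:
    """Split differentially expressed genes into stimulation-induced genes
    and the subset expressed higher in stimulated WT than stimulated KO."""
    if assoc is None:
        assoc = association_table(m.loc[list(de_genes)], design, th)
    stim_cols = [s.sample_id for s in design if s.stimulation == "RANKL"]
    unstim_cols = [s.sample_id for s in design if s.stimulation == "none"]
    wt_stim = [s.sample_id for s in design if s.stimulation == "RANKL" and s.genotype == "WT"]
    ko_stim = [s.sample_id for s in design if s.stimulation == "RANKL" and s.genotype == "KO"]
    induced, wt_higher = [], []
    for g in de_genes:
        if not assoc.loc[g, "associated"]:
            continue
        if m.loc[g, stim_cols].mean() > m.loc[g, unstim_cols].mean():
            induced.append(g)
            if (
                m.loc[g, wt_stim].mean() > m.loc[g, ko_stim].mean()
                and assoc.loc[g, "p_genotype"] < th.alpha
            ):
                wt_higher.append(g)
    return {"induced": induced, "wt_higher": wt_higher}


def screen_retained_introns(
    quant: IntronQuantResult,
    m: pd.DataFrame,
    design: Sequence[SampleInfo],
    th: ScreenThresholds | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the three-step retention cascade.

    Returns a RetentionCall table (one row per intron: pass flags, genotype
    IR means over stimulated replicates, KO/WT ratio, selected flag) and a
    funnel dict with the count surviving each step.
    """
    th = th or ScreenThresholds()
    wt_stim = [s.sample_id for s in design if s.stimulation == "RANKL" and s.genotype == "WT"]
    ko_stim = [s.sample_id for s in design if s.stimulation == "RANKL" and s.genotype == "KO"]
    if not wt_stim or not ko_stim:
        raise ValueError(
            "retention screen requires RANKL-stimulated samples of both genotypes"
        )
    genes = quant.introns["gene_id"]
    missing = set(genes) - set(m.index)
    if missing:
        raise ValueError(f"introns reference genes absent from the FPKM matrix: {sorted(missing)[:5]}")

    gene_max = m.max(axis=1)
    passed_gene = (gene_max.loc[genes] > th.gene_fpkm_min).to_numpy()
    passed_intronic = (quant.intronic_fpkm.max(axis=1) > th.intronic_fpkm_min).to_numpy()

    # per-sample IR with the pseudocount added to both FPKM terms
    def mean_ir(cols: list[str]) -> np.ndarray:
        ifpkm = quant.intronic_fpkm[cols].to_numpy(float)
        g = m.loc[genes, cols].to_numpy(float)
        ir = (ifpkm + th.pseudocount) / (g + th.pseudocount)
        return ir.mean(axis=1)

    ir_wt = mean_ir(wt_stim)
    ir_ko = mean_ir(ko_stim)
    ratio = ir_ko / ir_wt
    passed_ratio = ratio > th.ir_ratio_min
    selected = passed_gene & passed_intronic & passed_ratio

    calls = quant.introns.copy()
    calls["passed_gene_fpkm"] = passed_gene
    calls["passed_intronic_fpkm"] = passed_intronic
    calls["ir_wt_mean"] = ir_wt
    calls["ir_ko_mean"] = ir_ko
    calls["ir_ratio"] = ratio
    calls["passed_ratio"] = passed_ratio
    calls["selected"] = selected

    funnel = {
        "introns_total": int(len(calls)),
        "pass_gene_fpkm": int(passed_gene.sum()),
        "pass_intronic_fpkm": int((passed_gene & passed_intronic).sum()),
        "selected": int(selected.sum()),
    }
    return calls, funnel
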