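"""3' splice-site (acceptor) extraction, strength scoring and association.

The acceptor context is the 15-mer spanning the intron/exon junction in
transcript orientation: the last 14 intronic bases (polypyrimidine tract
plus the invariant AG) followed by the first exonic base.  Strength is a
Shapiro-Senapathy-style 0-100 score against the mammalian acceptor
consensus TTTTTTTTTTTCAG/G: per-position base weights are summed and
min-max normalised so the consensus scores exactly 100 and the
all-minimum sequence scores 0.

Sequences lacking AG at positions -2/-1 are not acceptors and are
rejected rather than scored low.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomicInterval, Intron

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: acceptor consensus, 14 intronic bases + first exonic base
CONSENSUS = "TTTTTTTTTTTCAGG"
#: position labels -14..-1 then +1
POSITIONS = list(range(-14, 0)) + [1]

# Per-position base weights (percent-style frequencies) for the mammalian
# 3' splice site, arranged A/C/G/T per row for positions -14..+1.  The
# polypyrimidine tract favours T over C; -3 is the C of the YAG; -2/-1 are
# the invariant AG; +1 is the G-biased first exonic base.  The consensus
# base is strictly maximal at every position (required for the score-100
# endpoint and substitution monotonicity).
_DEFAULT_WEIGHTS = np.array(
    [
        #  A    C    G    T
        [11.0, 31.0, 12.0, 46.0],  # -14
        [10.0, 31.0, 11.0, 48.0],  # -13
        [9.0, 33.0, 10.0, 48.0],   # -12
        [9.0, 31.0, 11.0, 49.0],   # -11
        [9.0, 34.0, 10.0, 47.0],   # -10
        [10.0, 35.0, 9.0, 46.0],   # -9
        [9.0, 38.0, 9.0, 44.0],    # -8
        [9.0, 41.0, 8.0, 42.0],    # -7
        [8.0, 40.0, 8.0, 44.0],    # -6
        [9.0, 30.0, 10.0, 51.0],   # -5
        [24.0, 26.0, 20.0, 30.0],  # -4
        [4.0, 74.0, 1.0, 21.0],    # -3
        [100.0, 0.0, 0.0, 0.0],    # -2 (A)
        [0.0, 0.0, 100.0, 0.0],    # -1 (G)
        [25.0, 15.0, 52.0, 8.0],   # +1
    ]
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AcceptorMatrix:
    """Per-position base weights for acceptor scoring.

    ``weights`` has shape (15, 4) with columns ordered A, C, G, T; the
    consensus base must carry the strictly maximal weight at every
    position.
    """

    weights: np.ndarray
    provenance: str = "irscreen default mammalian acceptor frequencies"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (15, 4):
            raise ValueError("acceptor matrix must be 15 positions x 4 bases")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        for i, base in enumerate(CONSENSUS):
            col = BASES.index(base)
            w = self.weights[i]
            if not np.all(w[col] > np.delete(w, col)):
                raise ValueError(
                    f"consensus base {base} not strictly maximal at position {POSITIONS[i]}"
                )

    @classmethod
    def default(cls) -> "AcceptorMatrix":
        return cls(_DEFAULT_WEIGHTS.copy())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AcceptorMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df[list(BASES)].to_numpy(float), provenance=str(path))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, index=POSITIONS, columns=list(BASES)).rename_axis(
            "position"
        ).to_csv(path, sep="\t")

    @property
    def s_max(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def s_min(self) -> float:
        return float(self.weights.min(axis=1).sum())


@dataclass
class AcceptorContext:
    """15-base acceptor context of one intron, in transcript orientation."""

    intron: Intron | None
    sequence: str
    valid_ag: bool

    def __init__(self, intron: Intron | None, sequence: str):
        sequence = sequence.upper()
        if len(sequence) != 15:
            raise ValueError("acceptor context must be exactly 15 bases")
        if set(sequence) - set("ACGTN"):
            raise ValueError(f"invalid bases in acceptor context {sequence!r}")
        self.intron = intron
        self.sequence = sequence
        self.valid_ag = sequence[12:14] == "AG"


@dataclass
class SpliceSiteScore:
    """Scored acceptor: 0-100, or None with a reason when not scorable."""

    context: AcceptorContext
    score: float | None
    reason: str | None = None


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice genome sequence; pads with N outside chromosome bounds.

    ``genome`` may be a pyfaidx.Fasta (or any mapping of chrom -> sliceable
    sequence) or a plain dict of strings.
    """
    record = genome[chrom]
    lo = max(start, 0)
    seq = str(record[lo:end])
    pad_left = "N" * (lo - start)
    pad_right = "N" * (end - start - len(pad_left) - len(seq))
    return (pad_left + seq + pad_right).upper()


def extract_acceptor(genome, intron: Intron) -> AcceptorContext:
    """Extract the 15-mer acceptor context of an intron.

    Plus strand: last 14 intronic bases plus the first base of the
    downstream exon.  Minus strand: the 15 bases on the genomic start side,
    reverse-complemented so the result reads 5'->3' in transcript
    orientation.
    """
    iv = intron.interval
    if iv.length < 14:
        raise ValueError(f"intron {intron.key} shorter than 14 bp")
    if iv.strand == "+":
        seq = _fetch(genome, iv.chrom, iv.end - 14, iv.end + 1)
    else:
        seq = reverse_complement(_fetch(genome, iv.chrom, iv.start - 1, iv.start + 14))
    return AcceptorContext(intron, seq)


def score_sequence(seq: str, matrix: AcceptorMatrix | None = None) -> SpliceSiteScore:
    """Score a 15-mer acceptor sequence (intron-less context)."""
    ctx = AcceptorContext(None, seq)
    return score_acceptor(ctx, matrix)


def score_acceptor(
    ctx: AcceptorContext, matrix: AcceptorMatrix | None = None
) -> SpliceSiteScore:
    """Min-max normalised weight sum: 100 = consensus, 0 = all-minimum."""
    matrix = matrix or AcceptorMatrix.default()
    if "N" in ctx.sequence:
        return SpliceSiteScore(ctx, None, "ambiguous_base")
    if not ctx.valid_ag:
        return SpliceSiteScore(ctx, None, "invalid_acceptor")
    s = sum(matrix.weights[i, BASES.index(b)] for i, b in enumerate(ctx.sequence))
    score = 100.0 * (s - matrix.s_min) / (matrix.s_max - matrix.s_min)
    return SpliceSiteScore(ctx, float(score))


def score_all(
    genome,
    introns: Sequence[Intron],
    matrix: AcceptorMatrix | None = None,
) -> pd.DataFrame:
    """Score every intron's acceptor; unscorable introns are flagged, not fatal."""
    matrix = matrix or AcceptorMatrix.default()
    rows = []
    for intron in introns:
        try:
            ctx = extract_acceptor(genome, intron)
        except (ValueError, KeyError) as exc:
            rows.append(
                {
                    "intron": intron.key,
                    "gene_id": intron.gene_id,
                    "ordinal": intron.ordinal,
                    "sequence": "",
                    "valid": False,
                    "score": np.nan,
                    "reason": str(exc),
                }
            )
            continue
        res = score_acceptor(ctx, matrix)
        rows.append(
            {
                "intron": intron.key,
                "gene_id": intron.gene_id,
                "ordinal": intron.ordinal,
                "sequence": ctx.sequence,
                "valid": res.score is not None,
                "score": res.score if res.score is not None else np.nan,
                "reason": res.reason or "",
            }
        )
    return pd.DataFrame(rows).set_index("intron")


def retention_association(
    scores: pd.DataFrame,
    retained: Iterable[str],
    bin_width: float = 10.0,
) -> dict:
    """Association between retention and acceptor strength.

    One-sided rank-sum test (retained scores lower than unretained) plus
    the retained fraction per fixed-width score bin.  ``scores`` is the
    table from :func:`score_all`; ``retained`` holds intron keys.
    """
    retained = set(retained)
    valid = scores[scores["score"].notna()]
    is_ret = valid.index.isin(retained)
    a = valid.loc[is_ret, "score"].to_numpy(float)
    b = valid.loc[~is_ret, "score"].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both retained and unretained score sets must be non-empty")
    stat = stats.mannwhitneyu(a, b, alternative="less")

    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(valid["score"].to_numpy(float), edges[1:-1]), 0, len(edges) - 2)
    table = []
    for k in range(len(edges) - 1):
        in_bin = idx == k
        n = int(in_bin.sum())
        n_ret = int((in_bin & is_ret).sum())
        table.append(
            {
                "bin_low": edges[k],
                "bin_high": edges[k + 1],
                "n": n,
                "n_retained": n_ret,
                "retained_fraction": n_ret / n if n else np.nan,
            }
        )
    return {
        "rank_sum_p": float(stat.pvalue),
        "statistic": float(stat.statistic),
        "n_retained": int(len(a)),
        "n_unretained": int(len(b)),
        "bins": pd.DataFrame(table),
    }
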