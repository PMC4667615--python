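import numpy as np
import pandas as pd
import pytest

from irscreen.annotation import GeneModel, GenomicInterval, Transcript
from irscreen.quantify import FragmentSet, IntronQuantResult, SampleInfo
from irscreen.simulate import default_design


def fragset(frags, sample=None, total_mapped=None):
    """Build a FragmentSet from (chrom, start, end[, strand]) tuples."""
    sample = sample or SampleInfo("s1", "WT", "RANKL", 1)
    per_chrom = {}
    for f in frags:
        chrom, start, end = f[0], f[1], f[2]
        strand = f[3] if len(f) > 3 else "+"
        per_chrom.setdefault(chrom, []).append((start, end, 1 if strand == "+" else -1))
    arrays = {
        c: (
            np.array([r[0] for r in recs], dtype=np.int64),
            np.array([r[1] for r in recs], dtype=np.int64),
            np.array([r[2] for r in recs], dtype=np.int8),
        )
        for c, recs in per_chrom.items()
    }
    return FragmentSet(sample, arrays, total_mapped=total_mapped)


def simple_gene(gene_id="gX", chrom="chr1", exons=((0, 100), (200, 300)), strand="+",
                cds=None):
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    cds_start, cds_end = cds if cds else (None, None)
    t = Transcript(f"{gene_id}.t1", gene_id, ivs, cds_start=cds_start, cds_end=cds_end)
    return GeneModel(gene_id, [t])


def quant_from_counts(meta_rows, counts, sample_ids, lengths=1000, total=1_000_000,
                      gene_fpkm=None):
    """IntronQuantResult from a dict of per-sample raw counts.

    With length 1000 bp and 1e6 total mapped fragments, FPKM equals the
    raw count numerically, which keeps hand fixtures legible.
    """
    meta = pd.DataFrame(meta_rows).set_index("intron")
    meta["length"] = lengths
    cdf = pd.DataFrame(counts, index=meta.index, columns=sample_ids, dtype=float)
    ifpkm = cdf * 1e9 / (lengths * total)
    if gene_fpkm is not None:
        g = gene_fpkm.loc[meta["gene_id"]].set_axis(meta.index)
        ir = ifpkm.where(g > 0).div(g.where(g > 0), axis=0)
    else:
        ir = ifpkm * np.nan
    return IntronQuantResult(meta, cdf.astype(int), ifpkm, ir)


@pytest.fixture(scope="session")
def six_design():
    return default_design()
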