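# Methods

This note documents the models, conventions and numerical choices behind
`irscreen`, and what the simulation-based validation does and does not
establish.

## Coordinates and the intron universe

All internal coordinates are 0-based half-open; the GTF reader/writer
converts at the boundary. Introns are the gaps between consecutive exons
of a transcript; the screen operates on the set of *unique* genomic
intervals `(chrom, start, end, strand)` collapsed across transcripts
(each keeps the gene and the 5′→3′ transcript-order ordinal of the first
transcript contributing it). The alternative — counting per-transcript
intron copies — would multiply-count shared introns without adding
information at the interval level. Introns are *not* masked against
exons of other isoforms: retention is quantified over the raw genomic
interval, matching plain interval-intersection counting.

## Counting and quantification

The counting unit is the **fragment**: one BED record per sequenced
fragment (a BAM adapter collapses proper read pairs to their
outer-coordinate span). A fragment counts for an interval when it
overlaps it by at least one base; a fragment overlapping two intervals
increments both. Counting is strand-agnostic by default
(`respect_strand=True` restricts to matching strands). Internally,
per-chromosome sorted start/end arrays give each single-interval count
as a difference of two binary searches; gene-level counts over the
merged exon union count each fragment once.

Gene expression is union-exon FPKM, `count · 10⁹ / (length · total)`.
This is a deterministic, assembly-free surrogate for assembler-derived
FPKM and equals it in expectation under uniform exonic coverage. The
per-sample denominator `total` defaults to the fragment-file record
count and can be overridden per sample in the design table.

The IR value is intronic FPKM over gene FPKM; it is undefined (NaN) when
the gene's FPKM is zero. Because junction-spanning fragments are
represented by their outer genomic span, a fragment bridging two exons
overlaps the intervening intron and inflates intronic counts by roughly
`fragment_length / intron_length` in IR units. This is a property of
interval counting on span-projected fragments, not of the simulator;
IR estimates are therefore accurate only when fragments are much shorter
than introns, and the retention *ratio* between genotypes is the robust
quantity at typical intron lengths.

## The retention screen

Defaults (all inequalities strict, configurable in `ScreenThresholds`):

| parameter | default | role |
|---|---|---|
| `pseudocount` | 0.1 FPKM | guards ratios against zero denominators |
| `de_ratio` | 3 | max/min FPKM ratio for differential expression |
| `alpha` | 0.05 | condition-association level |
| `gene_fpkm_min` | 10 FPKM | cascade step 1 (gene max across samples) |
| `intronic_fpkm_min` | 10 FPKM | cascade step 2 (any sample) |
| `ir_ratio_min` | 1.5 | cascade step 3 (KO/WT mean IR, stimulated) |

Step 3 computes, per intron and genotype, the mean over
RANKL-stimulated replicates of `(FPKM_intron + 0.1)/(FPKM_gene + 0.1)`;
unstimulated samples contribute only to the gene-level filters. Averaging
replicate IRs (rather than requiring the ratio in every replicate) is the
minimal aggregation consistent with a per-genotype retention level.

The condition-association test is a Welch (unequal-variance) two-sample
t-test on `log2(FPKM + 0.1)`, run once for stimulation (stimulated vs
not) and once for genotype (WT vs KO); a gene is "associated" when
either p < α. With one unstimulated sample per genotype the genotype
contrast leans on the stimulated replicates; a constant row (zero
variance in both groups, equal means) is defined to give p = 1, and
zero variance with unequal means gives p = 0. No multiple-testing
correction is applied anywhere — the screen is a deliberate
fixed-threshold funnel, not an FDR-controlled discovery procedure.

## Acceptor scoring

The acceptor context is the 15-mer of the last 14 intronic bases plus
the first exonic base, read 5′→3′ in transcript orientation (minus-strand
introns are taken from the genomic start side and reverse-complemented).
The score is `100·(S − S_min)/(S_max − S_min)` where `S` sums one
per-position weight per observed base; `S_max`/`S_min` sum the
per-position maxima/minima. The shipped weight table encodes mammalian
acceptor-site base preferences (T > C on the polypyrimidine tract,
C at −3, the invariant A/G at −2/−1, G-biased +1) with the consensus
`TTTTTTTTTTTCAG/G` strictly maximal at every position; it is an
editable, documented constant (`AcceptorMatrix.to_tsv`/`from_tsv`), and
correctness is defined by its invariants (consensus scores exactly 100,
every single substitution scores strictly lower), not by equality with
any particular web tool's unpublished table. Sequences lacking AG at
−2/−1 are structurally not acceptors and are flagged invalid instead of
scored; ambiguous (N-containing) contexts are likewise flagged.

The retention-vs-strength association is a one-sided Mann–Whitney
rank-sum test (retained scores lower), with a fixed-width decile
breakdown of the retained fraction per score bin for reporting.

## PTC consequence

A retained-intron transcript is the exon sequence with the retained
intron(s) inserted at their junctions; the CDS start offset is remapped
through the block structure. Translation uses the standard nuclear code
until the first stop. "Intact" residues are the longest common prefix
with the reference protein (itself derived by translating the mature
CDS), which is well-defined whether or not a junction-spanning codon
happens to agree with the reference; residues after the divergence point
and before the stop are "novel". The stop is premature when it occurs
strictly before the reference's natural end, and its source (retained
intron vs downstream exon) is the block containing the stop codon's
first base. No NMD-efficiency prediction, selenocysteine or readthrough
handling is attempted.

## The simulator

`SimConfig` defaults emulate the targeted study design: six samples (one
unstimulated and two stimulated replicates per genotype), 10⁶ fragments
per sample, 300 bp fragment outer spans (a 101-bp paired-end library),
60 genes of 4–8 exons (150–450 bp) with introns of 1.5–8 kb (typical
mouse intron scale), lognormal baseline expression, 30% of genes induced
8-fold by stimulation, 10% weak-acceptor (GAG-at-PPT) introns, and
retention fractions ρ_wt = ρ_ko,strong = 0.05, ρ_ko,weak = 0.25.

Retention is molar: a fraction ρ of a gene's molecules retain one given
intron (single-intron isoforms by default; `multi_intron=True` switches
to independent per-intron retention for doubly-retained species).
Fragments are allocated to isoforms in proportion to molar fraction ×
isoform length — the length-proportional yield that FPKM normalisation
assumes — which makes the expected measured IR equal ρ up to the
junction-span term above, independent of intron/exon length ratios.
Fragment counts per gene are Poisson (optional gamma overdispersion);
starts are uniform along the chosen isoform; fragments are projected to
their outer genomic span as single BED records (no split alignments).
Planted acceptors are written verbatim into the genome (the tract allows
at most two C substitutions, which keeps every TTT-core acceptor scoring
above every GAG-core acceptor under the default matrix, so acceptor
class and score order never disagree). In single-intron mode, weak-intron
assignment is capped per gene so molar fractions stay feasible (Σρ ≤ 1).

What the simulator does **not** model: sequencing errors and quality,
alignment ambiguity and multi-mappers, positional/GC coverage bias,
overlapping genes, alternative isoforms beyond intron retention, and
library strandedness effects. Passing tests therefore demonstrate the
pipeline's correctness and statistical behaviour under idealised uniform
coverage, not robustness to real-data artefacts.

## Validation scenarios and problem sizes

The test suite and `scripts/acceptance.py` use: (a) the default
screen scenario above (20 and 10 seeds respectively) for
sensitivity/specificity of weak-intron recovery and the rank-sum
association; (b) a parameter-recovery scenario of 18 two-exon genes with
40–80 kb introns (so the junction-span term ≪ ρ) and planted
ρ ∈ {0.05, 0.2, 0.5} on both genotypes, 10 and 6 seeds; (c) exact
small-sample checks (rank-sum p = 1/35 for complete 3-vs-4 separation;
a hand-computed 5-gene/8-intron cascade fixture; 1000-permutation null
calibration); and (d) byte-level determinism of simulator and pipeline
outputs under a fixed seed. Numeric output uses `%.6g` formatting, which
makes TSVs byte-stable across runs.

## Known limitations

- IR is upward-biased by `~fragment_length/intron_length` (outer-span
  projection); genotype ratios largely cancel the bias.
- With n = 1 unstimulated samples per genotype, the association test's
  stimulation contrast has limited power and the genotype contrast mixes
  conditions; this mirrors the screen's intended fixed design.
- The acceptor matrix is a documented default, not a fitted model;
  scores are comparable within a matrix only.
- `total_mapped` from file record counts undercounts fragments mapped
  outside the provided regions; override it in the design table when
  absolute FPKM levels matter.
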