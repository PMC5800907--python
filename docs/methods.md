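# Methods

This note documents the models, conventions and free parameters behind
`accstrat`, and what the synthetic-cohort tests do and do not establish
about real data.

## Coverage-based expression calling

FFPE RNA-seq libraries are dominated by intronic and intergenic fragments
(here ~9% of reads map to exons), so gene expression is called from
coverage over the whole gene body rather than exon counts. The track is
tiled into non-overlapping windows of `window_size` = 1000 bp starting at
the track origin (no sliding phases). The background model is Poisson with
genome-wide rate

    λ = total_mapped_reads × window_size / effective_genome_length,

and a window is significant when its approximate read count (depth sum /
read length) exceeds both the Poisson upper-tail quantile at p < 1e-3 and
`min_fold` = 4 × λ. Significant windows closer than `merge_distance` =
10 000 bp merge into one region. The window/merge geometry follows the
region-mode peak-finding convention for this kind of data; the Poisson +
fold thresholds are this package's own documented defaults, since region
callers differ in their internal scoring. Regions are window-aligned, so
region boundaries are accurate to one window.

A gene is *expressed* when any region overlaps its body;
`covered_fraction` is the covered share of the body. Truncation is decided
strand-aware in transcriptional coordinates: the body's 5′-most and
3′-most 30% are compared, and `truncated` = expressed AND 5′ bin coverage
≥ 0.5 AND 3′ bin coverage ≤ 0.1. These bin and threshold choices
(`end_bin_fraction`, `c_high`, `c_low`) are configurable; they encode the
qualitative phenotype — coverage that dies before the transcriptional 3′
end — as a testable rule. Samples are assigned MYB / MYBL1 / NEITHER; if
both oncogenes ever call expressed (never seen in practice, and impossible
by construction in the generator) the higher-CPM gene wins and an
exclusivity warning is raised.

## Fusion-partner assignment

Soft-clipped segments of length ≥ `min_clip_len` = 12 nt from reads
anchored in an oncogene are exact-matched against every contig on both
strands. Matches inside another gene's body vote for that gene (one vote
per read per gene); the winning gene needs ≥ `min_support` = 2 reads whose
match positions cluster within `cluster_window` = 50 bp. Below support, or
on a tie between genes, the partner is UNKNOWN (tie additionally flagged
ambiguous) — mirroring tumors with obvious truncations but insufficient
chimeric evidence. Exact matching replaces a local aligner deliberately:
on an i.i.d. random reference a ≥ 12-mer collision is vanishingly rare, so
matching is deterministic and the support counts are exact. Real genomes
have repeats; an aligner adapter would be the extension point there.

## Expression analysis

QC fails a sample whose total reads are below 10% of the cohort median
(total reads, not exon-mapped — exon fraction is reported but never
gates). Sex concordance uses XIST: CPM > 1 is female-typical; the
threshold is configurable and the check is advisory. The high-expression
filter keeps genes with ≥ 250 reads in ≥ 10 samples. Normalization is
log2(CPM + 1); the pseudocount-1/CPM convention is standard and makes a
zero count map to exactly 0. PCA is the SVD of the gene-centered matrix;
signs are fixed by making the largest-magnitude loading of each component
positive. Differential expression is a Welch t-test per gene on log2-CPM
(the DE strategy is a deliberate, swappable default), with BH step-up
adjustment and the significance rule |log2FC| ≥ 1 AND adjusted p ≤ 0.05.
The SAM-style statistic for PCA-correlated genes is d = slope / (se + s0)
from the per-gene regression on a PCA score, s0 defaulting to the median
slope SE; per-gene FDR is the median-false-call permutation estimate at
cutoff |d|.

## Clustering and survival

Samples are clustered on log2-CPM of the filtered genes (unscaled) with
Euclidean distance and complete linkage; the tree is cut at k = 2 and
clusters are numbered by size ascending, so the minority, poor-outcome
cluster is always Group 1. Kaplan–Meier estimation is product-limit with
Greenwood variance; confidence intervals use the log transformation
S·exp(±z·σ_logS) clipped to [0,1]; median survival is the smallest
observed event time with S ≤ 0.5 and is undefined when the curve never
reaches 0.5. The log-rank test is the standard k-group chi-square.

Cox models maximize the Efron-tied partial likelihood by Newton–Raphson
with step-halving, covariates centered for conditioning, convergence at
gradient sup-norm < 1e-8; Breslow ties are available (and make the score
test at β = 0 equal the log-rank statistic exactly). A monotone likelihood
(separation) is detected when the plateau drives |β| > 20 and is flagged
rather than reported as an estimate. The marker screen fits a univariate
model per gene on standardized log2-CPM, so hazard ratios are per-SD;
zero-variance genes are flagged, not fitted. The multivariate model uses
age/10 (continuous), metastasis (yes/no) and the Group 1 indicator, on
complete cases with the dropped-row count logged.

## GSEA

Genes are ranked by signal-to-noise (μ₁−μ₂)/(σ₁+σ₂+ε); each set's running
sum gains |metric|^p (p = 1, normalized over in-set genes) at hits and
loses 1/(N−N_set) at misses; ES is the signed maximum deviation. Null
distributions come from phenotype permutation (each class needs ≥ 3
samples); nominal p is the same-sign tail fraction, NES divides ES by the
mean same-sign permuted ES, and FDR q compares the pooled permuted NES
tail to the observed NES tail. Sets intersecting the matrix in fewer than
15 genes are excluded. Defaults: 1000 permutations, weight 1.

## Promoter analysis

Intervals carry an explicit coordinate convention (1-based inclusive at
I/O, 0-based half-open internally); length is end−start+1 under the
former. The bundled EN1 (345 bp) and SOX4 (161 bp) promoter-luciferase
fragments carry their hg19 coordinates; the EN1 fragment's lowercase
rs3731613 base is uppercased on ingest. MRE scanning matches the
degenerate consensus `YAACKG` position-by-position on both strands; an N
in the subject never satisfies a non-N consensus position. Luciferase fold
activation is (mean − background) / (control mean − background), which is
invariant to uniform rescaling of all luminescence values.

## The synthetic cohort generator

The generator's defaults are the study conditions: 68 samples in
72/10/18% MYB/MYBL1/NEITHER proportions; among MYB-class samples a 14/49
fraction forms the high-risk cluster; the per-class truncation/fusion
mixture follows the observed fusion table (of 49 MYB tumors: 11 NFIB, 1
PDCD1LG2, 1 EFR3A, 29 unknown-partner truncations, 7 intact; all 7 MYBL1
tumors truncated, 3 with NFIB). Sex is drawn at 30F/38M proportions, age
from N(50.1, 14.1²) clipped to [18, 90].

*Genome.* Six contigs totalling 440 kb with eleven genes (the two
oncogenes on opposite strands so strand handling is always exercised,
fusion partners, Myb targets, a neither-class marker, housekeeping genes);
sequence is i.i.d. uniform ACGT from a fixed seed, making exact-match clip
search collision-free at this scale. Real genomes differ in every way that
matters for alignment (repeats, homopolymers, GC structure); the generator
therefore validates the logic downstream of alignment, not alignment
itself.

*Reads.* Uniform fragment placement over expressed gene bodies (introns
included — the FFPE pre-mRNA regime) plus genome-wide uniform background;
the gene/background split is solved analytically so the realized
exon-mapped fraction matches the 9% target in expectation. For truncated
genes no fragments fall 3′ of the breakpoint (drawn uniformly at 40–65% of
the transcript so the truncation rule's bins are unambiguous); 6 junction
reads per event end at the breakpoint carrying a 24 nt clip from the
partner locus, or random sequence for unknown partners. Default depth is
20 000 reads/sample — far below real depth but calibrated so per-window
gene coverage exceeds background ~20-fold, which is the regime the peak
caller assumes. No sequencing-error, deamination or read-length modeling.

*Counts.* Negative binomial per gene: log2 μ = log2 baseline + class
offset + cluster offset + sex offset + log library factor; dispersions
α ∈ [0.08, 0.25]; library factors log-normal (σ = 0.25). The panel (~1400
genes) plants the named markers (SOX4/EN1/CXXC4 up 2–2.5 log2 in
oncogene classes; VGLL3/KLF4/FOXO1/JUNB/FOSB up in NEITHER), a 150-gene
moderate (±1–1.8 log2) oncogene-class program, a 30-gene embryonic
stem-cell-like up-set and 20-gene good-outcome down-set (±3–4 log2) for
the high-risk cluster, XIST keyed to sex, and log-uniform background. The
cluster offsets deliberately dominate the class program so that k = 2
clustering isolates the survival groups, as observed in the real cohort;
effect sizes are free parameters of the generator, not estimates of
tumors.

*Survival.* Exponential event times per cluster with medians 28 (high
risk) and 147 months (standard), uniform censoring over 300 months, and
proportional-hazards covariate effects (HR 1.5 per decade of age, HR 3 for
metastasis; metastasis probability 0.70/0.33 by cluster). Covariate
multipliers are divided by their group expectation so the marginal group
time scale stays near its anchor (the rate mixture still shifts small-n
medians upward somewhat). Setting the covariate HRs to 1 recovers the pure
per-group exponential model used in the closed-form recovery tests.

*Determinism.* `SeedSequence(seed)` spawns four children — cohort, counts,
reads (one grandchild per sample), survival — so identical seed and
configuration reproduce every artifact byte for byte.

## Problem sizes and what the tests show

The test suite and acceptance script run the full cohort at n = 68 and
20 000 reads/sample, DE calibration at 2000 genes × 40 samples, Cox CI
coverage over 500 replicates of n = 200, and GSEA at 1000 permutations —
sizes chosen so the whole suite completes in well under a minute while
keeping Monte-Carlo error far below the asserted tolerances. Passing tests
establish that the algorithms implement their stated contracts and recover
planted truth under the generator's assumptions (uniform coverage, exact
clip matches, NB counts, exponential hazards); they do not establish
robustness to alignment artifacts, repeat-mediated clip mismatches,
batch effects or non-proportional hazards in real cohorts.

## Known limitations

- The peak caller is equivalent to its own specified window/merge
  algorithm, not to any external tool's internal scoring.
- Fusion detection requires chimeric transcripts; genomic rearrangements
  that never produce a fusion transcript are invisible, so translocation
  tallies are lower bounds.
- The marker screen's hazard ratios are per-SD of log2-CPM; screens using
  other covariate codings (dichotomized expression, protein staining) are
  not numerically comparable.
- GSEA FDR q-values use the pooled-NES normalization and are meaningful
  only relative to the permutation scheme (phenotype labels) and set
  collection supplied.
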