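# accstrat

Transcriptome-based stratification of salivary gland adenoid cystic
carcinoma (ACC) from bulk RNA-seq, built for cohorts of archival FFPE
samples where reads are fragmented and mostly intronic.

ACC tumors are driven by the interchangeable *MYB* and *MYBL1* oncogenes,
typically activated by translocations (most famously the t(6;9) *MYB–NFIB*
fusion) that truncate the transcript and juxtapose foreign enhancers. This
package implements the full analysis a molecular-stratification study of
such a cohort needs, plus a synthetic cohort generator with planted ground
truth so every stage is testable end to end without any sequence download:

- **Peak-calling classification** (`accstrat.peakclass`): windowed region
  calling on per-base coverage (1 kb windows, merged within 10 kb; Poisson
  background with fold gate), per-gene expressed / covered-fraction /
  3′-truncation status evaluated in transcriptional orientation, and
  per-sample assignment to MYB, MYBL1 or NEITHER.
- **Fusion-partner scanning** (`accstrat.fusionscan`): soft-clipped
  segments of reads anchored in a truncated oncogene are matched against
  the reference (both strands); a partner needs ≥ 2 supporting reads
  clustering within 50 bp, otherwise it stays UNKNOWN, and a Table-style
  fusion catalog partitions the cohort.
- **Expression analysis** (`accstrat.exprmat`): read-count and XIST sex QC,
  the ≥ 250-reads-in-≥ 10-samples high-expression filter, log2-CPM,
  SVD-based PCA, Welch differential expression with the 2-fold +
  BH-adjusted p ≤ 0.05 rule, and a SAM-style permutation statistic for
  genes correlated with PCA dimensions.
- **Clustering and survival** (`accstrat.survclust`): Euclidean
  complete-linkage clustering into risk groups (the minority cluster is
  Group 1), Kaplan–Meier curves with Greenwood variance (median = smallest
  event time with S ≤ 0.5), the log-rank test, Cox proportional-hazards
  models (Newton–Raphson on the Efron-tied partial likelihood, HR =
  exp(β), Wald CIs), a univariate marker screen and the multivariate
  age/metastasis/cluster model.
- **GSEA** (`accstrat.gseakit`): weighted running-sum enrichment score
  (hit steps ∝ |signal-to-noise|, miss steps 1/(N−N_set), ES = signed
  maximum), phenotype permutations, NES and FDR q-values.
- **Promoter analysis** (`accstrat.promoseq`): coordinate arithmetic for
  the EN1/SOX4 promoter-luciferase fragments, Myb-response-element
  (consensus `YAACKG`) scanning on both strands, and luciferase
  fold-activation normalization.
- **Synthetic cohorts** (`accstrat.synthgen`): a desk-scale genome with
  MYB/MYBL1/NFIB-like loci, negative-binomial counts with class, cluster
  and sex signatures, FFPE-like reads (~9% exon-mapped) with planted
  truncations and junction-spanning clipped reads, and per-group
  exponential survival with covariate effects.

## Worked example

```python
from accstrat.pipeline import RunConfig, run_all

report = run_all(RunConfig(seed=1), "out")
print({k: report.summary[k] for k in
       ("class_counts", "group_sizes", "km_median_group1", "logrank_p")})
```

prints (seed 1):

```
{'class_counts': {'MYB': 47.0, 'MYBL1': 9.0, 'NEITHER': 12.0, 'EITHER_ONCOGENE': 56.0},
 'group_sizes': {2: 55, 1: 13},
 'km_median_group1': 54.77,
 'logrank_p': 0.006106...}
```

Reading: of 68 simulated tumors, peak calling assigns 47 to the MYB class,
9 to MYBL1 and 12 to neither oncogene (56/68 = 82% express a driver);
unsupervised clustering of the 705 high-expression genes isolates a
13-sample poor-outcome Group 1 whose Kaplan–Meier median survival is ~55
months in this draw (the generative median is 28 months; a 13-patient
median is noisy) versus 143 months cohort-wide, with a log-rank p of
6 × 10⁻³ against Group 2. The same run writes the full artifact set
(counts, clinical table, calls, fusion catalog, DE/PCA tables, dendrogram,
KM curves, Cox tables, GSEA results) plus a `report.json` indexing every
file with a checksum.

The same stages are exposed on the command line:

```bash
accstrat run --seed 1 --outdir out
accstrat simulate --seed 1 --outdir sim
accstrat de --counts sim/counts.tsv --groups groups.tsv --fc 2 --alpha 0.05 --out de.tsv
```

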