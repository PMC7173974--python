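# Methods

This note documents the models, parameter choices and numerical decisions
behind `vncatlas`, and what the synthetic fixture can and cannot show about
real data.

## Pipeline model and assumptions

The pipeline assumes droplet-style UMI counts: integer, sparse, with
per-cell totals spanning roughly an order of magnitude, a debris population
of ambient-only barcodes at low totals, and gene expression that is
adequately described by a negative binomial (Gamma–Poisson) law after
conditioning on the cell's total. All stage parameters default to the
values of the original VNC analysis:

| parameter | default | meaning |
| --- | --- | --- |
| `min_umi` / `max_umi` | 1200 / 10000 | nUMI gates; the lower gate sits in the debris/cell trough, the upper removes outliers (1–2% of barcodes). `max_umi=None` disables the cap, which matters for neuropeptide-class cells whose genuine output exceeds it; the census stage always re-filters without the cap. |
| `min_genes`, `max_mito` | 200, 0.15 | detected-gene and mitochondrial-fraction gates |
| `min_cells_per_gene` | 3 | gene filter, applied **after** the cell filter (detection counts are only meaningful over retained cells; the order is logged in the results object and configurable by filtering manually) |
| normalization scale | 10⁴ | ln(1 + scale·x/nUMI); per cell, Σ expm1 = scale exactly |
| scaling clip | ±10 | z-scores of OLS residuals vs replicate (indicator contrasts), nUMI, prop_mito |
| variable genes | mean > 0.001, dispersion z > 0.001 | dispersion = var/mean of expm1 values, z-scored within 20 equal-occupancy log-mean bins; per-sex selections intersected. The exact binning of the original toolchain is not published; 20 quantile bins is this package's choice. |
| CCA | d = 45 | SVD of the cross-product of the two sex-wise scaled matrices (LinearOperator + `svds`, fixed start vector, hence deterministic); per-cell loadings scaled by √n per group and stacked. The dynamic-time-warping subspace alignment of the original toolchain is deliberately not reproduced. |
| SNN graph | k = 30, Jaccard weights, prune < 1/15 | Euclidean metric in the reduced space, self included in neighbour lists |
| clustering | Louvain (igraph `community_multilevel`), resolution 12 | labels relabelled by decreasing size; igraph's RNG is seeded, so runs are reproducible. Louvain is order-dependent in principle; on well-separated data the partition is stable under permutation (tested). |
| NB marker test | logFC ≥ 0.5, Bonferroni α = 0.05, pre-screen pct.1 ≥ 0.1 | one-vs-rest likelihood-ratio test, count ~ NB(nUMI·r_group, α_disp); dispersion estimated by profile maximum likelihood per test and shared between the two groups, with a method-of-moments fallback flagged in the output. Bonferroni is over tests actually performed. A covariate-including variant (replicate terms via statsmodels NB regression) is available; the default is covariate-free. |
| mixing metric | k = 30 | mean over cells of (fraction of neighbours from other replicates) / (1 − own-replicate share), clipped at 1 |

Annotation thresholds (0.15 scaled for class, 0.5/0 scaled for cluster FAN,
2.0 log-normalized for cell FAN, Hox cut 0 with strict mode 1) are the
published rule set. Two readings of the FAN cascade's "greater than either"
clauses exist; the conjunctive reading (greater than both competitors) is
the default, the disjunctive one is behind `conjunctive=False`.

Design choices made where the procedure was genuinely open:

* **NP-class override** — the neurosecretory cluster is identified as any
  otherwise-unclassified cluster whose mean log-normalized
  neuropeptide-panel expression is at least half the maximum over clusters
  (and above 1). A strict argmax would break whenever high resolution
  splits the NP cluster in two.
* **Hemilineage score** — score(h, c) = mean scaled expression of h's
  markers − mean over h's anti-markers (markers of hemilineages sharing at
  least one marker with h), candidates restricted to the cluster's FAN,
  assignment when the best score ≥ 0.15 and is untied. The original
  assignments were manual curation from the same expression patterns; this
  score is validated purely by planted-truth recovery, not by claimed
  equivalence to the curated table.
* **Subtype labels** — each subcluster takes the biomarker with the largest
  positive margin of mean log-normalized expression over the *mean* of the
  other subclusters (max-margin lets two subclusters of one subtype cancel
  each other).
* **Debris trough** — the histogram of log10 nUMI is smoothed with a
  Gaussian kernel of 0.05 decades (bins of 0.01); the threshold is the
  deepest local minimum strictly between the two most prominent modes,
  ties resolved toward the smaller nUMI; unimodal input falls back to the
  configured bound with a warning.
* **Sub-clustering neighbourhoods** — sub-runs use
  k = clip(n/10, 10, 30) nearest neighbours: a 30-NN graph on a ~150-cell
  selection would span the subtype blocks it is meant to separate.
* **"Expressing"** means raw count > 0 wherever a rule speaks of detection
  (exclusion gates, co-expression, kn⁺ fractions).

## The synthetic atlas

`simulate.default_composition()` builds the packaged fixture: 120 clusters
— 110 neuronal (44 cholinergic, 42 GABAergic, 20 glutamatergic, and 4
without FAN identity: one neuropeptide/neurosecretory cluster, one
monoaminergic cluster with four planted subtypes, two plain), 5 glial
clusters totalling 3.6% of cells with four subtype programs (two of them
astrocytic, two carrying a tail of neuronal-signature cells), salivary and
sperm contaminant clusters, and 3 unannotated clusters. Cluster sizes vary
deterministically within each group and are drawn multinomially per run;
the FAN cell-composition of neurons is 40/38/18/4.

Per cell: library size LogNormal(log 2500, 0.3) (the neuropeptide cluster
at median ≈ 5300 with σ = 0.4, so a realistic tail exceeds the 10,000-UMI
cap), mitochondrial fraction Beta(2.5, 47.5) (mean 5%, ~1–2% of cells
beyond the 15% gate), counts NB with per-cluster dispersion 0.35. Each
cluster's background program is a shared rank/abundance power law
(exponent 0.6 with an exponentially decaying low-expression tail over the
last quarter of genes) times a cluster-specific log-normal jitter of
σ = 0.5 — cell types differ transcriptome-wide, not only in their
markers. Planted markers specify the expected UMI per expressing cell at
the reference library size; fractional markers are planted in exact-count
subsets so realised expressing fractions equal their specification (the
23B clusters carry kn in 31% and twz in 18% of cells; the Orcokinin
analogue is planted in exactly 5 cells of the NP cluster). Replicates
(two per sex, fractions matching the published replicate sizes) apply a
per-gene log-normal batch factor of σ = 0.05; males additionally express
roX1/roX2. Debris barcodes (10% of the cell count) are ambient-only draws
with 300–1000 total counts, which is what puts the histogram trough in the
1000–1200 interval.

Ambient contamination adds Poisson(rate·nUMI) counts per cell from an
ambient profile equal to the library-weighted mean transcriptome with the
NP cluster up-weighted (weight 0.15), modelling preferential rupture of
fragile high-output neurosecretory cells; the default rate is 0.02. This
reproduces the qualitative ambient signatures the annotation layer must
cope with: a double-digit FAN-marker co-expression rate that rises with the
rate, and a low-count (1–10) background of the super-expressed
neuropeptide genes across essentially all clusters while bona fide
expression (≥100 counts) stays confined to the planted cells.

Dispersion 0.35 was chosen (over coarser alternatives) because the
annotation rules read "expressing" as detection: at the planted marker
means it keeps realised detection close to the planted expressing
fractions, as the rule set presupposes; it is well within the range
reported for droplet UMI data.

**What the fixture does not emulate:** doublets, spliced/unspliced
structure, gene–gene correlation beyond cluster/subtype block structure,
batch effects that interact with cell type, empty-droplet barcode rank
structure beyond a single debris band, or the long tail of very small real
clusters. Passing tests therefore demonstrate that the implementation
recovers structure *of the kind the original analysis assumed*, not that
the pipeline is robust to every real-data pathology; in particular the
clustering ARI on the fixture should not be read as an accuracy claim for
real tissue.

## Problem sizes and numerical notes

The packaged fixture is desk-scale: 12,000 cells × 1,500 genes (plus 10%
debris barcodes), with `full_scale=True` emitting the published 26,768-cell
size; the test suite and the acceptance script run the full pipeline once
at desk scale (about a minute) and use 300–3,000-cell compositions for
unit-level checks. The default pipeline restricts the NB marker sweep to
the contaminant panels (all the downstream stages need from it); set
`AtlasConfig(marker_genes="all")` for a full marker table.

Other numerical choices: genes whose residual sd after covariate
regression is at floating-point noise level scale to exactly 0; NB rate
MLEs use a safeguarded Newton iteration with the dispersion profiled by
bounded scalar minimisation over log-dispersion ∈ [−12, 5]; the
likelihood-ratio statistic is clipped at 0 before the χ²(1) tail; the
percentile-of-maxima uses mean ranks for ties over all genes surviving the
gene filter; `pct_expressing` and census quantities are computed on raw
counts.

## Known limitations

* The hemilineage panel covers 14 hemilineages with 2–3 markers each — a
  configuration file, not a claim of biological completeness; users should
  supply their own panel for real data.
* Louvain order-dependence means cluster *counts* can shift by a few units
  between platforms even at a fixed seed; all recovery statistics are
  label-permutation invariant.
* The CCA step omits the original toolchain's time-warp alignment, so
  embeddings are comparable only in the aggregate (mixing metric, cluster
  recovery), not coordinate-by-coordinate.
* The NB test's profile-likelihood dispersion is per (gene, cluster) test;
  genes with fewer than ~10 expressing cells can hit the method-of-moments
  fallback, which is flagged per row rather than silently accepted.
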