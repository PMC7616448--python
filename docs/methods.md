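# Methods

## Data model and normalization

Counts are genes × cells unique-molecule integers (`CountMatrix`), read from
10x-style MatrixMarket triplets or dense TSV tables; duplicate gene symbols
are aggregated by summation at read time and matching is case-sensitive
everywhere. Normalization is the standard library-size log transform

    x_gc = ln(1 + n_gc / N_c · 10,000),

with `N_c` the cell's total count. Cells with zero total keep an all-zero
column through normalization (so I/O round-trips are exact) but contribute
nothing downstream: their module score and enrichment difference are 0, and
0 is never "active" or "positive" under the strict inequalities used.
Non-neuronal nuclei are removed by requiring a raw count > 0 in at least one
of the pan-neuronal markers *Meg3*, *Rbfox3*, *Snap25* (threshold
configurable; the filter is idempotent). No minimum-gene/minimum-count QC is
enforced by default — such thresholds are dataset-specific and are left to
the caller.

## IEG module score

For every gene the mean normalized expression over all scored cells is
computed, genes are ranked (ties broken lexicographically by symbol, which
makes every downstream draw independent of input gene order) and the rank
range is cut into `n_bins = 24` contiguous near-equal intervals, earlier
intervals absorbing the remainder. For each feature gene present in the
matrix, `n_ctrl_per_gene = 100` non-feature genes are sampled without
replacement from its interval (all of them when fewer are eligible); the
union of these draws is the control pool, drawn **once per run** from the
stated seed so that scores are comparable across cells. The score is the
difference of the cell's mean normalized expression over feature genes and
over the control pool. 24 bins and 100 controls are the defaults of the
scoring convention this reimplements; the panel itself is the 103-gene IEG
list (the packaged copy is a curated synthetic stand-in — see
`iegactivity/genesets.py`).

*IEG positivity* is `100 · #{score > 0} / n` per cluster — a score of
exactly zero is not positive. The reported "IEG score" adds a fixed +0.05
offset for display; positivity and activity calls always use the raw score.

## Activity-enrichment calling

One evaluation at marker threshold `k`:

1. **Highly variable genes.** Dispersion = variance/mean of normalized
   expression (ddof = 1), z-scored within 20 rank bins of mean expression;
   the top `n_hvg = 2000` genes by z are kept (constant genes never qualify;
   ties break by symbol).
2. **Markers.** Per cluster, a one-vs-rest two-sided Wilcoxon rank-sum test
   per gene on normalized expression (asymptotic normal approximation with
   tie and continuity correction — `scipy.stats.mannwhitneyu`); genes ranked
   by ascending p, ties by descending mean log-expression difference, then
   symbol; the top `k` per cluster enter the pool. Clusters with fewer than
   3 cells are skipped; at least two usable clusters are required.
3. **Pool.** Union of HVGs and markers, deduplicated and symbol-sorted;
   feature = pool ∩ IEG panel, background = the rest. Empty feature or
   background sets are configuration errors.
4. **Background resampling.** Background genes are ranked by mean normalized
   expression (raw-count mean available via `rank_by="raw_mean"`), cut into
   50 rank intervals (remainder to earlier intervals; if the background is
   smaller than 50 genes the interval count shrinks to the pool size), and
   50 genes are drawn from each interval without replacement — an interval
   smaller than 50 contributes all its genes, so a gene never appears twice
   in one draw.
5. **Calls.** For each of 100 repetitions a fresh background draw is made
   and every cell is scored by mean(feature) − mean(background sample) of
   normalized expression. `mean_diff` is the average over repetitions;
   `emp_p = (1 + #{diff_r ≤ 0}) / (1 + 100)` (add-one smoothing keeps p > 0
   and, at the default parameters, leaves the active set identical to the
   unsmoothed rule); a cell is active iff `mean_diff > 0` and
   `emp_p < 0.01`, which at 100 repetitions requires a positive difference
   in every repetition.

**Consensus.** Per cluster and threshold, active fractions per condition are
compared with a two-sided Fisher's exact test on the active/inactive ×
condition table. A cluster is *robustly perturbed* (direction up/down) iff
the sign of the treated-minus-control difference is the same and the test is
significant at 0.05 in all three evaluations (k = 250, 500, 1000). The
underlying convention does not fix a cluster-level test; Fisher + sign
agreement is this package's documented choice, as is the stability guard
that excludes clusters with fewer than 10 cells in either condition.

### Operating characteristics (limitation)

The empirical p measures only the variability introduced by the background
*draw*, not the sampling noise of the feature set. Because each repetition
draws up to 2,500 of a background pool that is itself typically ~2,100–2,700
genes, the background mean is nearly constant across repetitions and the
all-positive criterion degenerates into a per-cell sign threshold on
(mean feature expression − mean background-pool expression). Two
consequences, both computed by this package's own tests and acceptance
script:

* On exchangeable-null simulations (no activity signal, IEGs statistically
  identical to other genes) roughly half of all cells are called active —
  the procedure is not a calibrated per-cell test.
* The interval stratification matches the background *sample* to the
  background *pool*, not to the feature genes. Whenever the feature genes
  that enter the pool sit higher in the expression distribution than the
  pool average (which the activity signal itself promotes, since
  well-expressed IEGs gain the most dispersion and are preferentially
  selected), per-cell specificity against ground truth is poor even though
  sensitivity is essentially 1.

Cluster-level conclusions are much better behaved than per-cell ones: the
bias is shared by both conditions, so the *difference* in active fractions
still tracks the true shift, and on the default recovery scenario the
consensus identifies exactly the truly shifted clusters. Interpret per-cell
active totals as enrichment thresholds, not error-controlled discoveries.
The module score, whose controls are matched per feature gene, stays
centered on null data (cluster means within ±0.05 at the default scale).

## Composition comparison

Per (sample, cluster), counts and within-sample fractions over the full
sample × cluster grid (absent combinations get 0). Fractions — not raw
counts — are compared, since sample depth varies. Per cluster, an unpaired
two-sided t-test across samples (equal variances; identical zero-variance
groups give p = 1 by convention, differing constant groups p = 0, both
logged), then Holm–Šídák step-down adjustment across clusters:
`adj_(i) = max_{j ≤ i} 1 − (1 − p_(j))^(m − j + 1)`, clipped at 1
(`statsmodels.multipletests`, verified in tests against the closed form).

## Synthetic data generator

`SyntheticSpec` emulates the statistical structure the pipeline assumes:
negative-binomial UMI counts (mean μ, size s, variance μ + μ²/s), per-gene
baseline means drawn once from a log-normal, pairwise-disjoint per-cluster
marker sets (uniformly drawn from non-IEG genes) whose means are multiplied
by `marker_fold` in their own cluster, and a designated IEG subset whose
means are multiplied by `ieg_fold` in cells labelled active (Bernoulli per
cell with a (cluster, condition)-specific fraction). Defaults, fixed once on
realism grounds:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 10,000 | desk-scale stand-in for a full transcriptome; keeps pool sizes (~2,100–4,000) in the regime the method is used in |
| `n_ieg` | 103 | size of the IEG panel |
| clusters / samples | 4 clusters × 167 cells/sample, 3 samples per condition | ≈500 cells per cluster and condition; triplicate design |
| `baseline_log_mean` | (−2.0, 1.4) | median μ ≈ 0.14, ≈1,400–2,600 detected genes/nucleus — typical snRNA-seq sparsity |
| `nb_dispersion` | 2.0 | moderate UMI overdispersion |
| `marker_fold` / markers | 6 × 50 genes | clearly separable cell types |
| `ieg_fold` | 4.0 | strong activation signature |
| active fractions | 5% everywhere; 40% in clusters Ex2 and In1 under treatment | baseline spontaneous activity plus a treatment-driven shift in two cell types |

`null_dataset` zeroes every active fraction and forces `ieg_fold = 1`,
making the IEG subset exchangeable with all other non-marker genes — the
calibration fixture. The generator does **not** simulate doublets, ambient
RNA, batch effects, cell-level library-size gradients or correlated gene
modules beyond the marker/IEG structure, so passing recovery tests
demonstrate correctness of the procedure's mechanics under its own model
assumptions, not robustness to real-data artifacts. Everything is
reproducible from the spec's single seed; gene roles are drawn before
activity labels, so datasets differing only in fold/fraction share their
gene structure.

## Numerical conventions

* All rank cuts (score bins, HVG mean-bins, background intervals) share one
  helper: ascending value, lexicographic tie-break, earlier chunks absorb
  remainders.
* Random draws iterate over symbol-sorted gene lists with a
  `numpy.random.default_rng` seeded per run — results are independent of
  gene order and platform.
* Problem sizes used by the test-suite and acceptance runs (2,000-cell null
  replicates, a 4,008-cell recovery scenario, 10,000 genes) are the
  package's chosen desk-scale study conditions; the module-score null check
  runs at the same scale because control-bin granularity, and hence score
  centering, degrades when bins hold too few genes.
* The optional accession-scale replication of a real dataset's pool sizes is
  not part of the test suite; it requires downloading the corresponding
  repository data and is sensitive to upstream QC choices.
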