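# Methods

`cellsig` tests whether a gene signature — a named list of genes, optionally
split into up- and down-regulated members — is more strongly expressed in one
of two experimental conditions in droplet scRNA-seq data. The motivating use
case is comparing glioma-associated microglia/macrophage activation states
between tumors carrying a SELP-targeting shRNA (shSELP) and negative controls
(shNC), but nothing in the package is specific to that system.

## Processing model

Raw counts arrive as a genes-as-rows MTX triplet plus a per-cell metadata
table (condition, optional cluster). Processing order is fixed:

1. **Cell QC.** Cells with more than `max_mito_fraction` (default 0.10) of
   their raw counts on mitochondrial genes (gene-ID prefix `mt-`, the mouse
   convention), or with fewer than `min_genes_per_cell` (default 500)
   detected genes, are removed. The thresholds are strict inequalities: a
   cell at exactly 10% mitochondrial content and exactly 500 genes is kept.
   Mitochondrial share is computed on raw counts, before any normalization.
2. **Gene QC.** Among the retained cells, genes detected in strictly more
   than `min_cells_per_gene` (default 3) cells are kept. The cells-first
   order matters and is tested: a gene can owe its detection count to cells
   that fail QC.
3. **Log-normalization.** `log1p(count / cell_total * s)` with scale factor
   `s = 10,000`. The method names only the normalization, not `s`; 10,000 is
   the long-standing default of the reference toolchain and is configurable.
   Per cell, `sum(expm1(normalized)) == s` exactly (a conservation law the
   tests enforce to 1e-6 relative).
4. **Per-gene scaling.** Center and divide by the sample (n−1) standard
   deviation; constant genes map to zeros; values are clipped symmetrically
   to ±`clip_value` (default 10). Symmetric clipping is a deliberate choice:
   a z-score matrix feeding rank- and sum-based scores should treat extreme
   dropouts and extreme expressors alike.
5. **Optional equal-size downsampling** per condition (uniform, without
   replacement, seeded), mirroring the balanced-group design of the
   motivating experiment (e.g. 4580 cells drawn from each group).

## Signature scores

Both scores operate on the z-scored matrix, which removes the bias towards
highly expressed genes:

* **Rank score** — within each cell, all genes are ranked ascending
  (rank 1 = lowest; average ranks for ties, since sparse matrices are
  tie-heavy and average ranks make the score independent of input order);
  the score is the sum of the ranks of the up members minus the sum for the
  down members. Ascending ranks make a larger score mean "signature more
  expressed". The score depends on expression only through within-cell
  order, so it is invariant under any strictly increasing per-cell
  transform (a tested property).
* **Expression-sum score** — summed scaled expression of the up members
  minus the down members. The prose this implements can be read with either
  sign; up-minus-down is used so both scores point the same way, and a flag
  flips it.
* **Combined score** — each score z-scored across cells (n−1 denominator;
  constant vectors become zeros) and averaged.

A high-score mask marks cells strictly above a percentile (default 10th,
linear interpolation) of the score distribution — the contour device used to
highlight strongly scoring regions on an embedding.

## Per-cell CERNO enrichment

For each cell, genes are ranked **descending** by log-normalized expression
(rank 1 = most expressed; average ranks for ties) and

    F = −2 Σ_{i=1..N} ln(r_i / N_tot),      F ~ χ²(2N) under the null,

over the N resolved signature members (the up members for a bidirectional
signature — the statistic is defined for a single set, and mixing directions
would cancel). The per-cell p-value is the chi-square upper tail at F.
Per-cell p-values are then Benjamini–Hochberg-adjusted separately within each
condition, a cell is called *enriched* when q < 0.05 (both configurable), and
a Fisher exact test on the 2×2 (enriched / not) × condition table asks
whether one condition holds more enriched cells. The Fisher test is two-sided
by default (point-probability rule); a one-sided variant is exposed. A
two-sided Wilcoxon rank-sum test on the per-cell scores is reported
alongside (exact enumeration when both groups have ≤ 8 cells and no ties,
otherwise the normal approximation with tie and continuity correction).

The `SignatureEnrichment` model class bundles scoring, CERNO, FDR, Fisher and
Wilcoxon into one `fit()`; its results object carries the per-cell tables and
a `summary()`.

### Calibration and a known property

The χ²(2N) null assumes the signature's relative ranks are continuous and
exchangeable. On sparse count matrices two realities break that: zeros share
one large average rank, and genes with different baseline expression occupy
nearly fixed rank bands across cells. Both push F *down*, so the per-cell
test is conservative on count data (we measure mean F ≈ 94 against 2N = 100
and a KS distance ≈ 0.2 from uniformity on the default simulator). The tests
therefore check the chi-square calibration where its assumptions hold — on
uniform-rank cells and on a continuous tie-free expression null (KS ≈ 0.01)
— and check the *downstream* guarantee that actually matters on count data:
the cross-condition Fisher comparison, whose two arms share whatever per-cell
miscalibration exists, holds its nominal level (measured ≤ 6% at α = 0.05
over 200 null simulations).

## Marker detection and composition shifts

One-vs-rest marker detection uses a Wilcoxon rank-sum test with limit
testing: a gene is tested only when detected (nonzero raw count) in at least
`min_pct` (default 0.25) of the cluster or of the rest, and when its average
log fold-change `ln(mean(expm1(x_in)) + 1) − ln(mean(expm1(x_out)) + 1)` is
at least 0.25 in magnitude (the reference toolchain's fold-change formula;
a simple difference of mean log expression is available via `fc_method`).
Reported p-values are Bonferroni-adjusted over the total gene count, the
reference toolchain's default; the number of tests actually run is recorded
so the limit-testing contract is assertable.

Cluster-composition shifts between conditions use the same Fisher exact
routine per cluster (in-cluster/out-of-cluster × condition) with BH
adjustment across clusters — a handful of tests, so the lighter correction.

## Synthetic data generator

`simulate_counts` draws a gamma–Poisson (negative-binomial) droplet
experiment: variance = μ + φ·μ² with dispersion φ (default 0.5, mid-range
for 10x data). Per-gene baselines are log-normal (σ = 1.0 across genes);
each of `n_clusters` (default 3) subpopulations multiplies a random 10% of
non-mitochondrial genes by log-normal modifiers (σ = 0.7), giving
marker-like structure; planted effects multiply signature members by
`exp(log_fold)` in one condition only. Per cell, a Beta(2, 38) mitochondrial
fraction (mean 5%, occasional cells past the 10% QC bound) is imposed
exactly in expectation on the `mt-` genes, and the expected depth is 2,000
counts times a log-normal size factor (σ = 0.35, about a 2× spread). The
default experiment is two conditions (shNC, shSELP) × 500 cells.

The generator reproduces the features downstream stages depend on —
overdispersion, library-size variation, mitochondrial content, cluster
structure, condition-specific signature shifts — and deliberately omits
doublets, ambient RNA, batch effects and UMI-level noise. Passing tests
therefore demonstrate correctness of the statistics under a clean
negative-binomial world, not robustness to those artifacts. All randomness
flows from a single integer seed through one generator stream, so identical
configurations are bit-identical, and every drawn parameter is returned as
ground truth (`SimTruth`) for oracle-based testing.

## Problem sizes used in the checks

The repeated-simulation studies use 2,000 genes × 500 cells per condition
with a 50-gene signature: 200 replicates for the null (type-I error) study
and 100 for the power study at a planted natural-log fold of 1.0. Exact-test
agreement is checked against exhaustive rational-arithmetic enumeration on
all 2×2 tables with margins ≤ 15. CERNO calibration uses 10,000 cells.

## Numerical conventions

Odds ratios use the sample estimate a·d/(b·c) (∞ when only the denominator
is zero, NaN for 0/0). Percentiles use linear interpolation. BH-adjusted
values are clipped to 1. Degenerate inputs fail loudly: empty QC results,
single-cell scaling, zero-total cells, signatures disjoint from the matrix,
groups smaller than a requested downsample, and clusters below three cells
all raise typed errors naming the offender.
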