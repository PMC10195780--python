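# Methods

## Scope and data model

`dhsatlas` consumes per-sample DHS peak calls (narrowPeak) plus a metadata
table and produces a batch-corrected per-cell-type accessibility matrix of
replicable sites. Internal coordinates are 0-based half-open throughout;
GFF3 export converts to 1-based inclusive. Chromosome names are normalised
to the `chr` prefix on read. The pipeline restricts to the human autosomes
(chr1–chr22) by default; the flag `autosomes_only=False` disables this.
Column 8 of narrowPeak (−log10 p) is the intensity source; −1 or a
truncated line falls back to signalValue (column 7), and to 0 if both are
absent, so parsed peaks always satisfy `neglog10_p ≥ 0`.

## Sample QC

Samples without a cell type or donor ID cannot participate in
replicate pairing and are dropped. Peak-count outliers are removed with
strict inequalities (< 40,000 or > 500,000), so counts exactly at a
threshold are retained. Counts are taken after autosome filtering, keeping
the counted universe identical to the clustered one. The two filters
commute; the QC report reconciles exactly with the input count.

## Peak alignment

Similarity between two peaks is the interval Jaccard index: intersection
length over union length in bp. Since only overlapping pairs receive
edges, the union equals the spanning interval of the two peaks whenever an
edge exists. Graphs are built per chromosome with a start-sorted sweep
(O(n log n + E)); connected components are extracted
(scipy.sparse.csgraph) and MCL runs per component, which is exact — MCL
cannot merge nodes across disconnected components — and keeps the dense
iteration small. Singleton components bypass MCL.

MCL parameters default to the algorithm's classical values: expansion 2,
inflation 2.0, self-loop weight 1.0, prune threshold 1e-5, convergence
tolerance 1e-6 (max entrywise change between successive iterates), at most
100 iterations. Components up to 400 nodes iterate densely; larger ones
use sparse arithmetic. Attractors are rows with a positive diagonal in the
limit matrix; attractors that attract each other form one attractor
system, and every node joins the system holding the largest share of its
column mass, ties to the lowest-index system, which converts MCL's
(possibly overlapping) attractor systems into a hard partition. Nodes are
canonically sorted (start, end, sample, significance) before matrix
construction, so the partition is invariant to input order. Lower
inflation yields coarser partitions; results are always reported together
with the inflation used. Non-convergence emits a warning and returns the
current partition flagged as such.

## Replication test

For each of K runs (default 10) one unordered replicate pair per eligible
cell type (≥ 2 replicates) is drawn uniformly; run k seeds its generator
with `seed XOR k`. Per cluster and run, paired cell types are tabulated
into a 2×2 table by presence of the cluster in the (first, second)
replicate, and scored with the Pearson chi-squared statistic without
continuity correction — χ²(1) under the null at the default table size
(T ≈ 161 cell types, where the normal approximation is accurate and a
continuity correction would miscalibrate). Degenerate tables are resolved
by design: all-present scores the Pearson supremum T (a constitutively
open site is maximal evidence of concordance, not a missing value);
all-absent scores 0; any other constant margin scores 0 because
association is unidentifiable there. The statistic is two-sided in
association: strongly anti-concordant tables also score high, a known and
accepted property since the combined filter acts on magnitude.

Per-run statistics are summed and referred to χ²(df = K); `p ≤ alpha`
(inclusive, default 0.05) defines the replicable set. Cell types with
exactly two replicates contribute the same pair — hence the same statistic
— in every run; the χ²(K) reference is used regardless. This is a known
approximation: reusing presence data across runs (only C(r, 2) distinct
pairs exist for r replicates) makes the per-run statistics positively
dependent, so with few replicates per cell type the combined null is
slightly overdispersed relative to χ²(K) and the realised type-I error
exceeds the nominal level somewhat (the acceptance script computes the
realised rate under 4 replicates per cell type; with many replicates it
converges to the nominal level). The maximum-likelihood degrees of freedom
of the combined statistic remain ≈ K.

`stability_analysis` asks how many runs are enough: it draws `max_runs`
(default 20) pairings, takes the replicable calls from combining all of
them as reference labels, and reports the ROC AUC of the first-N-runs
p-values against those labels for each N; AUC is undefined (NaN) when the
labels are all one class. The threshold-sensitivity helper
`count_in_window(results, lo, hi)` counts clusters with `lo < p ≤ hi`.

Calibration utilities (`simulate_null`, `fit_chisq_df`) simulate clusters
with no replication structure — one presence probability per cluster,
uniform in (0.2, 0.8), each replicate present independently — and fit
chi-squared degrees of freedom by maximum likelihood, solving
`mean(log x) = log 2 + digamma(df/2)` on the strictly positive statistics
(the discrete 2×2 statistic has a small atom at zero, ~0.3% of single-run
draws, which the continuous model cannot carry).

## Intensities and batch correction

Entry (cluster, sample) is the maximum −log10 p over the cluster's member
peaks from that sample (several same-sample peaks may share a cluster; the
most significant wins), 0 when the sample has no member. Columns are
scaled by their maximum rather than min–max over non-zeros, so 0 keeps
meaning "inaccessible" and the weakest detected peak is not conflated with
absence. Quantile normalization draws `min(10000, #non-zero)` non-zero
entries per sample without replacement (one generator seeded from the
master seed, consumed in column order), sorts them, and uses the rank-wise
mean of the sorted subsamples as the reference distribution — the standard
convention; when subsample sizes differ, quantile functions are averaged
on a common grid of the largest size. Sampled values map to the reference
at their rank (ties averaged so equal inputs map equally); remaining
non-zero values map through monotone piecewise-linear interpolation of the
sampled (value → normalized) pairs, clipped at the extremes; zeros pass
through untouched. Because the correction is rank-based it removes exactly
the class of monotone per-batch intensity distortions; it cannot separate
batch from biology when a batch confounds a cell type entirely.

Replicates collapse to cell types by the median with zeros included (an
absent site in most replicates should read as closed), even counts
averaging the two middle values. Clusters with median intensity strictly
greater than 0.25 in at least one cell type form the final matrix.

## Synthetic data generator

The generator emulates: cell types with 2–4 replicates (cycled), 2
generating centers assigned per replicate so every multi-replicate cell
type spans batches (as in real multi-center collections), true sites
placed without overlap on a 4 × 30 Mb genome, log-normal site lengths
(median 310 bp, σ = 0.35, the typical replicable-DHS length scale),
activity probability 0.3 per (site, cell type) with at least one active
cell type, boundary jitter with σ = 30 bp, base intensities uniform on
(3, 60) distorted per batch by a monotone power/scale transform
(scale 0.55, power 1.25 for the second center) with lognormal noise
(σ = 0.15), 10% per-replicate dropout, and 2,000 spurious single-sample
peaks per sample placed overlapping nothing. Everything derives from one
generator seeded by the master seed, so outputs are byte-identical per
seed.

What it does not emulate: read-level noise and peak-caller artifacts,
correlated activity between related cell types, copy-number or mappability
structure, overlapping/nested regulatory sites, and non-monotone batch
effects. Passing tests therefore demonstrate correctness of the alignment,
testing and correction machinery under the stated generative assumptions,
not performance on any particular real collection.

`evaluate_recovery` matches a cluster to a truth site by reciprocal
overlap ≥ 50% or center distance ≤ 100 bp (tolerance configurable);
precision and recall are reported over true sites, and the spurious pass
rate is the fraction of clusters matching only spurious entries that were
called replicable.

## Pipeline, seeds, reproducibility

Stages run in the order qc → cluster → reptest → normalize → export. Each
stage writes TSV/BED/GFF3 artifacts plus `manifest.json` with a
configuration hash and per-artifact SHA-256 checksums; a rerun with the
same configuration reuses stages whose artifacts verify, and any
configuration change invalidates them. One master seed drives pairing
draws and quantile subsampling; reruns are byte-identical.

## Problem sizes

The shipped test suite and the acceptance script run at desk scale: null
calibrations use 5,000–20,000 simulated clusters over 161 cell types; the
end-to-end check uses the default synthetic conditions (20 cell types,
59 samples, 2,000 true sites, 2,000 spurious peaks per sample — about
150,000 peaks), which the full pipeline processes in well under a minute
per stage on one core. The algorithms stream per chromosome and per
component, so nothing in the design caps the input at this scale.

## Known limitations

* The per-run statistic is a reconstruction of a replicate-concordance
  chi-squared test from its documented distributional properties; other
  constructions with the same null are conceivable.
* The χ²(K) reference ignores between-run dependence (see above); users
  testing collections where most cell types have exactly two replicates
  should expect a mildly anticonservative replicable set.
* Anti-concordant clusters are not truncated to zero and can pass the
  filter in pathological cases.
* GFF3/TSV exports are plain text; compression and tabix indexing are left
  to deployment.
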