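# dhsatlas

Build a quality-checked, cross-sample atlas of open-chromatin regions from
per-sample DNase-I hypersensitive site (DHS) peak calls.

Peak callers such as Hotspot or MACS identify DHS peaks in each sample
separately, so the "same" regulatory site has slightly different coordinates
— and no shared identity — across hundreds of samples from consortia like
ENCODE, Roadmap or Blueprint. `dhsatlas` is for anyone who needs a uniform
reference map of regulatory sites across many cell types: it aligns peaks
across samples, tests every aligned site for replicate concordance, removes
center (batch) effects from accessibility intensities, and emits a
per-cell-type accessibility matrix plus browser-ready tracks.

## Method

Given narrowPeak files and a metadata table (sample, cell type,
donor/replicate, generating center):

1. **Sample QC.** Drop samples lacking a cell type or donor ID, and
   peak-count outliers (strictly fewer than 40,000 or more than 500,000
   autosomal peaks by default).
2. **Cross-sample alignment.** Each peak is a node; overlapping peaks on
   the same chromosome are joined with weight
   `J(a,b) = |a ∩ b| / |a ∪ b|` (interval Jaccard). Each connected
   component is partitioned by Markov clustering (MCL; expansion 2,
   inflation 2.0, self-loops 1.0), yielding *DHS clusters* that partition
   the peak set.
3. **Replication test.** For each of K = 10 runs, one pair of replicates
   is drawn per cell type (among cell types with ≥ 2 replicates). For a
   cluster, the 2×2 table `(n11, n10, n01, n00)` counts paired cell types
   by presence of the cluster in each replicate, and the per-run statistic
   is the Pearson chi-squared

   `X² = T·(n11·n00 − n10·n01)² / ((n11+n10)(n01+n00)(n11+n01)(n10+n00))`,

   which is χ²(1) under the null; a cluster present in both replicates of
   all T cell types scores the Pearson maximum T. The K per-run statistics
   are summed and referred to χ²(df = K); clusters with p ≤ 0.05 are
   *replicable*.
4. **Intensity & batch correction.** Each (cluster, sample) entry gets the
   −log10 p-value of the sample's most significant member peak (0 =
   inaccessible), columns are scaled to [0, 1] by their maximum, and a
   subsampled quantile normalization (10,000 non-zero sites per sample,
   extended by monotone interpolation) forces a common intensity
   distribution, removing monotone center/batch distortions.
5. **Cell-type matrix.** Replicate samples are collapsed by the median
   (zeros included) and clusters with median intensity > 0.25 in at least
   one cell type form the final atlas, exported as TSV, BED6 and one GFF3
   track per cell type (1-based inclusive coordinates).

A fully seeded synthetic-data generator (`dhsatlas simulate`) produces
datasets with known ground truth — true sites with jittered boundaries,
batch-distorted intensities and replicate dropout, plus single-sample
spurious peaks — so the whole pipeline is testable without downloads.

## Worked example

```bash
dhsatlas simulate -o demo/sim --seed 1 --n-cell-types 6 \
    --n-true-sites 200 --spurious-per-sample 200
# 18 samples, 200 true sites, 3600 spurious peaks -> demo/sim

dhsatlas run-all -m demo/sim/metadata.tsv -o demo/run --min-peaks 100 --seed 1
# 18 samples, 3800 clusters, 182 replicable, 134 final sites -> demo/run

dhsatlas evaluate --run-dir demo/run --truth demo/sim/truth.tsv
# precision=1.0000 recall=0.9100 spurious_pass_rate=0.0000
# (182 replicable clusters, 182/200 true sites matched)
```

The 3,800 clusters are the 200 true sites (each aligned across samples into
one cluster) plus 3,600 spurious single-sample peaks. The replication test
passes 182 true-site clusters (91% recall; the rest lost replicate support
to dropout) and none of the spurious ones; 134 survive the final > 0.25
activity filter. `demo/run/replicable_matrix.tsv` holds the per-cell-type
matrix:

```
chrom   start    end      cluster_id  CT01   CT02  CT03  CT04  CT05  CT06
chr1    766959   767227   DHS0000037  0.000  0.0   0.0   0.0   0.0   0.275
chr1    3351723  3352063  DHS0000129  0.781  0.0   0.0   0.0   0.0   0.0
```

Each value is the batch-corrected median accessibility of that site in that
cell type (0 = closed). `demo/run/gff3/` holds one genome-browser track per
cell type with the same intensities.

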