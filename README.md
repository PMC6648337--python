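# hemamap

Tools for analysing gene-expression collections pooled from many studies
and platforms — the situation of every large public transcriptomics
compendium, where systematic technical differences between studies (batch
effects) compete with, and often overwhelm, the biological signal.

The package is aimed at computational biologists who want to

* **quantify** whether a clustering of a pooled collection separates
  biology or batches,
* **build** a frozen 2-D reference map (t-SNE + mean-shift clusters) of a
  curated collection,
* **add new samples** — including samples from a different measurement
  platform — to that map *without recomputing it*, and
* **compare** independently clustered datasets through gene sets when a
  joint embedding is impossible.

## The metrics and algorithms

**Batch-aware clustering metrics.** With cluster labels X and a categorical
covariate Y, let `NMI(X, Y) = MI(X, Y) / ((H(X) + H(Y)) / 2)` with empirical
label frequencies. Then

* `pNMI` = NMI(clusters, phenotypes) — biological separation, maximize;
* `eNMI` = NMI(clusters, study ids) — technical separation, minimize;
* `cNMI = (pNMI + (1 − eNMI)) / 2` — the combined trade-off score.

A sweep harness scores feature-selection settings (top-variance genes vs
principal components) by these metrics over many embedding/clustering
seeds. The classical trustworthiness/continuity embedding diagnostics are
included — they measure neighborhood preservation and are blind to batch
structure, which is precisely why the NMI metrics are needed.

**Reference maps.** 15% most-variable genes → Barnes-Hut t-SNE →
Gaussian-kernel mean-shift clustering (cluster count emerges from the
kernel bandwidth). The map — features, coordinates, clusters, centroids,
annotations, parameters — is serialized as a frozen, human-readable bundle.

**Locked-map remapping.** A new sample is embedded by minimizing
`KL(P ‖ Q)` where P are its perplexity-calibrated Gaussian affinities to
the reference samples and Q is the Student-t kernel against the *fixed*
reference coordinates. Only the new point moves; each new sample is
optimized independently, so results do not depend on batch composition and
the reference map is bit-identical before and after. For cross-platform
data the input distance is one minus Pearson correlation. New samples get
a nearest-centroid cluster, a majority-vote annotation, and correlation
diagnostics that flag samples the reference does not represent (e.g. a
subtype missing from the map).

**Gene-set correspondence.** Each source cluster yields two gene sets (top
20 positively / negatively cluster-correlated genes at p < 0.05). Target
samples are scored with a GSVA-style single-sample enrichment score
(kernel-CDF gene statistic, weighted KS random walk, `tau = 0.25`,
maximum-deviation score), significance is calibrated against 1000 permuted
gene sets of matched size, and a hypergeometric test locates clusters
enriched in significant samples (BH-adjusted p < 0.001 for a match).

**Reference-anchored normalization.** The cross-sample steps of a
quantile-normalization + median-polish pipeline are frozen (reference
quantile distribution; per-probe effects), so a new array is normalized
into the original data space one sample at a time — originals re-processed
through the frozen model reproduce their jointly-normalized values exactly.

## Worked example

```python
import hemamap as hm
from hemamap.qc import SweepSetting

# 1. simulate a 6-study collection with batch effects and 3 phenotypes
matrix, annotations, truth = hm.generate_collection(hm.SimulationDesign(), seed=11)

# 2. score feature-selection settings by the NMI metrics
report = hm.sweep(matrix, annotations,
                  [SweepSetting(name="var15", mode="variable_pct", pct=15, bandwidth=2.5),
                   SweepSetting(name="pc20", mode="pca", n_components=20, bandwidth=2.5)],
                  n_seeds=3, master_seed=0)
print(report[["setting", "pNMI_mean", "eNMI_mean", "cNMI_mean"]].round(3))

# 3. build a frozen reference map and remap two held-out samples
reference = hm.build_reference_map(matrix, annotations, hm.FeatureSelection(pct=15),
                                   perplexity=30, seed=0, bandwidth=2.5)
held = matrix.subset_samples(matrix.sample_ids[:2])
held = hm.ExpressionMatrix(held.values, held.gene_ids, ["new1", "new2"])
print(hm.remap_samples(reference, held).to_frame().round(3))
```

Output:

```
setting  pNMI_mean  eNMI_mean  cNMI_mean
  var15        1.0      0.000      1.000
   pc20        0.0      0.933      0.033

sample_id     x      y  cluster annotation  max_r  assigned_cluster_mean_r  margin  flagged
     new1 0.862 -3.478        2         P1    1.0                    0.768   0.213    False
     new2 0.985 -6.352        2         P1    1.0                    0.787   0.235    False
```

Reading it: clustering on 20 principal components separates the data by
*study* (eNMI 0.93, cNMI ≈ 0), while the 15%-variable-gene pipeline
recovers the planted phenotypes perfectly (pNMI 1.0, eNMI 0) — the sweep
makes the batch artifact visible and picks the right setting. The two
remapped duplicates land in their twins' cluster with maximum reference
correlation 1.0 and are not flagged by the representativeness diagnostics.

The same pipelines are available from the shell via the `hemamap` CLI
(`simulate`, `sweep`, `map`, `remap`, `genesets`, `score`, `match`,
`refnorm`); see `hemamap --help`.

## Layout

```
src/hemamap/
  types.py           domain types (ExpressionMatrix, ReferenceMap, ...)
  io.py              TSV/GMT/JSON readers and writers
  simulate.py        synthetic multi-study collections with known truth
  qc.py              NMI metrics, trustworthiness/continuity, sweep harness
  embed.py           variable-gene selection, PCA, t-SNE, mean-shift
  remap.py           locked-map remapping, assignment, diagnostics
  correspondence.py  cluster gene sets, GSVA-style scores, map matching
  refnorm.py         frozen quantile normalization and median polish
  cli.py             command-line interface
docs/methods.md      model and design notes
```
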