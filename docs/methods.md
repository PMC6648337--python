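# Methods

This note records the models, numerical choices and known limitations
behind `hemamap`, in the spirit of a methods supplement.

## Clustering quality metrics

Entropies and mutual information use natural logarithms; NMI is a ratio,
so the base cancels — stated to avoid bits/nats confusion. NMI normalizes
by the arithmetic mean of the two entropies. Degenerate cases: if exactly
one label vector is constant the score is 0 (a single cluster carries no
information about the other labeling); if both are constant, the two
trivial one-block partitions coincide and the score is defined as 1,
avoiding 0/0.

pNMI drops samples without an annotated phenotype pairwise; eNMI keeps all
samples (study of origin is always known). This asymmetry is deliberate:
phenotype annotation is typically sparse in public collections, study
identity is not. Whether eNMI should instead be restricted to annotated
samples is exposed as a caller choice (pass the restricted vectors).

cNMI = (pNMI + (1 − eNMI)) / 2 weighs biological and technical separation
equally. Its value range is dataset-specific; the useful signal is the
*comparison* between settings, and eNMI exceeding pNMI is a general alarm
that batch structure dominates.

Trustworthiness and continuity use the standard rank-penalty form with
neighborhood size k (default 12, always reported alongside the value):
trustworthiness penalizes embedding neighbors that are not original-space
neighbors, weighted by original-space rank excess; continuity is the
mirror image. Both are checked in the test suite against an independent
brute-force rank enumeration and against scikit-learn's implementation.

## The sweep harness

"Settings" combine a feature-selection mode (top-p% variance genes, or k
principal components), t-SNE parameters, and the mean-shift bandwidth.
Each setting is run under `n_seeds` seeds of the embedding (default 100;
tests and the acceptance script use 10 to stay at desk scale) and the
metric means and SDs are reported; all settings see the same seed
sequence, so per-seed comparisons are paired.

## Synthetic collections

The generator emulates a pooled multi-study collection:

    x_gi = mu_g + delta * [g in module(phenotype(i))] + b_{g, study(i)} + eps_gi

with gene baselines mu_g ~ N(7, 1.5²) (log2 microarray intensity scale),
disjoint phenotype modules of `module_size` genes up-shifted by `delta`
(default 2 log2 units), batch shifts b ~ N(0, sigma_b²) drawn per
(gene, study) (default sigma_b = 0.6; a coarser per-study scalar mode is
available), and iid noise (sigma_e = 0.5). Studies are balanced across
phenotypes by default; full confounding is an option.

The defaults are chosen to reproduce the regime that motivates the NMI
metrics: the batch shift is *smaller per gene* than the biological effect,
but it touches every gene, so summed over thousands of genes it dominates
inter-sample distances (with the defaults, squared batch distance between
studies ≈ 2·2000·0.36 ≈ 1400 versus ≈ 480 for biology). Consequently
clustering on all genes or on top principal components groups samples by
study, while the most-variable genes — whose per-gene variance is
biology-dominated — recover the phenotypes. An iid per-gene batch model
with per-gene batch noise *larger* than delta would make every
feature-selection strategy fail and does not correspond to how array batch
effects behave; this aggregate-dominance regime is the package's modelling
choice.

The optional "platform" distortion is a single global monotone map
f(x) = shift + scale·x + quad·x² (monotonicity validated over the data
range). A global transform preserves within-sample gene ranking exactly —
the property that makes correlation-distance remapping work — whereas
per-gene distortions would scramble cross-gene ranks and model a different
(probe-specific) phenomenon that is out of scope here.

What the generator does **not** model: probe-level microarray physics,
dropout/zero inflation, correlated gene-gene structure beyond the planted
modules, outlier samples, or label noise. Passing tests on these
simulations therefore demonstrates correctness of the algorithms under
the stated signal model, not performance on any particular real dataset.

An RNA-seq mode draws negative-binomial counts around 2^x (gamma shape 10)
and returns log2(count+1), to exercise the Poisson-kernel scoring path.

## Reference maps

Variance selection keeps ceil(p% · n_genes) genes by n−1-denominator
variance on the log scale; ties break by gene id for platform-independent
determinism, and survivors keep their original row order.

t-SNE is delegated to scikit-learn's Barnes-Hut implementation with PCA
initialization, making maps deterministic given the seed. Perplexity
defaults to 30 and must be < (n−1)/3.

Mean-shift uses a Gaussian kernel with the stated bandwidth; every point
ascends the density via iterated kernel-weighted averaging (tolerance
1e-4, max 300 iterations), converged modes within bandwidth/2 merge, and
clusters are renumbered 1..K by decreasing size (ties by mode
coordinates), making labels invariant to input order up to renaming.
Centroids are means of member coordinates. The bandwidth is on the scale
of the embedding: for the maps produced here (extents of roughly 20–50
units) 2.5 gives phenotype-level clusters and 1.5 a finer partition; the
bandwidth-to-extent ratio, not the absolute number, is what transfers
between maps.

## Locked-map remapping

Input affinities of a new sample over the n reference samples use a
Gaussian kernel on squared distances — squared Euclidean, or squared
(1 − Pearson r) under the correlation metric, so both metrics enter the
kernel identically — with the bandwidth binary-searched so the
distribution's Shannon perplexity hits the target (tolerance 1e-6).
The affinity vector is normalized to 1 with no symmetrization: the
reverse conditional is undefined when reference affinities are frozen.

Each new point minimizes KL(P‖Q) against the fixed reference coordinates
(Student-t kernel) by momentum gradient descent: 500 iterations, learning
rate 100, momentum 0.5 switching to 0.8 at iteration 250, no early
exaggeration (P is fixed and unimodal per point). Two choices proved
important in practice:

* **Deterministic initialization** at the affinity-weighted mean of the
  top-10 reference coordinates (Gaussian random initialization is retained
  as an option). This starts the point in the right basin and makes
  results seed-independent by default.
* **Step capping** at 2% of the map extent per iteration. A single free
  point against a fixed field has no counteracting forces; an uncapped
  step can catapult it into the far field where gradients vanish.

Gradients are evaluated exactly: each new point interacts only with the
n reference points, so a step is O(n) and a tree approximation has nothing
to accelerate at these problem sizes. The Barnes-Hut accuracy parameter
theta (0.3 by convention for remapping) is recorded in the result for
provenance.

New samples must cover ≥ 90% of the map features (configurable); missing
features are imputed with the reference mean. Cluster assignment is
nearest centroid (ties to the lowest cluster id); annotation transfer is
majority vote over the cluster's annotated reference members, with
"ambiguous" on ties and "unlabeled" for clusters with no annotated member.

**Representativeness diagnostics.** Per new sample: the maximum Pearson
correlation to any reference sample (max_r), the mean correlation to the
assigned cluster, and the margin over the best other cluster. The default
warning threshold for max_r is data-adaptive — the 5th percentile of the
reference samples' own leave-one-out maximum correlations — because
absolute correlation levels vary strongly between datasets; the margin
threshold defaults to 0. A sample whose best match is worse than what 95%
of reference samples achieve against their own map is unlikely to be
represented; in the missing-subtype simulations this flags essentially all
foreign samples at a ~5% false-positive rate on genuine members.

## Gene-set correspondence

Cluster gene sets: genes are Pearson-correlated with the binary cluster
indicator; p-values use the t transform with n−2 df, two-sided (the
direction of the correlation is what assigns a gene to the up or down
set, so a one-sided test would be redundant). Among genes with p below
0.05, the 20 most positive form the `_UP` set and the 20 most negative the
`_DN` set; fewer significant genes give a smaller set.

Single-sample scores follow the GSVA construction: per-gene kernel CDF
statistic across samples (Gaussian kernel with bandwidth SD/4; Poisson
kernel with rate x+0.5 for count data), per-sample ranking of genes by the
statistic, symmetric rank weights |p/2 − position + ½| raised to
tau = 0.25, and a weighted KS random walk (in-set increments normalized by
the set's total weight, out-of-set decrements 1/(p−m)). The score is the
walk deviation of largest magnitude with its sign (ties resolve positive);
the max-minus-min variant is available. The walk is linear between in-set
genes, so its extrema are evaluated only at in-set positions — O(m log m)
per set per sample — and the test suite verifies exact agreement with a
full O(p) enumeration. Sets with fewer than 5 or more than 500 expressed
genes are skipped with a warning.

Empirical significance: for each needed size bin (each size 5–20 is its
own bin, then 25, 30, 40, 50, 75, 100, 200, 300, 400, 500; a set maps to
the nearest bin, ties upward), 1000 random gene sets are drawn and scored.
The per-(sample, set) p-value is twice the same-side tail count divided by
the permutation count, capped at 1 — the doubling makes the null
distribution of p uniform on (0,1), which the calibration test verifies by
KS. A score beyond every permutation yields p = 0; BH adjustment is
applied to these raw empirical p-values across the whole table (so such
scores remain callable at any threshold), and a companion
(count+1)/(n+1) estimator is reported for analyses that need a nonzero
floor. BH correction spans the whole sample × set table rather than being
applied per cluster.

Cluster-level enrichment of significant samples uses the hypergeometric
upper tail; cross-map matching calls a target sample significant when its
BH-adjusted p is below alpha = 0.001 *and* the score sign matches the
set's direction, and the best match of a source cluster is the target
cluster with the smallest adjusted enrichment p below alpha. The
cross-dataset consistency rule keeps sets with the same correlation sign
in both datasets, nominal p < 0.05 in the smaller and adjusted p < 0.001
in the larger.

## Reference-anchored normalization

The frozen model stores (i) the reference quantile distribution — the
across-sample mean of sorted per-sample vectors, the standard choice —
and (ii) per-gene median-polish decompositions of the quantile-normalized
original data: a grand effect per gene and a full fitted baseline per
probe (grand effect + probe deviation). A new background-corrected sample
is quantile-mapped (value at rank k becomes reference quantile k; tied
input values receive the mean of their tied reference quantiles) and then
summarized per gene as

    expression_g = overall_g + median_{p in g}(value_p − probe_effect_p).

Storing the *full* probe baseline is what makes this formula correct: the
inner difference isolates the sample's deviation from the reference
baseline, and the median over a gene's probes is robust to single-probe
artifacts. Because the final sweep of the median polish zeroes the
residuals' column medians, original samples pushed through the frozen
model reproduce their jointly-normalized values exactly (the test suite
asserts < 1e-10); this is the guarantee that makes one-at-a-time
normalization of new arrays consistent with the frozen collection.
Appending a genuinely new sample and re-running the whole pipeline from
scratch perturbs the joint artifacts at the 1/(n_samples+1) level, so
from-scratch co-normalization and the frozen path agree to well under the
measurement noise but not exactly; the probe-collection simulator
(per-sample intensity shifts, probe affinities, 0.1 log2 measurement
noise) quantifies this in the tests.

Median polish runs at most 10 sweeps with a 1% relative tolerance on the
total absolute residual; only the frozen effects are consumed downstream.
RMA background correction and clinical-array bias correction are outside
this module: inputs are assumed background-corrected, since background
correction needs no inter-sample information.

## Reproducibility

Every stochastic stage takes an explicit seed; derived seeds come from
`numpy.random.SeedSequence` spawning. Reference maps serialize to a JSON
manifest plus TSV payloads with round-trip-exact floats, so saving the
same map twice is byte-identical — the property used to verify that
remapping never touches the frozen map.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so each
experiment still has clear statistical resolution: collections of 300–2000
genes and 60–250 samples, 10-seed sweeps and replicate sets, 1000
permutations per null bin, 200 null sets for calibration. The pipelines
scale to repository-size collections (the heavy steps are t-SNE, O(p·n²)
kernel-CDF statistics, and permutation scoring at O(n·m log m) per set).

## Known limitations

* Mean-shift is quadratic in sample count per iteration; fine for maps of
  up to a few thousand samples, slow beyond.
* The remapping diagnostics use Pearson correlation over map features
  only; a sample can correlate well yet sit between clusters (the margin
  column exists for exactly this case).
* GSVA-style scores depend on the sample composition of the target matrix
  (the kernel CDF is estimated across samples), so scoring a sample inside
  two different cohorts gives different values; cross-map matching is
  therefore done at the cluster level, not the sample level.
* The exact mean-shift variant and merge rule of other published
  implementations differ in detail; the choices here (Gaussian kernel,
  bandwidth/2 merge radius) are explicit and configurable, not claims
  about any external package.
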