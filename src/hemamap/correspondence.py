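"""Gene-set correspondence between independently clustered datasets.

Two expression collections that cannot be embedded jointly can still be
compared through gene sets: each cluster of the source map is summarized by
its top up- and down-correlated genes, every sample of the target dataset
is scored for those sets with a single-sample enrichment score (a weighted
Kolmogorov-Smirnov random walk over genes ranked by a kernel-CDF
expression statistic), score significance is calibrated against permuted
gene sets of matched size, and a hypergeometric test asks whether the
significant samples concentrate in a target cluster. The best-matching
target cluster per source cluster is the one with the smallest adjusted
enrichment p-value below the significance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, poisson
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GeneSet, GeneSetCollection

log = logging.getLogger(__name__)

#: gene-set size limits after intersection with the expression matrix
MIN_SET_SIZE = 5
MAX_SET_SIZE = 500

#: permutation-null size bins: each size 5-20 is its own bin, then sparser
DEFAULT_SIZE_BINS = tuple(range(5, 21)) + (25, 30, 40, 50, 75, 100, 200, 300, 400, 500)


# ---------------------------------------------------------------------------
# cluster gene sets
# ---------------------------------------------------------------------------

def _pearson_to_indicator(values: np.ndarray, indicator: np.ndarray):
    """Per-gene Pearson r against a binary vector, with two-sided t-test p."""
    n = indicator.size
    y = indicator - indicator.mean()
    ny = np.linalg.norm(y)
    xc = values - values.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(xc, axis=1)
    nx_safe = np.where(nx == 0, np.inf, nx)
    r = (xc @ y) / (nx_safe * ny)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    from scipy.stats import t as t_dist
    p = 2.0 * t_dist.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def cluster_genesets(matrix: ExpressionMatrix, labels, n_top: int = 20,
                     p_threshold: float = 0.05, prefix: str = "") -> GeneSetCollection:
    """Derive up/down gene sets per cluster from gene-cluster correlation.

    For each cluster, every gene is correlated (Pearson) with the binary
    cluster indicator; among genes with a significant two-sided p-value
    (t-transform with n-2 df) the ``n_top`` most positively correlated form
    the cluster's ``_UP`` set and the ``n_top`` most negatively correlated
    its ``_DN`` set. Fewer significant genes give a smaller set; empty sets
    are omitted.
    """
    labels = np.asarray(labels)
    if labels.size != matrix.n_samples:
        raise ValueError("labels must align with matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters to derive cluster gene sets")
    small = uniq[counts < 3]
    if small.size:
        raise ValueError(f"cluster {small[0]} has fewer than 3 samples")

    genes = np.asarray(matrix.gene_ids, dtype=object)
    collection = GeneSetCollection()
    for c in uniq:
        indicator = (labels == c).astype(float)
        r, p = _pearson_to_indicator(matrix.values, indicator)
        sig = p < p_threshold
        for direction, suffix in (("up", "_UP"), ("down", "_DN")):
            mask = sig & (r > 0 if direction == "up" else r < 0)
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            key = -r[idx] if direction == "up" else r[idx]
            order = idx[np.lexsort((genes[idx], key))][:n_top]
            collection.add(GeneSet(name=f"{prefix}C{c}{suffix}",
                                   genes=[str(g) for g in genes[order]],
                                   direction=direction))
    return collection


# ---------------------------------------------------------------------------
# GSVA-style single-sample enrichment
# ---------------------------------------------------------------------------

class _GsvaEngine:
    """Precomputed machinery to score many gene sets on one matrix.

    The per-gene kernel-CDF statistic, the per-sample gene ranking and the
    symmetric rank weights are computed once; individual sets are then
    scored with an O(m log m) evaluation of the random-walk extrema at the
    set-gene positions (the walk is linear between in-set genes, so its
    extrema occur immediately after an in-set increment or just before one).
    """

    def __init__(self, matrix: ExpressionMatrix, tau: float = 0.25,
                 kcdf: str = "gaussian", mx_diff: bool = False):
        if kcdf not in ("gaussian", "poisson"):
            raise ValueError(f"unknown kcdf {kcdf!r}")
        self.matrix = matrix
        self.tau = float(tau)
        self.kcdf = kcdf
        self.mx_diff = bool(mx_diff)
        self.p = matrix.n_genes
        self.n = matrix.n_samples
        z = _kernel_cdf_statistic(matrix.values, kcdf)
        # position of each gene in each sample's decreasing-z order (0-based);
        # ties broken by gene index (stable)
        order = np.argsort(-z, axis=0, kind="stable")      # p x n
        self.positions = np.empty_like(order)
        rows = np.arange(self.p)
        for j in range(self.n):
            self.positions[order[:, j], j] = rows
        # symmetric rank weight by position: extremes heavy, middle light
        j = np.arange(1, self.p + 1, dtype=float)
        self.w_tau = np.abs(self.p / 2.0 - j + 0.5) ** self.tau
        self.gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}

    def score_indices(self, idx: np.ndarray) -> np.ndarray:
        """Enrichment score per sample for the gene set given by row indices."""
        m = idx.size
        pos = np.sort(self.positions[idx, :], axis=0)      # m x n, 0-based
        w = self.w_tau[pos]
        cumw = np.cumsum(w, axis=0)
        total = cumw[-1, :]
        k = np.arange(1, m + 1, dtype=float)[:, None]
        denom = float(self.p - m)
        # walk value right after the k-th in-set gene, and just before it
        nu_after = cumw / total - (pos + 1.0 - k) / denom
        nu_before = (cumw - w) / total - (pos - (k - 1.0)) / denom
        max_pos = np.maximum(nu_after.max(axis=0), 0.0)
        min_neg = np.minimum(nu_before.min(axis=0), 0.0)
        if self.mx_diff:
            return max_pos + min_neg
        return np.where(max_pos >= -min_neg, max_pos, min_neg)

    def score_set(self, gene_set: GeneSet) -> np.ndarray | None:
        idx = np.array([self.gene_index[g] for g in gene_set.genes
                        if g in self.gene_index], dtype=int)
        if not (MIN_SET_SIZE <= idx.size <= MAX_SET_SIZE):
            log.warning("gene set %s has %d expressed genes (outside %d-%d); skipped",
                        gene_set.name, idx.size, MIN_SET_SIZE, MAX_SET_SIZE)
            return None
        return self.score_indices(idx)

    def effective_size(self, gene_set: GeneSet) -> int:
        return sum(1 for g in gene_set.genes if g in self.gene_index)


def _kernel_cdf_statistic(values: np.ndarray, kcdf: str,
                          chunk: int = 256) -> np.ndarray:
    """Per-gene kernel estimate of the expression CDF at each observation.

    Gaussian kernel (bandwidth = per-gene SD / 4) for continuous log-scale
    data; Poisson kernel (rate = observed count + 0.5) for count-derived
    data. Returns a genes x samples matrix of values in (0, 1).
    """
    p, n = values.shape
    z = np.empty_like(values, dtype=float)
    for start in range(0, p, chunk):
        block = values[start:start + chunk]                # b x n
        if kcdf == "gaussian":
            h = block.std(axis=1, ddof=1) / 4.0
            h = np.maximum(h, 1e-8)[:, None, None]
            diff = (block[:, :, None] - block[:, None, :]) / h
            z[start:start + chunk] = norm.cdf(diff).mean(axis=2)
        else:
            lam = block[:, None, :] + 0.5
            z[start:start + chunk] = poisson.cdf(block[:, :, None], lam).mean(axis=2)
    return z


def gsva_scores(matrix: ExpressionMatrix, sets: GeneSetCollection,
                tau: float = 0.25, mx_diff: bool = False,
                kcdf: str = "gaussian") -> pd.DataFrame:
    """Single-sample enrichment scores (samples x sets).

    Positive scores indicate increased, negative decreased expression of the
    set. With ``mx_diff`` False (the default here) the score is the walk
    deviation of largest magnitude, sign retained; ties between equal
    positive and negative deviations resolve positive. Sets with fewer than
    5 or more than 500 expressed genes are skipped with a warning.
    """
    engine = _GsvaEngine(matrix, tau=tau, kcdf=kcdf, mx_diff=mx_diff)
    columns = {}
    for gene_set in sets:
        scores = engine.score_set(gene_set)
        if scores is not None:
            columns[gene_set.name] = scores
    return pd.DataFrame(columns, index=list(matrix.sample_ids))


# ---------------------------------------------------------------------------
# permutation nulls and empirical p-values
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Scores with permutation-based significance.

    ``empirical_p`` follows the count-of-more-extreme / total rule, doubled
    for two-sidedness (positive scores against the null's upper tail,
    negative against the lower); it can be exactly 0, and ``adjusted_p`` is
    its BH adjustment (a score beyond every permutation stays callable at
    any threshold). ``empirical_p_stable`` is the (count+1)/(n+1) companion
    estimator, never 0, for downstream analyses that need a nonzero floor.
    """

    scores: pd.DataFrame
    empirical_p: pd.DataFrame
    empirical_p_stable: pd.DataFrame
    adjusted_p: pd.DataFrame
    params: dict


def _nearest_bin(size: int, bins) -> int:
    bins = sorted(bins)
    best = min(bins, key=lambda b: (abs(b - size), -b))  # ties upward
    return best


def empirical_pvalues(matrix: ExpressionMatrix, sets: GeneSetCollection,
                      scores: pd.DataFrame | None = None,
                      n_permutations: int = 1000, seed: int = 0,
                      size_bins=DEFAULT_SIZE_BINS, tau: float = 0.25,
                      mx_diff: bool = False, kcdf: str = "gaussian") -> EnrichmentResult:
    """Empirical p-values against permuted gene sets of matched size.

    For each size bin actually needed, ``n_permutations`` random gene sets
    of that size are drawn from the matrix's gene universe and scored; each
    real set is compared per sample against its bin's null distribution.
    Each set maps to the nearest bin (ties toward the larger bin).
    Deterministic given ``seed``.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    if n_permutations < 100:
        log.warning("n_permutations=%d is low; empirical p-values will be coarse",
                    n_permutations)
    engine = _GsvaEngine(matrix, tau=tau, kcdf=kcdf, mx_diff=mx_diff)
    if scores is None:
        scores = gsva_scores(matrix, sets, tau=tau, mx_diff=mx_diff, kcdf=kcdf)

    bin_of = {}
    for gene_set in sets:
        if gene_set.name not in scores.columns:
            continue
        bin_of[gene_set.name] = _nearest_bin(engine.effective_size(gene_set),
                                             size_bins)

    rng = np.random.default_rng(seed)
    nulls: dict[int, np.ndarray] = {}
    for b in sorted(set(bin_of.values())):
        null = np.empty((engine.n, n_permutations))
        for t in range(n_permutations):
            idx = rng.choice(engine.p, size=b, replace=False)
            null[:, t] = engine.score_indices(idx)
        nulls[b] = null

    emp = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    stable = emp.copy()
    for name in scores.columns:
        null = nulls[bin_of[name]]
        s = scores[name].to_numpy()
        upper = (null >= s[:, None]).sum(axis=1)
        lower = (null <= s[:, None]).sum(axis=1)
        tail = np.where(s >= 0, upper, lower)
        emp[name] = np.minimum(1.0, 2.0 * tail / n_permutations)
        stable[name] = np.minimum(1.0, 2.0 * (tail + 1) / (n_permutations + 1))

    flat = emp.to_numpy().ravel()
    adj = multipletests(flat, method="fdr_bh")[1].reshape(stable.shape)
    adjusted = pd.DataFrame(adj, index=stable.index, columns=stable.columns)
    return EnrichmentResult(
        scores=scores, empirical_p=emp, empirical_p_stable=stable,
        adjusted_p=adjusted,
        params={"tau": tau, "mx_diff": mx_diff, "kcdf": kcdf,
                "n_permutations": n_permutations,
                "size_bins": list(size_bins), "seed": seed},
    )


# ---------------------------------------------------------------------------
# cluster-level enrichment and cross-map matching
# ---------------------------------------------------------------------------

def cluster_enrichment(significant: pd.DataFrame, clusters) -> pd.DataFrame:
    """Hypergeometric enrichment of significant samples within clusters.

    ``significant`` is a samples x sets boolean frame. For each (set,
    cluster): upper-tail probability of drawing at least the observed
    number of significant samples in a cluster-sized draw from the
    collection, given the set's total significant count. BH adjustment is
    applied across the whole table.
    """
    clusters = np.asarray(clusters)
    if clusters.size != len(significant):
        raise ValueError("clusters must align with the rows of `significant`")
    total = len(significant)
    rows = []
    for name in significant.columns:
        flags = significant[name].to_numpy(dtype=bool)
        n_sig = int(flags.sum())
        for c in np.unique(clusters):
            members = clusters == c
            size = int(members.sum())
            overlap = int((flags & members).sum())
            p = float(hypergeom.sf(overlap - 1, total, n_sig, size))
            rows.append({"set": name, "cluster": c, "cluster_size": size,
                         "n_significant": n_sig, "overlap": overlap,
                         "fraction": overlap / size if size else 0.0,
                         "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["adj_p"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


def _source_cluster_of(set_name: str) -> str:
    for suffix in ("_UP", "_DN"):
        if set_name.endswith(suffix):
            return set_name[: -len(suffix)]
    return set_name


def match_maps(source_sets: GeneSetCollection, target_matrix: ExpressionMatrix,
               target_clusters, alpha: float = 0.001,
               n_permutations: int = 1000, seed: int = 0, tau: float = 0.25,
               kcdf: str = "gaussian") -> pd.DataFrame:
    """Match source-map clusters to target-map clusters via gene sets.

    Pipeline: score the target samples for each source cluster gene set,
    calibrate empirical p-values by permutation, call a sample significant
    when its adjusted p-value is below ``alpha`` and the score sign matches
    the set direction, then test hypergeometric enrichment of significant
    samples per target cluster. The best match of a source cluster is the
    target cluster with the smallest adjusted enrichment p-value below
    ``alpha`` (no match if none qualifies).
    """
    result = empirical_pvalues(target_matrix, source_sets,
                               n_permutations=n_permutations, seed=seed,
                               tau=tau, kcdf=kcdf)
    direction = {s.name: s.direction for s in source_sets}
    significant = result.adjusted_p < alpha
    for name in significant.columns:
        d = direction.get(name, "unsigned")
        if d == "up":
            significant[name] &= result.scores[name] > 0
        elif d == "down":
            significant[name] &= result.scores[name] < 0

    table = cluster_enrichment(significant, target_clusters)
    table["source_cluster"] = table["set"].map(_source_cluster_of)
    table["best_match"] = False
    for source, grp in table.groupby("source_cluster"):
        qualified = grp[grp["adj_p"] < alpha]
        if len(qualified):
            best = qualified.sort_values(["adj_p", "p", "cluster"]).index[0]
            table.loc[best, "best_match"] = True
    return table


def consistent_enrichment(results_small: pd.DataFrame,
                          results_large: pd.DataFrame,
                          p_small: float = 0.05,
                          alpha_large: float = 0.001) -> list[str]:
    """Cross-dataset consistency filter for per-set cluster correlations.

    Keeps the sets whose correlation to the corresponding cluster has the
    same sign in both datasets, with nominal p < ``p_small`` in the smaller
    dataset and BH-adjusted p < ``alpha_large`` in the larger one.
    ``results_small`` needs columns (set, cluster, correlation, p);
    ``results_large`` needs (set, cluster, correlation, adj_p). Sets whose
    cluster ids disagree between the tables raise an error.
    """
    for frame, cols in ((results_small, {"set", "cluster", "correlation", "p"}),
                        (results_large, {"set", "cluster", "correlation", "adj_p"})):
        missing = cols - set(frame.columns)
        if missing:
            raise ValueError(f"result table missing columns: {sorted(missing)}")
    merged = results_small.merge(results_large, on="set",
                                 suffixes=("_small", "_large"))
    mismatched = merged[merged["cluster_small"] != merged["cluster_large"]]
    if len(mismatched):
        raise ValueError(
            f"unmatched cluster ids for sets: {list(mismatched['set'])[:5]}"
        )
    keep = merged[
        (np.sign(merged["correlation_small"]) == np.sign(merged["correlation_large"]))
        & (merged["p"] < p_small)
        & (merged["adj_p"] < alpha_large)
    ]
    return list(keep["set"])
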