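"""Clustering and embedding quality metrics for heterogeneous collections.

The NMI family quantifies what a clustering of a pooled multi-study
collection actually separates. With cluster labels X and a categorical
covariate Y,

    NMI(X, Y) = MI(X, Y) / ((H(X) + H(Y)) / 2)

where MI and the Shannon entropies H are computed from empirical label
frequencies (natural log; NMI is scale-free so the base cancels).

* pNMI — NMI between clusters and phenotype labels: high means the
  clustering separates biology (maximize).
* eNMI — NMI between clusters and study/experiment identifiers: high means
  the clustering separates batches (minimize).
* cNMI = (pNMI + (1 - eNMI)) / 2 — the combined trade-off score.

Also provided: the rank-based trustworthiness/continuity diagnostics of a
low-dimensional embedding, and :func:`sweep`, the harness that scores
feature-selection / embedding / clustering settings by these metrics over
many seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .types import ExpressionMatrix


# ---------------------------------------------------------------------------
# label handling
# ---------------------------------------------------------------------------

def _as_labels(x) -> np.ndarray:
    arr = np.asarray(x, dtype=object).ravel()
    if arr.size == 0:
        raise ValueError("empty label vector")
    return arr


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v == ""


def entropy(x) -> float:
    """Shannon entropy (nats) of the empirical label distribution."""
    arr = _as_labels(x)
    _, counts = np.unique(arr.astype(str), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(x, y) -> float:
    """Empirical mutual information (nats) from the joint contingency table."""
    ax, ay = _as_labels(x), _as_labels(y)
    if ax.size != ay.size:
        raise ValueError(f"length mismatch: {ax.size} vs {ay.size}")
    _, xi = np.unique(ax.astype(str), return_inverse=True)
    _, yi = np.unique(ay.astype(str), return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(table, (xi, yi), 1.0)
    pxy = table / table.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = (pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])).sum()
    return float(max(mi, 0.0))


def nmi(x, y) -> float:
    """NMI with arithmetic-mean normalization, in [0, 1].

    Degenerate cases: if exactly one vector is constant the score is 0 (a
    single cluster carries no information); if both are constant the two
    trivial one-block partitions are identical and the score is 1.
    """
    ax, ay = _as_labels(x), _as_labels(y)
    if ax.size != ay.size:
        raise ValueError(f"length mismatch: {ax.size} vs {ay.size}")
    hx, hy = entropy(ax), entropy(ay)
    if hx == 0.0 and hy == 0.0:
        return 1.0
    if hx == 0.0 or hy == 0.0:
        return 0.0
    value = mutual_information(ax, ay) / ((hx + hy) / 2.0)
    return float(min(max(value, 0.0), 1.0))


def pnmi(clusters, phenotypes) -> float:
    """NMI between cluster assignment and phenotype labels (maximize).

    Samples without an annotated phenotype are dropped pairwise before the
    computation; an error is raised if no annotated sample remains.
    """
    ac, ap = _as_labels(clusters), _as_labels(phenotypes)
    if ac.size != ap.size:
        raise ValueError(f"length mismatch: {ac.size} vs {ap.size}")
    keep = np.array([not _is_missing(v) for v in ap])
    if not keep.any():
        raise ValueError("no sample has an annotated phenotype")
    return nmi(ac[keep], ap[keep])


def enmi(clusters, studies) -> float:
    """NMI between cluster assignment and study identifiers (minimize)."""
    return nmi(clusters, studies)


def cnmi(pnmi_value: float, enmi_value: float) -> float:
    """Combined metric (pNMI + (1 - eNMI)) / 2, increasing in pNMI."""
    for name, v in (("pnmi_value", pnmi_value), ("enmi_value", enmi_value)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return (pnmi_value + (1.0 - enmi_value)) / 2.0


# ---------------------------------------------------------------------------
# trustworthiness / continuity
# ---------------------------------------------------------------------------

def _neighbor_ranks(dist: np.ndarray) -> np.ndarray:
    """ranks[i, j] = rank of j among i's neighbors (1 = nearest, self excluded)."""
    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    ranks = np.empty((n, n), dtype=int)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, n + 1)[None, :]
    return ranks


def _rank_penalty(rank_source: np.ndarray, rank_target: np.ndarray, k: int) -> float:
    """Shared kernel of trustworthiness/continuity.

    Penalizes points within the k-NN of the *target* space but outside the
    k-NN of the *source* space, weighted by their source-space rank excess.
    """
    n = rank_source.shape[0]
    if not (1 <= k < (n - 1) / 2):
        raise ValueError(f"k must satisfy 1 <= k < (n-1)/2, got k={k}, n={n}")
    intruders = (rank_target <= k) & (rank_source > k)
    penalty = float(((rank_source - k) * intruders).sum())
    norm = 2.0 / (n * k * (2.0 * n - 3.0 * k - 1.0))
    return 1.0 - norm * penalty


def _pairwise(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return squareform(pdist(x, metric="euclidean"))


def trustworthiness(high_dim, low_dim, k: int = 12) -> float:
    """Are embedding neighborhoods trustworthy?

    Penalizes points that appear among the k nearest neighbors in the 2-D
    embedding but are not neighbors in the original space, weighted by
    their original-space rank. 1.0 = no spurious neighbors. ``high_dim`` is
    samples x features (an ExpressionMatrix is transposed internally);
    ``low_dim`` is the samples x 2 embedding.
    """
    if isinstance(high_dim, ExpressionMatrix):
        high_dim = high_dim.values.T
    return _rank_penalty(_neighbor_ranks(_pairwise(high_dim)),
                         _neighbor_ranks(_pairwise(low_dim)), k)


def continuity(high_dim, low_dim, k: int = 12) -> float:
    """Are original neighborhoods preserved? The symmetric counterpart of
    trustworthiness: penalizes original-space neighbors missing from the
    embedding neighborhood, weighted by embedding rank."""
    if isinstance(high_dim, ExpressionMatrix):
        high_dim = high_dim.values.T
    return _rank_penalty(_neighbor_ranks(_pairwise(low_dim)),
                         _neighbor_ranks(_pairwise(high_dim)), k)


# ---------------------------------------------------------------------------
# setting sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepSetting:
    """One feature-selection + embedding + clustering configuration."""

    name: str
    mode: str                      # "variable_pct" | "pca"
    pct: float = 15.0
    n_components: int = 20
    perplexity: float = 30.0
    theta: float = 0.5
    bandwidth: float = 1.5


def sweep(matrix: ExpressionMatrix, annotations: pd.DataFrame,
          settings, n_seeds: int = 100, master_seed: int = 0,
          detail: bool = False) -> pd.DataFrame:
    """Score settings by pNMI/eNMI/cNMI over ``n_seeds`` pipeline seeds.

    For every setting and every seed: select features (top-variance genes or
    PCA scores), embed with Barnes-Hut t-SNE, cluster the embedding with
    Gaussian mean-shift, then compute the three NMI metrics against the
    annotation table. Returns one row per setting with mean and SD of each
    metric; with ``detail`` True returns ``(report, runs)`` where ``runs``
    has one row per (setting, seed). Deterministic given ``master_seed``;
    all settings see the same seed sequence, so per-seed rows are paired.
    """
    from .embed import select_variable_genes, pca_reduce, tsne_embed, meanshift_cluster

    if isinstance(settings, SweepSetting):
        settings = [settings]
    settings = [s if isinstance(s, SweepSetting) else SweepSetting(**s) for s in settings]
    ann = annotations.set_index("sample_id").loc[matrix.sample_ids]
    phenotypes = list(ann["phenotype"])
    studies = list(ann["study_id"])

    seeds = np.random.SeedSequence(master_seed).generate_state(n_seeds) % (2 ** 31)
    rows = []
    run_rows = []
    for setting in settings:
        if setting.mode == "pca" and setting.n_components >= matrix.n_samples:
            raise ValueError(
                f"setting {setting.name!r}: {setting.n_components} components "
                f">= {matrix.n_samples} samples"
            )
        metrics = {"pNMI": [], "eNMI": [], "cNMI": []}
        for seed in seeds:
            if setting.mode == "variable_pct":
                x = select_variable_genes(matrix, setting.pct).values.T
            elif setting.mode == "pca":
                x = pca_reduce(matrix, setting.n_components)
            else:
                raise ValueError(f"unknown sweep mode {setting.mode!r}")
            coords = tsne_embed(x, perplexity=setting.perplexity,
                                theta=setting.theta, seed=int(seed))
            model = meanshift_cluster(coords, setting.bandwidth)
            p = pnmi(model.labels, phenotypes)
            e = enmi(model.labels, studies)
            metrics["pNMI"].append(p)
            metrics["eNMI"].append(e)
            metrics["cNMI"].append(cnmi(p, e))
            run_rows.append({"setting": setting.name, "seed": int(seed),
                             "pNMI": p, "eNMI": e, "cNMI": cnmi(p, e)})
        row = {"setting": setting.name, "mode": setting.mode, "n_seeds": n_seeds}
        for key, vals in metrics.items():
            vals = np.asarray(vals)
            row[f"{key}_mean"] = float(vals.mean())
            row[f"{key}_sd"] = float(vals.std(ddof=1)) if n_seeds > 1 else 0.0
        rows.append(row)
    report = pd.DataFrame(rows)
    if detail:
        return report, pd.DataFrame(run_rows)
    return report
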