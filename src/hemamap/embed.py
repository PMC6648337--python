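"""Reference-map construction: feature selection, t-SNE, mean-shift.

The map-building pipeline selects the most variable genes (15% by default —
the setting the NMI sweep favors on batch-confounded collections), embeds
samples in 2-D with Barnes-Hut t-SNE, and clusters the embedding with a
Gaussian-kernel mean-shift, whose cluster count emerges from the kernel
bandwidth rather than being pre-specified (1.5 for focused subsets, 2.5 for
large heterogeneous collections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .types import ExpressionMatrix, ReferenceMap, validate_annotations


@dataclass
class FeatureSelection:
    """Feature selection mode for map building.

    mode "variable_pct" keeps the top ``pct`` % of genes by variance;
    "pca" projects onto ``n_components`` principal components; "both"
    selects variable genes first and then projects.
    """

    mode: str = "variable_pct"
    pct: float = 15.0
    n_components: int = 20

    def __post_init__(self):
        if self.mode not in ("variable_pct", "pca", "both"):
            raise ValueError(f"unknown feature selection mode {self.mode!r}")
        if not (0.0 < self.pct <= 100.0):
            raise ValueError(f"pct must lie in (0, 100], got {self.pct}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class ClusterModel:
    """Mean-shift clustering of a 2-D embedding."""

    labels: np.ndarray              # per-sample int, contiguous from 1
    modes: np.ndarray               # converged density mode per sample, n x 2
    centroids: dict[int, np.ndarray]  # label -> mean of member coordinates
    bandwidth: float

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def select_variable_genes(matrix: ExpressionMatrix, pct: float) -> ExpressionMatrix:
    """Keep the ceil(pct% of genes) with largest sample variance.

    Variance uses the n-1 denominator on the log-scale values. Ties are
    broken by gene id (stable, platform-independent); the surviving genes
    keep their original row order.
    """
    if not (0.0 < pct <= 100.0):
        raise ValueError(f"pct must lie in (0, 100], got {pct}")
    n_keep = int(np.ceil(pct / 100.0 * matrix.n_genes))
    if matrix.n_samples < 2:
        raise ValueError("variance selection needs at least 2 samples")
    variances = matrix.values.var(axis=1, ddof=1)
    order = sorted(range(matrix.n_genes),
                   key=lambda i: (-variances[i], matrix.gene_ids[i]))
    chosen = set(order[:n_keep])
    keep_ids = [g for i, g in enumerate(matrix.gene_ids) if i in chosen]
    return matrix.subset_genes(keep_ids)


def pca_reduce(matrix: ExpressionMatrix, n_components: int) -> np.ndarray:
    """Scores of centered samples on the top principal components.

    Returns a samples x n_components array ordered by explained variance.
    """
    limit = min(matrix.n_genes, matrix.n_samples)
    if not (1 <= n_components < limit):
        raise ValueError(
            f"n_components must satisfy 1 <= k < min(genes, samples)={limit}, "
            f"got {n_components}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    return model.fit_transform(matrix.values.T)


def tsne_embed(x: np.ndarray, perplexity: float = 30.0, theta: float = 0.5,
               seed: int = 0) -> np.ndarray:
    """Barnes-Hut t-SNE of samples x features data into 2-D.

    Deterministic given the seed (PCA initialization). ``theta`` is the
    Barnes-Hut accuracy/speed trade-off.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError(f"t-SNE needs at least 4 samples, got {n}")
    if perplexity >= (n - 1) / 3.0:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} samples "
            f"(must be < (n-1)/3 = {(n - 1) / 3:.1f})"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, angle=theta,
                method="barnes_hut", init="pca", random_state=int(seed))
    coords = tsne.fit_transform(x)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return np.asarray(coords, dtype=float)


def meanshift_cluster(coords: np.ndarray, bandwidth: float,
                      tol: float = 1e-4, max_iter: int = 300) -> ClusterModel:
    """Gaussian-kernel mean-shift clustering of 2-D coordinates.

    Every point ascends the kernel density estimate by iterated
    kernel-weighted averaging until its shift falls below ``tol`` (or
    ``max_iter`` iterations). Converged modes within bandwidth/2 of each
    other are merged; points sharing a merged mode form a cluster. Labels
    are contiguous from 1, numbered by decreasing cluster size (ties by
    mode coordinates); centroids are the means of member coordinates.
    The result is invariant to input point order up to this renumbering.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an n x 2 array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain non-finite values")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    n = coords.shape[0]

    y = coords.copy()
    active = np.ones(n, dtype=bool)
    inv_two_h2 = 1.0 / (2.0 * bandwidth ** 2)
    for _ in range(max_iter):
        if not active.any():
            break
        diff = y[active, None, :] - coords[None, :, :]
        w = np.exp(-(diff ** 2).sum(axis=2) * inv_two_h2)
        new = (w[:, :, None] * coords[None, :, :]).sum(axis=1) / w.sum(axis=1)[:, None]
        shift = np.linalg.norm(new - y[active], axis=1)
        y[active] = new
        still = np.flatnonzero(active)
        active[still[shift < tol]] = False

    # merge modes within bandwidth/2, deterministically: seeds ordered by
    # coordinates so the grouping is independent of input order
    merge_r = bandwidth / 2.0
    order = np.lexsort((y[:, 1], y[:, 0]))
    group_of = np.full(n, -1, dtype=int)
    group_modes: list[np.ndarray] = []
    for i in order:
        assigned = False
        for g, mode in enumerate(group_modes):
            if np.linalg.norm(y[i] - mode) < merge_r:
                group_of[i] = g
                assigned = True
                break
        if not assigned:
            group_of[i] = len(group_modes)
            group_modes.append(y[i])

    # renumber by decreasing size, ties by mode coordinates
    sizes = np.bincount(group_of, minlength=len(group_modes))
    rank = sorted(range(len(group_modes)),
                  key=lambda g: (-sizes[g], group_modes[g][0], group_modes[g][1]))
    relabel = {g: r + 1 for r, g in enumerate(rank)}
    labels = np.array([relabel[g] for g in group_of], dtype=int)
    centroids = {lbl: coords[labels == lbl].mean(axis=0)
                 for lbl in range(1, len(group_modes) + 1)}
    return ClusterModel(labels=labels, modes=y, centroids=centroids,
                        bandwidth=float(bandwidth))


def build_reference_map(matrix: ExpressionMatrix, annotations: pd.DataFrame,
                        selection: FeatureSelection | None = None,
                        perplexity: float = 30.0, theta: float = 0.5,
                        seed: int = 0, bandwidth: float = 1.5,
                        metric: str = "euclidean") -> ReferenceMap:
    """Build a frozen reference map from a collection.

    Runs feature selection, t-SNE and mean-shift, and bundles the result
    with the parameters used and the expression of the selected features
    (required later to compute affinities of new samples). ``metric``
    records the distance to be used at remap time.
    """
    selection = selection or FeatureSelection()
    ann = validate_annotations(annotations)
    ann = ann.set_index("sample_id").loc[matrix.sample_ids].reset_index()

    if selection.mode in ("variable_pct", "both"):
        selected = select_variable_genes(matrix, selection.pct)
    else:
        selected = matrix
    if selection.mode in ("pca", "both"):
        x = pca_reduce(selected, selection.n_components)
    else:
        x = selected.values.T

    coords = tsne_embed(x, perplexity=perplexity, theta=theta, seed=seed)
    model = meanshift_cluster(coords, bandwidth)
    return ReferenceMap(
        feature_ids=list(selected.gene_ids),
        embedding=coords,
        tsne_params={"perplexity": float(perplexity), "theta": float(theta),
                     "seed": int(seed), "metric": metric},
        cluster_labels=model.labels,
        centroids=model.centroids,
        bandwidth=float(bandwidth),
        annotations=ann,
        reference_expression=selected,
    )
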