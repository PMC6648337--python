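"""Embed new samples into a frozen t-SNE reference map.

The reference coordinates are given as input and kept locked throughout
gradient descent; only the coordinates of the new samples move, and each
new sample is optimized independently of every other, so

* the established map is never perturbed by new data, and
* a sample's coordinates do not depend on which other samples are in the
  batch (one-at-a-time and batch remapping agree exactly).

For each new sample the optimizer minimizes KL(P || Q) where P are
perplexity-calibrated Gaussian input affinities of the new sample to the
reference samples (Euclidean distance, or one minus Pearson correlation for
cross-platform data, where absolute intensity scales are incomparable) and
Q is the Student-t kernel between the free point and the fixed reference
coordinates. Since only the new point moves against the frozen references,
its gradient involves the reference coordinates alone and is evaluated
exactly (O(n_ref) per step); the Barnes-Hut accuracy parameter theta is
recorded in the result for provenance but no tree approximation is needed
at these problem sizes.

After placement, samples are assigned to the nearest cluster centroid, a
phenotype annotation is transferred by majority vote over the reference
members of that cluster, and correlation diagnostics flag samples the
reference does not represent well (e.g. a subtype absent from the map).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ReferenceMap

_AMBIGUOUS = "ambiguous"
_UNLABELED = "unlabeled"


@dataclass
class RemapResult:
    """Placement of new samples on a frozen reference map."""

    sample_ids: list[str]
    coordinates: np.ndarray            # m x 2
    assigned_clusters: np.ndarray      # m, int
    transferred_annotations: list[str]
    diagnostics: pd.DataFrame          # per-sample correlation diagnostics
    params: dict

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "sample_id": self.sample_ids,
            "x": self.coordinates[:, 0],
            "y": self.coordinates[:, 1],
            "cluster": self.assigned_clusters,
            "annotation": self.transferred_annotations,
        })
        return out.merge(self.diagnostics, on="sample_id")


# ---------------------------------------------------------------------------
# input affinities
# ---------------------------------------------------------------------------

def _squared_distances(new_vec: np.ndarray, reference_values: np.ndarray,
                       metric: str) -> np.ndarray:
    """Squared distances of one sample to each reference sample.

    ``reference_values`` is features x n_ref. The correlation distance
    (1 - Pearson r) is squared as well, so both metrics enter the Gaussian
    kernel the same way.
    """
    if metric == "euclidean":
        d2 = ((reference_values - new_vec[:, None]) ** 2).sum(axis=0)
    elif metric == "correlation":
        v = new_vec - new_vec.mean()
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError("zero-variance sample under correlation metric")
        r = (reference_values - reference_values.mean(axis=0)).T @ v
        norms = np.linalg.norm(
            reference_values - reference_values.mean(axis=0), axis=0)
        norms[norms == 0] = np.inf  # constant reference sample: r treated as 0
        r = r / (norms * nv)
        d2 = (1.0 - r) ** 2
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return np.maximum(d2, 0.0)


def _calibrated_affinities(d2: np.ndarray, perplexity: float,
                           tol: float = 1e-6, max_iter: int = 80) -> np.ndarray:
    """Gaussian affinities with bandwidth binary-searched to the target perplexity."""
    n = d2.size
    if not (1.0 < perplexity < n):
        raise ValueError(f"perplexity must lie in (1, n_ref={n}), got {perplexity}")
    target = np.log(perplexity)
    beta, lo, hi = 1.0, 0.0, np.inf
    d2 = d2 - d2.min()  # shift-invariant; improves numerics
    for _ in range(max_iter):
        w = np.exp(-beta * d2)
        sw = w.sum()
        p = w / sw
        # Shannon entropy of p in nats
        h = beta * (d2 * p).sum() + np.log(sw)
        diff = h - target
        if abs(diff) < tol:
            break
        if diff > 0:          # entropy too high -> narrow kernel
            lo = beta
            beta = beta * 2.0 if not np.isfinite(hi) else (beta + hi) / 2.0
        else:
            hi = beta
            beta = beta / 2.0 if lo == 0.0 else (beta + lo) / 2.0
    return p


def input_affinities(new_vec, reference, perplexity: float | None = None,
                     metric: str = "euclidean") -> np.ndarray:
    """Probability distribution of a new sample over the reference samples.

    ``new_vec`` is the sample's expression over the map features (aligned
    order). ``reference`` is a ReferenceMap or a features x n_ref array.
    The Gaussian kernel acts on squared distances with its bandwidth
    calibrated by binary search so the distribution's Shannon perplexity
    equals the target; probabilities sum to one.
    """
    if isinstance(reference, ReferenceMap):
        ref_values = reference.reference_expression.subset_genes(
            reference.feature_ids).values
        if perplexity is None:
            perplexity = reference.tsne_params["perplexity"]
    else:
        ref_values = np.asarray(reference, dtype=float)
        if perplexity is None:
            raise ValueError("perplexity required when reference is a bare array")
    new_vec = np.asarray(new_vec, dtype=float).ravel()
    if new_vec.size != ref_values.shape[0]:
        raise ValueError(
            f"feature mismatch: sample has {new_vec.size} values, reference "
            f"has {ref_values.shape[0]} features"
        )
    d2 = _squared_distances(new_vec, ref_values, metric)
    perplexity = min(float(perplexity), (ref_values.shape[1] - 1) / 3.0)
    return _calibrated_affinities(d2, perplexity)


# ---------------------------------------------------------------------------
# gradient descent against the locked map
# ---------------------------------------------------------------------------

def _optimize_point(p: np.ndarray, ref_coords: np.ndarray, y0: np.ndarray,
                    n_iter: int = 500, learning_rate: float = 100.0,
                    momentum_early: float = 0.5, momentum_late: float = 0.8,
                    switch_iter: int = 250) -> np.ndarray:
    """Minimize KL(P||Q) for one free 2-D point against fixed references.

    Q_j = w_j / sum(w), w_j = 1 / (1 + ||y - Y_j||^2); exact gradient
    dC/dy = 2 * sum_j (p_j - q_j) * w_j * (y - Y_j).

    Momentum gradient descent with the per-iteration step capped at 2% of
    the map extent: a single free point against a fixed field has no
    counteracting forces, so an uncapped step can overshoot into the far
    field where gradients vanish.
    """
    y = y0.astype(float).copy()
    velocity = np.zeros(2)
    extent = float(np.ptp(ref_coords, axis=0).max())
    max_step = 0.02 * max(extent, 1.0)
    for it in range(n_iter):
        diff = y[None, :] - ref_coords
        w = 1.0 / (1.0 + (diff ** 2).sum(axis=1))
        q = w / w.sum()
        grad = 2.0 * ((p - q) * w) @ diff
        m = momentum_early if it < switch_iter else momentum_late
        velocity = m * velocity - learning_rate * grad
        step = np.linalg.norm(velocity)
        if step > max_step:
            velocity *= max_step / step
        y = y + velocity
    return y


def _initial_point(p: np.ndarray, ref_coords: np.ndarray, n_top: int = 10,
                   rng: np.random.Generator | None = None,
                   gaussian: bool = False) -> np.ndarray:
    if gaussian:
        assert rng is not None
        return rng.normal(0.0, 1e-2, size=2)
    top = np.argsort(-p, kind="stable")[:n_top]
    w = p[top] / p[top].sum()
    return (w[:, None] * ref_coords[top]).sum(axis=0)


def remap_samples(reference: ReferenceMap, new_data: ExpressionMatrix,
                  metric: str | None = None, theta: float = 0.3,
                  seed: int = 0, perplexity: float | None = None,
                  n_iter: int = 500, learning_rate: float = 100.0,
                  feature_overlap_threshold: float = 0.9,
                  gaussian_init: bool = False,
                  max_r_threshold: float | None = None,
                  margin_threshold: float = 0.0) -> RemapResult:
    """Place each new sample on the frozen map, independently of the others.

    New samples must share at least ``feature_overlap_threshold`` of the map
    features; missing features are imputed with the reference mean. The
    reference map is never modified. Deterministic given ``seed`` (the seed
    only matters under ``gaussian_init``; the default initialization —
    affinity-weighted mean of the top-10 reference coordinates — is already
    deterministic).
    """
    if new_data.n_samples < 1:
        raise ValueError("no new samples to remap")
    metric = metric or reference.tsne_params.get("metric", "euclidean")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    if perplexity is None:
        perplexity = float(reference.tsne_params["perplexity"])

    features = reference.feature_ids
    have = set(new_data.gene_ids)
    shared = [f for f in features if f in have]
    coverage = len(shared) / len(features)
    if coverage < feature_overlap_threshold:
        missing = [f for f in features if f not in have]
        raise ValueError(
            f"new data covers only {coverage:.1%} of map features "
            f"(threshold {feature_overlap_threshold:.0%}); missing e.g. "
            f"{missing[:5]}"
        )

    ref_expr = reference.reference_expression.subset_genes(features)
    ref_values = ref_expr.values                       # features x n_ref
    new_frame = new_data.to_frame().reindex(features)  # align, NaN where missing
    new_values = new_frame.to_numpy(dtype=float)
    if np.isnan(new_values).any():
        impute = ref_values.mean(axis=1)
        nan_rows = np.isnan(new_values)
        new_values[nan_rows] = np.broadcast_to(impute[:, None],
                                               new_values.shape)[nan_rows]

    ref_coords = reference.embedding
    before = ref_coords.copy()
    rng = np.random.default_rng(seed)

    coords = np.empty((new_data.n_samples, 2))
    for j in range(new_data.n_samples):
        p = input_affinities(new_values[:, j], ref_values,
                             perplexity=perplexity, metric=metric)
        y0 = _initial_point(p, ref_coords, rng=rng, gaussian=gaussian_init)
        coords[j] = _optimize_point(p, ref_coords, y0, n_iter=n_iter,
                                    learning_rate=learning_rate)

    if not np.array_equal(reference.embedding, before):
        raise AssertionError("reference embedding was modified during remap")

    from .embed import ClusterModel
    model = ClusterModel(labels=reference.cluster_labels,
                         modes=reference.embedding,
                         centroids=reference.centroids,
                         bandwidth=reference.bandwidth)
    assigned = assign_clusters(coords, model)
    annotations = transfer_annotation(assigned, reference)
    new_aligned = ExpressionMatrix(new_values, features, new_data.sample_ids)
    diagnostics = remap_diagnostics(new_aligned, reference, assigned,
                                    max_r_threshold=max_r_threshold,
                                    margin_threshold=margin_threshold)
    return RemapResult(
        sample_ids=list(new_data.sample_ids),
        coordinates=coords,
        assigned_clusters=assigned,
        transferred_annotations=annotations,
        diagnostics=diagnostics,
        params={"metric": metric, "theta": float(theta), "seed": int(seed),
                "perplexity": float(perplexity), "n_iter": n_iter,
                "learning_rate": learning_rate,
                "feature_overlap": coverage},
    )


# ---------------------------------------------------------------------------
# cluster assignment / annotation transfer / diagnostics
# ---------------------------------------------------------------------------

def assign_clusters(coords: np.ndarray, model) -> np.ndarray:
    """Nearest-centroid cluster assignment in the 2-D map.

    Ties go to the lowest cluster id (strict improvement required to switch).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != 2:
        raise ValueError("coords must be m x 2")
    if not model.centroids:
        raise ValueError("cluster model has no centroids")
    labels = sorted(model.centroids)
    centers = np.stack([model.centroids[l] for l in labels])
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)  # argmin returns the first (lowest-id) minimum
    return np.array([labels[b] for b in best], dtype=int)


def cluster_annotation(reference: ReferenceMap) -> dict[int, str]:
    """Majority-vote phenotype per reference cluster.

    Ties produce "ambiguous"; clusters without any annotated member produce
    "unlabeled".
    """
    phenotypes = list(reference.annotations["phenotype"])
    out: dict[int, str] = {}
    for label in sorted(reference.centroids):
        members = reference.cluster_members(label)
        votes: dict[str, int] = {}
        for i in members:
            ph = phenotypes[i]
            if ph is not None:
                votes[ph] = votes.get(ph, 0) + 1
        if not votes:
            out[label] = _UNLABELED
            continue
        top = max(votes.values())
        winners = [ph for ph, c in votes.items() if c == top]
        out[label] = winners[0] if len(winners) == 1 else _AMBIGUOUS
    return out


def transfer_annotation(assigned: np.ndarray, reference: ReferenceMap) -> list[str]:
    """Annotation of each new sample = majority phenotype of its cluster."""
    lookup = cluster_annotation(reference)
    return [lookup[int(label)] for label in np.asarray(assigned).ravel()]


def _correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of a (features x m) and b (features x n)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    na = np.linalg.norm(ac, axis=0)
    nb = np.linalg.norm(bc, axis=0)
    na[na == 0] = np.inf
    nb[nb == 0] = np.inf
    return (ac.T @ bc) / np.outer(na, nb)


def reference_max_r_threshold(reference: ReferenceMap, quantile: float = 0.05) -> float:
    """Data-adaptive default for the representativeness warning.

    The 5th percentile of each reference sample's leave-one-out maximum
    correlation to the rest of the map: a new sample whose best match falls
    below what almost every reference sample achieves is unlikely to be
    represented by the map.
    """
    values = reference.reference_expression.subset_genes(reference.feature_ids).values
    r = _correlation_matrix(values, values)
    np.fill_diagonal(r, -np.inf)
    loo_max = r.max(axis=1)
    return float(np.quantile(loo_max, quantile))


def remap_diagnostics(new_data: ExpressionMatrix, reference: ReferenceMap,
                      assigned: np.ndarray,
                      max_r_threshold: float | None = None,
                      margin_threshold: float = 0.0) -> pd.DataFrame:
    """Correlation diagnostics of how well the reference represents each sample.

    Per new sample: ``max_r`` (highest Pearson correlation to any reference
    sample over the map features), ``assigned_cluster_mean_r`` (mean
    correlation to the assigned cluster's members), ``margin`` (assigned
    cluster mean minus the best other cluster mean) and a ``flagged``
    boolean raised when max_r falls below the threshold (default: the 5th
    percentile of reference leave-one-out max correlations) or the margin
    falls below ``margin_threshold``.
    """
    features = reference.feature_ids
    new_aligned = new_data.subset_genes(features)
    ref_values = reference.reference_expression.subset_genes(features).values
    r = _correlation_matrix(new_aligned.values, ref_values)  # m x n_ref
    if max_r_threshold is None:
        max_r_threshold = reference_max_r_threshold(reference)

    labels = sorted(reference.centroids)
    cluster_means = np.stack([
        r[:, reference.cluster_members(l)].mean(axis=1) for l in labels
    ], axis=1)  # m x n_clusters
    assigned = np.asarray(assigned).ravel()
    rows = []
    for j, sample in enumerate(new_aligned.sample_ids):
        li = labels.index(int(assigned[j]))
        own = cluster_means[j, li]
        others = np.delete(cluster_means[j], li)
        margin = own - (others.max() if others.size else -1.0)
        max_r = float(r[j].max())
        rows.append({
            "sample_id": sample,
            "max_r": max_r,
            "assigned_cluster_mean_r": float(own),
            "margin": float(margin),
            "flagged": bool(max_r < max_r_threshold or margin < margin_threshold),
        })
    return pd.DataFrame(rows)
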