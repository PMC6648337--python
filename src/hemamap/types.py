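"""Core domain types shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical annotation table columns
ANNOTATION_COLUMNS = ["sample_id", "study_id", "phenotype", "platform"]

#: serialization format version for ReferenceMap artifacts
MAP_FORMAT_VERSION = 1


class ExpressionMatrix:
    """A genes x samples matrix of log-scale expression values.

    The universal input of the package: rows are genes (unique ids), columns
    are samples (unique ids), values are finite log2 intensities or log-CPM.
    A single-sample matrix is allowed so that one new sample can be remapped
    on its own; ordinary collections have at least two samples.
    """

    def __init__(self, values, gene_ids: Sequence[str], sample_ids: Sequence[str]):
        values = np.asarray(values, dtype=float)
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"shape {values.shape} inconsistent with {len(gene_ids)} genes "
                f"x {len(sample_ids)} samples"
            )
        if len(gene_ids) < 2:
            raise ValueError("expression matrix needs at least 2 genes")
        if len(sample_ids) < 1:
            raise ValueError("expression matrix needs at least 1 sample")
        for name, ids in (("gene", gene_ids), ("sample", sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {gene_ids[g]!r}, "
                f"sample {sample_ids[s]!r}"
            )
        self.values = values
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    # -- basic container protocol -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    # -- conversions ---------------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    # -- subsetting ----------------------------------------------------------------
    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        missing = [g for g in gene_ids if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        idx = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(self.values[idx, :], list(gene_ids), self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, list(sample_ids))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_ids),
                                list(self.sample_ids))


def _first_duplicate(ids: Sequence[str]):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a sample annotation table.

    Required columns: sample_id, study_id; optional: phenotype, platform.
    Missing phenotype/platform are represented as None in memory (empty
    string in TSV files). Returns a normalized copy.
    """
    if "sample_id" not in annotations.columns or "study_id" not in annotations.columns:
        raise ValueError("annotation table requires 'sample_id' and 'study_id' columns")
    out = annotations.copy()
    for col in ("phenotype", "platform"):
        if col not in out.columns:
            out[col] = None
    out = out[ANNOTATION_COLUMNS]
    out["sample_id"] = out["sample_id"].astype(str)
    out["study_id"] = out["study_id"].astype(str)
    for col in ("phenotype", "platform"):
        out[col] = out[col].map(
            lambda v: None if v is None or (isinstance(v, float) and np.isnan(v))
            or str(v) == "" else str(v)
        )
    dup = out["sample_id"][out["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in annotations: {dup.iloc[0]!r}")
    if (out["study_id"] == "").any():
        bad = out.loc[out["study_id"] == "", "sample_id"].iloc[0]
        raise ValueError(f"empty study_id for sample {bad!r}")
    return out.reset_index(drop=True)


@dataclass
class GeneSet:
    """A named gene list with a regulation direction tag."""

    name: str
    genes: list[str]
    direction: str = "unsigned"  # up | down | unsigned
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.direction not in ("up", "down", "unsigned"):
            raise ValueError(f"invalid direction {self.direction!r}")
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise ValueError(f"duplicate gene {dup!r} in set {self.name!r}")


class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    def __init__(self, sets: Sequence[GeneSet] = ()):
        self.sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValueError(f"duplicate gene set name: {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ReferenceMap:
    """Frozen bundle of a 2-D embedding, its clusters and its provenance.

    This is the object new samples are projected onto: the gene subset used
    for the embedding, the locked coordinates, the t-SNE parameters, the
    mean-shift clustering (labels + centroids + bandwidth), per-sample
    annotations, and the reference expression restricted to the map features
    (needed to compute input affinities for new samples).
    """

    feature_ids: list[str]
    embedding: np.ndarray                      # n_samples x 2
    tsne_params: dict                          # perplexity, theta, seed, metric
    cluster_labels: np.ndarray                 # n_samples, int, 1-based
    centroids: dict[int, np.ndarray]           # label -> (2,)
    bandwidth: float
    annotations: pd.DataFrame                  # ANNOTATION_COLUMNS, row per sample
    reference_expression: ExpressionMatrix     # restricted to feature_ids

    def __post_init__(self):
        self.embedding = np.asarray(self.embedding, dtype=float)
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=int)
        n = self.embedding.shape[0]
        if self.embedding.ndim != 2 or self.embedding.shape[1] != 2:
            raise ValueError("embedding must be n x 2")
        if len(self.cluster_labels) != n:
            raise ValueError("cluster_labels length must match embedding rows")
        if self.reference_expression.n_samples != n:
            raise ValueError("reference_expression samples must match embedding rows")
        if len(self.annotations) != n:
            raise ValueError("annotations must have one row per sample")
        missing = set(np.unique(self.cluster_labels)) - set(self.centroids)
        if missing:
            raise ValueError(f"cluster labels without centroid: {sorted(missing)}")
        feats = set(self.reference_expression.gene_ids)
        extra = [f for f in self.feature_ids if f not in feats]
        if extra:
            raise ValueError(f"feature_ids missing from reference expression: {extra[:5]}")
        metric = self.tsne_params.get("metric", "euclidean")
        if metric not in ("euclidean", "correlation"):
            raise ValueError(f"invalid metric {metric!r}")

    @property
    def n_samples(self) -> int:
        return self.embedding.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return self.reference_expression.sample_ids

    def cluster_members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_labels == label)


@dataclass
class RunConfig:
    """Run-wide configuration; the seed propagates to every stochastic stage."""

    seed: int = 0
    variable_gene_pct: float = 15.0
    perplexity: float = 30.0
    theta: float = 0.5
    remap_theta: float = 0.3
    bandwidth: float = 1.5
    n_permutations: int = 1000
    p_nominal: float = 0.05
    alpha_adjusted: float = 0.001

    def __post_init__(self):
        for name in ("p_nominal", "alpha_adjusted"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        return cls(**{k: d[k] for k in d})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "variable_gene_pct": self.variable_gene_pct,
            "perplexity": self.perplexity,
            "theta": self.theta,
            "remap_theta": self.remap_theta,
            "bandwidth": self.bandwidth,
            "n_permutations": self.n_permutations,
            "p_nominal": self.p_nominal,
            "alpha_adjusted": self.alpha_adjusted,
        }
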