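"""Readers and writers for the package's on-disk formats.

Canonical dialects: TSV with genes in rows for expression matrices (the
genes x samples convention of expression repositories), TSV annotation
tables, standard GMT for gene sets, and a directory of a JSON manifest plus
TSV payloads for reference maps, so coordinates and clusters stay
human-inspectable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ANNOTATION_COLUMNS,
    MAP_FORMAT_VERSION,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ReferenceMap,
    validate_annotations,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for j in range(frame.shape[1]):
        try:
            values[:, j] = raw[:, j].astype(float)
        except ValueError:
            for i in range(frame.shape[0]):
                try:
                    float(raw[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {raw[i, j]!r} at gene {gene_ids[i]!r}, "
                        f"sample {sample_ids[j]!r} in {path}"
                    ) from None
            raise
    return ExpressionMatrix(values, gene_ids, sample_ids)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample annotations
# ---------------------------------------------------------------------------

def read_annotations(path) -> pd.DataFrame:
    """Read a sample annotation TSV; empty phenotype/platform become None."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_annotations(frame)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    out = validate_annotations(annotations).copy()
    for col in ("phenotype", "platform"):
        out[col] = out[col].map(lambda v: "" if v is None else v)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def _direction_from_name(name: str) -> str:
    if name.endswith("_UP"):
        return "up"
    if name.endswith("_DN"):
        return "down"
    return "unsigned"


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, genes.

    Direction is inferred from the conventional ``_UP`` / ``_DN`` name suffix.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g != ""]
            collection.add(GeneSet(name=name, genes=genes,
                                   direction=_direction_from_name(name),
                                   description=description))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# reference maps
# ---------------------------------------------------------------------------

_MAP_FILES = ("manifest.json", "embedding.tsv", "clusters.tsv",
              "annotations.tsv", "expression.tsv", "features.txt")


def save_reference_map(reference: ReferenceMap, path) -> None:
    """Serialize a reference map to a directory of JSON + TSV artifacts.

    Serialization is deterministic: saving the same map twice produces
    byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": MAP_FORMAT_VERSION,
        "tsne_params": reference.tsne_params,
        "bandwidth": reference.bandwidth,
        "centroids": {str(k): [float(v[0]), float(v[1])]
                      for k, v in sorted(reference.centroids.items())},
        "n_samples": reference.n_samples,
        "n_features": len(reference.feature_ids),
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    emb = pd.DataFrame(reference.embedding, columns=["x", "y"])
    emb.insert(0, "sample_id", reference.sample_ids)
    emb.to_csv(path / "embedding.tsv", sep="\t", index=False)
    clusters = pd.DataFrame({"sample_id": reference.sample_ids,
                             "cluster": reference.cluster_labels})
    clusters.to_csv(path / "clusters.tsv", sep="\t", index=False)
    write_annotations(reference.annotations, path / "annotations.tsv")
    write_expression(reference.reference_expression, path / "expression.tsv")
    with open(path / "features.txt", "w") as fh:
        fh.write("\n".join(reference.feature_ids) + "\n")


def load_reference_map(path) -> ReferenceMap:
    path = Path(path)
    for name in _MAP_FILES:
        if not (path / name).exists():
            raise FileNotFoundError(f"reference map at {path} is missing {name}")
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    version = manifest.get("format_version")
    if version != MAP_FORMAT_VERSION:
        raise ValueError(
            f"reference map format version {version!r} not supported "
            f"(expected {MAP_FORMAT_VERSION})"
        )
    emb = pd.read_csv(path / "embedding.tsv", sep="\t",
                      float_precision="round_trip")
    clusters = pd.read_csv(path / "clusters.tsv", sep="\t")
    if list(emb["sample_id"]) != list(clusters["sample_id"]):
        raise ValueError("embedding and cluster tables disagree on sample order")
    annotations = read_annotations(path / "annotations.tsv")
    expression = read_expression(path / "expression.tsv")
    with open(path / "features.txt") as fh:
        features = [line.strip() for line in fh if line.strip()]
    centroids = {int(k): np.asarray(v, dtype=float)
                 for k, v in manifest["centroids"].items()}
    return ReferenceMap(
        feature_ids=features,
        embedding=emb[["x", "y"]].to_numpy(dtype=float),
        tsne_params=manifest["tsne_params"],
        cluster_labels=clusters["cluster"].to_numpy(dtype=int),
        centroids=centroids,
        bandwidth=float(manifest["bandwidth"]),
        annotations=annotations,
        reference_expression=expression,
    )
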