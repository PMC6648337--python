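"""Reference-anchored normalization of probe-level array data.

Joint normalization pipelines (quantile normalization + median-polish
summarization) use information across all samples, so a new array would
normally force re-processing of the entire collection. This module freezes
the cross-sample components once — the reference quantile distribution
(the across-sample mean of sorted per-sample value vectors) and the
per-probe row effects of the original median polish — so a new
background-corrected array can be normalized into the space of the original
data one sample at a time:

1. quantile-map the new sample onto the stored reference distribution
   (its sorted values become exactly the reference quantiles), then
2. summarize probes to genes with the *stored* probe effects:
   expression_g = overall_g + median_{p in g}(value_p - probe_effect_p).

Normalizing an original sample through the frozen model reproduces its
jointly-normalized value exactly; new samples from the same population
agree with from-scratch co-normalization to well under the noise level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ReferenceNormModel:
    """Frozen normalization artifacts of an already-processed collection."""

    reference_quantiles: np.ndarray   # sorted, length = n_probes
    probe_effects: pd.Series          # probe id -> row effect
    overall_effects: pd.Series        # gene id -> overall (grand) effect
    probe_to_gene: pd.Series          # probe id -> gene id

    def __post_init__(self):
        self.reference_quantiles = np.asarray(self.reference_quantiles, dtype=float)
        if np.any(np.diff(self.reference_quantiles) < 0):
            raise ValueError("reference quantiles must be non-decreasing")
        if len(self.reference_quantiles) != len(self.probe_to_gene):
            raise ValueError("quantile vector length must equal probe count")
        missing = set(self.probe_to_gene.index) - set(self.probe_effects.index)
        if missing:
            raise ValueError(f"probes without an effect: {sorted(missing)[:5]}")
        missing_genes = set(self.probe_to_gene.values) - set(self.overall_effects.index)
        if missing_genes:
            raise ValueError(f"genes without an overall effect: {sorted(missing_genes)[:5]}")

    @property
    def probes(self) -> list[str]:
        return list(self.probe_to_gene.index)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.probe_to_gene.values:
            seen.setdefault(g, None)
        return list(seen)


def median_polish(table: np.ndarray, max_iter: int = 10, tol: float = 0.01):
    """Tukey two-way median polish of a rows x columns table.

    Returns (overall, row_effects, col_effects, residuals) with
    table ≈ overall + row[:, None] + col[None, :] + residuals.
    Iterates row- and column-median sweeps until the total absolute
    residual change falls below ``tol`` (or ``max_iter`` sweeps).
    """
    resid = np.asarray(table, dtype=float).copy()
    overall = 0.0
    row = np.zeros(resid.shape[0])
    col = np.zeros(resid.shape[1])
    prev = np.abs(resid).sum()
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        row += rmed
        resid -= rmed[:, None]
        cmed_of_row = np.median(row)
        overall += cmed_of_row
        row -= cmed_of_row
        cmed = np.median(resid, axis=0)
        col += cmed
        resid -= cmed[None, :]
        rmed_of_col = np.median(col)
        overall += rmed_of_col
        col -= rmed_of_col
        total = np.abs(resid).sum()
        if prev - total < tol * (prev if prev > 0 else 1.0):
            break
        prev = total
    return overall, row, col, resid


def _quantile_normalize_columns(frame: pd.DataFrame,
                                reference: np.ndarray | None = None):
    """Quantile-normalize columns; returns (normalized frame, reference)."""
    values = frame.to_numpy(dtype=float)
    sorted_cols = np.sort(values, axis=0)
    if reference is None:
        reference = sorted_cols.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = _map_to_quantiles(values[:, j], reference)
    return pd.DataFrame(out, index=frame.index, columns=frame.columns), reference


def _map_to_quantiles(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace the value at rank k with reference[k]; ties get the mean of
    their tied reference quantiles."""
    order = np.argsort(x, kind="stable")
    out = np.empty_like(reference, dtype=float)
    out[order] = reference
    # average over tied input values
    xs = x[order]
    tie_starts = np.flatnonzero(np.r_[True, xs[1:] != xs[:-1]])
    tie_ends = np.r_[tie_starts[1:], len(xs)]
    for s, e in zip(tie_starts, tie_ends):
        if e - s > 1:
            out[order[s:e]] = reference[s:e].mean()
    return out


def build_reference_model(original_probes: pd.DataFrame,
                          probe_to_gene) -> ReferenceNormModel:
    """Freeze the normalization artifacts of an original probe collection.

    ``original_probes`` is a probes x samples frame of background-corrected
    log2 intensities (>= 2 samples). The reference quantile distribution is
    the across-sample mean of sorted value vectors; probe and overall
    effects come from a per-gene two-way median polish of the
    quantile-normalized data. Deterministic.
    """
    probe_to_gene = pd.Series(probe_to_gene)
    if original_probes.shape[1] < 2:
        raise ValueError("reference model needs at least 2 samples")
    missing = set(original_probes.index) - set(probe_to_gene.index)
    if missing:
        raise ValueError(f"probes missing from the probe-to-gene map: "
                         f"{sorted(missing)[:5]}")
    probe_to_gene = probe_to_gene.loc[original_probes.index]

    normalized, reference = _quantile_normalize_columns(original_probes)
    probe_effects = pd.Series(0.0, index=original_probes.index)
    overall_effects = {}
    for gene, probes in probe_to_gene.groupby(probe_to_gene).groups.items():
        sub = normalized.loc[probes].to_numpy()
        overall, row, _col, _res = median_polish(sub)
        overall_effects[gene] = float(overall)
        # full fitted probe baseline (grand effect + probe deviation), so that
        # value - probe_effect isolates the sample's deviation from baseline
        probe_effects.loc[probes] = overall + row
    return ReferenceNormModel(
        reference_quantiles=np.sort(reference),
        probe_effects=probe_effects,
        overall_effects=pd.Series(overall_effects),
        probe_to_gene=probe_to_gene,
    )


def quantile_map_to_reference(new_sample, model: ReferenceNormModel) -> pd.Series:
    """Map one probe vector onto the stored reference distribution.

    The output's sorted values equal the reference quantiles exactly (up to
    tie averaging) and the input's ranks are preserved; the operation is
    idempotent.
    """
    x = _as_probe_series(new_sample, model)
    mapped = _map_to_quantiles(x.to_numpy(dtype=float), model.reference_quantiles)
    return pd.Series(mapped, index=x.index)


def summarize_with_fixed_effects(new_sample_probes, model: ReferenceNormModel) -> pd.Series:
    """Probe-to-gene summarization using the frozen probe effects.

    expression_g = overall_g + median over the gene's probes of
    (value_p - probe_effect_p). Input should already be quantile-mapped.
    """
    x = _as_probe_series(new_sample_probes, model)
    adjusted = x - model.probe_effects.loc[x.index]
    values = {}
    for gene, probes in model.probe_to_gene.groupby(model.probe_to_gene).groups.items():
        values[gene] = float(model.overall_effects[gene]
                             + np.median(adjusted.loc[probes].to_numpy()))
    return pd.Series(values).loc[model.genes]


def normalize_sample(new_sample_probes, model: ReferenceNormModel) -> pd.Series:
    """Full one-sample pipeline: quantile map, then fixed-effect summarization."""
    return summarize_with_fixed_effects(
        quantile_map_to_reference(new_sample_probes, model), model)


def joint_normalize(probe_frame: pd.DataFrame, probe_to_gene) -> pd.DataFrame:
    """From-scratch joint pipeline for a whole collection (genes x samples).

    Quantile normalization across all samples followed by per-gene median
    polish computing probe effects from these samples. The comparison
    baseline for the frozen one-at-a-time path.
    """
    probe_to_gene = pd.Series(probe_to_gene).loc[probe_frame.index]
    normalized, _ = _quantile_normalize_columns(probe_frame)
    rows = {}
    for gene, probes in probe_to_gene.groupby(probe_to_gene).groups.items():
        sub = normalized.loc[probes].to_numpy()
        overall, row, col, _res = median_polish(sub)
        rows[gene] = overall + col
    out = pd.DataFrame(rows).T
    out.columns = probe_frame.columns
    # preserve first-appearance gene order
    seen: dict[str, None] = {}
    for g in probe_to_gene.values:
        seen.setdefault(g, None)
    return out.loc[list(seen)]


def _as_probe_series(x, model: ReferenceNormModel) -> pd.Series:
    if isinstance(x, pd.Series):
        if len(x) != len(model.probe_to_gene):
            raise ValueError(
                f"probe vector has {len(x)} entries, model expects "
                f"{len(model.probe_to_gene)}"
            )
        return x.loc[model.probes].astype(float)
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size != len(model.probe_to_gene):
        raise ValueError(
            f"probe vector has {arr.size} entries, model expects "
            f"{len(model.probe_to_gene)}"
        )
    return pd.Series(arr, index=model.probes)
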