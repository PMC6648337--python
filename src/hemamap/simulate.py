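"""Synthetic multi-study expression collections with known ground truth.

The generator emulates the structure that makes pooled public expression
collections hard to analyse jointly: per-study batch shifts on every gene,
phenotype-specific up-regulated gene modules, heteroscedastic sample noise,
and an optional monotone "platform" distortion standing in for a change of
measurement technology. Ground truth (which genes belong to which phenotype
module) is returned alongside the data so downstream recovery claims can be
scored without re-derivation.

Defaults encode the regime of interest: batch shifts are moderate per gene
(``batch_sd`` = 0.6 log2 units) but act on *every* gene, so aggregated over
thousands of genes they dominate inter-sample distances; the biological
effect (``effect_size`` = 2.0 log2 units) is larger per gene but confined to
``module_size`` genes per phenotype. Under these conditions clustering on
all genes groups samples by study, while variance-based gene selection
recovers the phenotype structure — the contrast the quality metrics in
:mod:`hemamap.qc` are designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, validate_annotations


@dataclass
class SimulationDesign:
    """Parameters of a synthetic multi-study collection.

    Attributes
    ----------
    n_genes : total number of genes.
    n_phenotypes : number of biological classes; each gets a disjoint module
        of ``module_size`` up-regulated genes.
    samples_per_phenotype : samples simulated per class.
    n_studies : number of studies (batches); samples are spread across
        studies round-robin (balanced) unless ``confounded``.
    module_size : differentially expressed genes per phenotype.
    effect_size : log2 up-shift of a module gene in its phenotype.
    batch_sd : SD of the per-(gene, study) batch shift (``batch_mode=
        "gene_study"``) or of the per-study scalar shift ("study_scalar").
    noise_sd : SD of iid per-measurement noise.
    baseline_mean, baseline_sd : distribution of gene-level means, on the
        log2 microarray intensity scale.
    confounded : if True, each phenotype is observed in a single study
        (full phenotype/study confounding); otherwise studies are balanced.
    rnaseq_mode : if True, emit negative-binomial counts on the 2**x scale
        and return log2(count + 1) values (exercises the Poisson-kernel
        scoring path downstream).
    nb_dispersion : gamma shape of the negative-binomial in rnaseq_mode.
    """

    n_genes: int = 2000
    n_phenotypes: int = 3
    samples_per_phenotype: int = 40
    n_studies: int = 6
    module_size: int = 60
    effect_size: float = 2.0
    batch_sd: float = 0.6
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    batch_mode: str = "gene_study"  # or "study_scalar"
    confounded: bool = False
    rnaseq_mode: bool = False
    nb_dispersion: float = 10.0

    def __post_init__(self):
        if self.module_size * self.n_phenotypes > self.n_genes:
            raise ValueError(
                f"infeasible design: {self.n_phenotypes} disjoint modules of "
                f"{self.module_size} genes exceed {self.n_genes} genes"
            )
        for name in ("batch_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batch_mode not in ("gene_study", "study_scalar"):
            raise ValueError(f"unknown batch_mode {self.batch_mode!r}")
        if min(self.n_genes, self.n_phenotypes, self.samples_per_phenotype,
               self.n_studies, self.module_size) < 1:
            raise ValueError("all design counts must be positive")


def generate_collection(design: SimulationDesign, seed: int):
    """Simulate a collection; returns (matrix, annotations, truth).

    The signal model for gene g in sample i is

        x_gi = mu_g + effect_size * [g in module(phenotype(i))]
               + b_{g, study(i)} + eps_gi

    with mu_g ~ N(baseline_mean, baseline_sd^2), batch shifts
    b ~ N(0, batch_sd^2) and noise eps ~ N(0, noise_sd^2), all drawn from a
    single seeded generator, so the output is deterministic given the seed.

    ``truth`` maps each phenotype name to the exact list of planted module
    genes; in rnaseq_mode it additionally carries the raw count matrix.
    """
    rng = np.random.default_rng(seed)
    G, K = design.n_genes, design.n_phenotypes
    n = K * design.samples_per_phenotype
    width = max(4, len(str(G)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, G + 1)]
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    phenotype_names = [f"P{k + 1}" for k in range(K)]

    # disjoint modules occupy the leading genes, block per phenotype
    modules = {
        phenotype_names[k]: gene_ids[k * design.module_size:(k + 1) * design.module_size]
        for k in range(K)
    }

    phenotype_of = np.repeat(np.arange(K), design.samples_per_phenotype)
    if design.confounded:
        study_of = phenotype_of % design.n_studies
    else:
        # balanced: cycle studies within each phenotype block
        study_of = np.concatenate([
            np.arange(design.samples_per_phenotype) % design.n_studies
            for _ in range(K)
        ])

    mu = rng.normal(design.baseline_mean, design.baseline_sd, size=G)
    if design.batch_mode == "gene_study":
        batch = rng.normal(0.0, design.batch_sd, size=(G, design.n_studies))
    else:
        batch = np.tile(rng.normal(0.0, design.batch_sd, size=design.n_studies), (G, 1))

    values = mu[:, None] + batch[:, study_of]
    for k in range(K):
        rows = slice(k * design.module_size, (k + 1) * design.module_size)
        values[rows, phenotype_of == k] += design.effect_size
    values += rng.normal(0.0, design.noise_sd, size=(G, n))

    truth: dict = {"modules": modules}
    if design.rnaseq_mode:
        lam = np.power(2.0, values)
        shape = design.nb_dispersion
        counts = rng.poisson(rng.gamma(shape, lam / shape))
        values = np.log2(counts + 1.0)
        truth["counts"] = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)

    matrix = ExpressionMatrix(values, gene_ids, sample_ids)
    annotations = validate_annotations(pd.DataFrame({
        "sample_id": sample_ids,
        "study_id": [f"E{s + 1}" for s in study_of],
        "phenotype": [phenotype_names[k] for k in phenotype_of],
        "platform": ["sim" for _ in range(n)],
    }))
    return matrix, annotations, truth


@dataclass
class PlatformParams:
    """A global monotone intensity distortion: f(x) = shift + scale*x + quad*x**2.

    Applied to every value of a matrix, it models a change of measurement
    platform that warps the intensity scale but preserves within-sample gene
    ranking. Monotonicity (f' > 0) is validated over the observed data range.
    """

    shift: float = 0.0
    scale: float = 1.0
    quad: float = 0.0

    def is_identity(self) -> bool:
        return self.shift == 0.0 and self.scale == 1.0 and self.quad == 0.0


def platform_transform(matrix: ExpressionMatrix, params: PlatformParams) -> ExpressionMatrix:
    """Apply a strictly increasing global transform to all expression values.

    Raises ``ValueError`` if the parameterization is not strictly increasing
    over the range of the input values (the derivative scale + 2*quad*x is
    linear in x, so checking the two extremes suffices).
    """
    if params.is_identity():
        return matrix.copy()
    lo, hi = float(matrix.values.min()), float(matrix.values.max())
    for x in (lo, hi):
        if params.scale + 2.0 * params.quad * x <= 0:
            raise ValueError(
                f"platform transform not strictly increasing at x={x:.3g} "
                f"(scale={params.scale}, quad={params.quad})"
            )
    values = params.shift + params.scale * matrix.values + params.quad * matrix.values ** 2
    return ExpressionMatrix(values, list(matrix.gene_ids), list(matrix.sample_ids))


def generate_probe_collection(n_genes: int = 50, probes_per_gene: int = 4,
                              n_samples: int = 20, seed: int = 0,
                              gene_mean: float = 7.0, gene_sd: float = 1.5,
                              sample_effect_sd: float = 0.4,
                              sample_shift_sd: float = 0.3,
                              probe_affinity_sd: float = 1.0,
                              noise_sd: float = 0.1):
    """Simulate a background-corrected log2 probe-level intensity collection.

    Model per probe p of gene g in sample s:

        y_ps = mu_g + e_gs + a_p + t_s + eps_ps

    with gene means mu_g, per-(gene, sample) biological effects e_gs,
    probe affinities a_p (the systematic probe effect median polish must
    recover), a per-sample intensity shift t_s (what quantile normalization
    removes) and measurement noise eps.

    Returns (probe_frame, probe_to_gene): a probes x samples DataFrame and a
    Series mapping probe id -> gene id.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:03d}" for i in range(n_genes)]
    probes, probe_gene = [], []
    for g in genes:
        for j in range(probes_per_gene):
            probes.append(f"{g}_p{j + 1}")
            probe_gene.append(g)
    n_probes = len(probes)

    mu = rng.normal(gene_mean, gene_sd, size=n_genes)
    gene_sample = rng.normal(0.0, sample_effect_sd, size=(n_genes, n_samples))
    affinity = rng.normal(0.0, probe_affinity_sd, size=n_probes)
    sample_shift = rng.normal(0.0, sample_shift_sd, size=n_samples)
    noise = rng.normal(0.0, noise_sd, size=(n_probes, n_samples))

    gene_idx = np.repeat(np.arange(n_genes), probes_per_gene)
    values = (mu[gene_idx][:, None] + gene_sample[gene_idx, :]
              + affinity[:, None] + sample_shift[None, :] + noise)
    frame = pd.DataFrame(values, index=probes,
                         columns=[f"A{s + 1:03d}" for s in range(n_samples)])
    return frame, pd.Series(probe_gene, index=probes, name="gene")
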