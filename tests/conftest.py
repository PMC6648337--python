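import numpy as np
import pandas as pd
import pytest

import hemamap as hm


@pytest.fixture
def tiny_matrix() -> hm.ExpressionMatrix:
    values = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    return hm.ExpressionMatrix(values, ["gA", "gB", "gC"], ["s1", "s2"])


@pytest.fixture
def small_collection():
    """A small noisy 3-phenotype collection with mild batch effects."""
    design = hm.SimulationDesign(n_genes=300, n_phenotypes=3,
                                 samples_per_phenotype=20, n_studies=3,
                                 module_size=25, batch_sd=0.3)
    return hm.generate_collection(design, seed=42)


@pytest.fixture
def reference_map(small_collection) -> hm.ReferenceMap:
    matrix, annotations, _ = small_collection
    return hm.build_reference_map(
        matrix, annotations, hm.FeatureSelection(pct=20),
        perplexity=15, seed=0, bandwidth=2.5)


def random_labels(rng, n, k):
    return rng.integers(0, k, size=n)


def brute_force_nmi(x, y) -> float:
    """Independent dict-based NMI oracle (natural log, arithmetic mean)."""
    import math

    def ent(v):
        counts = {}
        for a in v:
            counts[a] = counts.get(a, 0) + 1
        n = len(v)
        return -sum(c / n * math.log(c / n) for c in counts.values())

    n = len(x)
    joint = {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px, py = {}, {}
    for a in x:
        px[a] = px.get(a, 0) + 1
    for b in y:
        py[b] = py.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        mi += pab * math.log(pab / (px[a] / n * py[b] / n))
    hx, hy = ent(x), ent(y)
    if hx == 0.0 and hy == 0.0:
        return 1.0
    if hx == 0.0 or hy == 0.0:
        return 0.0
    return mi / ((hx + hy) / 2.0)
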