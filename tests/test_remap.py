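import numpy as np
import pandas as pd
import pytest

import hemamap as hm
from hemamap.embed import ClusterModel
from hemamap.remap import input_affinities, remap_diagnostics


def _duplicates(matrix, indices, prefix="N"):
    sub = matrix.subset_samples([matrix.sample_ids[i] for i in indices])
    return hm.ExpressionMatrix(sub.values, sub.gene_ids,
                               [f"{prefix}{i}" for i in range(len(indices))])


class TestInputAffinities:
    def test_identical_sample_gets_maximum_probability(self, reference_map):
        ref_values = reference_map.reference_expression.values
        p = input_affinities(ref_values[:, 3], reference_map)
        assert p.argmax() == 3
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_affine_rescaling_has_zero_correlation_distance(self, reference_map):
        from hemamap.remap import _squared_distances
        ref_values = reference_map.reference_expression.values
        rescaled = 3.0 * ref_values[:, 7] + 2.0
        d2 = _squared_distances(rescaled, ref_values, "correlation")
        assert d2[7] == pytest.approx(0.0, abs=1e-12)

    def test_perplexity_calibration(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(7, 1, size=(60, 50))
        p = input_affinities(rng.normal(7, 1, size=60), ref, perplexity=5.0,
                             metric="euclidean")
        shannon = -(p * np.log(p)).sum()
        assert np.exp(shannon) == pytest.approx(5.0, abs=1e-4)

    def test_zero_variance_sample_rejected_under_correlation(self, reference_map):
        flat = np.full(len(reference_map.feature_ids), 5.0)
        with pytest.raises(ValueError, match="zero-variance"):
            input_affinities(flat, reference_map, metric="correlation")

    def test_feature_mismatch_rejected(self, reference_map):
        with pytest.raises(ValueError, match="feature"):
            input_affinities(np.zeros(3), reference_map)


class TestRemapSamples:
    def test_duplicates_land_in_their_twins_cluster(self, small_collection,
                                                    reference_map):
        matrix, _, _ = small_collection
        idx = list(range(0, 60, 7))
        result = hm.remap_samples(reference_map, _duplicates(matrix, idx))
        assert np.array_equal(result.assigned_clusters,
                              reference_map.cluster_labels[idx])
        assert result.diagnostics["max_r"].min() == pytest.approx(1.0, abs=1e-12)

    def test_batch_composition_independence(self, small_collection, reference_map):
        matrix, _, _ = small_collection
        a_b = hm.remap_samples(reference_map, _duplicates(matrix, [0, 10]))
        b_a = hm.remap_samples(reference_map, _duplicates(matrix, [10, 0]))
        b_alone = hm.remap_samples(reference_map, _duplicates(matrix, [10]))
        assert np.abs(a_b.coordinates[1] - b_a.coordinates[0]).max() < 1e-12
        assert np.abs(a_b.coordinates[1] - b_alone.coordinates[0]).max() < 1e-12

    def test_reference_map_untouched(self, small_collection, reference_map, tmp_path):
        matrix, _, _ = small_collection
        d1, d2 = tmp_path / "before", tmp_path / "after"
        hm.save_reference_map(reference_map, d1)
        hm.remap_samples(reference_map, _duplicates(matrix, [0, 5, 9]))
        hm.save_reference_map(reference_map, d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_empty_new_data_rejected(self, reference_map):
        with pytest.raises((ValueError, KeyError)):
            bad = hm.ExpressionMatrix(np.zeros((2, 1)), ["a", "b"], ["s"])
            hm.remap_samples(reference_map, bad)

    def test_low_feature_coverage_rejected(self, small_collection, reference_map):
        matrix, _, _ = small_collection
        few = reference_map.feature_ids[: int(len(reference_map.feature_ids) * 0.5)]
        partial = matrix.subset_genes(few)
        with pytest.raises(ValueError, match="features"):
            hm.remap_samples(reference_map, partial)

    def test_deterministic(self, small_collection, reference_map):
        matrix, _, _ = small_collection
        new = _duplicates(matrix, [2, 4])
        a = hm.remap_samples(reference_map, new, seed=1)
        b = hm.remap_samples(reference_map, new, seed=1)
        assert np.array_equal(a.coordinates, b.coordinates)


class TestAssignClusters:
    @pytest.fixture
    def model(self):
        centroids = {1: np.array([0.0, 0.0]), 2: np.array([10.0, 0.0]),
                     3: np.array([0.0, 10.0])}
        return ClusterModel(labels=np.array([1, 2, 3]),
                            modes=np.zeros((3, 2)), centroids=centroids,
                            bandwidth=1.5)

    def test_point_at_centroid(self, model):
        assert hm.assign_clusters(np.array([[0.0, 10.0]]), model)[0] == 3

    def test_equidistant_tie_goes_to_lowest_id(self, model):
        assert hm.assign_clusters(np.array([[5.0, 0.0]]), model)[0] == 1

    def test_matches_brute_force(self, model):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-5, 15, size=(100, 2))
        got = hm.assign_clusters(pts, model)
        labels = sorted(model.centroids)
        for i, pt in enumerate(pts):
            dists = [np.linalg.norm(pt - model.centroids[l]) for l in labels]
            assert got[i] == labels[int(np.argmin(dists))]


class TestTransferAnnotation:
    def _map_with_phenotypes(self, phenotypes, labels):
        n = len(phenotypes)
        rng = np.random.default_rng(0)
        expr = hm.ExpressionMatrix(rng.normal(7, 1, (10, n)),
                                   [f"g{i}" for i in range(10)],
                                   [f"s{i}" for i in range(n)])
        labels = np.asarray(labels)
        coords = np.stack([labels * 10.0, np.zeros(n)], axis=1)
        centroids = {int(l): np.array([l * 10.0, 0.0]) for l in np.unique(labels)}
        ann = pd.DataFrame({"sample_id": expr.sample_ids,
                            "study_id": "E1", "phenotype": phenotypes,
                            "platform": None})
        return hm.ReferenceMap(
            feature_ids=expr.gene_ids, embedding=coords,
            tsne_params={"perplexity": 5.0, "theta": 0.5, "seed": 0,
                         "metric": "euclidean"},
            cluster_labels=labels, centroids=centroids, bandwidth=1.5,
            annotations=ann, reference_expression=expr)

    def test_majority_vote(self):
        ref = self._map_with_phenotypes(["A", "A", "B"], [1, 1, 1])
        assert hm.transfer_annotation([1], ref) == ["A"]

    def test_tie_is_ambiguous(self):
        ref = self._map_with_phenotypes(["A", "B"], [1, 1])
        assert hm.transfer_annotation([1], ref) == ["ambiguous"]

    def test_unannotated_cluster_is_unlabeled(self):
        ref = self._map_with_phenotypes([None, None, "A"], [1, 1, 2])
        assert hm.transfer_annotation([1, 2], ref) == ["unlabeled", "A"]


class TestDiagnostics:
    def test_margin_equals_direct_group_means(self):
        rng = np.random.default_rng(0)
        n_feat = 30
        expr = hm.ExpressionMatrix(rng.normal(7, 1, (n_feat, 9)),
                                   [f"g{i}" for i in range(n_feat)],
                                   [f"s{i}" for i in range(9)])
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        coords = np.stack([labels * 5.0, np.zeros(9)], axis=1)
        ann = pd.DataFrame({"sample_id": expr.sample_ids, "study_id": "E1",
                            "phenotype": "A", "platform": None})
        ref = hm.ReferenceMap(
            feature_ids=expr.gene_ids, embedding=coords,
            tsne_params={"perplexity": 3.0, "theta": 0.5, "seed": 0,
                         "metric": "euclidean"},
            cluster_labels=labels,
            centroids={l: np.array([l * 5.0, 0.0]) for l in (1, 2, 3)},
            bandwidth=1.5, annotations=ann, reference_expression=expr)
        new = hm.ExpressionMatrix(rng.normal(7, 1, (n_feat, 1)),
                                  expr.gene_ids, ["new1"])
        table = remap_diagnostics(new, ref, np.array([2]),
                                  max_r_threshold=-1.0)
        r = np.array([np.corrcoef(new.values[:, 0], expr.values[:, j])[0, 1]
                      for j in range(9)])
        means = {l: r[labels == l].mean() for l in (1, 2, 3)}
        assert table.loc[0, "max_r"] == pytest.approx(r.max(), abs=1e-12)
        assert table.loc[0, "assigned_cluster_mean_r"] == pytest.approx(
            means[2], abs=1e-12)
        assert table.loc[0, "margin"] == pytest.approx(
            means[2] - max(means[1], means[3]), abs=1e-12)
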