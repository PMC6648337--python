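import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import hemamap as hm
from hemamap.correspondence import (
    _GsvaEngine,
    _nearest_bin,
    cluster_enrichment,
    consistent_enrichment,
)


def _matrix(rng, p, n, prefix="g"):
    return hm.ExpressionMatrix(rng.normal(7, 1, (p, n)),
                               [f"{prefix}{i}" for i in range(p)],
                               [f"s{i}" for i in range(n)])


class TestClusterGenesets:
    def test_indicator_gene_lands_in_up_set(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng, 50, 12)
        labels = np.array([1] * 6 + [2] * 6)
        values = m.values.copy()
        values[0] = (labels == 1) * 3.0 + rng.normal(0, 0.01, 12)
        m = hm.ExpressionMatrix(values, m.gene_ids, m.sample_ids)
        sets = hm.cluster_genesets(m, labels, n_top=20)
        assert "g0" in sets["C1_UP"].genes

    def test_truncation_to_significant_genes(self):
        # only 8 genes are associated with cluster 1; the rest is pure noise,
        # so the up set holds at most the significant ones (alpha leaks a few)
        rng = np.random.default_rng(1)
        labels = np.array([1] * 10 + [2] * 10)
        values = rng.normal(7, 1, (200, 20))
        values[:8, labels == 1] += 4.0
        m = hm.ExpressionMatrix(values, [f"g{i}" for i in range(200)],
                                [f"s{i}" for i in range(20)])
        sets = hm.cluster_genesets(m, labels, n_top=20, p_threshold=1e-4)
        assert set(sets["C1_UP"].genes) == {f"g{i}" for i in range(8)}

    def test_small_cluster_rejected(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng, 20, 8)
        with pytest.raises(ValueError, match="fewer than 3"):
            hm.cluster_genesets(m, np.array([1, 1, 1, 1, 1, 1, 2, 2]))

    def test_planted_modules_recovered(self):
        design = hm.SimulationDesign(n_genes=400, n_phenotypes=3,
                                     samples_per_phenotype=15, n_studies=3,
                                     module_size=30, effect_size=3.0,
                                     batch_sd=0.2, noise_sd=0.5)
        m, ann, truth = hm.generate_collection(design, seed=5)
        sets = hm.cluster_genesets(m, ann["phenotype"].to_numpy(), n_top=20)
        for ph in ("P1", "P2", "P3"):
            planted = set(truth["modules"][ph])
            assert set(sets[f"C{ph}_UP"].genes) <= planted


class TestGsvaScores:
    def brute_walk(self, engine, idx, sample):
        """Full O(p) enumeration of the weighted KS random walk."""
        pos = engine.positions[:, sample]
        order = np.argsort(pos)
        in_set = np.isin(order, idx)
        w = engine.w_tau[pos[order]]
        total_in = w[in_set].sum()
        dec = 1.0 / (engine.p - len(idx))
        nu, best = 0.0, 0.0
        for g in range(engine.p):
            nu = nu + w[g] / total_in if in_set[g] else nu - dec
            if abs(nu) > abs(best) or (abs(nu) == abs(best) and nu > best):
                best = nu
        return best

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng, 10, 3)
        engine = _GsvaEngine(m)
        for idx in ([0, 1, 2, 3, 4], [0, 9, 5], [2, 3, 4, 5, 6, 7]):
            idx = np.array(idx)
            fast = engine.score_indices(idx)
            for j in range(3):
                assert fast[j] == pytest.approx(self.brute_walk(engine, idx, j),
                                                abs=1e-12)

    def test_top_ranked_set_scores_positive_maximum(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng, 100, 10)
        engine = _GsvaEngine(m)
        target = 4
        top = np.argsort(engine.positions[:, target])[:20]  # best-ranked genes in s4
        sets = hm.GeneSetCollection(
            [hm.GeneSet("TOP", [m.gene_ids[i] for i in top])])
        scores = hm.gsva_scores(m, sets)["TOP"]
        assert scores.iloc[target] > 0
        assert scores.idxmax() == m.sample_ids[target]

    def test_undersized_set_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        m = _matrix(rng, 30, 5)
        sets = hm.GeneSetCollection([
            hm.GeneSet("TINY", ["g0", "g1", "missing_a", "missing_b"]),
            hm.GeneSet("OK", [f"g{i}" for i in range(10)]),
        ])
        with caplog.at_level("WARNING"):
            scores = hm.gsva_scores(m, sets)
        assert list(scores.columns) == ["OK"]
        assert "TINY" in caplog.text

    def test_reversed_regulation_flips_score_sign(self):
        rng = np.random.default_rng(5)
        values = rng.normal(7, 1, (100, 20))
        affected = np.arange(10) >= 0  # first 10 samples
        values[:15, :10] += 3.0    # up in first half
        m = hm.ExpressionMatrix(values, [f"g{i}" for i in range(100)],
                                [f"s{i}" for i in range(20)])
        down = values.copy()
        down[:15] = 14.0 - (down[:15] - 0.0) + 0.0  # mirror the module genes
        m_down = hm.ExpressionMatrix(down, m.gene_ids, m.sample_ids)
        sets = hm.GeneSetCollection([hm.GeneSet("MOD",
                                                [f"g{i}" for i in range(15)])])
        up_scores = hm.gsva_scores(m, sets)["MOD"].to_numpy()[:10]
        down_scores = hm.gsva_scores(m_down, sets)["MOD"].to_numpy()[:10]
        assert up_scores.mean() > 0 > down_scores.mean()

    def test_poisson_kernel_on_counts(self):
        design = hm.SimulationDesign(n_genes=80, n_phenotypes=2,
                                     samples_per_phenotype=5, module_size=10,
                                     rnaseq_mode=True)
        m, _, truth = hm.generate_collection(design, seed=6)
        counts = hm.ExpressionMatrix(truth["counts"].to_numpy(dtype=float),
                                     m.gene_ids, m.sample_ids)
        sets = hm.GeneSetCollection([hm.GeneSet("P1_MOD",
                                                truth["modules"]["P1"])])
        scores = hm.gsva_scores(counts, sets, kcdf="poisson")["P1_MOD"]
        assert scores.iloc[:5].mean() > scores.iloc[5:].mean()


class TestEmpiricalPvalues:
    def test_score_beyond_all_permutations_gives_zero(self):
        rng = np.random.default_rng(0)
        values = rng.normal(7, 0.5, (60, 6))
        values[:10, 0] += 50.0  # sample s0 extreme in the set genes
        m = hm.ExpressionMatrix(values, [f"g{i}" for i in range(60)],
                                [f"s{i}" for i in range(6)])
        sets = hm.GeneSetCollection([hm.GeneSet("HOT",
                                                [f"g{i}" for i in range(10)])])
        res = hm.empirical_pvalues(m, sets, n_permutations=200, seed=1)
        assert res.empirical_p.loc["s0", "HOT"] == 0.0
        assert res.empirical_p_stable.loc["s0", "HOT"] > 0.0
        assert (res.adjusted_p.to_numpy() >= res.empirical_p.to_numpy()).all()

    def test_nearest_bin_rule(self):
        bins = list(range(5, 21)) + [25, 30, 40]
        assert _nearest_bin(23, bins) == 25   # 25 is closer than 20
        assert _nearest_bin(22, bins) == 20   # 20 is closer than 25
        assert _nearest_bin(7, bins) == 7     # sizes 5-20 are their own bins
        assert _nearest_bin(35, bins) == 40   # tie between 30 and 40 -> upward

    def test_zero_permutations_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            hm.empirical_pvalues(tiny_matrix, hm.GeneSetCollection(),
                                 n_permutations=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng, 50, 5)
        sets = hm.GeneSetCollection([hm.GeneSet("S",
                                                [f"g{i}" for i in range(8)])])
        a = hm.empirical_pvalues(m, sets, n_permutations=100, seed=9)
        b = hm.empirical_pvalues(m, sets, n_permutations=100, seed=9)
        assert a.empirical_p.equals(b.empirical_p)


class TestClusterEnrichment:
    def test_matches_exact_tail_sum(self):
        # 100 samples, 20 significant, cluster of 10 holding 8 of them
        flags = np.zeros(100, dtype=bool)
        flags[:8] = True      # in cluster
        flags[10:22] = True   # outside cluster
        clusters = np.array([1] * 10 + [2] * 90)
        sig = pd.DataFrame({"S": flags})
        table = cluster_enrichment(sig, clusters)
        row = table[(table["set"] == "S") & (table["cluster"] == 1)].iloc[0]
        from math import comb
        exact = sum(comb(20, k) * comb(80, 10 - k) for k in range(8, 11)) / comb(100, 10)
        assert row["p"] == pytest.approx(exact, abs=1e-12)
        assert row["overlap"] == 8

    def test_no_significant_in_cluster_gives_p_one(self):
        sig = pd.DataFrame({"S": [False] * 5 + [True] * 5})
        clusters = np.array([1] * 5 + [2] * 5)
        table = cluster_enrichment(sig, clusters)
        row = table[(table["cluster"] == 1)].iloc[0]
        assert row["p"] == pytest.approx(1.0)

    def test_all_significant_gives_p_one(self):
        sig = pd.DataFrame({"S": [True] * 10})
        clusters = np.array([1] * 5 + [2] * 5)
        table = cluster_enrichment(sig, clusters)
        assert np.allclose(table["p"].to_numpy(), 1.0)


class TestMatchMaps:
    def test_self_match(self):
        design = hm.SimulationDesign(n_genes=400, n_phenotypes=3,
                                     samples_per_phenotype=15, n_studies=3,
                                     module_size=30, effect_size=3.0,
                                     batch_sd=0.2)
        m, ann, _ = hm.generate_collection(design, seed=8)
        labels = ann["phenotype"].map({"P1": 1, "P2": 2, "P3": 3}).to_numpy()
        sets = hm.cluster_genesets(m, labels, n_top=20)
        table = hm.match_maps(sets, m, labels, alpha=0.001,
                              n_permutations=300, seed=0)
        best = table[table["best_match"]]
        for _, row in best.iterrows():
            assert f"C{row['cluster']}" == row["source_cluster"]


class TestConsistentEnrichment:
    small = pd.DataFrame({
        "set": ["A", "B", "C", "D"],
        "cluster": [1, 1, 2, 2],
        "correlation": [0.8, 0.7, -0.6, 0.5],
        "p": [0.04, 0.06, 0.01, 0.002],
    })
    large = pd.DataFrame({
        "set": ["A", "B", "C", "D"],
        "cluster": [1, 1, 2, 2],
        "correlation": [0.9, 0.8, 0.7, 0.6],
        "adj_p": [5e-4, 1e-5, 1e-5, 0.01],
    })

    def test_threshold_and_sign_rules(self):
        kept = consistent_enrichment(self.small, self.large)
        # A passes; B fails small p; C fails sign; D fails large adj p
        assert kept == ["A"]

    def test_unmatched_cluster_ids_rejected(self):
        bad = self.large.copy()
        bad.loc[0, "cluster"] = 9
        with pytest.raises(ValueError, match="cluster"):
            consistent_enrichment(self.small, bad)
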