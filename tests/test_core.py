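import numpy as np
import pytest
from scipy.stats import norm as norm_dist
from sklearn.metrics import adjusted_rand_score

from clustrat.core import (
    STATUS_DEGENERATE,
    STATUS_OK,
    ClustratConfig,
    ahc,
    cluster_assoc,
    clustrat,
    cut_to_k,
    meta_analyze,
    prune_inconsistency,
    select_k_cv,
)
from clustrat.grm import DistanceMatrix, mahalanobis_grm
from clustrat.io_genotype import Phenotype, impute_and_normalize
from clustrat.simulate import (
    PhenotypeConfig,
    SimulationConfig,
    simulate_bn,
    simulate_phenotype,
)
from conftest import normalized_random


def toy_distance(D):
    D = np.asarray(D, dtype=float)
    return DistanceMatrix(D, None, 1)


class TestAhc:
    def test_two_samples_single_merge(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        cm = ahc(toy_distance(D))
        assert cm.linkage_tree.shape == (1, 4)
        assert abs(cm.linkage_tree[0, 2] - 2.0) < 1e-12  # sqrt(4)

    def test_duplicates_merge_first_at_zero(self, rng):
        x = normalized_random(rng, 8, 20)
        X = x.X.copy()
        X[3] = X[1]
        d = mahalanobis_grm(X, k=3, seed=0)
        cm = ahc(d)
        assert cm.linkage_tree[0, 2] < 1e-6
        assert set(cm.linkage_tree[0, :2].astype(int)) == {1, 3}

    def test_block_structure_recovered_at_k2(self):
        # two zero-distance blocks joined at large height
        D = np.full((6, 6), 100.0)
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        np.fill_diagonal(D, 0.0)
        cm = ahc(toy_distance(D))
        lab = cut_to_k(cm, 2)
        assert len(set(lab[:3])) == 1 and len(set(lab[3:])) == 1
        assert lab[0] != lab[3]

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            ahc(DistanceMatrix(np.zeros((1, 1)), None, 1))

    def test_bn_three_populations_recovered(self):
        cfg = SimulationConfig(model="BN", m=300, n=2000, d=3, fst=0.1, seed=0)
        g, truth = simulate_bn(cfg)
        x = impute_and_normalize(g)
        d = mahalanobis_grm(x, k=2, seed=0)
        lab = cut_to_k(ahc(d), 3)
        assert adjusted_rand_score(truth.pop_labels, lab) >= 0.95


class TestCutToK:
    def test_k1_and_km(self, rng):
        cm = ahc(toy_distance(_rand_dist(rng, 7)))
        assert len(set(cut_to_k(cm, 1))) == 1
        assert len(set(cut_to_k(cm, 7))) == 7

    def test_out_of_range(self, rng):
        cm = ahc(toy_distance(_rand_dist(rng, 5)))
        with pytest.raises(ValueError):
            cut_to_k(cm, 0)
        with pytest.raises(ValueError):
            cut_to_k(cm, 6)


def _rand_dist(rng, m):
    P = rng.standard_normal((m, 3))
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(P, "sqeuclidean"))


class TestInconsistencyPruning:
    def test_equal_heights_give_one_cluster(self):
        # chain with identical merge heights: all coefficients 0
        D = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        cm = ahc(toy_distance(D**2), method="single")
        assert prune_inconsistency(cm, depth=2, threshold=0.5) == 1

    def test_infinite_threshold_gives_one_cluster(self, rng):
        cm = ahc(toy_distance(_rand_dist(rng, 12)))
        assert prune_inconsistency(cm, threshold=np.inf) == 1

    def test_two_tight_clusters_detected(self):
        # 3+3 points, within-distance 1, between-distance 400
        D = np.full((6, 6), 400.0)
        for blk in (slice(0, 3), slice(3, 6)):
            D[blk, blk] = 1.0
        np.fill_diagonal(D, 0.0)
        cm = ahc(toy_distance(D))
        assert prune_inconsistency(cm, depth=2, threshold=1.15) == 2

    def test_depth_validation(self, rng):
        cm = ahc(toy_distance(_rand_dist(rng, 6)))
        with pytest.raises(ValueError):
            prune_inconsistency(cm, depth=0)


class TestClusterAssoc:
    def test_ols_matches_closed_form_oracle(self, rng):
        m, n = 40, 6
        X = rng.standard_normal((m, n))
        y = rng.standard_normal(m)
        res = cluster_assoc(X, Phenotype(y, "quantitative"),
                            np.ones(m, dtype=int), min_cluster_size=2)
        for j in range(n):
            # textbook simple-regression formulas, computed independently
            g = X[:, j]
            b = np.cov(g, y, bias=True)[0, 1] / g.var()
            resid = (y - y.mean()) - b * (g - g.mean())
            se = np.sqrt((resid**2).sum() / (m - 2) / ((g - g.mean()) ** 2).sum())
            assert abs(res.beta[0, j] - b) < 1e-8
            assert abs(res.se[0, j] - se) < 1e-8

    def test_logistic_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        m = 120
        g = rng.binomial(2, 0.4, size=m).astype(float)
        logits = -0.5 + 0.6 * g
        y = (rng.random(m) < 1 / (1 + np.exp(-logits))).astype(float)
        res = cluster_assoc(g[:, None], Phenotype(y, "binary"),
                            np.ones(m, dtype=int),
                            min_cluster_size=2, min_class_count=1)
        fit = sm.Logit(y, np.column_stack([np.ones(m), g])).fit(disp=0)
        assert abs(res.beta[0, 0] - fit.params[1]) < 1e-5
        assert abs(res.se[0, 0] - fit.bse[1]) < 1e-5

    def test_constant_genotype_flagged_degenerate(self, rng):
        m = 30
        X = rng.standard_normal((m, 3))
        X[:, 1] = 2.0
        res = cluster_assoc(X, Phenotype(rng.standard_normal(m), "quantitative"),
                            np.ones(m, dtype=int), min_cluster_size=2)
        assert res.status[0, 1] == STATUS_DEGENERATE
        assert np.isnan(res.p[0, 1])
        assert (res.status[0, [0, 2]] == STATUS_OK).all()

    def test_small_cluster_skipped_entirely(self, rng):
        X = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        lab = np.ones(60, dtype=int)
        lab[:5] = 2
        res = cluster_assoc(X, Phenotype(y, "quantitative"), lab,
                            min_cluster_size=10)
        small = list(res.cluster_labels).index(2)
        assert (res.status[small] == "no-data").all()

    def test_null_p_fraction_nominal(self, rng):
        # permuted trait: ~5% of p-values below 0.05
        m, n = 400, 2000
        X = rng.standard_normal((m, n))
        y = rng.permutation(rng.standard_normal(m))
        res = cluster_assoc(X, Phenotype(y, "quantitative"),
                            np.ones(m, dtype=int), min_cluster_size=2)
        frac = (res.p[0] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_z_consistent_with_p(self, rng):
        X = rng.standard_normal((50, 5))
        res = cluster_assoc(X, Phenotype(rng.standard_normal(50), "quantitative"),
                            np.ones(50, dtype=int), min_cluster_size=2)
        ok = res.status == STATUS_OK
        recomputed = 2 * norm_dist.sf(np.abs(res.z[ok]))
        np.testing.assert_allclose(res.p[ok], recomputed, atol=1e-6)


class TestMetaAnalyze:
    def _single_result(self, z_by_cluster, n_by_cluster):
        from clustrat.core import AssocResult

        nc = len(z_by_cluster)
        z = np.array(z_by_cluster, dtype=float)[:, None]
        se = np.ones((nc, 1))
        beta = z * se
        status = np.full((nc, 1), STATUS_OK, dtype=object)
        return AssocResult(beta, se, z, 2 * norm_dist.sf(np.abs(z)), status,
                           np.array(n_by_cluster), np.arange(1, nc + 1),
                           "linear")

    def test_single_cluster_identity(self):
        res = self._single_result([1.7], [100])
        meta = meta_analyze(res)
        assert abs(meta.meta_z[0] - 1.7) < 1e-12
        assert abs(meta.meta_p[0] - 2 * norm_dist.sf(1.7)) < 1e-12

    def test_equal_pair_scales_by_sqrt2(self):
        meta = meta_analyze(self._single_result([2.0, 2.0], [50, 50]))
        assert abs(meta.meta_z[0] - 2.0 * np.sqrt(2)) < 1e-12

    def test_opposing_pair_cancels(self):
        meta = meta_analyze(self._single_result([2.0, -2.0], [50, 50]))
        assert abs(meta.meta_z[0]) < 1e-12
        assert abs(meta.meta_p[0] - 1.0) < 1e-12

    def test_direction_string(self):
        meta = meta_analyze(self._single_result([2.0, -2.0], [50, 50]))
        assert meta.direction[0] == "+-"

    def test_inverse_variance_rule(self):
        from clustrat.core import AssocResult

        beta = np.array([[1.0], [3.0]])
        se = np.array([[1.0], [2.0]])
        status = np.full((2, 1), STATUS_OK, dtype=object)
        res = AssocResult(beta, se, beta / se,
                          2 * norm_dist.sf(np.abs(beta / se)), status,
                          np.array([10, 10]), np.array([1, 2]), "linear")
        meta = meta_analyze(res, method="inverse_variance")
        w = 1 / se[:, 0] ** 2
        expect_beta = (beta[:, 0] * w).sum() / w.sum()
        assert abs(meta.meta_beta[0] - expect_beta) < 1e-12
        assert abs(meta.meta_se[0] - w.sum() ** -0.5) < 1e-12

    def test_no_contributing_cluster_flagged(self):
        res = self._single_result([1.0], [100])
        res.status[:] = STATUS_DEGENERATE
        meta = meta_analyze(res)
        assert meta.status[0] == "no-data"
        assert np.isnan(meta.meta_p[0])


class TestSelectK:
    def test_singleton_candidate_returned(self, rng):
        X = rng.standard_normal((40, 10))
        y = Phenotype(rng.standard_normal(40), "quantitative")
        d = mahalanobis_grm(X, k=2, seed=0)
        assert select_k_cv(X, y, d, d=2, q_range=(0, 0), min_cluster_size=20,
                           seed=0) == 2

    def test_degenerate_distances_return_smallest(self, rng):
        X = rng.standard_normal((30, 8))
        y = Phenotype(rng.standard_normal(30), "quantitative")
        d = DistanceMatrix(np.zeros((30, 30)), None, 1)
        assert select_k_cv(X, y, d, d=2, q_range=(0, 2), min_cluster_size=5,
                           seed=0) == 2

    def test_empty_candidate_set_errors(self, rng):
        X = rng.standard_normal((20, 8))
        y = Phenotype(rng.standard_normal(20), "quantitative")
        d = mahalanobis_grm(X, k=2, seed=0)
        with pytest.raises(ValueError, match="candidate"):
            select_k_cv(X, y, d, d=50, q_range=(0, 0), min_cluster_size=50)

    def test_recovers_true_population_count(self):
        hits = 0
        for seed in range(5):
            g, _ = simulate_bn(SimulationConfig(model="BN", m=800, n=1500,
                                                d=3, fst=0.1, seed=seed))
            x = impute_and_normalize(g, min_maf=0.05)
            y, _ = simulate_phenotype(x, PhenotypeConfig(
                n_causal=10, h2=0.9, trait_kind="quantitative",
                seed=seed + 100))
            d = mahalanobis_grm(x, k=2, seed=0)
            if select_k_cv(x, y, d, d=3, q_range=(0, 3), seed=seed) == 3:
                hits += 1
        assert hits >= 4


class TestPipeline:
    def test_single_cluster_equals_plain_regression(self, rng):
        X = rng.standard_normal((80, 30))
        X = (X - X.mean(0)) / X.std(0)
        y = Phenotype(rng.standard_normal(80), "quantitative")
        cfg = ClustratConfig(n_clusters=1, k_svd=3, min_cluster_size=2, seed=0)
        meta, cm = clustrat(X, y, cfg)
        res = cluster_assoc(X, y, np.ones(80, dtype=int), min_cluster_size=2)
        np.testing.assert_allclose(meta.meta_p, res.p[0], atol=1e-12)
        assert cm.chosen_k == 1

    def test_sample_permutation_invariance(self, rng):
        g, _ = simulate_bn(SimulationConfig(model="BN", m=150, n=300, d=2,
                                            fst=0.1, seed=4))
        x = impute_and_normalize(g)
        y = rng.standard_normal(150)
        perm = rng.permutation(150)
        cfg = ClustratConfig(n_clusters=2, d=2, min_cluster_size=10, seed=0)
        meta1, _ = clustrat(x.X, Phenotype(y, "quantitative"), cfg)
        meta2, _ = clustrat(x.X[perm], Phenotype(y[perm], "quantitative"), cfg)
        np.testing.assert_allclose(meta1.meta_p, meta2.meta_p, atol=1e-10)

    def test_null_trait_no_genomewide_hits(self, rng):
        g, _ = simulate_bn(SimulationConfig(model="BN", m=400, n=5000, d=3,
                                            fst=0.1, seed=6))
        x = impute_and_normalize(g)
        y = Phenotype(rng.standard_normal(400), "quantitative")
        cfg = ClustratConfig(n_clusters=3, d=3, seed=0)
        meta, _ = clustrat(x, y, cfg)
        hits = np.nansum(meta.meta_p < 5e-8)
        assert hits == 0

    def test_cluster_recovery_at_true_k(self):
        g, truth = simulate_bn(SimulationConfig(model="BN", m=300, n=2000,
                                                d=3, fst=0.05, seed=7))
        x = impute_and_normalize(g)
        y = Phenotype(np.random.default_rng(0).standard_normal(300),
                      "quantitative")
        cfg = ClustratConfig(n_clusters=3, d=3, min_cluster_size=10, seed=0)
        _, cm = clustrat(x, y, cfg)
        assert adjusted_rand_score(truth.pop_labels, cm.assignment) >= 0.9
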