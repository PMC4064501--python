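import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptk import (
    ConsensusModel,
    GenotypeCounts,
    compute_features,
    estimate_consensus,
    feature_D,
    feature_H,
    feature_R,
    k1_confidence,
    kmeans_1d,
    map_clusters_to_genotypes,
    silhouette_widths,
)
from adaptk.cluster_core import kmeans_1d_seeded
from adaptk.errors import EstimationError, ParameterError

from .oracles import brute_kmeans_1d, brute_mahalanobis, brute_silhouette


class TestKmeans1d:
    def test_two_tight_clusters(self):
        fit = kmeans_1d([0, 0, 10, 10], 2)
        np.testing.assert_allclose(fit.centers, [10.0, 0.0])
        assert fit.within_ss == 0.0

    def test_derived_partition(self):
        # enumerating contiguous 2-partitions of [1,2,3,10]: {1,2,3}/{10} wins
        fit = kmeans_1d([1, 2, 3, 10], 2)
        np.testing.assert_allclose(fit.centers, [10.0, 2.0])
        assert fit.within_ss == pytest.approx(2.0)

    def test_k1_closed_form(self):
        v = np.array([1.5, -2.0, 0.25, 7.0])
        fit = kmeans_1d(v, 1)
        assert fit.centers[0] == pytest.approx(v.mean())
        assert fit.within_ss == pytest.approx(np.sum((v - v.mean()) ** 2))

    def test_centers_decreasing_and_assignments(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        for k in (2, 3):
            fit = kmeans_1d(v, k)
            assert np.all(np.diff(fit.centers) < 0)
            for c in range(k):
                members = v[fit.assignments == c]
                assert members.mean() == pytest.approx(fit.centers[c])

    def test_degenerate_fewer_distinct_values(self):
        fit = kmeans_1d([1.0, 1.0, 1.0], 2)
        assert fit.degenerate
        assert fit.k_eff == 1
        assert fit.centers[0] == fit.centers[1] == 1.0

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(42)
        for n in range(2, 13):
            for k in (1, 2, 3):
                if k > n:
                    continue
                for _ in range(5):
                    v = rng.normal(size=n)
                    fit = kmeans_1d(v, k)
                    ss, centers = brute_kmeans_1d(v, k)
                    assert fit.within_ss == pytest.approx(ss, abs=1e-9)
                    np.testing.assert_allclose(fit.centers, centers, atol=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12), st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_hypothesis(self, values, k):
        v = np.asarray(values)
        if np.unique(v).size < k:
            return
        fit = kmeans_1d(v, k)
        ss, _ = brute_kmeans_1d(v, k)
        assert fit.within_ss == pytest.approx(ss, abs=1e-7)

    def test_rejects_bad_k(self):
        with pytest.raises(ParameterError):
            kmeans_1d([1, 2, 3], 4)

    def test_deterministic(self):
        v = np.random.default_rng(3).normal(size=40)
        a = kmeans_1d(v, 3)
        b = kmeans_1d(v, 3)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.centers, b.centers)


class TestKmeansSeeded:
    def test_recovers_from_consensus_start(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(2, 0.2, 50), rng.normal(0, 0.2, 30),
                            rng.normal(-2, 0.2, 2)])
        fit = kmeans_1d_seeded(v, [2.0, 0.0, -2.0])
        assert fit is not None
        np.testing.assert_allclose(fit.centers, [2, 0, -2], atol=0.25)

    def test_empty_basin_returns_none(self):
        v = np.concatenate([np.random.default_rng(2).normal(2, 0.1, 40)])
        assert kmeans_1d_seeded(v, [2.0, 0.0, -2.0]) is None


class TestEstimateConsensus:
    def test_exact_shared_centers(self):
        # each SNP holds the same three tight clusters
        row = np.repeat([1.0, 0.0, -1.0], 4)
        M = np.tile(row, (10, 1))
        model = estimate_consensus(M)
        np.testing.assert_allclose(model.mu, [1.0, 0.0, -1.0], atol=1e-12)
        np.testing.assert_allclose(model.V, 0.0, atol=1e-12)

    def test_recovers_generative_centers(self):
        rng = np.random.default_rng(0)
        n_snps = 2000
        base = np.array([2.0, 0.0, -2.0])
        rows = []
        for _ in range(n_snps):
            centers = base + rng.normal(0, 0.1, 3)
            rows.append(np.repeat(centers, 5) + rng.normal(0, 1e-4, 15))
        model = estimate_consensus(np.array(rows))
        np.testing.assert_allclose(model.mu, base, atol=0.02)
        np.testing.assert_allclose(np.diag(model.V), 0.01, rtol=0.2)

    def test_subset_order_invariance(self):
        rng = np.random.default_rng(5)
        M = np.array([np.repeat([2, 0, -2], 4) + rng.normal(0, 0.05, 12)
                      for _ in range(50)])
        idx = np.arange(50)
        a = estimate_consensus(M, snp_subset=idx)
        b = estimate_consensus(M, snp_subset=idx[::-1])
        np.testing.assert_allclose(a.mu, b.mu)
        np.testing.assert_allclose(a.V, b.V)

    def test_all_degenerate_errors(self):
        with pytest.raises((EstimationError, ParameterError)):
            estimate_consensus(np.ones((5, 10)))


class TestGenotypeMapping:
    def test_k2_maps_to_AA_AB(self, consensus):
        fit = kmeans_1d([2.1, 2.1, 2.1, -0.05, -0.05, -0.05], 2)
        np.testing.assert_allclose(fit.centers, [2.1, -0.05])
        map_clusters_to_genotypes(fit, consensus)
        assert fit.genotype_map == (0, 1)

    def test_k1_maps_to_nearest(self, consensus):
        fit = kmeans_1d([-1.9, -1.9, -1.9], 1)
        map_clusters_to_genotypes(fit, consensus)
        assert fit.genotype_map == (2,)

    def test_k3_identity(self, consensus):
        fit = kmeans_1d([2, 2, 0, 0, -2, -2], 3)
        map_clusters_to_genotypes(fit, consensus)
        assert fit.genotype_map == (0, 1, 2)

    def test_restricted_classes(self, consensus):
        fit = kmeans_1d([2.0, 2.0, -1.8, -1.8], 2)
        map_clusters_to_genotypes(fit, consensus, allowed_classes=(0, 2))
        assert fit.genotype_map == (0, 2)


class TestFeatureR:
    def test_perfect_clusters_zero(self):
        fit = kmeans_1d([1, 1, 5, 5], 2)
        assert feature_R([1, 1, 5, 5], fit) == 0.0

    def test_derived_value(self):
        v = [1, 2, 3, 10]
        assert feature_R(v, kmeans_1d(v, 2)) == pytest.approx(2.0)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            v = rng.normal(size=rng.integers(4, 40))
            r = [kmeans_1d(v, k).within_ss for k in (1, 2, 3)]
            assert r[0] >= r[1] - 1e-12
            assert r[1] >= r[2] - 1e-12


class TestFeatureD:
    def test_zero_at_consensus(self, consensus):
        fit = kmeans_1d([2, 2, 0, 0, -2, -2], 3)
        map_clusters_to_genotypes(fit, consensus)
        assert feature_D(fit, consensus) == pytest.approx(0.0, abs=1e-9)

    def test_unit_offset_identity_V(self):
        cons = ConsensusModel(mu=np.array([2.0, 0.0, -2.0]), V=np.eye(3))
        v = np.repeat([3.0, 0.0, -2.0], 3)  # AA center shifted by +1
        fit = kmeans_1d(v, 3)
        map_clusters_to_genotypes(fit, cons)
        assert feature_D(fit, cons) == pytest.approx(1.0, abs=1e-9)

    def test_matches_explicit_quadratic_form(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(3, 3))
        V = A @ A.T + np.eye(3) * 0.5
        cons = ConsensusModel(mu=np.array([2.0, 0.0, -2.0]), V=V)
        for _ in range(100):
            centers = np.sort(rng.normal([2, 0, -2], 0.4))[::-1]
            v = np.repeat(centers, 3)
            fit = kmeans_1d(v, 3)
            map_clusters_to_genotypes(fit, cons)
            expected = brute_mahalanobis(fit.centers, cons.mu, V)
            assert feature_D(fit, cons) == pytest.approx(expected, abs=1e-8)


class TestFeatureH:
    def test_exact_hwe_is_zero(self):
        counts = GenotypeCounts.from_counts([49, 42, 9])
        assert counts.p == pytest.approx(0.7)
        assert feature_H(counts) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed(self):
        # N=(50,0,50): p=0.5, expected (25,50,25), H = 25+50+25
        assert feature_H(GenotypeCounts.from_counts([50, 0, 50])) == pytest.approx(100.0)

    def test_nonnegative_and_matches_chisquare(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            N = rng.integers(0, 50, size=3)
            if N.sum() == 0 or N[0] + N[1] == 0 or N[1] + N[2] == 0:
                continue
            h = feature_H(GenotypeCounts.from_counts(N))
            assert h >= 0
            from .oracles import brute_hardy_weinberg

            assert h == pytest.approx(brute_hardy_weinberg(N), abs=1e-9)


class TestComputeFeatures:
    def test_three_tight_clusters(self, consensus):
        rng = np.random.default_rng(21)
        v = np.concatenate([
            rng.normal(2, 0.05, 25), rng.normal(0, 0.05, 50), rng.normal(-2, 0.05, 25)
        ])
        f = compute_features(v, consensus)
        assert f.R[2] < 1.0 < f.R[1] < f.R[0]
        assert f.D[2] < 1.0
        assert f.H[1] < 1.0

    def test_single_cluster_at_BB(self, consensus):
        v = np.random.default_rng(22).normal(-2, 0.05, 60)
        f = compute_features(v, consensus)
        assert f.R[0] < 0.5
        assert f.D[0] < 0.5

    def test_deterministic(self, consensus):
        v = np.random.default_rng(23).normal(size=50)
        a = compute_features(v, consensus).as_vector()
        b = compute_features(v, consensus).as_vector()
        np.testing.assert_array_equal(a, b)

    def test_permutation_invariant(self, consensus):
        rng = np.random.default_rng(24)
        v = rng.normal(size=50)
        a = compute_features(v, consensus).as_vector()
        b = compute_features(v[rng.permutation(50)], consensus).as_vector()
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestSilhouette:
    def test_hand_computed_example(self):
        v = np.array([0.0, 0.1, 5.0])
        fit = kmeans_1d(v, 2)
        sw = silhouette_widths(v, fit)
        i = int(np.argmin(v))
        assert sw[i] == pytest.approx((5.0 - 0.1) / 5.0)

    def test_singleton_is_zero(self):
        v = np.array([0.0, 0.1, 5.0])
        sw = silhouette_widths(v, kmeans_1d(v, 2))
        assert sw[int(np.argmax(v))] == 0.0

    def test_identical_pair_far_from_rest(self):
        v = np.array([5.0, 5.0, 0.0, 0.1, -0.1])
        sw = silhouette_widths(v, kmeans_1d(v, 2))
        assert sw[0] == pytest.approx(1.0)
        assert sw[1] == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            n = int(rng.integers(4, 50))
            v = rng.normal(size=n)
            for k in (2, 3):
                fit = kmeans_1d(v, k)
                if fit.degenerate:
                    continue
                np.testing.assert_allclose(
                    silhouette_widths(v, fit),
                    brute_silhouette(v, fit.assignments),
                    atol=1e-9,
                )

    def test_range(self):
        v = np.random.default_rng(33).normal(size=60)
        sw = silhouette_widths(v, kmeans_1d(v, 3))
        assert np.all(sw >= -1 - 1e-12) and np.all(sw <= 1 + 1e-12)


class TestK1Confidence:
    def test_in_unit_interval_and_monotone(self):
        v = np.array([0.0, 0.1, 0.5, 2.0])
        conf = k1_confidence(v, 0.0)
        assert np.all(conf > 0) and np.all(conf <= 1)
        assert conf[0] >= conf[1] >= conf[2] >= conf[3]

    def test_all_identical(self):
        np.testing.assert_array_equal(k1_confidence(np.ones(5), 1.0), np.ones(5))
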