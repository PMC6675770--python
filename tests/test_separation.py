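"""Class statistics estimation and the Mahalanobis separation distance."""

import numpy as np
import pytest

from chromosep import (
    ClassStatistics,
    RegionColorModel,
    closed_form_separation,
    estimate_class_stats,
    mahalanobis_distance,
)
from chromosep.base import DegenerateCovarianceError, InsufficientSampleError


class TestEstimateClassStats:
    def test_identical_samples_give_zero_covariance(self):
        stats = estimate_class_stats(np.tile([10.0, 20.0, 30.0], (8, 1)))
        assert np.array_equal(stats.mean, [10, 20, 30])
        assert np.array_equal(stats.covariance, np.zeros((3, 3)))

    def test_matches_direct_summation_on_hand_listed_vectors(self):
        x = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 5.0],
                      [2.0, 2.0, 9.0], [5.0, 10.0, 3.0]])
        stats = estimate_class_stats(x)
        # independent oracle: explicit pairwise-deviation summation
        mean = x.sum(axis=0) / 4
        cov = np.zeros((3, 3))
        for row in x:
            d = row - mean
            cov += np.outer(d, d)
        cov /= 3  # n - 1
        assert np.allclose(stats.mean, mean, atol=1e-12)
        assert np.allclose(stats.covariance, cov, atol=1e-12)
        assert stats.n == 4

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientSampleError):
            estimate_class_stats(np.zeros((3, 3)))

    def test_gaussian_mean_recovery_within_sampling_bound(self):
        rng = np.random.default_rng(99)
        true_mean = np.array([140.0, 90.0, 85.0])
        x = rng.multivariate_normal(true_mean, 100 * np.eye(3), size=2000)
        stats = estimate_class_stats(x)
        assert np.all(np.abs(stats.mean - true_mean) < 3 * 10 / np.sqrt(2000))


def _stats(mean, cov, n=2000):
    return ClassStatistics(mean=np.asarray(mean, float),
                           covariance=np.asarray(cov, float), n=n)


class TestMahalanobisDistance:
    def test_identical_stats_give_zero(self):
        a = _stats([100, 50, 50], np.eye(3))
        res = mahalanobis_distance(a, a)
        assert res.distance == 0.0 and not res.regularized

    def test_unit_covariance_euclidean_case(self):
        res = mahalanobis_distance(_stats([103, 50, 50], np.eye(3)),
                                   _stats([100, 50, 50], np.eye(3)))
        assert res.distance == pytest.approx(3.0, abs=1e-12)

    def test_matches_closed_form_oracle_on_random_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            mu_a = rng.uniform(60, 200, 3)
            mu_b = rng.uniform(60, 200, 3)
            a_mat, b_mat = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
            cov_a = a_mat @ a_mat.T * 4 + 0.5 * np.eye(3)
            cov_b = b_mat @ b_mat.T * 4 + 0.5 * np.eye(3)
            got = mahalanobis_distance(_stats(mu_a, cov_a),
                                       _stats(mu_b, cov_b)).distance
            want = closed_form_separation(RegionColorModel(mu_a, cov_a),
                                          RegionColorModel(mu_b, cov_b))
            assert got == pytest.approx(want, rel=1e-9)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(3, 3))
        a = _stats([120, 80, 60], m @ m.T + np.eye(3))
        b = _stats([100, 95, 70], 2 * np.eye(3))
        assert (mahalanobis_distance(a, b).distance
                == mahalanobis_distance(b, a).distance)

    def test_affine_invariance(self):
        """Applying one invertible linear map + offset to all samples of both
        classes leaves the distance unchanged."""
        rng = np.random.default_rng(5)
        xa = rng.multivariate_normal([140, 90, 85], 80 * np.eye(3), 800)
        xb = rng.multivariate_normal([120, 100, 95], 60 * np.eye(3), 800)
        amat = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        assert abs(np.linalg.det(amat)) > 1e-6
        offset = rng.normal(size=3) * 10
        before = mahalanobis_distance(estimate_class_stats(xa),
                                      estimate_class_stats(xb)).distance
        after = mahalanobis_distance(
            estimate_class_stats(xa @ amat.T + offset),
            estimate_class_stats(xb @ amat.T + offset)).distance
        assert after == pytest.approx(before, rel=1e-6)

    def test_distance_scales_linearly_with_mean_difference(self):
        cov = np.diag([9.0, 4.0, 1.0])
        base = np.array([100.0, 100.0, 100.0])
        delta = np.array([4.0, -2.0, 1.0])
        d1 = mahalanobis_distance(_stats(base + delta, cov),
                                  _stats(base, cov)).distance
        d2 = mahalanobis_distance(_stats(base + 2 * delta, cov),
                                  _stats(base, cov)).distance
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_consistency_median_within_5pct_over_replicates(self):
        """At n=2000/class the median estimated distance over 20 seeded
        replicates recovers the true Gaussian separation within 5%."""
        for true_d in (1.0, 3.0):
            estimates = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                delta = np.array([true_d, 0.0, 0.0]) * 10 / 2
                xa = rng.multivariate_normal([128, 110, 110] + delta,
                                             100 * np.eye(3), 2000)
                xb = rng.multivariate_normal([128, 110, 110] - delta,
                                             100 * np.eye(3), 2000)
                estimates.append(
                    mahalanobis_distance(estimate_class_stats(xa),
                                         estimate_class_stats(xb)).distance)
            assert np.median(estimates) == pytest.approx(true_d, rel=0.05)

    def test_zero_covariance_unequal_means_is_degenerate(self):
        with pytest.raises(DegenerateCovarianceError):
            mahalanobis_distance(_stats([1, 0, 0], np.zeros((3, 3))),
                                 _stats([0, 0, 0], np.zeros((3, 3))))

    def test_zero_covariance_equal_means_is_zero_not_error(self):
        res = mahalanobis_distance(_stats([5, 5, 5], np.zeros((3, 3))),
                                   _stats([5, 5, 5], np.zeros((3, 3))))
        assert res.distance == 0.0

    def test_near_singular_covariance_sets_regularized_flag(self):
        cov = np.diag([100.0, 100.0, 1e-12])
        res = mahalanobis_distance(_stats([110, 80, 80], cov),
                                   _stats([100, 80, 80], cov))
        assert res.regularized
        assert np.isfinite(res.distance) and res.distance > 0

    def test_count_weighted_pooling_matches_unweighted_at_equal_n(self):
        a = _stats([120, 80, 60], np.diag([4.0, 2.0, 1.0]), n=2000)
        b = _stats([100, 95, 70], np.diag([1.0, 3.0, 2.0]), n=2000)
        assert (mahalanobis_distance(a, b, "by_n").distance
                == pytest.approx(mahalanobis_distance(a, b).distance,
                                 rel=1e-12))
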