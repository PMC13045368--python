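"""Metric implementations against closed forms, brute-force loops, and
independent library oracles (scipy sqrtm, scikit-image SSIM)."""

import numpy as np
import pytest
import scipy.linalg
from skimage.metrics import structural_similarity as sk_ssim

from histobridge.metrics import (FeatureGaussian, cosine_distance, delta_fid,
                                 editing_effectiveness, fid,
                                 fit_feature_gaussian, inlier_scores,
                                 inverted_normalized_fid, retrieval_mv_at_k,
                                 ssim_map, structural_distance)


def _random_gaussian(rng, d):
    a = rng.standard_normal((d, d))
    return FeatureGaussian(mu=rng.standard_normal(d),
                           sigma=a @ a.T / d + np.eye(d) * 0.1, n=100)


class TestFitFeatureGaussian:
    def test_identical_rows_zero_covariance(self):
        g = fit_feature_gaussian(np.array([[1.0, 2.0], [1.0, 2.0]]))
        np.testing.assert_allclose(g.sigma, 0, atol=1e-12)

    def test_hand_sized_matrix(self):
        f = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 8.0]])
        g = fit_feature_gaussian(f)
        np.testing.assert_allclose(g.mu, [2.0, 4.0])
        # unbiased covariance computed by hand
        np.testing.assert_allclose(g.sigma, [[4.0, 7.0], [7.0, 13.0]])

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((10, 3))
        g1 = fit_feature_gaussian(f)
        g2 = fit_feature_gaussian(f[::-1])
        np.testing.assert_allclose(g1.mu, g2.mu)
        np.testing.assert_allclose(g1.sigma, g2.sigma)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_feature_gaussian(np.ones((1, 3)))


class TestFid:
    def test_zero_at_identity(self):
        g = _random_gaussian(np.random.default_rng(1), 4)
        assert fid(g, g) == pytest.approx(0.0, abs=1e-8)

    def test_one_dimensional_closed_form(self):
        a = FeatureGaussian(np.array([0.0]), np.array([[1.0]]), 10)
        b = FeatureGaussian(np.array([1.0]), np.array([[1.0]]), 10)
        assert fid(a, b) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_diagonal_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        d = 6
        mu1, mu2 = rng.standard_normal(d), rng.standard_normal(d)
        s1, s2 = rng.uniform(0.1, 2.0, d), rng.uniform(0.1, 2.0, d)
        a = FeatureGaussian(mu1, np.diag(s1), 10)
        b = FeatureGaussian(mu2, np.diag(s2), 10)
        # independent element-wise closed form for diagonal covariances
        expected = np.sum((mu1 - mu2) ** 2) + np.sum((np.sqrt(s1) - np.sqrt(s2)) ** 2)
        assert fid(a, b) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_full_covariance_matches_scipy_sqrtm(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = _random_gaussian(rng, 5), _random_gaussian(rng, 5)
        covmean = scipy.linalg.sqrtm(a.sigma @ b.sigma)
        expected = (np.sum((a.mu - b.mu) ** 2) + np.trace(a.sigma)
                    + np.trace(b.sigma) - 2 * np.trace(covmean.real))
        assert fid(a, b) == pytest.approx(expected, rel=1e-6)
        assert fid(a, b) == pytest.approx(fid(b, a), rel=1e-9)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            fid(_random_gaussian(rng, 3), _random_gaussian(rng, 4))


class TestDeltaAndNormalizedFid:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.ref = rng.standard_normal((200, 5))
        self.near = rng.standard_normal((200, 5)) + 0.1
        self.far = rng.standard_normal((200, 5)) + 3.0

    def test_identical_before_after_gives_zero(self):
        assert delta_fid(self.near, self.near, self.ref) == pytest.approx(0.0)

    def test_moving_closer_is_positive(self):
        assert delta_fid(self.far, self.near, self.ref) > 0

    def test_after_equal_to_reference_sample(self):
        val = delta_fid(self.far, self.ref, self.ref)
        g = fit_feature_gaussian(self.ref)
        assert val == pytest.approx(fid(fit_feature_gaussian(self.far), g))

    def test_inverted_normalized_near_one_for_matched_synth(self):
        # single ratios of two noise-floor FIDs are heavy-tailed, so check
        # the median over independent replicates against a sampling band
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(11):
            real_a = rng.standard_normal((300, 4))
            real_b = rng.standard_normal((300, 4))
            synth = rng.standard_normal((300, 4))
            ratios.append(inverted_normalized_fid(real_a, real_b, synth))
        assert 1 / 3 < np.median(ratios) < 3.0

    def test_inverted_normalized_small_for_off_distribution_synth(self):
        rng = np.random.default_rng(9)
        real_a = rng.standard_normal((300, 4))
        real_b = rng.standard_normal((300, 4))
        synth = rng.standard_normal((300, 4)) + 5.0
        assert inverted_normalized_fid(real_a, real_b, synth) < 0.2


def _ssim_bruteforce(x, y, window, c1, c2):
    """Direct per-window double loop with explicit sample statistics."""
    h, w = x.shape
    n = window * window
    out = np.empty((h - window + 1, w - window + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            wx = x[i:i + window, j:j + window].ravel()
            wy = y[i:i + window, j:j + window].ravel()
            mx, my = wx.mean(), wy.mean()
            vx = ((wx - mx) ** 2).sum() / (n - 1)
            vy = ((wy - my) ** 2).sum() / (n - 1)
            cxy = ((wx - mx) * (wy - my)).sum() / (n - 1)
            out[i, j] = ((2 * mx * my + c1) * (2 * cxy + c2)
                         / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return out


class TestSsim:
    def test_identical_images_score_one(self):
        x = np.random.default_rng(0).random((20, 20))
        score, smap = ssim_map(x, x)
        assert score == pytest.approx(1.0)
        np.testing.assert_allclose(smap, 1.0)

    def test_constant_images_closed_form(self):
        a, b = 0.3, 0.8
        c1 = 0.01 ** 2
        x = np.full((16, 16), a)
        y = np.full((16, 16), b)
        score, _ = ssim_map(x, y)
        assert score == pytest.approx((2 * a * b + c1) / (a * a + b * b + c1),
                                      rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_window_loop(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random((14, 17)), rng.random((14, 17))
        score, smap = ssim_map(x, y)
        expected = _ssim_bruteforce(x, y, 7, 0.01 ** 2, 0.03 ** 2)
        np.testing.assert_allclose(smap, expected, atol=1e-10)
        assert score == pytest.approx(expected.mean(), abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scikit_image(self, seed):
        rng = np.random.default_rng(50 + seed)
        x, y = rng.random((24, 24)), rng.random((24, 24))
        score, _ = ssim_map(x, y)
        reference = sk_ssim(x, y, win_size=7, data_range=1.0,
                            gaussian_weights=False)
        assert score == pytest.approx(reference, abs=2e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim_map(np.zeros((10, 10)), np.zeros((11, 10)))


class TestStructuralDistance:
    def test_identical_images_distance_zero(self):
        x = np.random.default_rng(1).random((16, 16, 3))
        score, dmap = structural_distance(x, x)
        assert score == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(dmap, 0.0, atol=1e-12)

    def test_equals_rescaled_ssim(self):
        rng = np.random.default_rng(2)
        x, y = rng.random((16, 16)), rng.random((16, 16))
        s_score, s_map = ssim_map(x, y)
        d_score, d_map = structural_distance(x, y)
        np.testing.assert_allclose(d_map, (1 - s_map) / 2, atol=1e-12)
        assert d_score == pytest.approx((1 - s_map).mean() / 2, abs=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x, y = rng.random((12, 12)), rng.random((12, 12))
            score, dmap = structural_distance(x, y)
            assert 0.0 <= score <= 1.0
            assert dmap.min() >= 0.0 and dmap.max() <= 1.0


class TestCosineDistance:
    def test_trivial_values(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(v, v) == pytest.approx(0.0)
        assert cosine_distance(v, -v) == pytest.approx(2.0)
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0.0, 0.0], [1.0, 0.0])


class TestInlierScores:
    def test_range_and_planted_outlier(self):
        rng = np.random.default_rng(4)
        train = rng.standard_normal((300, 5))
        queries = np.vstack([rng.standard_normal((50, 5)),
                             np.full((1, 5), 30.0)])  # far outside the hull
        scores = inlier_scores(train, queries, seed=0)
        assert np.all(scores >= -1.0) and np.all(scores <= 1.0)
        train_scores = inlier_scores(train, train, seed=0)
        assert scores[-1] < np.median(train_scores)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        train = rng.standard_normal((100, 3))
        q = rng.standard_normal((10, 3))
        np.testing.assert_array_equal(inlier_scores(train, q, seed=3),
                                      inlier_scores(train, q, seed=3))

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            inlier_scores(np.empty((0, 3)), np.ones((2, 3)))


class TestRetrieval:
    def test_self_retrieval_is_perfect(self):
        rng = np.random.default_rng(6)
        q = rng.standard_normal((10, 4))
        db = np.repeat(q, 3, axis=0)
        labels = np.repeat(np.arange(10), 3)
        acc = retrieval_mv_at_k(q, np.arange(10), db, labels, k=3)
        assert acc == 1.0

    def test_k1_equals_bruteforce_nearest_neighbor(self):
        rng = np.random.default_rng(7)
        q = rng.standard_normal((20, 5))
        db = rng.standard_normal((50, 5))
        db_labels = rng.integers(0, 3, 50)
        q_labels = rng.integers(0, 3, 20)
        acc = retrieval_mv_at_k(q, q_labels, db, db_labels, k=1)
        correct = 0
        for i in range(20):  # brute-force nearest neighbour
            dists = [1 - q[i] @ db[j] / np.linalg.norm(q[i]) / np.linalg.norm(db[j])
                     for j in range(50)]
            correct += int(db_labels[int(np.argmin(dists))] == q_labels[i])
        assert acc == pytest.approx(correct / 20)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(8)
        db = rng.standard_normal((1000, 6))
        labels = rng.permutation(np.repeat([0, 1], 500))
        q = rng.standard_normal((500, 6))
        q_labels = rng.integers(0, 2, 500)
        acc = retrieval_mv_at_k(q, q_labels, db, labels, k=5)
        assert abs(acc - 0.5) < 0.05

    def test_k_larger_than_db_rejected(self):
        with pytest.raises(ValueError):
            retrieval_mv_at_k(np.ones((1, 2)), [0], np.ones((3, 2)), [0, 1, 2], k=4)


class TestEditingEffectiveness:
    DB = np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0],
                   [0.1, 0.9], [0.7, 0.7], [-1.0, 0.2]])

    def test_hand_computed_toy_database(self):
        q = np.array([0.0, 1.0])
        q_edit = np.array([1.0, 0.05])
        # hand enumeration with K=2:
        def mean_top2(v):
            d = sorted(1 - (self.DB @ v) / (np.linalg.norm(self.DB, axis=1)
                                            * np.linalg.norm(v)))
            return (d[0] + d[1]) / 2
        expected = (mean_top2(q) - mean_top2(q_edit)) / mean_top2(q)
        assert editing_effectiveness(q, q_edit, self.DB, K=2) == pytest.approx(expected)

    def test_unchanged_query_scores_zero(self):
        q = np.array([0.3, 0.8])
        assert editing_effectiveness(q, q, self.DB, K=3) == pytest.approx(0.0)

    def test_exact_database_hit_with_k1(self):
        q = np.array([0.5, 1.5])
        q_edit = self.DB[2].copy()
        assert editing_effectiveness(q, q_edit, self.DB, K=1) == pytest.approx(1.0)

    def test_zero_baseline_distance_rejected(self):
        q = self.DB[0].copy()
        with pytest.raises(ZeroDivisionError):
            editing_effectiveness(q, q * 2, self.DB[:1], K=1)
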