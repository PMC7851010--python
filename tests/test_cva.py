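import numpy as np
import pytest
from scipy import stats

from mitemorph import (
    compare_distance_means,
    cv_size_correlation,
    cva,
    loo_classify,
    mean_offdiagonal,
    pooled_within_covariance,
    project_passive,
)
from mitemorph.cva import CVAUndefinedError, _pair_permutation_p


def two_gaussian_groups(rng, n=30, sep=3.0):
    a = rng.standard_normal((n, 2)) + [0.0, 0.0]
    b = rng.standard_normal((n, 2)) + [sep, 0.0]
    x = np.vstack([a, b])
    g = np.array(["a"] * n + ["b"] * n)
    return x, g


class TestPooledWithinCovariance:
    def test_identical_specimens_zero_rank(self):
        x = np.tile([1.0, 2.0, 3.0], (6, 1))
        g = np.array(["a"] * 3 + ["b"] * 3)
        w, rank = pooled_within_covariance(x, g)
        np.testing.assert_allclose(w, 0.0)
        assert rank == 0

    def test_single_group_reduces_to_sample_covariance(self, rng):
        x = rng.standard_normal((20, 4))
        w, rank = pooled_within_covariance(x, np.array(["a"] * 20))
        np.testing.assert_allclose(w, np.cov(x, rowvar=False), atol=1e-12)
        assert rank == 4

    def test_matches_brute_force_loop(self, rng):
        x = rng.standard_normal((12, 2))
        g = np.array(["a"] * 4 + ["b"] * 5 + ["c"] * 3)
        w, _ = pooled_within_covariance(x, g)
        # independent brute-force accumulation
        acc = np.zeros((2, 2))
        for lab in ["a", "b", "c"]:
            xs = x[g == lab]
            m = xs.mean(axis=0)
            for row in xs:
                acc += np.outer(row - m, row - m)
        np.testing.assert_allclose(w, acc / (12 - 3), atol=1e-12)

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(CVAUndefinedError):
            pooled_within_covariance(rng.standard_normal((2, 3)), np.array(["a", "b"]))


class TestCVA:
    def test_two_groups_single_axis(self, rng):
        x, g = two_gaussian_groups(rng)
        res = cva(x, g, n_perm=0)
        assert res.n_axes == 1
        assert res.eigenvalues.shape == (1,)
        assert res.eigenvalues[0] > 0

    def test_mahalanobis_matches_closed_form_2x2(self, rng):
        x, g = two_gaussian_groups(rng, n=40, sep=2.5)
        res = cva(x, g, n_perm=0)
        # closed-form oracle: sqrt(d' S^-1 d) with direct 2x2 inversion
        a, b = x[g == "a"], x[g == "b"]
        sa = (a - a.mean(0)).T @ (a - a.mean(0))
        sb = (b - b.mean(0)).T @ (b - b.mean(0))
        s = (sa + sb) / (len(x) - 2)
        d = a.mean(0) - b.mean(0)
        det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
        s_inv = np.array([[s[1, 1], -s[0, 1]], [-s[1, 0], s[0, 0]]]) / det
        expected = np.sqrt(d @ s_inv @ d)
        assert res.mahalanobis[0, 1] == pytest.approx(expected, abs=1e-8)

    def test_scores_have_unit_pooled_within_variance(self, rng):
        x = rng.standard_normal((60, 5))
        x[20:40] += 2.0
        x[40:] += [0, 4, 0, 0, 0]
        g = np.repeat(["a", "b", "c"], 20)
        res = cva(x, g, n_perm=0)
        for ax in range(res.n_axes):
            ss = 0.0
            for lab in "abc":
                sc = res.scores[g == lab, ax]
                ss += ((sc - sc.mean()) ** 2).sum()
            assert ss / (60 - 3) == pytest.approx(1.0, abs=1e-8)

    def test_affine_invariance_of_mahalanobis_and_eigenvalues(self, rng):
        x = rng.standard_normal((45, 4))
        x[15:30] += [1, 0, 0, 0]
        x[30:] += [0, 1.5, 0, 0]
        g = np.repeat(["a", "b", "c"], 15)
        res1 = cva(x, g, n_perm=0)
        amat = rng.standard_normal((4, 4)) + 0.5 * np.eye(4)
        res2 = cva(x @ amat + rng.standard_normal(4), g, n_perm=0)
        np.testing.assert_allclose(res1.mahalanobis, res2.mahalanobis, atol=1e-8)
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-8)

    def test_distance_matrix_structure(self, default_study):
        from mitemorph import gpa

        al = gpa(default_study)
        inc = al.included_mask()
        x = al.shape_variables()[inc]
        res = cva(x, al.populations()[inc], n_perm=0)
        m = res.mahalanobis
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)
        iu = np.triu_indices(m.shape[0], 1)
        assert (m[iu] > 0).all()
        assert res.n_axes <= len(res.group_labels) - 1

    def test_rank_zero_within_rejected(self):
        x = np.tile([1.0, 2.0], (8, 1))
        g = np.repeat(["a", "b"], 4)
        with pytest.raises(CVAUndefinedError):
            cva(x, g, n_perm=0)

    def test_pairwise_permutation_detects_separation(self, rng):
        x, g = two_gaussian_groups(rng, n=20, sep=4.0)
        res = cva(x, g, n_perm=199, seed=0, procrustes=False)
        assert res.perm_p_mahalanobis[0, 1] == pytest.approx(1 / 200)

    def test_permutation_seed_determinism(self, rng):
        x, g = two_gaussian_groups(rng, n=15, sep=1.0)
        p1 = cva(x, g, n_perm=99, seed=5, procrustes=False).perm_p_mahalanobis[0, 1]
        p2 = cva(x, g, n_perm=99, seed=5, procrustes=False).perm_p_mahalanobis[0, 1]
        assert p1 == p2


class TestPassiveProjection:
    def test_group_mean_projects_to_score_centroid(self, rng):
        x, g = two_gaussian_groups(rng)
        res = cva(x, g, n_perm=0)
        mean_a = x[g == "a"].mean(axis=0)
        proj = project_passive(res, mean_a)
        np.testing.assert_allclose(proj[0], res.scores[g == "a"].mean(axis=0), atol=1e-10)

    def test_duplicate_specimens_get_identical_scores(self, rng):
        x, g = two_gaussian_groups(rng)
        res = cva(x, g, n_perm=0)
        proj = project_passive(res, np.vstack([x[3], x[3]]))
        np.testing.assert_allclose(proj[0], proj[1], atol=1e-12)
        np.testing.assert_allclose(proj[0], res.scores[3], atol=1e-10)

    def test_dimension_mismatch(self, rng):
        x, g = two_gaussian_groups(rng)
        res = cva(x, g, n_perm=0)
        with pytest.raises(ValueError, match="dimension mismatch"):
            project_passive(res, np.zeros(5))


class TestDistanceSummaries:
    def test_mean_offdiagonal_2x2(self):
        assert mean_offdiagonal(np.array([[0, 5], [5, 0]])) == 5

    def test_mean_offdiagonal_3x3(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert mean_offdiagonal(m) == pytest.approx(2.0)

    def test_mean_offdiagonal_needs_square(self):
        with pytest.raises(ValueError):
            mean_offdiagonal(np.zeros((1, 1)))

    def test_t_test_identical_sets(self):
        t, p = compare_distance_means([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_t_test_shifted_sets(self):
        t, p = compare_distance_means([1.0, 2, 3], [11.0, 12, 13])
        assert p < 0.001 and t < 0

    def test_t_test_matches_textbook_formula(self):
        a = np.array([3.1, 2.9, 3.5, 3.0])
        b = np.array([4.2, 4.8, 4.5])
        t, p = compare_distance_means(a, b)
        # pooled-variance t computed by direct arithmetic
        na, nb = len(a), len(b)
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
        t_direct = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_direct, rel=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_direct), na + nb - 2), rel=1e-10)


class TestLeaveOneOut:
    def test_far_separated_clusters_fully_correct(self, rng):
        x, g = two_gaussian_groups(rng, n=15, sep=50.0)
        res = loo_classify(x, g)
        assert res.pct_correct_overall == 100.0
        assert res.confusion.sum() == 30
        np.testing.assert_array_equal(res.confusion.sum(axis=1), [15, 15])

    def test_chance_level_for_random_labels(self, rng):
        """One homogeneous cloud with g = 5 random equal groups classifies
        at roughly chance (100/g = 20%), averaged over datasets."""
        accs = []
        for _ in range(15):
            x = rng.standard_normal((85, 4))
            g = np.repeat(np.arange(5), 17)
            accs.append(loo_classify(x, g).pct_correct_overall)
        assert np.mean(accs) == pytest.approx(20.0, abs=8.0)

    def test_full_covariance_option_differs_but_close(self, rng):
        x, g = two_gaussian_groups(rng, n=20, sep=2.0)
        strict = loo_classify(x, g)
        relaxed = loo_classify(x, g, refit_covariance=False)
        assert abs(strict.pct_correct_overall - relaxed.pct_correct_overall) <= 20.0

    def test_group_of_one_rejected(self, rng):
        x = rng.standard_normal((5, 2))
        g = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(CVAUndefinedError):
            loo_classify(x, g)


class TestCVSizeCorrelation:
    def test_perfect_correlation(self, rng):
        s = rng.uniform(10, 20, 30)
        assert cv_size_correlation(s, s) == pytest.approx(1.0)

    def test_orthogonalized_scores_give_zero(self, rng):
        sizes = rng.uniform(10, 20, 30)
        scores = rng.standard_normal(30)
        s_c = sizes - sizes.mean()
        scores = scores - scores.mean() - s_c * ((scores - scores.mean()) @ s_c) / (s_c @ s_c)
        assert cv_size_correlation(scores, sizes) == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cv_size_correlation(np.ones(5), np.arange(5.0))
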