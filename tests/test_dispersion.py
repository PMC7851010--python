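import numpy as np
import pytest

from mitemorph import dispersion_test, great_circle_matrix, mantel_test, pairwise_dispersion
from mitemorph.dispersion import _spatial_median, mantel_exhaustive_p


class TestSpatialMedian:
    def test_square_corners_median_at_center(self):
        pts = np.array([[1.0, 1], [1, -1], [-1, -1], [-1, 1]]) + [5.0, -3.0]
        med = _spatial_median(pts)
        np.testing.assert_allclose(med, [5.0, -3.0], atol=1e-6)
        d = np.linalg.norm(pts - med, axis=1)
        np.testing.assert_allclose(d, np.sqrt(2), atol=1e-6)

    def test_median_minimizes_summed_distance(self, rng):
        pts = rng.standard_normal((25, 3))
        med = _spatial_median(pts)
        obj = np.linalg.norm(pts - med, axis=1).sum()
        for _ in range(50):
            other = med + rng.normal(0, 0.05, 3)
            assert obj <= np.linalg.norm(pts - other, axis=1).sum() + 1e-9


class TestDispersionTest:
    def test_gross_heterogeneity_detected(self, rng):
        a = rng.standard_normal((30, 4))
        b = rng.standard_normal((30, 4)) * 3.0
        x = np.vstack([a, b])
        g = np.repeat(["a", "b"], 30)
        res = dispersion_test(x, g, n_perm=999, seed=0)
        assert res.perm_p < 0.01
        assert res.group_mean_dispersion[1] > res.group_mean_dispersion[0]

    def test_rotation_invariance(self, rng):
        x = rng.standard_normal((40, 4))
        g = np.repeat(["a", "b"], 20)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        r1 = dispersion_test(x, g, n_perm=99, seed=3)
        r2 = dispersion_test(x @ q, g, n_perm=99, seed=3)
        np.testing.assert_allclose(r1.dist_to_median, r2.dist_to_median, atol=1e-6)
        assert r1.f_stat == pytest.approx(r2.f_stat, abs=1e-6)
        assert r1.perm_p == r2.perm_p

    def test_seed_determinism_and_seed_stability(self, rng):
        x = rng.standard_normal((40, 3))
        g = np.repeat(["a", "b"], 20)
        p1 = dispersion_test(x, g, n_perm=499, seed=7).perm_p
        p2 = dispersion_test(x, g, n_perm=499, seed=7).perm_p
        p3 = dispersion_test(x, g, n_perm=499, seed=8).perm_p
        assert p1 == p2
        assert abs(p1 - p3) < 3 / np.sqrt(499)

    def test_singleton_group_dropped(self, rng):
        x = rng.standard_normal((21, 3))
        g = np.array(["a"] * 10 + ["b"] * 10 + ["c"])
        res = dispersion_test(x, g, n_perm=99, seed=0)
        assert res.group_labels == ["a", "b"]
        assert res.dist_to_median.shape == (20,)

    def test_matches_vegan_betadisper_f_statistic(self, rng):
        """Independent oracle: vegan's betadisper (spatial median) on the
        same small dataset must give the same F."""
        import shutil
        import subprocess
        import tempfile
        from pathlib import Path

        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the vegan cross-check")
        x = np.round(rng.standard_normal((16, 3)), 6)
        x[8:] *= 2.0
        g = np.repeat(["a", "b"], 8)
        res = dispersion_test(x, g, n_perm=99, seed=0)
        with tempfile.TemporaryDirectory() as td:
            xp = Path(td) / "x.csv"
            np.savetxt(xp, x, delimiter=",")
            script = f"""
            suppressMessages(library(vegan))
            x <- as.matrix(read.csv("{xp}", header=FALSE))
            g <- factor(rep(c("a","b"), each=8))
            bd <- betadisper(dist(x), g, type="median")
            cat(anova(bd)$F[1], "\n")
            """
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, check=True
            )
            f_vegan = float(out.stdout.strip().split()[-1])
        # vegan optimizes the spatial median with its own tolerance
        assert res.f_stat == pytest.approx(f_vegan, rel=1e-3)


class TestPairwiseDispersion:
    def test_structure_symmetric_unit_diagonal(self, rng):
        x = rng.standard_normal((45, 3))
        g = np.repeat(["a", "b", "c"], 15)
        labels, pmat = pairwise_dispersion(x, g, n_perm=99, seed=0)
        assert labels == ["a", "b", "c"]
        np.testing.assert_allclose(pmat, pmat.T)
        np.testing.assert_allclose(np.diag(pmat), 1.0)

    def test_inflated_group_flagged_in_both_pairs(self, rng):
        a = rng.standard_normal((30, 4))
        b = rng.standard_normal((30, 4))
        c = rng.standard_normal((30, 4)) * 2.5
        x = np.vstack([a, b, c])
        g = np.repeat(["a", "b", "c"], 30)
        labels, pmat = pairwise_dispersion(x, g, n_perm=199, seed=1)
        i = labels.index("c")
        others = [j for j in range(3) if j != i]
        assert pmat[i, others[0]] < 0.05 and pmat[i, others[1]] < 0.05
        assert pmat[others[0], others[1]] > 0.05

    def test_identical_groups_not_systematically_significant(self, rng):
        base = rng.standard_normal((20, 3))
        ps = []
        for rep in range(10):
            x = np.vstack([base + rng.normal(0, 1, base.shape) for _ in range(2)])
            g = np.repeat(["a", "b"], 20)
            ps.append(dispersion_test(x, g, n_perm=99, seed=rep).perm_p)
        assert np.mean(ps) > 0.2


class TestGreatCircle:
    def test_identical_points_zero(self):
        m = great_circle_matrix([[47.0, 15.0], [47.0, 15.0]])
        np.testing.assert_allclose(m, 0.0, atol=1e-9)

    def test_pole_to_equator_quarter_circumference(self):
        m = great_circle_matrix([[90.0, 0.0], [0.0, 0.0]])
        assert m[0, 1] == pytest.approx(np.pi / 2 * 6371.0, rel=1e-6)  # ~10007 km

    def test_european_sampling_distances(self):
        # Carinthia, Elba, Tarifa: the two map-measured reference spans
        coords = [[46.62, 14.31], [42.78, 10.19], [36.01, -5.60]]
        m = great_circle_matrix(coords)
        assert m[0, 1] == pytest.approx(520.0, rel=0.05)
        assert m[0, 2] == pytest.approx(2005.0, rel=0.05)
        np.testing.assert_allclose(m, m.T)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_matrix([[95.0, 0.0], [0.0, 0.0]])


class TestMantel:
    def symmetric(self, rng, g):
        x = rng.standard_normal((g, 3))
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(x))

    def test_self_correlation_is_one_minimal_p(self, rng):
        a = self.symmetric(rng, 6)
        res = mantel_test(a, a, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.perm_p < 0.05

    def test_exhaustive_enumeration_at_g4(self, rng):
        a = self.symmetric(rng, 4)
        b = self.symmetric(rng, 4)
        p_exact = mantel_exhaustive_p(a, b)
        res = mantel_test(a, b, n_perm=9999, seed=1)
        assert res.perm_p == pytest.approx(p_exact, abs=0.03)

    def test_monotone_transform_invariance_of_r_sign(self, rng):
        a = self.symmetric(rng, 7)
        b = self.symmetric(rng, 7)
        r1 = mantel_test(a, b, n_perm=99, seed=0).r
        r2 = mantel_test(a, 3.0 * b + 10.0, n_perm=99, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_isolation_by_distance_recovered(self, rng):
        """Divergence proportional to geography plus noise gives a
        significant positive Mantel r at g = 8."""
        lat = rng.uniform(36, 55, 8)
        lon = rng.uniform(-10, 20, 8)
        geo = great_circle_matrix(np.column_stack([lat, lon]))
        shape_d = geo / geo.max() + rng.normal(0, 0.1, geo.shape)
        shape_d = (shape_d + shape_d.T) / 2
        np.fill_diagonal(shape_d, 0.0)
        res = mantel_test(geo, shape_d, n_perm=999, seed=0)
        assert res.r > 0.5
        assert res.perm_p < 0.05

    def test_constant_matrix_rejected(self):
        a = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(a, a)

    def test_small_g_rejected(self, rng):
        a = self.symmetric(rng, 3)
        with pytest.raises(ValueError):
            mantel_test(a, a)
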