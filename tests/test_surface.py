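"""Mat-plane (least squares + RANSAC) and head-sphere fitting."""

import numpy as np
import pytest

from headcirc.surface import (DegenerateGeometryError, Plane, fit_plane_lsq,
                              fit_plane_ransac, fit_sphere_lsq, point_plane_height)


def _plane_points(rng, n, normal, offset, noise=0.0):
    """n points on the plane normal.p = offset (+ Gaussian noise along the normal)."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    basis = np.linalg.svd(normal.reshape(1, 3))[2][1:]
    coeffs = rng.uniform(-150, 150, (n, 2))
    pts = offset * normal + coeffs @ basis
    if noise:
        pts = pts + rng.normal(0, noise, n)[:, None] * normal
    return pts


class TestPlaneLsq:
    def test_horizontal_plane_coefficients(self, rng):
        pts = _plane_points(rng, 50, (0, 0, 1), 500.0)
        plane = fit_plane_lsq(pts)
        np.testing.assert_allclose(plane.coefficients, (0, 0, 0.002), atol=1e-12)

    def test_oblique_plane_coefficients(self, rng):
        # x + z = 1000  ->  (A, B, C) = (0.001, 0, 0.001)
        pts = _plane_points(rng, 50, (1, 0, 1), 1000.0 / np.sqrt(2))
        plane = fit_plane_lsq(pts)
        np.testing.assert_allclose(plane.coefficients, (0.001, 0, 0.001), atol=1e-12)

    def test_underdetermined_and_collinear_rejected(self, rng):
        with pytest.raises(DegenerateGeometryError):
            fit_plane_lsq([[0, 0, 500], [1, 1, 500]])
        t = rng.uniform(-100, 100, 20)
        line = np.outer(t, [1.0, 2.0, 0.5]) + [0, 0, 500]
        with pytest.raises(DegenerateGeometryError):
            fit_plane_lsq(line)

    def test_origin_plane_unrepresentable(self, rng):
        # plane x = z passes through the camera origin
        t, s = rng.uniform(-100, 100, (2, 30))
        pts = np.column_stack([t, s, t])
        with pytest.raises(DegenerateGeometryError, match="origin"):
            fit_plane_lsq(pts)

    def test_residual_is_locally_minimal(self, rng):
        pts = _plane_points(rng, 40, (0.2, -0.1, 1), 600.0, noise=2.0)
        plane = fit_plane_lsq(pts)
        coef = np.asarray(plane.coefficients)
        base = np.sum((pts @ coef - 1) ** 2)
        for _ in range(20):
            perturbed = coef + rng.normal(0, 1e-6 * np.linalg.norm(coef), 3)
            assert np.sum((pts @ perturbed - 1) ** 2) >= base - 1e-15


class TestPointPlaneHeight:
    def test_on_plane_is_zero(self, rng):
        plane = Plane((0.0003, -0.0001, 0.002))
        pts = _plane_points(rng, 10, plane.coefficients,
                            1.0 / np.linalg.norm(plane.coefficients))
        np.testing.assert_allclose(point_plane_height(pts, plane), 0, atol=1e-9)

    def test_camera_side_positive(self):
        plane = Plane((0, 0, 1 / 500))
        assert point_plane_height((0, 0, 450), plane) == pytest.approx(50.0)
        assert point_plane_height((0, 0, 520), plane) == pytest.approx(-20.0)

    def test_invariance_under_in_plane_translation(self, rng):
        plane = Plane((0.001, 0.0005, 0.0015))
        n = plane.normal
        basis = np.linalg.svd(n.reshape(1, 3))[2][1]
        p = np.array([10.0, -20.0, 400.0])
        h0 = point_plane_height(p, plane)
        for step in rng.uniform(-50, 50, 10):
            assert point_plane_height(p + step * basis, plane) == pytest.approx(h0)


class TestRansac:
    def test_exact_data_recovers_plane(self, rng):
        pts = _plane_points(rng, 200, (0, 0, 1), 500.0)
        result = fit_plane_ransac(pts, seed=0)
        assert result.inlier_count == 200
        np.testing.assert_allclose(result.plane.coefficients, (0, 0, 0.002), atol=1e-12)

    def test_matches_lsq_without_outliers(self, rng):
        pts = _plane_points(rng, 150, (0.1, 0.2, 1), 700.0)
        ransac = fit_plane_ransac(pts, seed=3)
        lsq = fit_plane_lsq(pts)
        np.testing.assert_allclose(ransac.plane.coefficients, lsq.coefficients,
                                   rtol=1e-9)

    def test_robust_to_outliers(self, rng):
        """Oracle: the least-squares fit on the known inlier subset."""
        inliers = _plane_points(rng, 200, (0, 0, 1), 500.0, noise=1.0)
        outliers = _plane_points(rng, 40, (0, 0, 1), 500.0)
        outliers[:, 2] += rng.choice([-1, 1], 40) * rng.uniform(30, 80, 40)
        pts = np.vstack([inliers, outliers])
        result = fit_plane_ransac(pts, tolerance_mm=3.0, seed=11)
        normal = result.plane.normal
        angle = np.degrees(np.arccos(np.clip(abs(normal[2]), -1, 1)))
        assert angle < 0.5
        assert result.inlier_count >= 180

    def test_unstructured_cloud_flagged_low_confidence(self, rng):
        pts = rng.uniform(0, 200, (400, 3)) + [0, 0, 400]
        result = fit_plane_ransac(pts, tolerance_mm=3.0, seed=5)
        assert result.inlier_fraction < 0.3
        assert result.low_confidence

    def test_all_degenerate_samples_error(self):
        line = np.outer(np.linspace(-1, 1, 30), [1.0, 0.0, 0.2]) + [0, 0, 500]
        with pytest.raises(DegenerateGeometryError):
            fit_plane_ransac(line, iterations=20, seed=0)

    def test_deterministic_under_seed(self, rng):
        pts = _plane_points(rng, 100, (0, 0.1, 1), 600.0, noise=1.5)
        a = fit_plane_ransac(pts, seed=9)
        b = fit_plane_ransac(pts, seed=9)
        assert a.plane.coefficients == b.plane.coefficients
        assert a.inlier_count == b.inlier_count


class TestSphereLsq:
    def _sphere_points(self, rng, center, radius, n=100, hemisphere=False):
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        if hemisphere:
            u[:, 2] = -np.abs(u[:, 2])   # camera-facing (upper) half only
        return np.asarray(center) + radius * u

    def test_hand_expanded_standard_form(self, rng):
        pts = self._sphere_points(rng, (10, -20, 500), 60.0)
        sphere = fit_sphere_lsq(pts)
        np.testing.assert_allclose(sphere.standard_form,
                                   (-20, 40, -1000, 246900), rtol=1e-9)
        np.testing.assert_allclose(sphere.center, (10, -20, 500), atol=1e-7)
        assert sphere.radius == pytest.approx(60.0, rel=1e-9)

    def test_upper_hemisphere_recovery_is_exact(self, rng):
        center, radius = (35.0, -10.0, 880.0), 52.0
        sphere = fit_sphere_lsq(self._sphere_points(rng, center, radius,
                                                    hemisphere=True))
        np.testing.assert_allclose(sphere.center, center, rtol=1e-9)
        assert sphere.radius == pytest.approx(radius, rel=1e-9)

    def test_radius_invariant_holds(self, rng):
        for _ in range(10):
            c = rng.uniform(-200, 200, 3) + [0, 0, 700]
            r = rng.uniform(20, 90)
            s = fit_sphere_lsq(self._sphere_points(rng, c, r, n=30))
            a, b, cc = s.center
            k, l, m, n = s.standard_form
            assert s.radius ** 2 == pytest.approx(a * a + b * b + cc * cc - n, rel=1e-9)
            np.testing.assert_allclose((a, b, cc), (-k / 2, -l / 2, -m / 2))

    def test_degenerate_configurations_rejected(self, rng):
        with pytest.raises(DegenerateGeometryError):
            fit_sphere_lsq(rng.uniform(0, 10, (3, 3)))
        planar = np.column_stack([rng.uniform(-50, 50, (20, 2)),
                                  np.full(20, 500.0)])
        with pytest.raises(DegenerateGeometryError):
            fit_sphere_lsq(planar)
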