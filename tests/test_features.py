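"""Cross-section extraction and the three circumference features."""

import numpy as np
import pytest
from scipy.integrate import quad

from headcirc.alignment import BodyFrame
from headcirc.features import (CrossSection, InsufficientSectionError,
                               compute_features, extract_cross_section)
from headcirc.surface import Plane, fit_sphere_lsq

D = 900.0            # mat depth (mm)
MAT = Plane((0.0, 0.0, 1 / D))
FRAME = BodyFrame(np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]]),
                  np.array([0.0, 0.0, D]))
# rows: longitudinal = +x, vertical = mat normal (0,0,-1), lateral completes


def dome_cloud(radius=50.0, pitch=1.55, rows=(-1.0, 0.0, 1.0), rim=True):
    """Dense analytic hemisphere dome resting on the mat: one profile per
    longitudinal row, sampled every ``pitch`` mm in the lateral direction
    (the pixel footprint of a 640x480 camera at this depth)."""
    n = int(round(2 * radius / pitch))
    s = np.linspace(-radius, radius, n + 1)
    pts = []
    for x in rows:
        h_sq = radius ** 2 - s ** 2 - x ** 2
        keep = h_sq >= 0 if rim else h_sq > 25.0
        pts.append(np.column_stack([np.full(keep.sum(), x), s[keep],
                                    D - np.sqrt(h_sq[keep])]))
    return np.vstack(pts)


@pytest.fixture
def dome_section():
    pts = dome_cloud()
    sphere = fit_sphere_lsq(pts)
    return extract_cross_section(pts, sphere, MAT, FRAME), sphere


class TestExtractCrossSection:
    def test_semicircular_profile_of_dome(self, dome_section):
        section, _ = dome_section
        assert section.h.max() == pytest.approx(50.0, abs=0.5)
        assert abs(section.s[np.argmax(section.h)]) < 2.0
        assert section.width_mm == pytest.approx(100.0, abs=1.0)

    def test_slab_selection_predicate(self):
        pts = dome_cloud(rows=(-3.0, -1.5, 0.0, 1.5, 3.0))
        sphere = fit_sphere_lsq(pts)
        slab_w = 2.0
        section = extract_cross_section(pts, sphere, MAT, FRAME,
                                        slab_half_width_mm=slab_w)
        # only the rows within the slab contribute: |x - center_x| <= 2
        center = np.asarray(sphere.center)
        signed = (pts - center) @ FRAME.longitudinal
        inside = pts[np.abs(signed) <= slab_w]
        assert len(section) >= 5
        assert section.s.min() >= inside[:, 1].min() - 1e-6

    def test_one_sided_cloud_is_insufficient(self):
        pts = dome_cloud()
        sphere = fit_sphere_lsq(pts)
        one_side = pts[pts[:, 0] > 30.0]
        with pytest.raises(InsufficientSectionError):
            extract_cross_section(one_side, sphere, MAT, FRAME)

    def test_too_few_bins_rejected(self):
        pts = dome_cloud()
        sphere = fit_sphere_lsq(pts)
        narrow = pts[np.abs(pts[:, 1]) < 3.0]   # a couple of lateral bins
        with pytest.raises(InsufficientSectionError, match="bins"):
            extract_cross_section(narrow, sphere, MAT, FRAME)

    def test_samples_strictly_ordered(self, dome_section):
        section, _ = dome_section
        assert np.all(np.diff(section.s) > 0)


class TestComputeFeatures:
    def test_dome_arc_is_half_circumference(self, dome_section):
        """Full dome: arc = pi*r within 1%, rim heights ~ 0."""
        section, _ = dome_section
        fv = compute_features(section)
        assert fv.top_arc_length_cm * 10 == pytest.approx(np.pi * 50, rel=0.01)
        assert fv.left_height_cm * 10 <= 2.0
        assert fv.right_height_cm * 10 <= 2.0

    def test_flat_profile(self):
        s = np.arange(-30.0, 30.1, 1.5)
        section = CrossSection(s=s, h=np.full_like(s, 25.0),
                               plane_point=np.zeros(3),
                               plane_normal=np.array([1.0, 0, 0]),
                               slab_half_width_mm=2.0, bin_width_mm=1.5)
        fv = compute_features(section)
        assert fv.left_height_cm == pytest.approx(2.5)
        assert fv.right_height_cm == pytest.approx(2.5)
        assert fv.top_arc_length_cm * 10 == pytest.approx(60.0)

    def test_truncated_profile_matches_quadrature_oracle(self):
        """Visibility-truncated dome: arc matches numerical quadrature of
        the generating circle over the same lateral span within 1%, and
        the edge heights equal the truncation height."""
        r, h_cut = 50.0, 5.0
        pts = dome_cloud(rim=False)              # truncated at h = 5 mm
        sphere = fit_sphere_lsq(pts)
        section = extract_cross_section(pts, sphere, MAT, FRAME)
        fv = compute_features(section)
        s_lo, s_hi = section.s[0], section.s[-1]
        arc_oracle, _ = quad(lambda s: np.sqrt(1 + s ** 2 / (r ** 2 - s ** 2)),
                             s_lo, s_hi)
        assert fv.top_arc_length_cm * 10 == pytest.approx(arc_oracle, rel=0.01)
        assert fv.left_height_cm * 10 == pytest.approx(
            np.sqrt(r ** 2 - s_lo ** 2), abs=1.5)

    def test_features_nonnegative_and_arc_bounds_width(self, dome_section):
        section, sphere = dome_section
        fv = compute_features(section, sphere=sphere, include_extras=True)
        assert all(v >= 0 for v in fv.to_dict().values())
        assert fv.top_arc_length_cm * 10 >= section.width_mm
        assert fv.extras["sphere_radius_cm"] == pytest.approx(5.0, abs=0.1)

    def test_degenerate_section_rejected(self):
        section = CrossSection(s=np.array([0.0]), h=np.array([10.0]),
                               plane_point=np.zeros(3),
                               plane_normal=np.array([1.0, 0, 0]),
                               slab_half_width_mm=2.0, bin_width_mm=1.5)
        with pytest.raises(InsufficientSectionError):
            compute_features(section)


class TestSectionInvariances:
    def test_arc_invariant_under_rotation_about_mat_normal(self):
        pts = dome_cloud()
        base = compute_features(extract_cross_section(
            pts, fit_sphere_lsq(pts), MAT, FRAME)).top_arc_length_cm
        a = np.deg2rad(40.0)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        moved = (pts - [0, 0, D]) @ rot.T + [30.0, -20.0, D]
        frame_rot = BodyFrame(
            np.vstack([rot @ [1.0, 0, 0], -(rot @ [0, 1.0, 0]), [0, 0, -1.0]]),
            np.array([30.0, -20.0, D]))
        arc = compute_features(extract_cross_section(
            moved, fit_sphere_lsq(moved), MAT, frame_rot)).top_arc_length_cm
        assert arc == pytest.approx(base, rel=0.01)

    def test_arc_converges_under_bin_refinement(self):
        """On a smooth (finite-slope) profile, halving the bin width never
        shrinks the arc beyond discretization noise and converges to the
        quadrature value of the generating curve."""
        r = 50.0
        n = 801
        s_grid = np.linspace(-40.0, 40.0, n)        # slopes bounded by ~1.4
        pts = np.vstack([np.column_stack([np.full(n, x), s_grid,
                                          D - np.sqrt(r ** 2 - s_grid ** 2 - x ** 2)])
                         for x in (-1.0, 0.0, 1.0)])
        sphere = fit_sphere_lsq(pts)
        arcs = []
        for w in (4.0, 2.0, 1.0):
            sec = extract_cross_section(pts, sphere, MAT, FRAME, bin_width_mm=w)
            arcs.append(compute_features(sec).top_arc_length_cm)
        assert arcs[1] >= arcs[0] - 0.05
        assert arcs[2] >= arcs[1] - 0.05
        oracle, _ = quad(lambda s: np.sqrt(1 + s ** 2 / (r ** 2 - s ** 2)),
                         -40.0, 40.0)
        assert arcs[2] * 10 == pytest.approx(oracle, rel=0.01)
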