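"""Least-squares and RANSAC fitting of the mat plane and the head sphere.

The mat is modelled as the plane ``A x + B y + C z = 1`` and fitted by
linear least squares (pseudoinverse of the stacked coordinate matrix
against a vector of ones).  This parameterization cannot represent a plane
through the camera origin, which is harmless here -- the camera never lies
on the mat -- but is guarded explicitly.  Robustness to the undulating
bedding comes from RANSAC: minimal 3-point hypotheses are scored by the
number of points within a distance tolerance, and the winning hypothesis is
refit on its full inlier set.

The head is modelled as a sphere via its standard form

    x^2 + y^2 + z^2 + k x + l y + m z + n = 0,

which is linear in (k, l, m, n) and hence solved exactly by least squares;
the centre is (-k/2, -l/2, -m/2) and r^2 = a^2 + b^2 + c^2 - n.  Because
the system stays full-rank for any non-coplanar sample, top-down
(hemisphere-only) visibility does not degrade the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Plane", "Sphere", "RansacResult", "DegenerateGeometryError",
    "fit_plane_lsq", "fit_plane_ransac", "point_plane_height", "fit_sphere_lsq",
]


class DegenerateGeometryError(ValueError):
    """Raised when the input configuration cannot determine the primitive."""


_COLLINEAR_RTOL = 1e-10
_ORIGIN_PLANE_RCOND = 1e-12


@dataclass(frozen=True)
class Plane:
    """Plane ``A x + B y + C z = 1`` with the camera at the origin.

    The unit normal is oriented toward the camera side, so
    :func:`point_plane_height` is positive for points between the mat and
    the camera.
    """

    coefficients: tuple[float, float, float]

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=np.float64)
        if c.shape != (3,) or not np.all(np.isfinite(c)) or np.allclose(c, 0):
            raise ValueError(f"invalid plane coefficients {self.coefficients}")
        object.__setattr__(self, "coefficients", tuple(float(x) for x in c))

    @property
    def normal(self) -> np.ndarray:
        """Unit normal pointing toward the camera (origin) side."""
        n = np.asarray(self.coefficients)
        # The origin gives A*0+B*0+C*0 - 1 = -1 < 0, so -n/|n| points at it.
        return -n / np.linalg.norm(n)

    def to_dict(self) -> dict:
        return {"A": self.coefficients[0], "B": self.coefficients[1],
                "C": self.coefficients[2]}


@dataclass(frozen=True)
class Sphere:
    """Fitted sphere: centre (a, b, c) mm, radius r mm, and the raw
    standard-form coefficients (k, l, m, n) it was derived from."""

    center: tuple[float, float, float]
    radius: float
    standard_form: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be > 0, got {self.radius}")

    def to_dict(self) -> dict:
        return {"center_mm": list(self.center), "radius_mm": self.radius,
                "standard_form_klmn": list(self.standard_form)}


@dataclass
class RansacResult:
    plane: Plane
    inlier_count: int
    inlier_fraction: float
    iterations_run: int
    inlier_mask: np.ndarray = field(repr=False, default=None)

    @property
    def low_confidence(self) -> bool:
        """True when fewer than 30% of points support the plane."""
        return self.inlier_fraction < 0.3

    def to_dict(self) -> dict:
        return {"plane": self.plane.to_dict(),
                "inlier_count": int(self.inlier_count),
                "inlier_fraction": float(self.inlier_fraction),
                "iterations_run": int(self.iterations_run)}


def _as_points(points) -> np.ndarray:
    if hasattr(points, "points"):
        points = points.points
    p = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if not np.all(np.isfinite(p)):
        raise ValueError("points contain non-finite values")
    return p


def fit_plane_lsq(points) -> Plane:
    """Least-squares plane ``A x + B y + C z = 1`` through the points.

    Raises :class:`DegenerateGeometryError` for fewer than 3 points, a
    collinear configuration, or a plane passing (numerically) through the
    origin, which this parameterization cannot express.
    """
    p = _as_points(points)
    if len(p) < 3:
        raise DegenerateGeometryError(f"plane fit needs >= 3 points, got {len(p)}")
    centered = p - p.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= _COLLINEAR_RTOL * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane undetermined")
    coef, residual, rank, sv = np.linalg.lstsq(p, np.ones(len(p)), rcond=None)
    norm = np.linalg.norm(coef)
    if norm < _ORIGIN_PLANE_RCOND or not np.all(np.isfinite(coef)):
        raise DegenerateGeometryError(
            "best-fit plane passes through the camera origin; "
            "the Ax+By+Cz=1 form cannot represent it")
    # The =1 form cannot express origin planes: detect by comparing the
    # constrained fit's orthogonal residual with the unconstrained (total
    # least squares) one -- a gross mismatch means the true plane contains
    # the origin.
    rms_constrained = float(np.sqrt(np.mean((p @ coef - 1.0) ** 2))) / norm
    rms_free = s[2] / np.sqrt(len(p))
    scale = float(np.mean(np.linalg.norm(p, axis=1)))
    if rms_constrained > 10.0 * rms_free + 1e-9 * max(scale, 1.0):
        raise DegenerateGeometryError(
            "points lie on a plane through the camera origin, which the "
            "Ax+By+Cz=1 form cannot represent")
    return Plane(tuple(coef))


def point_plane_height(points, plane: Plane) -> np.ndarray | float:
    """Signed perpendicular distance (mm) above the plane, positive on the
    camera side.  Accepts a single point or an (n, 3) array."""
    p = np.asarray(points, dtype=np.float64)
    single = p.ndim == 1
    p = p.reshape(-1, 3)
    n = np.asarray(plane.coefficients)
    h = (1.0 - p @ n) / np.linalg.norm(n)
    return float(h[0]) if single else h


def fit_plane_ransac(points, iterations: int = 500, tolerance_mm: float = 3.0,
                     seed: int | np.random.Generator = 0,
                     min_inliers: int = 3) -> RansacResult:
    """RANSAC plane fit: best-of-``iterations`` minimal-sample consensus.

    Each iteration samples 3 points, fits the plane, and counts points
    within ``tolerance_mm`` of it.  The plane with the most inliers wins
    (ties keep the earlier iteration, so a fixed seed is fully
    deterministic) and is refit by least squares on its inlier set.
    Degenerate samples are skipped; if every iteration degenerates a
    :class:`DegenerateGeometryError` is raised.
    """
    p = _as_points(points)
    n_pts = len(p)
    if n_pts < 3:
        raise DegenerateGeometryError(f"RANSAC needs >= 3 points, got {n_pts}")
    if tolerance_mm <= 0:
        raise ValueError("tolerance must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best_count = -1
    best_mask = None
    any_valid = False
    for _ in range(iterations):
        idx = rng.choice(n_pts, size=3, replace=False)
        try:
            cand = fit_plane_lsq(p[idx])
        except DegenerateGeometryError:
            continue
        any_valid = True
        dist = np.abs(point_plane_height(p, cand))
        mask = dist <= tolerance_mm
        count = int(mask.sum())
        if count > best_count:
            best_count = count
            best_mask = mask
    if not any_valid:
        raise DegenerateGeometryError("all RANSAC samples were degenerate")

    if best_count >= max(min_inliers, 3):
        refined = fit_plane_lsq(p[best_mask])
        dist = np.abs(point_plane_height(p, refined))
        best_mask = dist <= tolerance_mm
        best_count = int(best_mask.sum())
    else:
        raise DegenerateGeometryError("no RANSAC hypothesis gathered enough inliers")
    return RansacResult(plane=refined, inlier_count=best_count,
                        inlier_fraction=best_count / n_pts,
                        iterations_run=iterations, inlier_mask=best_mask)


def fit_sphere_lsq(points) -> Sphere:
    """Exact linear least-squares sphere fit via the standard form.

    Solves ``[x y z 1] . (k, l, m, n) = -(x^2 + y^2 + z^2)`` by
    pseudoinverse, then converts to centre and radius.  Exact (to rounding)
    on noiseless spherical data, including hemisphere-only samples.
    """
    p = _as_points(points)
    if len(p) < 4:
        raise DegenerateGeometryError(f"sphere fit needs >= 4 points, got {len(p)}")
    design = np.column_stack([p, np.ones(len(p))])
    rhs = -np.sum(p * p, axis=1)
    coef, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("coplanar points: sphere system is rank-deficient")
    k, l, m, n = (float(v) for v in coef)
    a, b, c = -k / 2.0, -l / 2.0, -m / 2.0
    r_sq = a * a + b * b + c * c - n
    if r_sq <= 0:
        raise DegenerateGeometryError(f"sphere fit failed: r^2 = {r_sq:.3g} <= 0")
    return Sphere(center=(a, b, c), radius=float(np.sqrt(r_sq)),
                  standard_form=(k, l, m, n))
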