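"""Head cross-section extraction and the circumference feature vector.

Only the top of the head is visible from above, so the circumference is
never measured directly.  Instead, the head surface is sliced at the
coronal plane through the fitted sphere centre (the plane containing the
mat normal and the lateral axis, orthogonal to the body's longitudinal
axis), and three mat-referenced quantities are taken from the visible
curve: the height above the mat at its left and right visible extremes,
and the arc length of the visible top.  Together with the head-touches-mat
constraint these characterize the occluded perimeter well enough for a
learned regressor to recover it.

All geometry is in millimetres; the feature vector is reported in
centimetres (clinical convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import BodyFrame
from .surface import Plane, Sphere, point_plane_height

MM_PER_CM = 10.0

FEATURE_NAMES = ("left_height_cm", "right_height_cm", "top_arc_length_cm")
EXTRA_FEATURE_NAMES = ("sphere_radius_cm", "max_height_cm", "section_width_cm")


class InsufficientSectionError(RuntimeError):
    """Too few points or bins at the measurement plane."""


@dataclass
class CrossSection:
    """Ordered planar curve of head heights above the mat.

    ``s`` is the lateral coordinate (mm, body frame, increasing left to
    right), ``h`` the height above the mat plane (mm).  One (median)
    sample per occupied lateral bin.
    """

    s: np.ndarray
    h: np.ndarray
    plane_point: np.ndarray          # sphere centre the plane passes through
    plane_normal: np.ndarray         # longitudinal axis
    slab_half_width_mm: float
    bin_width_mm: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.s.shape != self.h.shape or self.s.ndim != 1:
            raise ValueError("s and h must be matching 1-D arrays")
        if len(self.s) and np.any(np.diff(self.s) <= 0):
            raise ValueError("section samples must be strictly ordered in s")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def width_mm(self) -> float:
        return float(self.s[-1] - self.s[0])


@dataclass
class FeatureVector:
    left_height_cm: float
    right_height_cm: float
    top_arc_length_cm: float
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_NAMES + tuple(self.extras)

    def as_array(self) -> np.ndarray:
        base = [self.left_height_cm, self.right_height_cm, self.top_arc_length_cm]
        return np.asarray(base + list(self.extras.values()), dtype=np.float64)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in FEATURE_NAMES}
        d.update(self.extras)
        return d


def extract_cross_section(head_points, sphere: Sphere, mat: Plane,
                          frame: BodyFrame, *,
                          slab_half_width_mm: float = 2.0,
                          bin_width_mm: float = 1.5,
                          min_bins: int = 5,
                          smooth_window: int = 0) -> CrossSection:
    """Slice the head cloud at the coronal plane through the sphere centre.

    Points within ``slab_half_width_mm`` of the plane (normal = the body's
    longitudinal axis, through the sphere centre) are projected to
    ``(s, h)`` -- lateral coordinate and height above the mat -- binned by
    ``s``, and reduced to the median height per bin.  Raises
    :class:`InsufficientSectionError` for an empty slab or fewer than
    ``min_bins`` occupied bins.  ``smooth_window`` > 1 applies a moving
    median over the binned curve.
    """
    if hasattr(head_points, "points"):
        head_points = head_points.points
    p = np.asarray(head_points, dtype=np.float64).reshape(-1, 3)
    center = np.asarray(sphere.center, dtype=np.float64)

    normal = frame.longitudinal
    signed = (p - center) @ normal
    in_slab = np.abs(signed) <= slab_half_width_mm
    if not np.any(in_slab):
        raise InsufficientSectionError("no head points within the section slab")
    slab = p[in_slab]

    s = (slab - center) @ frame.lateral
    h = point_plane_height(slab, mat)

    bins = np.floor(s / bin_width_mm).astype(np.int64)
    order = np.argsort(bins, kind="stable")
    bins_sorted = bins[order]
    unique_bins, starts = np.unique(bins_sorted, return_index=True)
    if len(unique_bins) < min_bins:
        raise InsufficientSectionError(
            f"only {len(unique_bins)} occupied bins (< {min_bins}) at the section plane")
    s_sorted, h_sorted = s[order], h[order]
    s_rep = np.empty(len(unique_bins))
    h_rep = np.empty(len(unique_bins))
    for i, (b, start) in enumerate(zip(unique_bins, starts)):
        stop = starts[i + 1] if i + 1 < len(starts) else len(bins_sorted)
        s_rep[i] = np.median(s_sorted[start:stop])
        h_rep[i] = np.median(h_sorted[start:stop])

    if smooth_window and smooth_window > 1:
        from scipy.ndimage import median_filter
        h_rep = median_filter(h_rep, size=smooth_window, mode="nearest")

    return CrossSection(s=s_rep, h=h_rep, plane_point=center,
                        plane_normal=normal,
                        slab_half_width_mm=slab_half_width_mm,
                        bin_width_mm=bin_width_mm)


def compute_features(section: CrossSection, *,
                     sphere: Sphere | None = None,
                     include_extras: bool = False) -> FeatureVector:
    """Reduce a cross-section to the circumference features, in cm.

    left/right height = height above the mat at the smallest/largest
    occupied lateral bin (where the camera loses sight of the head);
    top arc length = polyline length of the (s, h) curve.
    """
    if len(section) < 2:
        raise InsufficientSectionError("degenerate section: fewer than 2 bins")
    ds = np.diff(section.s)
    dh = np.diff(section.h)
    arc_mm = float(np.sum(np.hypot(ds, dh)))
    left_mm = max(float(section.h[0]), 0.0)
    right_mm = max(float(section.h[-1]), 0.0)

    extras: dict[str, float] = {}
    if include_extras:
        extras["max_height_cm"] = float(section.h.max()) / MM_PER_CM
        extras["section_width_cm"] = section.width_mm / MM_PER_CM
        if sphere is not None:
            extras["sphere_radius_cm"] = sphere.radius / MM_PER_CM
    return FeatureVector(left_height_cm=left_mm / MM_PER_CM,
                         right_height_cm=right_mm / MM_PER_CM,
                         top_arc_length_cm=arc_mm / MM_PER_CM,
                         extras=extras)
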