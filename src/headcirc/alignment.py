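"""Canonical body frame from PCA, with the head-left convention.

The longitudinal (head-feet) axis is the first principal direction of the
body cloud, projected into the mat plane; the vertical axis is the mat
normal (camera side positive); the lateral axis completes a right-handed
frame.  Because a principal direction is only defined up to sign, the
head's position relative to the body fixes it: after
:func:`orient_head_left` the head centroid always has the smaller
longitudinal coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surface import Plane


class AmbiguousOrientationError(ValueError):
    """No dominant principal axis: body orientation cannot be determined."""


@dataclass
class BodyFrame:
    """Right-handed orthonormal frame anchored at the body centroid.

    Rows of ``rotation`` are the longitudinal, lateral and vertical axes
    expressed in global coordinates, so ``rotation @ (p - origin)`` maps a
    global point into body coordinates (longitudinal, lateral, height).
    """

    rotation: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation is not right-handed")
        self.rotation = r
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def longitudinal(self) -> np.ndarray:
        return self.rotation[0]

    @property
    def lateral(self) -> np.ndarray:
        return self.rotation[1]

    @property
    def vertical(self) -> np.ndarray:
        return self.rotation[2]

    def to_body(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return (p.reshape(-1, 3) - self.origin) @ self.rotation.T

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "origin": self.origin.tolist()}


def pca_align(body_points, mat: Plane, *,
              conditioning_ratio: float = 1.5) -> BodyFrame:
    """Build the canonical body frame from the body point cloud.

    The first principal axis of the centred covariance is the longitudinal
    direction (the body's long axis dominates the variance); it is
    projected into the mat plane so that "vertical" is the mat normal
    rather than the camera axis.  Raises
    :class:`AmbiguousOrientationError` when the top two eigenvalues are
    within ``conditioning_ratio`` of each other (no dominant axis).
    """
    if hasattr(body_points, "points"):
        body_points = body_points.points
    p = np.asarray(body_points, dtype=np.float64).reshape(-1, 3)
    if len(p) < 3:
        raise ValueError(f"PCA alignment needs >= 3 points, got {len(p)}")
    centroid = p.mean(axis=0)
    cov = np.cov((p - centroid).T)
    eigvals, eigvecs = np.linalg.eigh(cov)     # ascending
    if eigvals[2] <= 0 or eigvals[2] < conditioning_ratio * max(eigvals[1], 1e-30):
        raise AmbiguousOrientationError(
            f"principal axes too isotropic (ratio {eigvals[2] / max(eigvals[1], 1e-30):.3g} "
            f"< {conditioning_ratio}); body orientation ambiguous")
    longitudinal = eigvecs[:, 2]

    vertical = mat.normal                       # unit, camera side positive
    longitudinal = longitudinal - (longitudinal @ vertical) * vertical
    norm = np.linalg.norm(longitudinal)
    if norm < 1e-9:
        raise AmbiguousOrientationError("longitudinal axis parallel to the mat normal")
    longitudinal = longitudinal / norm
    lateral = np.cross(vertical, longitudinal)
    rotation = np.vstack([longitudinal, lateral, vertical])
    return BodyFrame(rotation=rotation, origin=centroid)


def orient_head_left(frame: BodyFrame, head_centroid, body_centroid) -> BodyFrame:
    """Flip the frame 180 degrees about its vertical axis iff the head sits
    on the positive longitudinal side, so the head always ends up on the
    negative ("left") side.  Handedness is preserved."""
    head = np.asarray(head_centroid, dtype=np.float64).reshape(3)
    body = np.asarray(body_centroid, dtype=np.float64).reshape(3)
    if np.allclose(head, body):
        raise ValueError("head and body centroids coincide; orientation undefined")
    if (head - body) @ frame.longitudinal > 0:
        rotation = np.vstack([-frame.longitudinal, -frame.lateral, frame.vertical])
        return BodyFrame(rotation=rotation, origin=frame.origin)
    return frame
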