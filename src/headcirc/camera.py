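"""Pinhole camera geometry: depth image <-> metric point cloud.

The global coordinate frame has its origin ``Og`` at the camera, with the
z-axis along the optical axis pointing into the scene (all scene depths
``zp > 0``).  The depth image plane sits at distance ``f`` (in pixels) from
the origin, and pixel offsets ``(ud, vd)`` are measured from the principal
point ``Od``.  A surface point maps to its pixel as

    xp = -(zp / f) * ud,        yp = -(zp / f) * vd,

with ``zp`` read directly from the depth image.  The renderer in
:mod:`headcirc.synthetic` uses the exact inverse, so the sign convention is
self-consistent end to end.

Depths are 16-bit millimetres; 0 is the sensor's "no return" sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics: focal length in pixels and principal point.

    Parameters
    ----------
    focal_length_px
        Focal length ``f`` in pixels, > 0.
    principal_point
        ``(cu, cv)`` pixel coordinates of the image-plane origin.  Defaults
        to the image centre when not given explicitly (the optical axis is
        assumed to pierce the centre of the sensor).
    image_size
        ``(width, height)`` in pixels.
    """

    focal_length_px: float
    image_size: tuple[int, int]
    principal_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        w, h = self.image_size
        if self.focal_length_px <= 0:
            raise ValueError(f"focal length must be > 0, got {self.focal_length_px}")
        if w <= 0 or h <= 0:
            raise ValueError(f"image size must be positive, got {self.image_size}")
        if self.principal_point is None:
            object.__setattr__(self, "principal_point", ((w - 1) / 2.0, (h - 1) / 2.0))
        cu, cv = self.principal_point
        if not (0 <= cu < w and 0 <= cv < h):
            raise ValueError(f"principal point {self.principal_point} outside image {self.image_size}")

    @property
    def width(self) -> int:
        return self.image_size[0]

    @property
    def height(self) -> int:
        return self.image_size[1]

    def to_dict(self) -> dict:
        cu, cv = self.principal_point
        return {"f_px": self.focal_length_px, "cu": cu, "cv": cv,
                "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        pp = None
        if "cu" in d and "cv" in d:
            pp = (float(d["cu"]), float(d["cv"]))
        return cls(focal_length_px=float(d["f_px"]),
                   image_size=(int(d["width"]), int(d["height"])),
                   principal_point=pp)


@dataclass
class DepthImage:
    """A height x width grid of depths in millimetres; 0 marks no return.

    NaNs on ingest are normalised to the missing sentinel.  Values must fit
    the sensor's 16-bit range.
    """

    values: np.ndarray
    missing_value: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"depth image must be 2-D, got shape {v.shape}")
        v = np.where(np.isnan(v), self.missing_value, v)
        present = v != self.missing_value
        if np.any(v[present] < 0) or np.any(v[present] >= 2**16):
            raise ValueError("non-missing depths must lie in (0, 2^16)")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where the sensor returned a depth."""
        return self.values != self.missing_value


@dataclass
class PointCloud:
    """Metric 3-D points (mm) in the camera-origin global frame.

    ``pixels`` optionally records the source ``(row, col)`` of each point.
    """

    points: np.ndarray
    pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(p)):
            raise ValueError("point cloud contains non-finite coordinates")
        if p.size and np.any(p[:, 2] <= 0):
            raise ValueError("all points must have zp > 0 (in front of the camera)")
        self.points = p
        if self.pixels is not None:
            self.pixels = np.asarray(self.pixels).reshape(-1, 2)
            if len(self.pixels) != len(p):
                raise ValueError("pixels/points length mismatch")

    def __len__(self) -> int:
        return len(self.points)


def depth_to_points(depth: DepthImage, cam: CameraModel,
                    mask: np.ndarray | None = None) -> PointCloud:
    """Back-project a depth image into the metric global frame.

    Each valid (and mask-selected) pixel with depth ``zp`` at pixel offset
    ``(ud, vd)`` from the principal point yields the point
    ``(-(zp/f) ud, -(zp/f) vd, zp)``.  Missing pixels emit nothing; output
    is row-major over the image.
    """
    h, w = depth.shape
    if (w, h) != cam.image_size:
        raise ValueError(f"depth shape {depth.shape} does not match camera {cam.image_size}")
    select = depth.valid_mask
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != depth.shape:
            raise ValueError(f"mask shape {mask.shape} does not match depth {depth.shape}")
        select = select & mask

    rows, cols = np.nonzero(select)
    zp = depth.values[rows, cols]
    cu, cv = cam.principal_point
    ud = cols - cu
    vd = rows - cv
    scale = zp / cam.focal_length_px
    pts = np.column_stack([-scale * ud, -scale * vd, zp])
    return PointCloud(pts, pixels=np.column_stack([rows, cols]))


def project_points(points: np.ndarray, cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Project metric points to pixel offsets from the principal point.

    Exact inverse of :func:`depth_to_points`: ``ud = -f xp / zp``,
    ``vd = -f yp / zp``.  Returns ``(uv, depth)`` where ``uv[:, 0]`` is
    ``ud`` (column offset) and ``uv[:, 1]`` is ``vd`` (row offset).
    """
    p = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    z = p[:, 2]
    if np.any(z <= 0):
        raise ValueError("cannot project points with zp <= 0")
    f = cam.focal_length_px
    uv = np.column_stack([-f * p[:, 0] / z, -f * p[:, 1] / z])
    return uv, z.copy()


def write_ply(path, cloud: PointCloud) -> None:
    """Write a point cloud as ASCII PLY (x, y, z in millimetres)."""
    pts = cloud.points
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in pts:
            fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")
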