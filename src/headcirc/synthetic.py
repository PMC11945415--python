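"""Seeded synthetic incubator scenes with full ground truth.

Clinical depth recordings of newborns are not distributable, so every
stage of the pipeline is exercised on simulated scenes instead: a head
(ellipsoid) and body (larger ellipsoid) resting tangent on an undulating
mat, viewed top-down by the pinhole camera and rendered to a 16-bit depth
image with z-buffering, additive Gaussian depth noise and sparse large
outliers.

Key modelling choices:

* The head is an ellipsoid, not a sphere, with mild coronal anisotropy
  (vertical/lateral semi-axis ratio 0.85-1.15).  Its coronal section
  perimeter is then analytic -- the ground truth -- while the sphere-fit
  stage is exercised under realistic non-sphericity.
* Tangency is exact: the head centre is placed at the ellipsoid's support
  height above the ideal mat plane, so the minimum surface height above
  that plane is zero to numerical precision (the head-touches-mat
  constraint the measurement relies on).
* The mat is an ideal plane plus two seeded sinusoids (total amplitude
  <= 8 mm by default), emulating towel thickness and folding; rendering
  solves the ray/heightfield intersection by fixed-point iteration and is
  exact when the undulation is zero.
* Outliers displace 1-5% of pixels by +/-30-80 mm, emulating the specular
  and transparency artefacts of imaging through an incubator hood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import ellipe

from .camera import CameraModel, DepthImage
from .segmentation import BoundingBox
from .surface import Plane

MM_PER_CM = 10.0

DEFAULT_CAMERA = dict(focal_length_px=580.0, image_size=(640, 480))


def true_circumference(semi_axes_mm: tuple[float, float]) -> float:
    """Perimeter (cm) of the ellipse with the given semi-axes (mm).

    Uses the complete elliptic integral of the second kind:
    P = 4 a E(1 - (b/a)^2) with a the larger semi-axis.  Agrees with the
    Ramanujan approximation to well under 0.01% for aspect ratios <= 3.
    """
    p, q = semi_axes_mm
    if p <= 0 or q <= 0:
        raise ValueError(f"semi-axes must be > 0, got {semi_axes_mm}")
    a, b = max(p, q), min(p, q)
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * ellipe(m)) / MM_PER_CM


def _rotation(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    if axis == 0:
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == 1:
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


@dataclass
class SceneSpec:
    """Complete, reproducible description of one synthetic scene.

    Angles in degrees, lengths in millimetres.  ``head_tilt_deg`` rotates
    the head ellipsoid about its own longitudinal/lateral/vertical axes;
    ``yaw_deg`` rotates the whole subject about the mat normal;
    ``head_sign`` puts the head at the +/- longitudinal end (both occur in
    practice, and the pipeline must canonicalize either).
    """

    head_semi_axes_mm: tuple[float, float, float]          # (long, lat, vert)
    body_semi_axes_mm: tuple[float, float, float]
    head_tilt_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    yaw_deg: float = 0.0
    head_sign: int = -1
    mat_depth_mm: float = 900.0
    mat_tilt_deg: tuple[float, float] = (0.0, 0.0)
    mat_half_extent_mm: tuple[float, float] = (420.0, 330.0)
    undulation_amplitude_mm: tuple[float, float] = (0.0, 0.0)
    undulation_wavelength_mm: tuple[float, float] = (150.0, 90.0)
    undulation_phase_rad: tuple[float, float] = (0.0, 0.0)
    undulation_direction_deg: tuple[float, float] = (0.0, 90.0)
    noise_sigma_mm: float = 0.0
    outlier_fraction: float = 0.0
    outlier_range_mm: tuple[float, float] = (30.0, 80.0)
    camera: dict = field(default_factory=lambda: dict(DEFAULT_CAMERA))
    seed: int = 0
    scene_id: str = "scene"

    def __post_init__(self) -> None:
        for axes in (self.head_semi_axes_mm, self.body_semi_axes_mm):
            if any(a <= 0 for a in axes):
                raise ValueError(f"semi-axes must be positive, got {axes}")
        if self.noise_sigma_mm < 0 or not (0 <= self.outlier_fraction < 1):
            raise ValueError("invalid noise specification")
        if self.head_sign not in (-1, 1):
            raise ValueError("head_sign must be +/-1")

    @property
    def camera_model(self) -> CameraModel:
        cam = dict(self.camera)
        size = tuple(cam["image_size"])
        pp = tuple(cam["principal_point"]) if "principal_point" in cam else None
        return CameraModel(focal_length_px=cam["focal_length_px"],
                           image_size=size, principal_point=pp)

    @property
    def true_coronal_circumference_cm(self) -> float:
        """Perimeter of the head's own coronal section (lateral x vertical
        semi-axes) -- the quantity a tape measure would report."""
        _, ay, az = self.head_semi_axes_mm
        return true_circumference((ay, az))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        d = json.loads(text)
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        if isinstance(d.get("camera"), dict) and isinstance(d["camera"].get("image_size"), list):
            d["camera"]["image_size"] = tuple(d["camera"]["image_size"])
        return cls(**d)


@dataclass
class SyntheticScene:
    """A rendered scene plus every piece of ground truth the tests need."""

    depth: DepthImage
    camera: CameraModel
    head_mask: np.ndarray
    body_mask: np.ndarray
    mat_mask: np.ndarray
    boxes: list[BoundingBox]
    mat_plane: Plane                 # ideal plane, undulation excluded
    true_circumference_cm: float
    spec: SceneSpec

    @property
    def scene_id(self) -> str:
        return self.spec.scene_id


class _Ellipsoid:
    """World-frame ellipsoid: centre c, rotation R (rows = body axes in
    world coordinates), semi-axes a."""

    def __init__(self, center, rotation, semi_axes):
        self.center = np.asarray(center, dtype=float)
        self.rotation = np.asarray(rotation, dtype=float)
        self.semi_axes = np.asarray(semi_axes, dtype=float)

    def support_below(self, unit_normal: np.ndarray) -> float:
        """Distance from the centre to the tangent plane with the given
        (unit) normal: h = || diag(a) R n ||."""
        return float(np.linalg.norm(self.semi_axes * (self.rotation @ unit_normal)))

    def ray_hits(self, dirs: np.ndarray) -> np.ndarray:
        """Smallest positive ray parameter t (rays from the origin along
        ``dirs``); inf where the ray misses.  Vectorized over rays."""
        inv_a = 1.0 / self.semi_axes
        u = (dirs @ self.rotation.T) * inv_a            # (n, 3)
        w = (self.rotation @ self.center) * inv_a       # (3,)
        uu = np.einsum("ij,ij->i", u, u)
        uw = u @ w
        ww = w @ w
        disc = uw * uw - uu * (ww - 1.0)
        t = np.full(len(dirs), np.inf)
        ok = disc >= 0
        sqrt_disc = np.sqrt(np.maximum(disc, 0.0))
        t_near = (uw[ok] - sqrt_disc[ok]) / uu[ok]
        t_far = (uw[ok] + sqrt_disc[ok]) / uu[ok]
        best = np.where(t_near > 0, t_near, np.where(t_far > 0, t_far, np.inf))
        t[ok] = best
        return t


def _build_geometry(spec: SceneSpec):
    """Lay out mat plane, body and head in the world frame."""
    tx, ty = np.deg2rad(spec.mat_tilt_deg)
    n_hat = _rotation(0, tx) @ _rotation(1, ty) @ np.array([0.0, 0.0, -1.0])
    p0 = np.array([0.0, 0.0, spec.mat_depth_mm])

    # in-plane basis for the undulation field and the mat extent
    e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 - (e1 @ n_hat) * n_hat
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_hat, e1)

    # subject frame: longitudinal axis in the mat plane, rotated by yaw
    yaw = np.deg2rad(spec.yaw_deg)
    ell = np.cos(yaw) * e1 + np.sin(yaw) * e2
    lat = np.cross(n_hat, ell)
    subject_rows = np.vstack([ell, lat, n_hat])          # rows = axes

    bx = spec.body_semi_axes_mm[0]
    hx = spec.head_semi_axes_mm[0]
    offset = spec.head_sign * (bx + hx + 3.0)

    rx, ry, rz = np.deg2rad(spec.head_tilt_deg)
    tilt = _rotation(0, rx) @ _rotation(1, ry) @ _rotation(2, rz)
    head_rows = tilt.T @ subject_rows

    body = _Ellipsoid(center=np.zeros(3), rotation=subject_rows,
                      semi_axes=spec.body_semi_axes_mm)
    body.center = p0 + body.support_below(n_hat) * n_hat

    head = _Ellipsoid(center=np.zeros(3), rotation=head_rows,
                      semi_axes=spec.head_semi_axes_mm)
    head.center = p0 + offset * ell + head.support_below(n_hat) * n_hat

    gap = np.linalg.norm(head.center - body.center) - (bx + hx)
    if gap < -0.25 * hx:
        raise ValueError("head and body interpenetrate beyond tolerance")

    plane_coef = n_hat / (n_hat @ p0)
    return n_hat, p0, e1, e2, body, head, Plane(tuple(plane_coef))


def _undulation(spec: SceneSpec, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    w = np.zeros_like(alpha)
    for amp, lam, phase, theta_deg in zip(spec.undulation_amplitude_mm,
                                          spec.undulation_wavelength_mm,
                                          spec.undulation_phase_rad,
                                          spec.undulation_direction_deg):
        if amp == 0:
            continue
        th = np.deg2rad(theta_deg)
        coord = alpha * np.cos(th) + beta * np.sin(th)
        w = w + amp * np.sin(2 * np.pi * coord / lam + phase)
    return w


def _boxes_from_mask(mask: np.ndarray, label: str, margin: int = 2) -> BoundingBox | None:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return None
    h, w = mask.shape
    y0, y1 = max(int(rows.min()) - margin, 0), min(int(rows.max()) + margin + 1, h)
    x0, x1 = max(int(cols.min()) - margin, 0), min(int(cols.max()) + margin + 1, w)
    return BoundingBox(label, x0, y0, x1 - x0, y1 - y0, confidence=1.0)


def render_scene(spec: SceneSpec) -> SyntheticScene:
    """Render the spec to a depth image with oracle masks and boxes.

    Per pixel the nearest surface along the viewing ray among {undulating
    mat, body, head} wins the z-buffer; its identity becomes the oracle
    mask.  Gaussian noise and outliers are applied afterwards, so masks
    and boxes remain exact.  Deterministic for a fixed spec (seed
    included).
    """
    cam = spec.camera_model
    w, h = cam.image_size
    n_hat, p0, e1, e2, body, head, plane = _build_geometry(spec)

    cu, cv = cam.principal_point
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    ud = (cols - cu).ravel()
    vd = (rows - cv).ravel()
    f = cam.focal_length_px
    dirs = np.column_stack([-ud / f, -vd / f, np.ones_like(ud, dtype=float)])

    # mat: fixed-point iteration on the heightfield (exact when flat)
    nd = dirs @ n_hat
    np0 = float(n_hat @ p0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mat = np.where(nd < 0, np0 / nd, np.inf)
    if any(a > 0 for a in spec.undulation_amplitude_mm):
        for _ in range(3):
            pts = dirs * t_mat[:, None]
            rel = pts - p0
            alpha, beta = rel @ e1, rel @ e2
            wfield = _undulation(spec, alpha, beta)
            t_mat = np.where(nd < 0, (np0 + wfield) / nd, np.inf)
    pts = dirs * t_mat[:, None]
    rel = pts - p0
    alpha, beta = rel @ e1, rel @ e2
    half_a, half_b = spec.mat_half_extent_mm
    on_mat = (np.abs(alpha) <= half_a) & (np.abs(beta) <= half_b) & np.isfinite(t_mat)
    t_mat = np.where(on_mat, t_mat, np.inf)

    t_body = body.ray_hits(dirs)
    t_head = head.ray_hits(dirs)

    stack = np.vstack([t_mat, t_body, t_head])          # 0=mat, 1=body, 2=head
    winner = np.argmin(stack, axis=0)
    t_best = stack[winner, np.arange(stack.shape[1])]
    valid = np.isfinite(t_best)

    depth_flat = np.where(valid, t_best, 0.0)           # t is zp since dir_z = 1
    identity = np.where(valid, winner, -1)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma_mm > 0:
        depth_flat = np.where(valid,
                              depth_flat + rng.normal(0.0, spec.noise_sigma_mm,
                                                      size=depth_flat.shape),
                              0.0)
    if spec.outlier_fraction > 0:
        valid_idx = np.nonzero(valid)[0]
        k = int(round(spec.outlier_fraction * len(valid_idx)))
        if k > 0:
            chosen = rng.choice(valid_idx, size=k, replace=False)
            lo, hi = spec.outlier_range_mm
            magnitude = rng.uniform(lo, hi, size=k)
            sign = rng.choice([-1.0, 1.0], size=k)
            depth_flat[chosen] = depth_flat[chosen] + sign * magnitude
    depth_flat = np.clip(depth_flat, 0.0, 2**16 - 1)

    depth = DepthImage(depth_flat.reshape(h, w))
    head_mask = (identity == 2).reshape(h, w)
    body_mask = (identity == 1).reshape(h, w)
    mat_mask = (identity == 0).reshape(h, w)

    boxes = []
    for mask, label in ((head_mask, "head"), (body_mask, "body")):
        box = _boxes_from_mask(mask, label)
        if box is not None:
            boxes.append(box)
    return SyntheticScene(depth=depth, camera=cam, head_mask=head_mask,
                          body_mask=body_mask, mat_mask=mat_mask, boxes=boxes,
                          mat_plane=plane,
                          true_circumference_cm=spec.true_coronal_circumference_cm,
                          spec=spec)


def _spec_for_circumference(circ_cm: float, rng: np.random.Generator, *,
                            index: int, noise_sigma_mm: float,
                            undulation_max_mm: float, outlier_fraction: float,
                            tilt_max_deg: float, seed_pool: int) -> SceneSpec:
    ratio = rng.uniform(0.85, 1.15)                     # az / ay
    unit_perimeter_mm = true_circumference((1.0, ratio)) * MM_PER_CM
    ay = circ_cm * MM_PER_CM / unit_perimeter_mm
    az = ratio * ay
    ax = 1.25 * (ay + az) / 2.0

    scale = circ_cm / 31.4                              # body grows with the head
    body_axes = (105.0 * scale, 48.0 * scale, 38.0 * scale)
    amp_total = rng.uniform(0.0, undulation_max_mm)
    split = rng.uniform(0.3, 0.7)
    return SceneSpec(
        head_semi_axes_mm=(ax, ay, az),
        body_semi_axes_mm=body_axes,
        head_tilt_deg=tuple(rng.uniform(-tilt_max_deg, tilt_max_deg, size=3)),
        yaw_deg=float(rng.uniform(0.0, 360.0)),
        head_sign=int(rng.choice([-1, 1])),
        mat_tilt_deg=tuple(rng.uniform(-3.0, 3.0, size=2)),
        undulation_amplitude_mm=(amp_total * split, amp_total * (1 - split)),
        undulation_wavelength_mm=tuple(rng.uniform(80.0, 250.0, size=2)),
        undulation_phase_rad=tuple(rng.uniform(0.0, 2 * np.pi, size=2)),
        undulation_direction_deg=tuple(rng.uniform(0.0, 180.0, size=2)),
        noise_sigma_mm=noise_sigma_mm,
        outlier_fraction=outlier_fraction,
        seed=int(rng.integers(0, 2**31 - 1)) if seed_pool else 0,
        scene_id=f"scene_{index:04d}",
    )


def generate_cohort(n: int, circumference_range_cm: tuple[float, float] = (22.0, 38.0),
                    *, seed: int = 0, noise_sigma_mm: float = 1.0,
                    undulation_max_mm: float = 8.0, outlier_fraction: float = 0.02,
                    tilt_max_deg: float = 10.0,
                    render: bool = True) -> list[SyntheticScene] | list[SceneSpec]:
    """Generate ``n`` seeded scenes with circumferences sampled uniformly.

    Head tilt, subject yaw, mat tilt and undulation are randomized within
    their stated ranges.  Reproducible: the same ``seed`` gives an
    identical cohort (specs and rendered grids).  With ``render=False``
    only the :class:`SceneSpec` list is returned.
    """
    low, high = circumference_range_cm
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < low < high):
        raise ValueError(f"invalid circumference range {circumference_range_cm}")
    rng = np.random.default_rng(seed)
    circs = rng.uniform(low, high, size=n)
    specs = [_spec_for_circumference(c, rng, index=i, noise_sigma_mm=noise_sigma_mm,
                                     undulation_max_mm=undulation_max_mm,
                                     outlier_fraction=outlier_fraction,
                                     tilt_max_deg=tilt_max_deg, seed_pool=1)
             for i, c in enumerate(circs)]
    if not render:
        return specs
    return [render_scene(s) for s in specs]


def save_scene(directory, scene: SyntheticScene) -> None:
    """Persist a scene as 16-bit depth PNG + masks + JSON spec/boxes."""
    import imageio.v3 as iio
    from pathlib import Path
    from .segmentation import save_boxes

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    iio.imwrite(d / "depth.png",
                np.round(scene.depth.values).astype(np.uint16))
    for name, mask in (("head", scene.head_mask), ("body", scene.body_mask),
                       ("mat", scene.mat_mask)):
        iio.imwrite(d / f"mask_{name}.png", (mask.astype(np.uint8) * 255))
    (d / "spec.json").write_text(scene.spec.to_json())
    (d / "intrinsics.json").write_text(json.dumps(scene.camera.to_dict()))
    save_boxes(d / "boxes.json", scene.boxes)
    (d / "truth.json").write_text(json.dumps(
        {"scene_id": scene.scene_id,
         "true_circumference_cm": scene.true_circumference_cm,
         "mat_plane": scene.mat_plane.to_dict()}))
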