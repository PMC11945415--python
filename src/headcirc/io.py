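"""File-format plumbing: depth PNGs, raw grids, intrinsics, datasets."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .camera import CameraModel, DepthImage


def read_depth_png(path) -> DepthImage:
    """Read a 16-bit grayscale PNG where 1 unit = 1 mm and 0 = no return."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel depth PNG, got shape {arr.shape}")
    return DepthImage(arr.astype(np.float64))


def write_depth_png(path, depth: DepthImage) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.round(depth.values).astype(np.uint16))


def read_depth_raw(path, width: int, height: int, dtype=np.uint16) -> DepthImage:
    """Read a headerless binary depth grid with dimensions from config."""
    data = np.fromfile(path, dtype=dtype)
    if data.size != width * height:
        raise ValueError(f"{path}: {data.size} values, expected {width * height}")
    return DepthImage(data.reshape(height, width).astype(np.float64))


def read_intrinsics(path) -> CameraModel:
    """JSON with keys f_px, width, height and optionally cu, cv."""
    return CameraModel.from_dict(json.loads(Path(path).read_text()))


def write_intrinsics(path, cam: CameraModel) -> None:
    Path(path).write_text(json.dumps(cam.to_dict(), indent=2))
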