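"""End-to-end measurement flow and its configuration.

One call to :func:`measure` runs the whole chain on a depth image:

    detect -> masks + morphology -> mat ring -> back-projection ->
    RANSAC mat plane -> PCA alignment (head left) -> sphere fit ->
    sphere-consistency despike -> coronal cross-section -> features ->
    circumference prediction

Every stage failure is caught and reported with its stage tag in the
:class:`MeasurementReport`; a report is never partially silent.  The
effective configuration is embedded in each report for provenance.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import alignment, estimator, features, segmentation, surface
from .camera import CameraModel, DepthImage, depth_to_points
from .estimator import CircumferenceModel
from .features import FeatureVector
from .segmentation import DetectorProvider


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every tolerance and seed the pipeline uses, in one place.

    Values are millimetres/pixels unless suffixed otherwise.
    """

    ransac_iterations: int = 500
    ransac_tolerance_mm: float = 3.0
    ransac_seed: int = 0
    max_plane_points: int = 4000
    morphology_kernel: int = 3
    mat_ring_px: int = 40
    min_elevation_mm: float = 10.0
    refine_masks: bool = False
    slab_half_width_mm: float = 2.0
    bin_width_mm: float = 1.5
    min_section_bins: int = 5
    smooth_window: int = 0
    sphere_residual_mm: float = 15.0   # despike: drop points this far off the fitted sphere
    include_extra_features: bool = False
    pca_conditioning_ratio: float = 1.5

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_json_file(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(open(path).read()))


@dataclass
class MeasurementReport:
    """Result of one measurement with per-stage diagnostics."""

    scene_id: str
    circumference_cm: float | None
    features: dict | None
    diagnostics: dict
    warnings: list[dict]
    error: dict | None
    config: dict
    stage_timings_s: dict

    @property
    def ok(self) -> bool:
        return self.error is None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    @classmethod
    def from_json(cls, text: str) -> "MeasurementReport":
        return cls(**json.loads(text))


def _subsample(points: np.ndarray, limit: int, seed: int) -> np.ndarray:
    if len(points) <= limit:
        return points
    idx = np.random.default_rng(seed).choice(len(points), size=limit, replace=False)
    return points[idx]


def measure(depth: DepthImage, cam: CameraModel, detector: DetectorProvider,
            model: CircumferenceModel | None,
            config: PipelineConfig | None = None,
            scene_id: str = "scene") -> MeasurementReport:
    """Run the full measurement flow on one depth image.

    With ``model=None`` the pipeline stops after feature extraction (the
    report then carries features but no circumference) -- this is how
    training datasets are built.
    """
    cfg = config or PipelineConfig()
    diagnostics: dict = {}
    warnings_list: list[dict] = []
    timings: dict = {}
    t_start = time.perf_counter()

    def finish(circ=None, feats=None, error=None):
        timings["total"] = time.perf_counter() - t_start
        return MeasurementReport(scene_id=scene_id, circumference_cm=circ,
                                 features=feats, diagnostics=diagnostics,
                                 warnings=warnings_list, error=error,
                                 config=cfg.to_dict(), stage_timings_s=timings)

    def run_stage(tag, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(tag, str(exc)) from exc
        finally:
            timings[tag] = time.perf_counter() - t0
        return out

    try:
        # -- detection ----------------------------------------------------
        boxes = run_stage("detection", detector.detect, depth)
        labels = {b.label for b in boxes}
        if "head" not in labels:
            raise StageError("detection", "no head detected")
        if "body" not in labels:
            raise StageError("detection", "no body detected")
        diagnostics["n_boxes"] = len(boxes)

        # -- segmentation -------------------------------------------------
        masks = run_stage("segmentation", segmentation.masks_from_boxes,
                          depth, boxes, refine=cfg.refine_masks,
                          kernel_size=cfg.morphology_kernel,
                          min_elevation_mm=cfg.min_elevation_mm,
                          mat_ring_px=cfg.mat_ring_px)
        diagnostics["head_pixels"] = int(masks.head_mask.sum())
        diagnostics["body_pixels"] = int(masks.body_mask.sum())
        diagnostics["mat_pixels"] = int(masks.mat_mask.sum())

        # -- back-projection ----------------------------------------------
        def backproject():
            head = depth_to_points(depth, cam, masks.head_mask).points
            body = depth_to_points(depth, cam, masks.body_mask & ~masks.head_mask).points
            mat = depth_to_points(depth, cam, masks.mat_mask).points
            if len(head) < 50:
                raise StageError("backprojection", f"only {len(head)} head points")
            if len(mat) < 100:
                raise StageError("backprojection", f"only {len(mat)} mat points")
            return head, body, mat
        head_pts, body_pts, mat_pts = run_stage("backprojection", backproject)

        # -- mat plane ----------------------------------------------------
        mat_sample = _subsample(mat_pts, cfg.max_plane_points, cfg.ransac_seed)
        ransac = run_stage("mat_plane", surface.fit_plane_ransac, mat_sample,
                           iterations=cfg.ransac_iterations,
                           tolerance_mm=cfg.ransac_tolerance_mm,
                           seed=cfg.ransac_seed)
        diagnostics["plane"] = ransac.to_dict()
        if ransac.low_confidence:
            warnings_list.append({"stage": "mat_plane",
                                  "message": f"low plane support "
                                             f"({ransac.inlier_fraction:.2f} inliers)"})

        # -- alignment ----------------------------------------------------
        def align():
            frame = alignment.pca_align(body_pts, ransac.plane,
                                        conditioning_ratio=cfg.pca_conditioning_ratio)
            return alignment.orient_head_left(frame, head_pts.mean(axis=0),
                                              body_pts.mean(axis=0))
        frame = run_stage("alignment", align)
        diagnostics["body_frame"] = frame.to_dict()

        # -- sphere fit + despike -----------------------------------------
        def fit_head():
            sph = surface.fit_sphere_lsq(head_pts)
            resid = np.abs(np.linalg.norm(head_pts - np.asarray(sph.center), axis=1)
                           - sph.radius)
            keep = resid <= cfg.sphere_residual_mm
            dropped = int((~keep).sum())
            if dropped and keep.sum() >= 50:
                sph = surface.fit_sphere_lsq(head_pts[keep])
                return sph, head_pts[keep], dropped
            return sph, head_pts, dropped
        sphere, head_clean, n_dropped = run_stage("sphere_fit", fit_head)
        diagnostics["sphere"] = sphere.to_dict()
        diagnostics["head_points_despiked"] = n_dropped

        # -- cross-section + features -------------------------------------
        section = run_stage("features", features.extract_cross_section,
                            head_clean, sphere, ransac.plane, frame,
                            slab_half_width_mm=cfg.slab_half_width_mm,
                            bin_width_mm=cfg.bin_width_mm,
                            min_bins=cfg.min_section_bins,
                            smooth_window=cfg.smooth_window)
        fv = run_stage("features", features.compute_features, section,
                       sphere=sphere, include_extras=cfg.include_extra_features)
        diagnostics["section_bins"] = len(section)
        feats = fv.to_dict()

        if model is None:
            return finish(circ=None, feats=feats)

        # -- prediction ---------------------------------------------------
        pred = run_stage("predict", model.predict, fv)
        return finish(circ=float(pred[0]), feats=feats)

    except StageError as exc:
        return finish(error={"stage": exc.stage, "message": str(exc)})


def extract_features(scenes, config: PipelineConfig | None = None,
                     detector_factory=None):
    """Run the pipeline (without a model) over scenes; return a DataFrame
    of features + ground truth, skipping scenes whose pipeline failed.

    ``detector_factory(scene) -> DetectorProvider`` defaults to the oracle
    detector fed by each synthetic scene's ground-truth boxes.
    """
    import pandas as pd
    from .segmentation import OracleDetector

    if detector_factory is None:
        detector_factory = lambda scene: OracleDetector(scene.boxes)
    rows = []
    for scene in scenes:
        report = measure(scene.depth, scene.camera, detector_factory(scene),
                         model=None, config=config, scene_id=scene.scene_id)
        row = {"scene_id": scene.scene_id,
               "truth_cm": scene.true_circumference_cm,
               "ok": report.ok}
        if report.ok:
            row.update(report.features)
        else:
            row["error_stage"] = report.error["stage"]
        rows.append(row)
    return pd.DataFrame(rows)


def train_test_experiment(n_scenes: int = 184, n_train: int = 135, *, seed: int = 0,
                          algorithm: str = "random_forest",
                          config: PipelineConfig | None = None,
                          cohort_kwargs: dict | None = None):
    """Cohort -> features -> split -> train -> evaluate, in one call.

    Mirrors a 184-scene study split 135 train / 49 test.  Returns
    ``(model, EvaluationReport, dataframe)``.  Failed scenes (if any) are
    excluded from both splits, keeping the train fraction.
    """
    from .synthetic import generate_cohort

    scenes = generate_cohort(n_scenes, seed=seed, **(cohort_kwargs or {}))
    df = extract_features(scenes, config=config)
    good = df[df["ok"]].reset_index(drop=True)
    feature_cols = [c for c in good.columns
                    if c not in ("scene_id", "truth_cm", "ok", "error_stage")]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(good))
    k = int(round(n_train * len(good) / len(df)))
    train_idx, test_idx = order[:k], order[k:]

    x = good[feature_cols].to_numpy()
    y = good["truth_cm"].to_numpy()
    model = estimator.train(x[train_idx], y[train_idx], algorithm=algorithm,
                            seed=seed, feature_names=tuple(feature_cols))
    report = estimator.evaluate(model.predict(x[test_idx]), y[test_idx])
    good = good.assign(split=np.where(np.isin(np.arange(len(good)), train_idx),
                                      "train", "test"))
    return model, report, good
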