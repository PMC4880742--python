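"""Randomized synthetic-scene benchmarks of every pipeline stage.

These drive both the test suite's accuracy checks and the acceptance
script: each function renders seeded synthetic scenes, runs the stage
under test, and scores it against the renderer's analytic ground truth.
"""

from __future__ import annotations

import numpy as np

from . import nutrition, recognition, segmentation, stereo_volume
from .errors import CarbPlateError
from .geometry import default_camera
from .pipeline import PipelineConfig, estimate_meal
from .plate_detect import PlateDetectConfig, detect_plate, plate_from_ground_truth
from .recognition import FoodClassifier, classify_region, train_classifier
from .scene_synth import (
    CardPose,
    FoodPrimitive,
    SceneSpec,
    StudyTableParams,
    make_stereo_scene,
    make_study_table,
    random_scene_spec,
)
from .segmentation import SegmentationMask
from .stereo_volume import Correspondences, StereoConfig
from .study_stats import compute_errors, mann_whitney_u


def _per_item_ious(mask: SegmentationMask, gt_label: np.ndarray) -> list[float]:
    ious = []
    for k in range(1, int(gt_label.max()) + 1):
        g = gt_label == k
        best = 0.0
        for r in range(1, mask.n_regions + 1):
            m = mask.region_mask(r)
            union = np.logical_or(g, m).sum()
            if union:
                best = max(best, float(np.logical_and(g, m).sum() / union))
        ious.append(best)
    return ious


def plate_detection_benchmark(n_scenes: int = 100, seed: int = 0,
                              iou_threshold: float = 0.95) -> dict:
    """Detection success rate over seeded scenes at both protocol tilts."""
    rng = np.random.default_rng(seed)
    n_ok = n_views = 0
    for _ in range(n_scenes):
        spec = random_scene_spec(rng, noise_sigma=float(rng.uniform(0.0, 5.0)))
        scene = make_stereo_scene(spec)
        for img, gt in zip(scene.images, scene.ground_truths):
            n_views += 1
            try:
                fitted = detect_plate(img, PlateDetectConfig(rng_seed=seed))
            except CarbPlateError:
                continue
            true = plate_from_ground_truth(gt.plate_ellipse_px)
            if fitted.iou(true, img.shape[:2]) >= iou_threshold:
                n_ok += 1
    return {"numerator": n_ok, "denominator": n_views,
            "success_pct": 100.0 * n_ok / n_views}


def segmentation_benchmark(n_scenes: int = 100, seed: int = 0,
                           iou_threshold: float = 0.8) -> dict:
    """Fraction of scenes whose items are all recovered automatically."""
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_scenes):
        spec = random_scene_spec(rng)
        scene = make_stereo_scene(spec)
        img, gt = scene.images[0], scene.ground_truths[0]
        plate = plate_from_ground_truth(gt.plate_ellipse_px)
        mask = segmentation.auto_segment(img, plate)
        ious = _per_item_ious(mask, gt.label_map)
        if (mask.n_regions == len(ious)
                and all(v >= iou_threshold for v in ious)):
            n_ok += 1
    return {"numerator": n_ok, "denominator": n_scenes,
            "success_pct": 100.0 * n_ok / n_scenes}


def train_default_classifier(seed: int = 0, n_per_class: int = 20) -> FoodClassifier:
    feats, labels = recognition.render_labeled_regions(seed, n_per_class)
    return train_classifier(feats, labels)


def recognition_benchmark(seed: int = 0, n_train_per_class: int = 20,
                          n_test_per_class: int = 30,
                          classifier: FoodClassifier | None = None) -> dict:
    """Held-out per-item accuracy over fresh single-item renders."""
    if classifier is None:
        classifier = train_default_classifier(seed, n_train_per_class)
    feats, labels = recognition.render_labeled_regions(seed + 1, n_test_per_class)
    ok = sum(classify_region(classifier, f).top1 == y
             for f, y in zip(feats, labels))
    return {"numerator": ok, "denominator": len(labels),
            "accuracy_pct": 100.0 * ok / len(labels)}


def _stereo_volume_of(scene) -> float:
    gt0, gt1 = scene.ground_truths
    K = scene.cameras[0].K
    cfg = StereoConfig()
    plate = plate_from_ground_truth(gt0.plate_ellipse_px)
    areas = np.bincount(gt0.label_map.ravel())[1:]
    mask = SegmentationMask(label_map=gt0.label_map, region_areas_px=areas)
    corr = stereo_volume.match_keypoints(scene.images[0], scene.images[1], cfg)
    corr = Correspondences(
        view0_px=np.vstack([corr.view0_px, gt0.card_corners_px]),
        view1_px=np.vstack([corr.view1_px, gt1.card_corners_px]),
        scores=np.concatenate([corr.scores, np.ones(4)]))
    pose = stereo_volume.estimate_pose(corr, K, cfg)
    cloud = stereo_volume.reconstruct_depth(scene.images[0], scene.images[1],
                                            pose, cfg, corr=corr)
    plane = stereo_volume.fit_plate_plane(cloud, plate, mask, cfg)
    s = stereo_volume.scale_from_reference(pose, gt0.card_corners_px,
                                           gt1.card_corners_px, scene.card_size_cm)
    vols = stereo_volume.compute_volumes(cloud, s, plane, mask, plate, cfg,
                                         intrinsics=K)
    return vols.total_ml


def _primitive_scene(item: FoodPrimitive, seed: int, scale_all: float = 1.0):
    spec = SceneSpec(items=(item,), seed=seed, noise_sigma=2.0,
                     plate_radius_cm=12.0 * scale_all,
                     card_size_cm=(8.5 * scale_all, 5.4 * scale_all),
                     card_pose=CardPose(center_xy=(16.5 * scale_all, 0.0),
                                        angle_deg=20.0),
                     texture_unit_cm=scale_all)
    cams = (default_camera(0.0, distance_cm=45 * scale_all),
            default_camera(15.0, distance_cm=45 * scale_all))
    return make_stereo_scene(spec, cameras=cams)


def volume_benchmark(seed: int = 0, n_rep: int = 3) -> dict:
    """Closed-form primitives recovered from stereo + scale equivariance.

    Reconstructs a spherical cap (a = 3 cm, h = 2 cm, 32.46 ml) and a box
    (4 x 4 x 1 cm, 16 ml) from rendered stereo pairs (ground-truth masks
    and card corners isolate the reconstruction), and checks that scaling
    every physical dimension x2 scales the volume x8.
    """
    cap = FoodPrimitive("spherical_cap", (3.0, 2.0), (0, 0),
                        (0.95, 0.94, 0.90), "speckle", "rice", 0.25, 1.0)
    box = FoodPrimitive("box", (4.0, 4.0, 1.0), (0, 0),
                        (0.72, 0.50, 0.22), "speckle", "breaded", 0.35, 2.0)
    out: dict = {}
    for name, item in (("spherical_cap", cap), ("box", box)):
        errs = []
        for k in range(n_rep):
            scene = _primitive_scene(item, seed + k)
            est = _stereo_volume_of(scene)
            true = scene.item_volumes_ml[0]
            errs.append(100.0 * (est - true) / true)
        out[name] = {"true_ml": float(true), "errors_pct": errs,
                     "max_abs_err_pct": float(np.max(np.abs(errs)))}
    cap2 = FoodPrimitive("spherical_cap", (6.0, 4.0), (0, 0),
                         (0.95, 0.94, 0.90), "speckle", "rice", 0.5, 1.0)
    v1 = _stereo_volume_of(_primitive_scene(cap, seed + 10))
    v2 = _stereo_volume_of(_primitive_scene(cap2, seed + 10, scale_all=2.0))
    out["equivariance_ratio"] = float(v2 / v1)
    return out


def end_to_end_benchmark(n_scenes: int = 50, seed: int = 0,
                         classifier: FoodClassifier | None = None) -> dict:
    """Mean absolute carbohydrate error of the full pipeline.

    The reference for each meal is the ground-truth item volumes passed
    through the same density table with the true classes, so the error
    isolates the pipeline (not the toy nutrient values).
    """
    if classifier is None:
        classifier = train_default_classifier(seed)
    table = nutrition.load_density_table()
    cfg = PipelineConfig()
    rng = np.random.default_rng(seed + 7)
    errors, failures = [], 0
    for _ in range(n_scenes):
        spec = random_scene_spec(rng)
        scene = make_stereo_scene(spec)
        gt = scene.ground_truths[0]
        seeds = [tuple(np.mean(np.nonzero(gt.label_map == k), axis=1))
                 for k in range(1, int(gt.label_map.max()) + 1)]
        report = estimate_meal(scene, cfg, classifier, seeds=seeds or None)
        if not report.ok:
            failures += 1
            continue
        ref = sum(nutrition.carbs_from_volume(v, c, table)
                  for v, c in zip(gt.item_volumes_ml, gt.item_classes))
        errors.append(abs(report.meal.total_carbs_g - ref))
    errors = np.asarray(errors)
    return {
        "n_scenes": n_scenes,
        "n_failed": failures,
        "mean_abs_error_g": float(errors.mean()) if len(errors) else float("nan"),
        "p90_abs_error_g": float(np.percentile(errors, 90)) if len(errors) else float("nan"),
        "frac_within_20g": float(np.mean(errors < 20.0)) if len(errors) else 0.0,
    }


def mann_whitney_power(n_replicates: int = 200, seed: int = 0,
                       n_meals: int = 114, self_sd: float = 35.0,
                       system_sd: float = 12.0, alpha: float = 0.05) -> dict:
    """Rejection rate of the with/without comparison on simulated studies."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        params = StudyTableParams(n_meals=n_meals, self_error_sd_g=self_sd,
                                  system_error_sd_g=system_sd, self_bias_g=-5.0,
                                  seed=int(rng.integers(0, 2 ** 31 - 1)))
        t = make_study_table(params)
        a = compute_errors(t, "self")["abs_g"]
        b = compute_errors(t, "system")["abs_g"]
        _, p = mann_whitney_u(a, b)
        rejections += p < alpha
    return {"numerator": rejections, "denominator": n_replicates,
            "rejection_pct": 100.0 * rejections / n_replicates}
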