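"""Two-view pose, dense reconstruction, metric scale, and volumes."""

import numpy as np
import pytest

from carbplate.errors import (
    InsufficientPlatePointsError,
    InsufficientTextureError,
    NoReferenceError,
)
from carbplate.geometry import camera_pose, project_points, rotation_angle_deg
from carbplate.plate_detect import plate_from_ground_truth
from carbplate.scene_synth import FoodPrimitive, SceneSpec, make_stereo_scene
from carbplate.segmentation import SegmentationMask
from carbplate.stereo_volume import (
    Correspondences,
    RelativePose,
    compute_volumes,
    detect_card_corners,
    estimate_pose,
    fit_plate_plane,
    match_keypoints,
    reconstruct_depth,
    scale_from_reference,
)


def gt_relative_pose(scene):
    R0, C0 = camera_pose(scene.cameras[0])
    R1, C1 = camera_pose(scene.cameras[1])
    R = R1 @ R0.T
    t = R1 @ (C0 - C1)
    B = float(np.linalg.norm(t))
    return RelativePose(rotation=R, translation_dir=t / B,
                        intrinsics=scene.cameras[0].K), B


def gt_correspondences(scene, n=400, seed=0):
    """Exact matches: view0 hit points projected into view1."""
    gt0 = scene.ground_truths[0]
    rng = np.random.default_rng(seed)
    rows, cols = gt0.label_map.shape
    r = rng.integers(15, rows - 15, n)
    c = rng.integers(15, cols - 15, n)
    world = gt0.hit_points[r, c]
    ok = np.isfinite(world).all(axis=1)
    p1 = project_points(world[ok], scene.cameras[1])
    inb = ((p1[:, 0] >= 0) & (p1[:, 0] < rows) & (p1[:, 1] >= 0) & (p1[:, 1] < cols))
    p0 = np.column_stack([r[ok], c[ok]]).astype(float)[inb]
    return Correspondences(view0_px=p0, view1_px=p1[inb], scores=np.ones(inb.sum()))


def gt_mask(gt):
    areas = np.bincount(gt.label_map.ravel())[1:]
    return SegmentationMask(label_map=gt.label_map, region_areas_px=areas)


class TestMatchKeypoints:
    def test_self_match_has_zero_disparity(self, three_item_scene):
        img = three_item_scene.images[0]
        corr = match_keypoints(img, img)
        d = np.linalg.norm(corr.view0_px - corr.view1_px, axis=1)
        assert np.mean(d < 0.75) >= 0.95

    def test_uniform_images_raise(self):
        g = np.full((200, 200, 3), 128, dtype=np.uint8)
        with pytest.raises(InsufficientTextureError):
            match_keypoints(g, g)

    def test_matches_agree_with_ground_truth_projection(self, three_item_scene):
        corr = match_keypoints(three_item_scene.images[0], three_item_scene.images[1])
        gt0 = three_item_scene.ground_truths[0]
        rc = np.round(corr.view0_px).astype(int)
        world = gt0.hit_points[rc[:, 0], rc[:, 1]]
        ok = np.isfinite(world).all(axis=1)
        expected = project_points(world[ok], three_item_scene.cameras[1])
        err = np.linalg.norm(expected - corr.view1_px[ok], axis=1)
        # most matches are sub-pixel; a minority of coarse-octave keypoints
        # localize to a few px, which the robust pose stage absorbs
        assert np.median(err) < 0.75
        assert np.mean(err < 1.5) >= 0.75
        assert np.mean(err > 12.0) < 0.05


class TestEstimatePose:
    def test_exact_recovery_from_ground_truth_matches(self, three_item_scene):
        pose_gt, _ = gt_relative_pose(three_item_scene)
        corr = gt_correspondences(three_item_scene)
        pose = estimate_pose(corr, three_item_scene.cameras[0].K)
        assert rotation_angle_deg(pose.rotation @ pose_gt.rotation.T) < 0.5
        cos = abs(pose.translation_dir @ pose_gt.translation_dir)
        assert np.rad2deg(np.arccos(min(cos, 1.0))) < 0.5

    def test_recovered_tilt_is_fifteen_degrees(self, three_item_scene):
        corr = gt_correspondences(three_item_scene)
        pose = estimate_pose(corr, three_item_scene.cameras[0].K)
        assert rotation_angle_deg(pose.rotation) == pytest.approx(15.0, abs=0.5)

    def test_robust_to_20pct_outlier_matches(self, three_item_scene):
        pose_gt, _ = gt_relative_pose(three_item_scene)
        corr = gt_correspondences(three_item_scene)
        rng = np.random.default_rng(3)
        n_out = int(0.2 * len(corr))
        idx = rng.choice(len(corr), n_out, replace=False)
        v1 = corr.view1_px.copy()
        v1[idx] = rng.uniform(0, 320, size=(n_out, 2))
        noisy = Correspondences(corr.view0_px, v1, corr.scores)
        pose = estimate_pose(noisy, three_item_scene.cameras[0].K)
        assert rotation_angle_deg(pose.rotation @ pose_gt.rotation.T) < 1.0

    def test_too_few_correspondences_rejected(self, three_item_scene):
        corr = gt_correspondences(three_item_scene)
        small = Correspondences(corr.view0_px[:5], corr.view1_px[:5], corr.scores[:5])
        from carbplate.errors import PoseFailureError
        with pytest.raises(PoseFailureError):
            estimate_pose(small, three_item_scene.cameras[0].K)


class TestReconstructDepth:
    def test_table_points_are_coplanar(self, one_item_scene):
        pose, _ = gt_relative_pose(one_item_scene)
        gt0 = one_item_scene.ground_truths[0]
        corr = match_keypoints(one_item_scene.images[0], one_item_scene.images[1])
        cloud = reconstruct_depth(one_item_scene.images[0], one_item_scene.images[1],
                                  pose, corr=corr)
        plate = plate_from_ground_truth(gt0.plate_ellipse_px)
        plane = fit_plate_plane(cloud, plate, gt_mask(gt0))
        lab = gt0.label_map[cloud.pixels_rc[:, 0], cloud.pixels_rc[:, 1]]
        on_plate = (lab == 0) & plate.contains(cloud.pixels_rc, margin_px=6)
        res = cloud.points[on_plate] @ plane.normal - plane.d
        r_model = (plate.semi_axes_px[0] * (plane.d / plane.normal[2])
                   / one_item_scene.cameras[0].K[0, 0])
        assert np.sqrt(np.mean(res ** 2)) < 0.01 * abs(r_model)

    def test_cap_apex_to_plate_radius_ratio(self):
        cap = FoodPrimitive("spherical_cap", (3.0, 2.0), (0.0, 0.0),
                            (0.95, 0.94, 0.90), "speckle", "rice", 0.25, 1.0)
        scene = make_stereo_scene(SceneSpec(items=(cap,), seed=1))
        pose, _ = gt_relative_pose(scene)
        gt0 = scene.ground_truths[0]
        corr = match_keypoints(scene.images[0], scene.images[1])
        cloud = reconstruct_depth(scene.images[0], scene.images[1], pose, corr=corr)
        plate = plate_from_ground_truth(gt0.plate_ellipse_px)
        plane = fit_plate_plane(cloud, plate, gt_mask(gt0))
        lab = gt0.label_map[cloud.pixels_rc[:, 0], cloud.pixels_rc[:, 1]]
        apex = np.percentile((cloud.points @ plane.normal - plane.d)[lab == 1], 99)
        r_model = (plate.semi_axes_px[0] * (plane.d / plane.normal[2])
                   / scene.cameras[0].K[0, 0])
        assert apex / abs(r_model) == pytest.approx(2.0 / 12.0, rel=0.05)

    def test_view_swap_gives_congruent_geometry(self, one_item_scene):
        """Swapping the two views must reconstruct the same metric shape."""
        gt0 = one_item_scene.ground_truths[0]
        plate0 = plate_from_ground_truth(gt0.plate_ellipse_px)
        heights = []
        for v0, v1, gt, cam in ((0, 1, gt0, 0),
                                (1, 0, one_item_scene.ground_truths[1], 1)):
            corr = match_keypoints(one_item_scene.images[v0], one_item_scene.images[v1])
            pose = estimate_pose(corr, one_item_scene.cameras[cam].K)
            cloud = reconstruct_depth(one_item_scene.images[v0],
                                      one_item_scene.images[v1], pose, corr=corr)
            plate = plate_from_ground_truth(gt.plate_ellipse_px)
            plane = fit_plate_plane(cloud, plate, gt_mask(gt))
            lab = gt.label_map[cloud.pixels_rc[:, 0], cloud.pixels_rc[:, 1]]
            h = (cloud.points @ plane.normal - plane.d)[lab == 1]
            s = scale_from_reference(
                pose, one_item_scene.ground_truths[v0].card_corners_px,
                one_item_scene.ground_truths[v1].card_corners_px,
                one_item_scene.card_size_cm)
            heights.append(np.percentile(h, 95) * s)
        assert heights[1] == pytest.approx(heights[0], rel=0.05)


class TestScaleFromReference:
    def test_scale_recovers_baseline(self, three_item_scene):
        pose, B = gt_relative_pose(three_item_scene)
        gt0, gt1 = three_item_scene.ground_truths
        s = scale_from_reference(pose, gt0.card_corners_px, gt1.card_corners_px,
                                 three_item_scene.card_size_cm)
        assert s == pytest.approx(B, rel=1e-6)

    def test_inverse_scaling_with_card_size(self, three_item_scene):
        pose, _ = gt_relative_pose(three_item_scene)
        gt0, gt1 = three_item_scene.ground_truths
        w, h = three_item_scene.card_size_cm
        s1 = scale_from_reference(pose, gt0.card_corners_px, gt1.card_corners_px, (w, h))
        s2 = scale_from_reference(pose, gt0.card_corners_px, gt1.card_corners_px,
                                  (2 * w, 2 * h))
        assert s2 == pytest.approx(2 * s1, rel=1e-9)

    def test_card_diagonal_within_one_percent(self, three_item_scene):
        from carbplate.stereo_volume import _triangulate_linear
        from carbplate.geometry import rc_to_uv

        pose, B = gt_relative_pose(three_item_scene)
        gt0, gt1 = three_item_scene.ground_truths
        X = _triangulate_linear(pose.intrinsics, pose.rotation, pose.translation_dir,
                                rc_to_uv(gt0.card_corners_px),
                                rc_to_uv(gt1.card_corners_px)) * B
        diag = np.linalg.norm(X[0] - X[2])
        w, h = three_item_scene.card_size_cm
        assert diag == pytest.approx(np.hypot(w, h), rel=0.01)

    def test_detected_corners_close_to_truth(self, three_item_scene):
        for v in (0, 1):
            gt = three_item_scene.ground_truths[v]
            plate = plate_from_ground_truth(gt.plate_ellipse_px)
            det = detect_card_corners(three_item_scene.images[v], plate)
            err = [np.min(np.linalg.norm(gt.card_corners_px - d, axis=1)) for d in det]
            assert np.median(err) < 1.0
            assert max(err) < 5.0

    def test_missing_card_raises(self):
        img = np.full((200, 200, 3), 180, dtype=np.uint8)
        with pytest.raises(NoReferenceError):
            detect_card_corners(img)


class TestFitPlatePlane:
    def test_noiseless_normal_matches_world_up(self, one_item_scene):
        pose, _ = gt_relative_pose(one_item_scene)
        gt0 = one_item_scene.ground_truths[0]
        corr = match_keypoints(one_item_scene.images[0], one_item_scene.images[1])
        cloud = reconstruct_depth(one_item_scene.images[0], one_item_scene.images[1],
                                  pose, corr=corr)
        plate = plate_from_ground_truth(gt0.plate_ellipse_px)
        plane = fit_plate_plane(cloud, plate, gt_mask(gt0))
        R0, _ = camera_pose(one_item_scene.cameras[0])
        n_world = R0.T @ plane.normal
        assert np.rad2deg(np.arccos(abs(n_world[2]))) < 0.5

    def test_outlier_points_do_not_tilt_plane(self, one_item_scene):
        from carbplate.stereo_volume import DepthCloud

        pose, _ = gt_relative_pose(one_item_scene)
        gt0 = one_item_scene.ground_truths[0]
        corr = match_keypoints(one_item_scene.images[0], one_item_scene.images[1])
        cloud = reconstruct_depth(one_item_scene.images[0], one_item_scene.images[1],
                                  pose, corr=corr)
        plate = plate_from_ground_truth(gt0.plate_ellipse_px)
        clean = fit_plate_plane(cloud, plate, gt_mask(gt0))
        rng = np.random.default_rng(0)
        n_out = int(0.1 * len(cloud.points))
        pts = cloud.points.copy()
        idx = rng.choice(len(pts), n_out, replace=False)
        pts[idx, 2] *= rng.uniform(0.7, 1.3, n_out)
        noisy = fit_plate_plane(DepthCloud(points=pts, pixels_rc=cloud.pixels_rc),
                                plate, gt_mask(gt0))
        ang = np.rad2deg(np.arccos(abs(clean.normal @ noisy.normal)))
        assert ang < 1.0

    def test_fully_covered_plate_rejected(self, one_item_scene):
        pose, _ = gt_relative_pose(one_item_scene)
        gt0 = one_item_scene.ground_truths[0]
        corr = match_keypoints(one_item_scene.images[0], one_item_scene.images[1])
        cloud = reconstruct_depth(one_item_scene.images[0], one_item_scene.images[1],
                                  pose, corr=corr)
        plate = plate_from_ground_truth(gt0.plate_ellipse_px)
        all_food = SegmentationMask(
            label_map=np.ones_like(gt0.label_map),
            region_areas_px=np.array([gt0.label_map.size]))
        with pytest.raises(InsufficientPlatePointsError):
            fit_plate_plane(cloud, plate, all_food)


class TestComputeVolumes:
    def _run(self, scene):
        pose, B = gt_relative_pose(scene)
        gt0, gt1 = scene.ground_truths
        corr = match_keypoints(scene.images[0], scene.images[1])
        cloud = reconstruct_depth(scene.images[0], scene.images[1], pose, corr=corr)
        plate = plate_from_ground_truth(gt0.plate_ellipse_px)
        mask = gt_mask(gt0)
        plane = fit_plate_plane(cloud, plate, mask)
        s = scale_from_reference(pose, gt0.card_corners_px, gt1.card_corners_px,
                                 scene.card_size_cm)
        return compute_volumes(cloud, s, plane, mask, plate,
                               intrinsics=scene.cameras[0].K)

    def test_spherical_cap_within_ten_percent(self):
        cap = FoodPrimitive("spherical_cap", (3.0, 2.0), (0.0, 0.0),
                            (0.95, 0.94, 0.90), "speckle", "rice", 0.25, 1.0)
        scene = make_stereo_scene(SceneSpec(items=(cap,), seed=0))
        vols = self._run(scene)
        assert vols.total_ml == pytest.approx(32.4631, rel=0.10)

    def test_box_within_ten_percent(self):
        box = FoodPrimitive("box", (4.0, 4.0, 1.0), (0.0, 0.0),
                            (0.72, 0.50, 0.22), "speckle", "breaded", 0.35, 2.0)
        scene = make_stereo_scene(SceneSpec(items=(box,), seed=0))
        vols = self._run(scene)
        assert vols.total_ml == pytest.approx(16.0, rel=0.10)

    def test_flat_sticker_volume_near_zero(self):
        # 0.1 mm tall disc: volume should vanish up to the method's
        # height-noise floor (~0.5 mm over the region)
        sticker = FoodPrimitive("cylinder", (1.5, 0.01), (0.0, 0.0),
                                (0.9, 0.2, 0.2), "speckle", "beans", 0.3, 1.0)
        scene = make_stereo_scene(SceneSpec(items=(sticker,), seed=0))
        vols = self._run(scene)
        assert vols.total_ml < 2.0

    def test_total_is_sum_of_regions(self, three_item_scene):
        vols = self._run(three_item_scene)
        assert vols.total_ml == pytest.approx(sum(vols.region_volumes_ml.values()),
                                              abs=1e-12)
        assert len(vols.region_volumes_ml) == 3
        assert all(v >= 0 for v in vols.region_volumes_ml.values())
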