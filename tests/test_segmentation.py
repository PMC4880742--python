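"""Region growing, merging, and the two segmentation modes."""

import numpy as np
import pytest

from carbplate.errors import InvalidSeedError
from carbplate.plate_detect import PlateEllipse, plate_from_ground_truth
from carbplate.scene_synth import SceneSpec, render_view
from carbplate.geometry import default_camera
from carbplate.segmentation import (
    SegmentationConfig,
    auto_segment,
    grow_regions,
    merge_regions,
    region_adjacency,
    seeded_segment,
)
from conftest import per_item_ious

PLATE = PlateEllipse(center_px=(100.0, 100.0), semi_axes_px=(80.0, 80.0),
                     rotation_deg=0.0)


def _blob_image(centers, radius=18, colors=((220, 40, 40), (40, 220, 40), (40, 40, 220))):
    """Uniform plate-colored disc with uniform-color blobs."""
    img = np.full((200, 200, 3), (150, 170, 200), dtype=np.uint8)
    r, c = np.mgrid[0:200, 0:200]
    gt = np.zeros((200, 200), dtype=int)
    for k, ((cr, cc), col) in enumerate(zip(centers, colors), start=1):
        m = (r - cr) ** 2 + (c - cc) ** 2 <= radius ** 2
        img[m] = col
        gt[m] = k
    return img, gt


class TestGrowRegions:
    def test_three_uniform_blobs_recovered(self):
        centers = [(70, 70), (70, 130), (135, 100)]
        img, gt = _blob_image(centers)
        # no smoothing: isolates the growth logic from the blur halo
        mask = grow_regions(img, PLATE, centers, SegmentationConfig(smooth_sigma=0))
        assert mask.n_regions == 3
        assert min(per_item_ious(mask, gt)) >= 0.95

    def test_single_seed_floods_uniform_plate(self):
        img = np.full((200, 200, 3), (150, 170, 200), dtype=np.uint8)
        mask = grow_regions(img, PLATE, [(100, 100)])
        inside = PLATE.mask((200, 200))
        margin_inside = PLATE.contains(
            np.column_stack([g.ravel() for g in np.mgrid[0:200, 0:200]]),
            margin_px=SegmentationConfig().rim_margin_px).reshape(200, 200)
        covered = (mask.label_map == 1)
        assert covered.sum() >= 0.99 * margin_inside.sum()
        assert not np.any(covered & ~inside)

    def test_seed_outside_plate_rejected(self):
        img = np.full((200, 200, 3), 128, dtype=np.uint8)
        with pytest.raises(InvalidSeedError):
            grow_regions(img, PLATE, [(5, 5)])

    def test_zero_seeds_rejected(self):
        img = np.full((200, 200, 3), 128, dtype=np.uint8)
        with pytest.raises(InvalidSeedError):
            grow_regions(img, PLATE, [])

    def test_deterministic(self):
        centers = [(70, 70), (130, 130)]
        img, _ = _blob_image(centers)
        m1 = grow_regions(img, PLATE, centers)
        m2 = grow_regions(img, PLATE, centers)
        assert np.array_equal(m1.label_map, m2.label_map)

    def test_areas_sum_to_labeled_pixels(self):
        centers = [(70, 70), (130, 130)]
        img, _ = _blob_image(centers)
        m = grow_regions(img, PLATE, centers)
        assert m.region_areas_px.sum() == (m.label_map > 0).sum()


class TestMergeRegions:
    def test_same_color_adjacent_fragments_merge(self):
        img, gt = _blob_image([(100, 90)], radius=25)
        # two seeds in one blob -> two fragments of the same color
        mask = grow_regions(img, PLATE, [(100, 80), (100, 100)],
                            SegmentationConfig(grow_tol=4.0))
        assert mask.n_regions == 2
        adj = region_adjacency(img, mask)
        merged = merge_regions(mask, adj, plate_area_px=PLATE.area_px)
        labels = np.unique(merged.label_map[gt == 1])
        assert len(labels[labels > 0]) == 1

    def test_non_adjacent_same_color_never_merge(self):
        img, _ = _blob_image([(70, 70), (130, 130)],
                             colors=((220, 40, 40), (220, 40, 40)))
        mask = grow_regions(img, PLATE, [(70, 70), (130, 130)])
        adj = region_adjacency(img, mask)
        assert (1, 2) not in adj.pairs
        merged = merge_regions(mask, adj, plate_area_px=PLATE.area_px)
        assert merged.n_regions == 2

    def test_never_increases_region_count(self):
        img, _ = _blob_image([(70, 70), (130, 130)])
        mask = grow_regions(img, PLATE, [(70, 70), (130, 130), (100, 100)])
        adj = region_adjacency(img, mask)
        merged = merge_regions(mask, adj, plate_area_px=PLATE.area_px)
        assert merged.n_regions <= mask.n_regions


class TestAutoSegment:
    def test_three_item_scene_fully_recovered(self, three_item_scene):
        img, gt = three_item_scene.images[0], three_item_scene.ground_truths[0]
        plate = plate_from_ground_truth(gt.plate_ellipse_px)
        mask = auto_segment(img, plate)
        assert mask.n_regions == 3
        assert min(per_item_ious(mask, gt.label_map)) >= 0.9

    def test_empty_plate_yields_zero_regions(self):
        spec = SceneSpec(items=(), seed=2)
        img, gt = render_view(spec, default_camera(0.0))
        plate = plate_from_ground_truth(gt.plate_ellipse_px)
        mask = auto_segment(img, plate)
        assert mask.n_regions == 0

    def test_labels_form_partition(self, three_item_scene):
        img, gt = three_item_scene.images[0], three_item_scene.ground_truths[0]
        plate = plate_from_ground_truth(gt.plate_ellipse_px)
        mask = auto_segment(img, plate)
        labels = np.unique(mask.label_map)
        assert labels.min() == 0
        assert set(labels) == set(range(mask.n_regions + 1))
        inside = plate.mask(img.shape[:2])
        assert not np.any((mask.label_map > 0) & ~inside)


class TestSeededSegment:
    def test_three_seeds_recover_three_items(self, three_item_scene):
        img, gt = three_item_scene.images[0], three_item_scene.ground_truths[0]
        plate = plate_from_ground_truth(gt.plate_ellipse_px)
        seeds = [tuple(np.mean(np.nonzero(gt.label_map == k), axis=1))
                 for k in (1, 2, 3)]
        mask = seeded_segment(img, plate, seeds)
        assert mask.n_regions == 3
        assert min(per_item_ious(mask, gt.label_map)) >= 0.95

    def test_single_seed_gives_single_region(self, three_item_scene):
        img, gt = three_item_scene.images[0], three_item_scene.ground_truths[0]
        plate = plate_from_ground_truth(gt.plate_ellipse_px)
        seed = tuple(np.mean(np.nonzero(gt.label_map == 1), axis=1))
        mask = seeded_segment(img, plate, [seed])
        assert mask.n_regions == 1

    def test_deterministic(self, three_item_scene):
        img, gt = three_item_scene.images[0], three_item_scene.ground_truths[0]
        plate = plate_from_ground_truth(gt.plate_ellipse_px)
        seeds = [tuple(np.mean(np.nonzero(gt.label_map == k), axis=1))
                 for k in (1, 2, 3)]
        m1 = seeded_segment(img, plate, seeds)
        m2 = seeded_segment(img, plate, seeds)
        assert np.array_equal(m1.label_map, m2.label_map)

    def test_agrees_with_auto_on_uniform_fixture(self):
        centers = [(70, 70), (70, 130), (135, 100)]
        img, gt = _blob_image(centers)
        auto = auto_segment(img, PLATE)
        seeded = seeded_segment(img, PLATE, centers)
        assert auto.n_regions == seeded.n_regions == 3
        for k in (1, 2, 3):
            g = gt == k
            best = max(
                np.logical_and(g, seeded.label_map == r).sum()
                / max(np.logical_or(g, seeded.label_map == r).sum(), 1)
                for r in (1, 2, 3))
            assert best >= 0.95
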