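"""Feature extraction, SVM training, ranked labels, manual override."""

import numpy as np
import pytest

from carbplate.errors import TooSmallRegionError
from carbplate.recognition import (
    FOOD_CLASSES,
    FeatureVector,
    RecognitionConfig,
    apply_override,
    classify_region,
    extract_features,
    load_classifier,
    save_classifier,
    train_classifier,
)
from carbplate.segmentation import SegmentationMask


def _mask_from(label_map):
    areas = np.bincount(label_map.ravel())[1:]
    return SegmentationMask(label_map=label_map.astype(np.int32),
                            region_areas_px=areas)


def _textured_patch(rng, size=40):
    return rng.integers(0, 256, size=(size, size, 3)).astype(np.uint8)


class TestExtractFeatures:
    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        patch = _textured_patch(rng)
        img = np.full((200, 200, 3), 90, dtype=np.uint8)
        img[10:50, 10:50] = patch
        img[120:160, 140:180] = patch
        lab = np.zeros((200, 200), dtype=np.int32)
        lab[10:50, 10:50] = 1
        lab[120:160, 140:180] = 2
        mask = _mask_from(lab)
        f1 = extract_features(img, mask, 1)
        f2 = extract_features(img, mask, 2)
        assert np.array_equal(f1.values, f2.values)

    def test_constant_region_lbp_mass_in_flat_bin(self):
        # for a constant field every neighbor equals the center, which the
        # uniform LBP maps to the all-ones pattern: histogram bin P (here 8)
        img = np.full((100, 100, 3), 120, dtype=np.uint8)
        lab = np.zeros((100, 100), dtype=np.int32)
        lab[20:60, 20:60] = 1
        fv = extract_features(img, _mask_from(lab), 1)
        assert fv.texture_block[8] == pytest.approx(1.0)
        assert fv.texture_block.sum() == pytest.approx(1.0)

    def test_pure_colors_occupy_disjoint_bins(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        img[:, :50] = (255, 0, 0)
        img[:, 50:] = (0, 255, 0)
        lab = np.zeros((100, 100), dtype=np.int32)
        lab[10:40, 10:40] = 1
        lab[10:40, 60:90] = 2
        f1 = extract_features(img, _mask_from(lab), 1)
        f2 = extract_features(img, _mask_from(lab), 2)
        assert np.sum((f1.color_block > 0) & (f2.color_block > 0)) == 0

    def test_too_small_region_rejected(self):
        img = np.full((50, 50, 3), 100, dtype=np.uint8)
        lab = np.zeros((50, 50), dtype=np.int32)
        lab[10:12, 10:12] = 1
        with pytest.raises(TooSmallRegionError):
            extract_features(img, _mask_from(lab), 1)


def _separable_features(rng, n_per_class=10):
    feats, labels = [], []
    dim = RecognitionConfig().n_features
    for k, cls in enumerate(FOOD_CLASSES[:3]):
        for _ in range(n_per_class):
            v = rng.normal(scale=0.01, size=dim)
            v[k] += 1.0
            feats.append(FeatureVector(color_block=v[:64], texture_block=v[64:]))
            labels.append(cls)
    return feats, labels


class TestTrainClassifier:
    def test_separable_classes_training_accuracy_100(self):
        rng = np.random.default_rng(0)
        feats, labels = _separable_features(rng)
        clf = train_classifier(feats, labels)
        preds = [classify_region(clf, f).top1 for f in feats]
        assert preds == labels

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        feats, _ = _separable_features(rng)
        with pytest.raises(ValueError):
            train_classifier(feats[:10], ["pasta"] * 10)

    def test_training_order_invariance(self):
        rng = np.random.default_rng(1)
        feats, labels = _separable_features(rng)
        clf1 = train_classifier(feats, labels)
        perm = rng.permutation(len(feats))
        clf2 = train_classifier([feats[i] for i in perm], [labels[i] for i in perm])
        test = _separable_features(np.random.default_rng(2), n_per_class=5)[0]
        for fv in test:
            p1 = clf1.predict_proba_all(fv)
            p2 = clf2.predict_proba_all(fv)
            assert np.allclose(p1, p2, atol=1e-12)

    def test_roundtrip_persistence(self, tmp_path):
        rng = np.random.default_rng(3)
        feats, labels = _separable_features(rng)
        clf = train_classifier(feats, labels)
        save_classifier(clf, tmp_path / "m.joblib")
        loaded = load_classifier(tmp_path / "m.joblib")
        fv = feats[0]
        assert np.allclose(loaded.predict_proba_all(fv), clf.predict_proba_all(fv))


class TestClassifyRegion:
    def test_ranking_is_valid_probability_ordering(self, small_classifier):
        rng = np.random.default_rng(4)
        dim = RecognitionConfig().n_features
        for _ in range(100):
            v = np.abs(rng.normal(size=dim))
            v /= v.sum()
            fv = FeatureVector(color_block=v[:64], texture_block=v[64:])
            ranked = classify_region(small_classifier, fv)
            confs = [p for _, p in ranked.entries]
            assert len(ranked.entries) == 9
            assert sum(confs) == pytest.approx(1.0, abs=1e-9)
            assert all(confs[i] >= confs[i + 1] for i in range(8))

    def test_dimension_mismatch_rejected(self, small_classifier):
        fv = FeatureVector(color_block=np.ones(10), texture_block=np.ones(3))
        with pytest.raises(ValueError):
            classify_region(small_classifier, fv)


class TestApplyOverride:
    def _ranked(self, small_classifier):
        rng = np.random.default_rng(5)
        dim = RecognitionConfig().n_features
        v = np.abs(rng.normal(size=dim))
        fv = FeatureVector(color_block=v[:64], texture_block=v[64:])
        return classify_region(small_classifier, fv)

    def test_override_moves_choice_to_rank_one(self, small_classifier):
        ranked = self._ranked(small_classifier)
        out = apply_override(ranked, "rice")
        assert out.top1 == "rice"
        assert out.entries[0][1] == 1.0
        assert sum(p for _, p in out.entries[1:]) == 0.0
        assert out.manual

    def test_override_of_top_class_idempotent(self, small_classifier):
        ranked = self._ranked(small_classifier)
        once = apply_override(ranked, ranked.top1)
        twice = apply_override(once, ranked.top1)
        assert once.entries == twice.entries

    def test_unknown_class_rejected(self, small_classifier):
        with pytest.raises(ValueError):
            apply_override(self._ranked(small_classifier), "pizza")
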