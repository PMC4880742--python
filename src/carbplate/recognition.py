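"""Food recognition: color + texture features and a margin classifier.

Each segmented region is described by a joint color histogram and a
local-binary-pattern (LBP) texture histogram, and classified into one of
nine broad food classes (pasta, potatoes, meat, breaded, rice, green
salad/vegetables, mashed potatoes, carrots, beans) by an RBF support
vector machine with Platt-style probability calibration.  The classifier
returns the full confidence-ordered candidate list so a user can correct
a wrong top-1 pick with a single choice from the list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.feature import local_binary_pattern
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .errors import TooSmallRegionError
from .scene_synth import FOOD_CLASSES
from .segmentation import SegmentationMask


@dataclass
class RecognitionConfig:
    color_bins: int = 4                  # per channel -> bins^3 joint histogram
    color_space: str = "rgb"
    lbp_radius: int = 1
    lbp_points: int = 8
    min_region_px: int = 50
    svm_C: float = 10.0
    svm_gamma: str | float = "scale"
    rng_seed: int = 0

    @property
    def n_features(self) -> int:
        return self.color_bins ** 3 + self.lbp_points + 2


@dataclass
class FeatureVector:
    """Concatenated color and texture descriptors of one region."""

    color_block: np.ndarray
    texture_block: np.ndarray
    region_id: int = 0

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.color_block, self.texture_block])


@dataclass
class RankedLabels:
    """All nine classes ordered by classifier confidence (descending).

    Confidences are a probability vector: nonnegative, summing to 1.
    """

    entries: list[tuple[str, float]]
    manual: bool = False

    @property
    def top1(self) -> str:
        return self.entries[0][0]

    def confidence_of(self, cls: str) -> float:
        for c, p in self.entries:
            if c == cls:
                return p
        raise KeyError(cls)


def extract_features(image: np.ndarray, mask: SegmentationMask, region_id: int,
                     config: RecognitionConfig | None = None) -> FeatureVector:
    """Color + LBP histograms from the pixels of one region.

    The color histogram is a joint per-channel binning of the raw region
    pixels; the texture histogram is a uniform-LBP histogram over the
    region eroded by one pixel (so every LBP neighborhood lies fully
    inside the region, making the descriptor exactly translation
    invariant).  Both blocks are L1-normalized.
    """
    config = config or RecognitionConfig()
    region = mask.region_mask(region_id)
    npx = int(region.sum())
    if npx < config.min_region_px:
        raise TooSmallRegionError(
            f"region {region_id} has {npx} px < {config.min_region_px}")
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(np.asarray(img, dtype=float) * 255, 0, 255).astype(np.uint8)

    vals = img[region].astype(int)
    b = config.color_bins
    idx = (vals * b) // 256
    flat = (idx[:, 0] * b + idx[:, 1]) * b + idx[:, 2]
    color_hist = np.bincount(flat, minlength=b ** 3).astype(float)
    color_hist /= color_hist.sum()

    gray = (rgb2gray(img) * 255.0 + 0.5).astype(np.uint8)
    lbp = local_binary_pattern(gray, config.lbp_points, config.lbp_radius,
                               method="uniform")
    inner = ndi.binary_erosion(region, iterations=max(config.lbp_radius, 1))
    codes = lbp[inner if inner.any() else region].astype(int)
    tex_hist = np.bincount(codes, minlength=config.lbp_points + 2).astype(float)
    tex_hist /= max(tex_hist.sum(), 1.0)
    return FeatureVector(color_block=color_hist, texture_block=tex_hist,
                         region_id=region_id)


class FoodClassifier:
    """Multi-class max-margin food classifier with calibrated confidences.

    One-vs-one RBF SVM (Platt-calibrated probabilities).  Training is
    made order-invariant by sorting samples canonically before fitting.
    """

    def __init__(self, config: RecognitionConfig | None = None):
        self.config = config or RecognitionConfig()
        self._pipe = None
        self.classes_: list[str] = []

    def fit(self, X: np.ndarray, y: list[str]) -> "FoodClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training needs at least two classes")
        if counts.min() < 2:
            raise ValueError("training needs at least two samples per class")
        unknown = set(classes) - set(FOOD_CLASSES)
        if unknown:
            raise ValueError(f"unknown food classes: {sorted(unknown)}")
        codes = np.array([FOOD_CLASSES.index(c) for c in y])
        order = np.lexsort(np.vstack([X.T[::-1], codes]))
        X, y = X[order], y[order]
        # no per-dimension standardization: the features are L1-normalized
        # histograms, and standardizing near-constant bins makes the RBF
        # kernel saturate on slightly out-of-distribution regions
        svc = SVC(kernel="rbf", C=self.config.svm_C, gamma=self.config.svm_gamma,
                  random_state=self.config.rng_seed)
        self._pipe = CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)
        self._pipe.fit(X, y)
        self.classes_ = list(self._pipe.classes_)
        return self

    def predict_proba_all(self, fv: FeatureVector) -> np.ndarray:
        """Probabilities over the full nine-class list (zeros if untrained)."""
        if self._pipe is None:
            raise ValueError("classifier is not fitted")
        x = np.atleast_2d(fv.values)
        if x.shape[1] != self.config.n_features:
            raise ValueError(
                f"feature dimension {x.shape[1]} != configured {self.config.n_features}")
        p = self._pipe.predict_proba(x)[0]
        out = np.zeros(len(FOOD_CLASSES))
        for cls, pi in zip(self.classes_, p):
            out[FOOD_CLASSES.index(cls)] = pi
        return out


def train_classifier(features: list[FeatureVector], labels: list[str],
                     config: RecognitionConfig | None = None) -> FoodClassifier:
    X = np.stack([f.values for f in features])
    clf = FoodClassifier(config)
    return clf.fit(X, labels)


def classify_region(clf: FoodClassifier, fv: FeatureVector) -> RankedLabels:
    """Confidence-ordered candidate list over all nine classes.

    Ties in confidence break by class-list order, so the output is
    deterministic.
    """
    p = clf.predict_proba_all(fv)
    order = sorted(range(len(FOOD_CLASSES)), key=lambda i: (-p[i], i))
    return RankedLabels(entries=[(FOOD_CLASSES[i], float(p[i])) for i in order])


def apply_override(ranked: RankedLabels, chosen_class: str) -> RankedLabels:
    """Manual correction: the chosen class becomes rank 1 with confidence 1."""
    if chosen_class not in FOOD_CLASSES:
        raise ValueError(f"{chosen_class!r} is not one of the nine food classes")
    rest = [c for c, _ in ranked.entries if c != chosen_class]
    return RankedLabels(entries=[(chosen_class, 1.0)] + [(c, 0.0) for c in rest],
                        manual=True)


def save_classifier(clf: FoodClassifier, path) -> None:
    """Persist a fitted classifier (versioned joblib file)."""
    import joblib

    joblib.dump({"format_version": 1, "config": clf.config,
                 "pipe": clf._pipe, "classes": clf.classes_}, path)


def load_classifier(path) -> FoodClassifier:
    import joblib

    blob = joblib.load(path)
    if blob.get("format_version") != 1:
        raise ValueError(f"unsupported classifier file version: {blob.get('format_version')}")
    clf = FoodClassifier(blob["config"])
    clf._pipe = blob["pipe"]
    clf.classes_ = blob["classes"]
    return clf


def select_hyperparameters(X: np.ndarray, y: list[str],
                           C_grid=(1.0, 10.0, 100.0),
                           gamma_grid=("scale", 0.1, 1.0),
                           cv: int = 3, seed: int = 0) -> tuple[float, str | float]:
    """Small-grid CV selection of (C, gamma) for the RBF SVM."""
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    best = None
    for C in C_grid:
        for g in gamma_grid:
            svc = SVC(kernel="rbf", C=C, gamma=g, random_state=seed)
            skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
            score = cross_val_score(svc, X, np.asarray(y, dtype=object), cv=skf).mean()
            if best is None or score > best[0]:
                best = (score, C, g)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Synthetic training data
# ---------------------------------------------------------------------------

def render_labeled_regions(seed: int, n_per_class: int,
                           config: RecognitionConfig | None = None,
                           noise_sigma: float = 2.0):
    """Render single-item scenes and extract (features, labels) pairs.

    Uses the near-vertical view and the renderer's ground-truth region
    masks, so the pairs isolate the recognition stage from segmentation.
    """
    from .scene_synth import single_item_scene, render_view
    from .geometry import default_camera

    config = config or RecognitionConfig()
    rng = np.random.default_rng(seed)
    cam = default_camera(0.0)
    feats, labels = [], []
    for cls in FOOD_CLASSES:
        made = 0
        while made < n_per_class:
            spec = single_item_scene(rng, cls, noise_sigma=noise_sigma)
            img, gt = render_view(spec, cam)
            areas = np.bincount(gt.label_map.ravel())[1:]
            mask = SegmentationMask(label_map=gt.label_map, region_areas_px=areas)
            feats.append(extract_features(img, mask, 1, config))
            labels.append(cls)
            made += 1
    return feats, labels
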