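import numpy as np
import pytest

from carbplate.benchmarks import train_default_classifier
from carbplate.scene_synth import make_stereo_scene, random_scene_spec


def per_item_ious(mask, gt_label):
    """Best IoU of any predicted region against each true item."""
    ious = []
    for k in range(1, int(gt_label.max()) + 1):
        g = gt_label == k
        best = 0.0
        for r in range(1, mask.n_regions + 1):
            m = mask.label_map == r
            union = np.logical_or(g, m).sum()
            if union:
                best = max(best, float(np.logical_and(g, m).sum() / union))
        ious.append(best)
    return ious


@pytest.fixture(scope="session")
def three_item_scene():
    """A fixed three-item meal scene rendered at both protocol tilts."""
    rng = np.random.default_rng(7)
    spec = random_scene_spec(rng, n_items=3)
    return make_stereo_scene(spec)


@pytest.fixture(scope="session")
def one_item_scene():
    rng = np.random.default_rng(3)
    spec = random_scene_spec(rng, n_items=1)
    return make_stereo_scene(spec)


@pytest.fixture(scope="session")
def small_classifier():
    """A food classifier trained on a reduced synthetic set (unit tests)."""
    return train_default_classifier(seed=42, n_per_class=8)
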