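import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cls_seg.roi import crop_and_resize
from cls_seg.synth import (SceneSpec, generate_scene, rasterize_lesions,
                           sample_scene_specs)

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: 4:3 canvas used for desk-scale training scenes
SMALL_CANVAS = (512, 384)


def make_crop_pairs(n, seed, side=128, canvas=SMALL_CANVAS, **overrides):
    """(cervix crop, lesion mask) pairs at the canonical square side."""
    pairs = []
    for spec in sample_scene_specs(n, seed, canvas=canvas, **overrides):
        ann = generate_scene(spec)
        crop, box = crop_and_resize(ann.image, ann.cervix_box, side)
        mask = rasterize_lesions(ann)
        mask3 = (mask * 255).astype(np.uint8)[:, :, None].repeat(3, axis=2)
        mcrop, _ = crop_and_resize(mask3, box, side)
        pairs.append((crop, mcrop[:, :, 0] > 127))
    return pairs


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic desk-scale scene with two lesions."""
    return generate_scene(SceneSpec(canvas_width=512, canvas_height=384,
                                    seed=7, n_lesions=2))


@pytest.fixture(scope="session")
def mixed_label_scene():
    """A scene with exactly one LSIL and one HSIL+ blob."""
    return generate_scene(SceneSpec(canvas_width=512, canvas_height=384,
                                    seed=21, n_lesions=2,
                                    lesion_labels=("LSIL", "HSIL+")))
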