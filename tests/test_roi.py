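"""Box geometry, IoU/AP evaluation, crop-resize and detector plumbing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cls_seg.roi import (Box, CervixDetector, Detection, NoWeightsError,
                         average_precision, crop_and_resize, iou)

boxes = st.builds(Box,
                  x=st.integers(-20, 40), y=st.integers(-20, 40),
                  w=st.integers(1, 50), h=st.integers(1, 50))


class TestBox:
    def test_positive_size_required(self):
        with pytest.raises(ValueError):
            Box(0, 0, 0, 5)

    def test_clip_is_identity_for_contained_box(self):
        b = Box(10, 20, 30, 40)
        assert b.clip(100, 100) == b

    def test_clip_bounds(self):
        b = Box(-5, -5, 200, 200).clip(100, 80)
        assert (b.x, b.y, b.w, b.h) == (0, 0, 100, 80)

    def test_json_round_trip(self, tmp_path):
        b = Box(3, 4, 5, 6)
        b.to_json(tmp_path / "b.json")
        assert Box.from_json(tmp_path / "b.json") == b


class TestIoU:
    def test_identical_boxes(self):
        assert iou(Box(2, 3, 10, 12), Box(2, 3, 10, 12)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 10, 10), Box(20, 20, 5, 5)) == 0.0

    def test_half_overlap_matches_pixel_counting(self):
        a, b = Box(0, 0, 10, 10), Box(5, 0, 10, 10)
        # brute-force: count integer pixels in each half-open box
        grid = np.zeros((20, 30, 2), bool)
        for box, k in ((a, 0), (b, 1)):
            grid[box.y:box.y + box.h, box.x:box.x + box.w, k] = True
        inter = (grid[:, :, 0] & grid[:, :, 1]).sum()
        union = (grid[:, :, 0] | grid[:, :, 1]).sum()
        assert iou(a, b) == pytest.approx(inter / union)
        assert iou(a, b) == pytest.approx(1 / 3)

    @given(a=boxes, b=boxes)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b, a))


class TestAveragePrecision:
    def test_perfect_detector(self):
        dets = [(Detection(Box(0, 0, 10, 10), 0.9), "a"),
                (Detection(Box(5, 5, 10, 10), 0.8), "b")]
        truths = [(Box(0, 0, 10, 10), "a"), (Box(5, 5, 10, 10), "b")]
        assert average_precision(dets, truths, 0.8) == 1.0

    def test_no_matches(self):
        dets = [(Detection(Box(50, 50, 5, 5), 0.9), "a")]
        truths = [(Box(0, 0, 10, 10), "a")]
        assert average_precision(dets, truths, 0.5) == 0.0

    def test_three_detection_table_matches_hand_enumeration(self):
        # ranked TP/FP/TP over two truths:
        #   rank1 TP: P=1,   R=1/2
        #   rank2 FP: P=1/2, R=1/2
        #   rank3 TP: P=2/3, R=1
        # envelope -> AP = 1/2 * 1 + 1/2 * 2/3 = 5/6
        dets = [(Detection(Box(0, 0, 10, 10), 0.9), "a"),
                (Detection(Box(60, 60, 10, 10), 0.8), "a"),
                (Detection(Box(0, 0, 10, 10), 0.7), "b")]
        truths = [(Box(0, 0, 10, 10), "a"), (Box(0, 0, 10, 10), "b")]
        assert average_precision(dets, truths, 0.5) == pytest.approx(5 / 6)

    def test_invariant_to_monotone_score_rescaling(self):
        rng = np.random.default_rng(3)
        truths = [(Box(10, 10, 20, 20), i) for i in range(6)]
        dets = []
        for i in range(6):
            jitter = rng.integers(-8, 8, 2)
            dets.append((Detection(Box(10 + jitter[0], 10 + jitter[1], 20, 20),
                                   float(rng.uniform(0.1, 0.9))), i))
        base = average_precision(dets, truths, 0.5)
        squashed = [(Detection(d.box, 0.1 + 0.5 * d.objectness ** 3), i)
                    for d, i in dets]
        assert average_precision(squashed, truths, 0.5) == pytest.approx(base)

    def test_empty_truths_error(self):
        with pytest.raises(ValueError, match="empty"):
            average_precision([], [], 0.5)


class TestCropAndResize:
    def test_identity_when_box_equals_canonical_side(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (640, 640, 3)).astype(np.uint8)
        out, box = crop_and_resize(img, Box(0, 0, 640, 640), side=640)
        assert np.array_equal(out, img)
        assert box == Box(0, 0, 640, 640)

    def test_default_side_is_640(self):
        img = np.zeros((1300, 1300, 3), np.uint8)
        out, _ = crop_and_resize(img, Box(0, 0, 1280, 1280))
        assert out.shape == (640, 640, 3)

    def test_downscale_matches_per_pixel_bilinear_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        out, _ = crop_and_resize(img, Box(0, 0, 16, 16), side=8)
        # direct bilinear oracle with half-pixel sample centers
        oracle = np.zeros((8, 8, 3))
        for i in range(8):
            for j in range(8):
                sy = np.clip((i + 0.5) * 2 - 0.5, 0, 15)
                sx = np.clip((j + 0.5) * 2 - 0.5, 0, 15)
                y0, x0 = int(np.floor(sy)), int(np.floor(sx))
                y1, x1 = min(y0 + 1, 15), min(x0 + 1, 15)
                fy, fx = sy - y0, sx - x0
                oracle[i, j] = ((1 - fy) * (1 - fx) * img[y0, x0]
                                + (1 - fy) * fx * img[y0, x1]
                                + fy * (1 - fx) * img[y1, x0]
                                + fy * fx * img[y1, x1])
        assert np.abs(out.astype(float) - np.rint(oracle)).max() <= 1

    def test_box_outside_image_errors(self):
        img = np.zeros((50, 50, 3), np.uint8)
        with pytest.raises(ValueError, match="clip"):
            crop_and_resize(img, Box(40, 40, 20, 20), side=8)


class TestDetectorContracts:
    def test_untrained_detector_refuses(self):
        det = CervixDetector(input_side=64)
        with pytest.raises(NoWeightsError, match="weights"):
            det.detect(np.zeros((100, 100, 3), np.uint8))

    def test_fallback_full_image_box_below_floor(self):
        # an objectness floor of 1.0 can never be exceeded by a sigmoid
        det = CervixDetector(input_side=64, objectness_floor=1.0, seed=0)
        det.trained = True
        det.net.eval()
        img = np.zeros((120, 160, 3), np.uint8)
        assert det.detect(img) == Box(0, 0, 160, 120)

    def test_detection_inside_image_bounds(self, small_scene):
        det = CervixDetector(input_side=64, objectness_floor=0.0, seed=0)
        det.trained = True
        det.net.eval()
        box = det.detect(small_scene.image)
        h, w = small_scene.image.shape[:2]
        assert box.x >= 0 and box.y >= 0
        assert box.x + box.w <= w and box.y + box.h <= h

    def test_save_load_round_trip(self, tmp_path):
        det = CervixDetector(input_side=64, seed=0)
        det.trained = True
        det.net.eval()
        img = np.random.default_rng(0).integers(0, 255, (96, 128, 3)) \
            .astype(np.uint8)
        b1 = det.detect(img)
        path = tmp_path / "det.npz"
        det.save(path)
        det2 = CervixDetector.load(path)
        assert det2.detect(img) == b1
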