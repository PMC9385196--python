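"""Cervical-region extraction.

The cervix dominates a colposcopic post-acetic-acid frame but is
surrounded by instrument and vaginal-wall clutter, so the pipeline first
localizes it with a single-class detector and crops the region to a
canonical square before segmentation.

The detector is a two-stage region-proposal network in the Faster R-CNN
mold with two deliberate departures: region features are pooled with
ROI-Align (bilinear sampling at exact fractional coordinates, no
quantization), and the classification branch is removed entirely — with
one category ("cervix") only an objectness score and a box regressor
remain.

Coordinates are 0-based with half-open pixel intervals: a box (x, y, w, h)
covers columns [x, x+w) and rows [y, y+h).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Tensor

__all__ = ["Box", "Detection", "NoWeightsError", "iou", "average_precision",
           "crop_and_resize", "resize_image", "CervixDetector",
           "detect_cervix"]


class NoWeightsError(RuntimeError):
    """Raised when detection is attempted with an untrained detector."""


@dataclass
class Box:
    """Axis-aligned pixel box: top-left corner (x, y), width w, height h."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        self.x, self.y = int(self.x), int(self.y)
        self.w, self.h = int(self.w), int(self.h)
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w} h={self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h

    def clip(self, width: int, height: int) -> "Box":
        """Clip to image bounds [0, width) x [0, height)."""
        x0 = min(max(self.x, 0), width - 1)
        y0 = min(max(self.y, 0), height - 1)
        x1 = max(min(self.x + self.w, width), x0 + 1)
        y1 = max(min(self.y + self.h, height), y0 + 1)
        return Box(x0, y0, x1 - x0, y1 - y0)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.w, self.h)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as f:
            json.dump({"x": self.x, "y": self.y, "w": self.w, "h": self.h}, f)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "Box":
        with open(path) as f:
            d = json.load(f)
        return cls(d["x"], d["y"], d["w"], d["h"])


@dataclass
class Detection:
    box: Box
    objectness: float

    def __post_init__(self):
        if not np.isfinite(self.objectness):
            raise ValueError("objectness must be finite")


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes (half-open pixel intervals)."""
    iw = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
    ih = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def average_precision(detections, truths, iou_threshold: float) -> float:
    """AP at one IoU threshold with all-point PR interpolation.

    ``detections`` is a list of (Detection, image id) and ``truths`` a list
    of (Box, image id) with exactly one ground-truth box per image.
    Detections are ranked by descending objectness; each is a true positive
    if it overlaps its image's still-unmatched truth at or above the
    threshold. AP is the area under the precision envelope (precision at
    each recall point taken as the maximum at any recall >= it).
    """
    if not truths:
        raise ValueError("truth list is empty")
    truth_by_img = {img: box for box, img in truths}
    if len(truth_by_img) != len(truths):
        raise ValueError("expected exactly one ground-truth box per image")
    order = sorted(detections, key=lambda d: -d[0].objectness)
    matched: set = set()
    tp = np.zeros(len(order))
    for i, (det, img) in enumerate(order):
        gt = truth_by_img.get(img)
        if gt is not None and img not in matched \
                and iou(det.box, gt) >= iou_threshold:
            tp[i] = 1.0
            matched.add(img)
    if not len(order):
        return 0.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / len(truths)
    precision = cum_tp / np.arange(1, len(order) + 1)
    # precision envelope, then sum rectangle areas between recall steps
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def resize_image(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize of an H x W x C (or H x W) array; returns float32."""
    arr = np.asarray(image, dtype=np.float32)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    My = _nn.interp_matrix(arr.shape[0], out_h)
    Mx = _nn.interp_matrix(arr.shape[1], out_w)
    out = np.einsum("oh,hwc->owc", My, arr, optimize=True)
    out = np.einsum("pw,owc->opc", Mx, out, optimize=True)
    return out[:, :, 0] if squeeze else out


def crop_and_resize(image: np.ndarray, box: Box, side: int = 640):
    """Crop exactly ``box`` and bilinearly resize to ``side`` x ``side``.

    The aspect ratio is intentionally not preserved — the region is
    squashed uniformly onto a square canvas. Returns the canonical image
    (uint8) together with the box, which downstream code keeps for the
    inverse mapping back to original coordinates.
    """
    h, w = image.shape[:2]
    if box.x < 0 or box.y < 0 or box.x + box.w > w or box.y + box.h > h:
        raise ValueError(f"box {box.as_tuple()} not contained in image {w}x{h}; "
                         "clip it first")
    crop = np.asarray(image)[box.y: box.y + box.h, box.x: box.x + box.w]
    out = resize_image(crop, side, side)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), box


# ---------------------------------------------------------------------------
# detector

def _nms(boxes: np.ndarray, scores: np.ndarray, thresh: float) -> list[int]:
    """Greedy non-maximum suppression; boxes as (x0, y0, x1, y1)."""
    order = np.argsort(-scores)
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        xx0 = np.maximum(boxes[i, 0], boxes[rest, 0])
        yy0 = np.maximum(boxes[i, 1], boxes[rest, 1])
        xx1 = np.minimum(boxes[i, 2], boxes[rest, 2])
        yy1 = np.minimum(boxes[i, 3], boxes[rest, 3])
        inter = np.maximum(xx1 - xx0, 0) * np.maximum(yy1 - yy0, 0)
        area_i = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        area_r = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        ious = inter / np.maximum(area_i + area_r - inter, 1e-9)
        order = rest[ious <= thresh]
    return keep


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) corner-format boxes."""
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.maximum(x1 - x0, 0) * np.maximum(y1 - y0, 0)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / np.maximum(area_a[:, None] + area_b[None, :] - inter, 1e-9)


def _encode_deltas(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gx = gt[:, 0] + gw / 2
    gy = gt[:, 1] + gh / 2
    return np.stack([(gx - ax) / aw, (gy - ay) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def _decode_deltas(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    cx = ax + deltas[:, 0] * aw
    cy = ay + deltas[:, 1] * ah
    w = aw * np.exp(np.clip(deltas[:, 2], -4, 4))
    h = ah * np.exp(np.clip(deltas[:, 3], -4, 4))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


class _DetectorNet(_nn.Module):
    """Backbone + proposal head + ROI-Align refinement head."""

    def __init__(self, n_anchors: int, roi_size: int, rng: np.random.Generator):
        super().__init__()
        self.backbone = _nn.Sequential(
            _nn.ConvBNAct(3, 16, 3, stride=2, rng=rng),
            _nn.ConvBNAct(16, 32, 3, stride=2, rng=rng),
            _nn.ConvBNAct(32, 48, 3, stride=2, rng=rng),
            _nn.ConvBNAct(48, 64, 3, stride=2, rng=rng),
        )
        self.rpn_conv = _nn.ConvBNAct(64, 64, 3, rng=rng)
        self.rpn_obj = _nn.Conv2d(64, n_anchors, 1, rng=rng)
        self.rpn_box = _nn.Conv2d(64, 4 * n_anchors, 1, rng=rng)
        self.roi_size = roi_size
        feat = 64 * roi_size * roi_size
        self.head_fc = _nn.Linear(feat, 128, rng=rng)
        self.head_obj = _nn.Linear(128, 1, rng=rng)
        self.head_box = _nn.Linear(128, 4, rng=rng)

    def features(self, x: Tensor) -> Tensor:
        return self.backbone(x)

    def rpn(self, feat: Tensor) -> tuple[Tensor, Tensor]:
        h = self.rpn_conv(feat)
        return self.rpn_obj(h), self.rpn_box(h)

    def head(self, feat: Tensor, rois: np.ndarray, stride: int):
        pooled = _nn.roi_align(feat, rois, self.roi_size, 1.0 / stride)
        k = pooled.data.shape[0]
        flat = pooled.reshape(k, -1)
        h = _nn.relu(self.head_fc(flat))
        return self.head_obj(h), self.head_box(h)


class CervixDetector:
    """Single-class cervix-region detector.

    Operates on images resized to ``input_side`` x ``input_side``; boxes
    are mapped back to original pixel coordinates on output. The detector
    returns only the single highest-objectness box (one cervix per frame)
    and falls back to the full-image box when nothing clears the
    objectness floor.
    """

    STRIDE = 16

    def __init__(self, input_side: int = 128, scales=(0.3, 0.45, 0.6),
                 aspects=(1.0, 1.4), nms_iou: float = 0.5,
                 objectness_floor: float = 0.5, roi_size: int = 5,
                 seed: int = 0):
        self.input_side = input_side
        self.scales = tuple(scales)
        self.aspects = tuple(aspects)
        self.nms_iou = nms_iou
        self.objectness_floor = objectness_floor
        rng = np.random.default_rng(seed)
        self.net = _DetectorNet(len(scales) * len(aspects), roi_size, rng)
        self.anchors = self._make_anchors()
        self.trained = False

    def _make_anchors(self) -> np.ndarray:
        """Anchor boxes enumerated anchor-type-major, then cell row-major.

        This matches the memory layout of the proposal-head logits
        (channel = anchor type, then spatial cells), so logits reshape
        straight onto the anchor list with no permutation.
        """
        D, S = self.input_side, self.STRIDE
        g = D // S
        centers = (np.arange(g) + 0.5) * S
        sizes = [(D * s / np.sqrt(a), D * s * np.sqrt(a))
                 for s in self.scales for a in self.aspects]  # (w, h)
        anchors = []
        for w, h in sizes:
            for yc in centers:
                for xc in centers:
                    anchors.append([xc - w / 2, yc - h / 2,
                                    xc + w / 2, yc + h / 2])
        return np.asarray(anchors, dtype=np.float64)

    # -- data plumbing ----------------------------------------------------
    def _prep_image(self, image: np.ndarray) -> np.ndarray:
        D = self.input_side
        x = resize_image(image, D, D) / 255.0 - 0.5
        return x.transpose(2, 0, 1)[None].astype(np.float32)

    def _scale_box(self, box: Box, shape) -> np.ndarray:
        h, w = shape[:2]
        sx, sy = self.input_side / w, self.input_side / h
        return np.array([box.x * sx, box.y * sy,
                         (box.x + box.w) * sx, (box.y + box.h) * sy])

    # -- training ---------------------------------------------------------
    def fit(self, images, boxes, *, epochs: int = 12, batch_size: int = 8,
            lr: float = 2e-3, weight_decay: float = 1e-4, seed: int = 0,
            verbose: bool = False) -> list[float]:
        """Train on full scenes with one ground-truth cervix box each."""
        if len(images) != len(boxes) or not images:
            raise ValueError("need equally many images and boxes")
        rng = np.random.default_rng(seed)
        xs = np.concatenate([self._prep_image(im) for im in images])
        gts = np.stack([self._scale_box(b, im.shape)
                        for b, im in zip(boxes, images)])
        opt = _nn.Adam(self.net.parameters(), lr=lr, weight_decay=weight_decay)
        self.net.train()
        n = len(images)
        losses = []
        for ep in range(epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss = self._step(xs[idx], gts[idx], rng)
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += loss.item() * len(idx)
            losses.append(ep_loss / n)
            if verbose:
                print(f"epoch {ep + 1}/{epochs} loss {losses[-1]:.4f}")
        self.net.eval()
        self.trained = True
        return losses

    def _step(self, xb: np.ndarray, gtb: np.ndarray,
              rng: np.random.Generator) -> Tensor:
        net, A = self.net, self.anchors
        feat = net.features(Tensor(xb))
        obj, box = net.rpn(feat)
        N = xb.shape[0]
        nA = len(self.scales) * len(self.aspects)
        g = self.input_side // self.STRIDE
        gg = g * g
        # anchor assignment: positive at IoU >= 0.5 (or the best anchor),
        # negatives sampled from IoU < 0.3 at ~3:1
        obj_t = np.zeros((N, A.shape[0]), dtype=np.float32)
        obj_w = np.zeros((N, A.shape[0]), dtype=np.float32)
        pos_list = []
        for i in range(N):
            ious = _iou_matrix(A, gtb[i:i + 1])[:, 0]
            pos = np.where(ious >= 0.5)[0]
            if pos.size == 0:
                pos = np.array([int(np.argmax(ious))])
            neg = np.where(ious < 0.3)[0]
            neg = rng.choice(neg, size=min(len(neg), 3 * max(len(pos), 4)),
                             replace=False)
            obj_t[i, pos] = 1.0
            obj_w[i, pos] = 1.0
            obj_w[i, neg] = 1.0
            pos_list.append(pos)
        # logits reshape directly onto the anchor enumeration (see
        # _make_anchors); objectness BCE over the sampled anchors
        loss = _nn.bce_with_logits(obj.reshape(N, -1), obj_t, obj_w)
        # box regression on positive anchors
        flat = box.reshape(-1)
        reg_terms = []
        for i in range(N):
            pos = pos_list[i]
            tgt = _encode_deltas(A[pos], np.repeat(gtb[i:i + 1], len(pos), 0))
            aidx, cell = pos // gg, pos % gg
            rows = []
            for k in range(4):
                sel = np.ravel_multi_index(
                    (np.full_like(pos, i), aidx, np.full_like(pos, k), cell),
                    (N, nA, 4, gg))
                rows.append(gather(flat, sel))
            pred = stack_cols(rows)
            reg_terms.append(_nn.smooth_l1(pred, tgt.astype(np.float32), beta=0.2))
        for t in reg_terms:
            loss = loss + t * (1.0 / max(len(reg_terms), 1))
        # second stage: refine proposals (decoded positive anchors + gt jitter)
        rois = []
        roi_tgt = []
        roi_obj = []
        with_det = box.data.reshape(N, nA, 4, gg)
        for i in range(N):
            pos = pos_list[i][:4]
            aidx, cell = pos // gg, pos % gg
            d = with_det[i, aidx, :, cell]
            prop = _decode_deltas(A[pos], d)
            jit = gtb[i] + rng.normal(0, 0.04 * self.input_side, 4)
            cand = np.vstack([prop, jit[None, :], gtb[i][None, :]])
            cand = np.clip(cand, 0, self.input_side)
            ok = (cand[:, 2] - cand[:, 0] > 4) & (cand[:, 3] - cand[:, 1] > 4)
            cand = cand[ok]
            ious = _iou_matrix(cand, gtb[i:i + 1])[:, 0]
            for c, ov in zip(cand, ious):
                rois.append([i, *c])
                roi_obj.append(1.0 if ov >= 0.5 else 0.0)
                roi_tgt.append(_encode_deltas(c[None], gtb[i:i + 1])[0])
            # a background roi
            bg = np.array([rng.uniform(0, 0.3), rng.uniform(0, 0.3), 0, 0])
            bg[2] = bg[0] + rng.uniform(0.15, 0.3)
            bg[3] = bg[1] + rng.uniform(0.15, 0.3)
            rois.append([i, *(bg * self.input_side)])
            roi_obj.append(0.0)
            roi_tgt.append(np.zeros(4))
        rois = np.asarray(rois)
        roi_obj = np.asarray(roi_obj, dtype=np.float32)
        roi_tgt = np.asarray(roi_tgt, dtype=np.float32)
        h_obj, h_box = net.head(feat, rois, self.STRIDE)
        loss = loss + _nn.bce_with_logits(h_obj.reshape(-1), roi_obj)
        posm = roi_obj > 0.5
        if posm.any():
            sel = np.where(posm)[0]
            pred_rows = take_rows(h_box, sel)
            loss = loss + _nn.smooth_l1(pred_rows, roi_tgt[sel], beta=0.2)
        return loss

    # -- inference --------------------------------------------------------
    def detect(self, image: np.ndarray) -> Box:
        """Detect the cervix box in original image coordinates."""
        if not self.trained:
            raise NoWeightsError(
                "detector has no trained weights; call fit() or load()")
        h, w = image.shape[:2]
        D = self.input_side
        self.net.eval()
        x = Tensor(self._prep_image(image))
        feat = self.net.features(x)
        obj, boxd = self.net.rpn(feat)
        nA = len(self.scales) * len(self.aspects)
        g = D // self.STRIDE
        # flatten to the anchor enumeration (anchor-type-major, cell-minor)
        scores = 1 / (1 + np.exp(-obj.data.reshape(-1)))
        deltas = boxd.data.reshape(nA, 4, g * g).transpose(0, 2, 1).reshape(-1, 4)
        top = np.argsort(-scores)[:20]
        cand = _decode_deltas(self.anchors[top], deltas[top])
        cand = np.clip(cand, 0, D)
        ok = (cand[:, 2] - cand[:, 0] > 2) & (cand[:, 3] - cand[:, 1] > 2)
        cand, cscores = cand[ok], scores[top][ok]
        box_full = Box(0, 0, w, h)
        if not len(cand):
            return box_full
        keep = _nms(cand, cscores, self.nms_iou)[:5]
        rois = np.concatenate([np.zeros((len(keep), 1)), cand[keep]], axis=1)
        h_obj, h_box = self.net.head(feat, rois, self.STRIDE)
        final_scores = 1 / (1 + np.exp(-h_obj.data.reshape(-1)))
        refined = _decode_deltas(cand[keep], h_box.data)
        refined = np.clip(refined, 0, D)
        best = int(np.argmax(final_scores))
        if final_scores[best] <= self.objectness_floor:
            return box_full
        bx = refined[best]
        sx, sy = w / D, h / D
        x0 = bx[0] * sx
        y0 = bx[1] * sy
        bw = max((bx[2] - bx[0]) * sx, 1)
        bh = max((bx[3] - bx[1]) * sy, 1)
        return Box(round(x0), round(y0), round(bw), round(bh)).clip(w, h)

    detect_cervix = detect

    # -- persistence ------------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        meta = dict(input_side=self.input_side, scales=self.scales,
                    aspects=self.aspects, nms_iou=self.nms_iou,
                    objectness_floor=self.objectness_floor,
                    roi_size=self.net.roi_size)
        np.savez(path, __meta__=json.dumps(meta),
                 **self.net.state_dict())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CervixDetector":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        det = cls(input_side=int(meta["input_side"]), scales=meta["scales"],
                  aspects=meta["aspects"], nms_iou=meta["nms_iou"],
                  objectness_floor=meta["objectness_floor"],
                  roi_size=int(meta["roi_size"]))
        det.net.load_state_dict({k: data[k] for k in data.files
                                 if k != "__meta__"})
        det.net.eval()
        det.trained = True
        return det


def detect_cervix(image: np.ndarray, detector: CervixDetector) -> Box:
    """Module-level convenience wrapper around ``detector.detect``."""
    return detector.detect(image)


# small autodiff gather helpers used by the training step ------------------

def gather(flat: Tensor, idx: np.ndarray) -> Tensor:
    data = flat.data[idx]

    def backward(g, flat=flat, idx=idx):
        gx = np.zeros_like(flat.data)
        np.add.at(gx, idx, g)
        flat._accumulate(gx)

    return Tensor._result(data, (flat,), backward)


def stack_cols(cols: list[Tensor]) -> Tensor:
    data = np.stack([c.data for c in cols], axis=1)

    def backward(g, cols=cols):
        for k, c in enumerate(cols):
            if c.requires_grad:
                c._accumulate(g[:, k])

    return Tensor._result(data, tuple(cols), backward)


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    data = x.data[idx]

    def backward(g, x=x, idx=idx):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        x._accumulate(gx)

    return Tensor._result(data, (x,), backward)
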