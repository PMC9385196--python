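"""Synthetic colposcopy-like scenes with ground-truth annotations.

The clinical dataset this pipeline targets is private, so every
downstream stage is exercised on generated scenes that mimic its
geometry: a 2,656 x 1,992 (4:3) canvas holding one bright pinkish cervix
(an ellipse), zero or more acetowhite-like lesion blobs strictly inside
the cervix, instrument/vaginal-wall distractors outside the cervix box,
and small specular-reflection speckles (high brightness, low color
saturation). Lesions carry an LSIL or HSIL+ label; the two differ only in
label and whitening contrast — no biological claim is attached.

A configurable fraction of scenes additionally receives a whitish
"metaplastic epithelium" confuser blob inside the cervix that is *not*
annotated as lesion, emulating the benign acetowhite mimic that makes
fine contour labeling hard in real images.

Everything is a pure function of the spec (including its seed): the same
spec yields byte-identical images and identical annotations.

Polygon rasterization uses the even-odd (parity) fill rule evaluated at
pixel centers: pixel (row r, column c) is foreground iff the point
(c + 0.5, r + 0.5) lies inside the polygon.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .imgio import load_image, save_image
from .roi import Box

__all__ = ["SceneSpec", "AnnotatedImage", "LabelMeError", "generate_scene",
           "rasterize_lesions", "polygon_mask", "write_labelme",
           "read_labelme", "sample_scene_specs", "LABELS"]

LABELS = ("LSIL", "HSIL+")

# whitening strength of lesion blobs by label; HSIL+ reacts more strongly
_CONTRAST = {"LSIL": 0.45, "HSIL+": 0.68}
_CONFUSER_CONTRAST = 0.32


class LabelMeError(ValueError):
    """Raised when an annotation file cannot be parsed."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene; geometry scales with the canvas.

    ``None`` for the cervix ellipse or lesion parameters means "sample a
    realistic value from the scene's own RNG", which keeps generation a
    deterministic function of (spec, seed).
    """

    canvas_width: int = 2656
    canvas_height: int = 1992
    cervix_center: tuple[float, float] | None = None
    cervix_axes: tuple[float, float] | None = None
    cervix_rotation: float | None = None  # degrees
    n_lesions: int = 2
    lesion_labels: tuple[str, ...] | None = None
    lesion_scale: float | None = None  # base blob radius, pixels
    n_distractors: int = 3
    n_speckles: int = 12
    noise_sd: float = 3.0
    confuser_prob: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.canvas_width <= 0:
            raise ValueError("canvas_width must be positive")
        if self.canvas_height <= 0:
            raise ValueError("canvas_height must be positive")
        for name in ("n_lesions", "n_distractors", "n_speckles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cervix_axes is not None and min(self.cervix_axes) <= 0:
            raise ValueError("cervix_axes must be positive")
        if self.lesion_scale is not None and self.lesion_scale <= 0:
            raise ValueError("lesion_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.confuser_prob <= 1.0:
            raise ValueError("confuser_prob must be in [0, 1]")
        if self.lesion_labels is not None:
            if len(self.lesion_labels) != self.n_lesions:
                raise ValueError("lesion_labels length must equal n_lesions")
            bad = set(self.lesion_labels) - set(LABELS)
            if bad:
                raise ValueError(f"lesion_labels must be in {LABELS}, got {bad}")


@dataclass
class AnnotatedImage:
    """One dataset record: RGB image, cervix box, labeled lesion polygons."""

    image: np.ndarray  # H x W x 3 uint8
    cervix_box: Box
    lesions: list[tuple[np.ndarray, str]] = field(default_factory=list)
    id: str = ""


def sample_scene_specs(n: int, seed: int, canvas: tuple[int, int] = (2656, 1992),
                       **overrides) -> list[SceneSpec]:
    """Draw ``n`` scene specs with per-scene seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        s = SceneSpec(canvas_width=canvas[0], canvas_height=canvas[1],
                      seed=int(rng.integers(2 ** 31)),
                      n_lesions=int(rng.integers(1, 4)))
        specs.append(replace(s, **overrides) if overrides else s)
    return specs


# ---------------------------------------------------------------------------
# rendering helpers

def _smooth_field(rng: np.random.Generator, h: int, w: int,
                  coarse: int = 7) -> np.ndarray:
    """Low-frequency noise in [-1, 1] via bilinear upsampling of a coarse grid."""
    from ._nn import interp_matrix
    grid = rng.uniform(-1, 1, (coarse, coarse)).astype(np.float32)
    return interp_matrix(coarse, h) @ grid @ interp_matrix(coarse, w).T


def _blob_polygon(rng: np.random.Generator, cx: float, cy: float, r0: float,
                  n_vertices: int = 28) -> np.ndarray:
    """Irregular closed blob: elliptical harmonics on top of a base circle."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for m in range(2, 6):
        amp = rng.uniform(0, 0.35 / (m - 1) / 2)
        r += amp * np.sin(m * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.5, 1.35) * r0
    sx = rng.uniform(0.8, 1.25)
    return np.stack([cx + sx * r * np.cos(theta),
                     cy + r / sx * np.sin(theta)], axis=1)


def polygon_mask(poly: np.ndarray, height: int, width: int) -> np.ndarray:
    """Rasterize one polygon under the even-odd rule at pixel centers."""
    poly = np.asarray(poly, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError(
            f"polygon needs >= 3 (x, y) vertices, got shape {poly.shape}")
    r0 = max(int(np.floor(poly[:, 1].min() - 1)), 0)
    r1 = min(int(np.ceil(poly[:, 1].max() + 1)), height - 1)
    c0 = max(int(np.floor(poly[:, 0].min() - 1)), 0)
    c1 = min(int(np.ceil(poly[:, 0].max() + 1)), width - 1)
    mask = np.zeros((height, width), dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    py = (np.arange(r0, r1 + 1) + 0.5)[:, None]
    px = (np.arange(c0, c1 + 1) + 0.5)[None, :]
    inside = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    x1s, y1s = poly[:, 0], poly[:, 1]
    x2s, y2s = np.roll(x1s, -1), np.roll(y1s, -1)
    for x1, y1, x2, y2 in zip(x1s, y1s, x2s, y2s):
        if y1 == y2:
            continue
        crosses = (y1 > py) != (y2 > py)
        xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xi)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    return mask


def rasterize_lesions(ann: AnnotatedImage, label_filter: str | None = None
                      ) -> np.ndarray:
    """Union mask of the lesion polygons (optionally one label only).

    A pixel is foreground iff it lies inside at least one polygon passing
    the filter; each polygon is filled with the even-odd rule documented
    in the module docstring.
    """
    h, w = ann.image.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    for poly, label in ann.lesions:
        if label_filter is not None and label != label_filter:
            continue
        mask |= polygon_mask(poly, h, w)
    return mask


def _soft_mask(mask: np.ndarray, factor: int = 4) -> np.ndarray:
    """Feather a binary mask by down/up bilinear resampling."""
    from .roi import resize_image
    h, w = mask.shape
    small = resize_image(mask.astype(np.float32),
                         max(h // factor, 1), max(w // factor, 1))
    return np.clip(resize_image(small, h, w), 0.0, 1.0)


def generate_scene(spec: SceneSpec) -> AnnotatedImage:
    """Render one annotated scene; deterministic in (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    W, H = spec.canvas_width, spec.canvas_height
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float32)

    # --- background: dark vaginal-wall red with slow shading
    img = np.empty((H, W, 3), dtype=np.float32)
    shade = _smooth_field(rng, H, W) * 12
    for k, base in enumerate((128, 72, 78)):
        img[:, :, k] = base + shade

    # --- cervix ellipse
    if spec.cervix_center is None:
        cx = W * rng.uniform(0.44, 0.56)
        cy = H * rng.uniform(0.44, 0.56)
    else:
        cx, cy = spec.cervix_center
    if spec.cervix_axes is None:
        a = W * rng.uniform(0.14, 0.21)
        b = H * rng.uniform(0.19, 0.28)
    else:
        a, b = spec.cervix_axes
    rot = np.deg2rad(rng.uniform(-20, 20) if spec.cervix_rotation is None
                     else spec.cervix_rotation)
    ct, st = np.cos(rot), np.sin(rot)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    d2 = (u / a) ** 2 + (v / b) ** 2
    cervix = d2 <= 1.0
    # brighter, pinker tissue with gentle radial falloff and texture
    tex = _smooth_field(rng, H, W, coarse=11) * 8
    fall = 1.0 - 0.25 * np.clip(d2, 0, 1)
    for k, base in enumerate((214, 158, 162)):
        img[:, :, k][cervix] = (base * fall + tex)[cervix]
    # cervical os: small dark ellipse at the center
    os_mask = d2 <= rng.uniform(0.004, 0.012)
    for k, base in enumerate((120, 52, 62)):
        img[:, :, k][os_mask] = base

    # cervix box = bounding box of the rotated ellipse, clipped to canvas
    ex = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
    bx0, by0 = max(int(np.floor(cx - ex)), 0), max(int(np.floor(cy - ey)), 0)
    bx1, by1 = min(int(np.ceil(cx + ex)), W), min(int(np.ceil(cy + ey)), H)
    box = Box(bx0, by0, bx1 - bx0, by1 - by0)

    # --- lesion blobs strictly inside the ellipse (hence inside the box)
    labels = (list(spec.lesion_labels) if spec.lesion_labels is not None
              else [LABELS[int(rng.integers(2))] for _ in range(spec.n_lesions)])
    lesions: list[tuple[np.ndarray, str]] = []
    whiten = np.zeros((H, W), dtype=np.float32)
    for label in labels:
        rho = rng.uniform(0.0, 0.45)
        phi = rng.uniform(0, 2 * np.pi)
        r0 = (spec.lesion_scale if spec.lesion_scale is not None
              else rng.uniform(0.18, 0.38) * min(a, b))
        # keep the blob (max radius 1.35 * 1.25 * r0) inside the ellipse
        margin = 0.93 - rho
        r0 = min(r0, margin * min(a, b) / 1.7)
        bu = a * rho * np.cos(phi)
        bv = b * rho * np.sin(phi)
        poly_uv = _blob_polygon(rng, bu, bv, r0)
        # rotate back to image coordinates
        px = cx + poly_uv[:, 0] * ct - poly_uv[:, 1] * st
        py = cy + poly_uv[:, 0] * st + poly_uv[:, 1] * ct
        poly = np.stack([px, py], axis=1)
        lesions.append((poly, label))
        soft = _soft_mask(polygon_mask(poly, H, W))
        whiten = np.maximum(whiten, soft * _CONTRAST[label])

    # --- optional benign acetowhite confuser (not annotated)
    if rng.uniform() < spec.confuser_prob:
        rho, phi = rng.uniform(0.2, 0.5), rng.uniform(0, 2 * np.pi)
        r0 = rng.uniform(0.12, 0.22) * min(a, b)
        poly_uv = _blob_polygon(rng, a * rho * np.cos(phi),
                                b * rho * np.sin(phi), r0)
        px = cx + poly_uv[:, 0] * ct - poly_uv[:, 1] * st
        py = cy + poly_uv[:, 0] * st + poly_uv[:, 1] * ct
        conf = _soft_mask(polygon_mask(np.stack([px, py], 1), H, W))
        whiten = np.maximum(whiten, conf * _CONFUSER_CONTRAST)

    wtex = 1.0 - 0.2 * np.abs(_smooth_field(rng, H, W, coarse=13))
    whiten *= wtex
    white = np.array([240, 232, 228], dtype=np.float32)
    img += whiten[:, :, None] * (white - img)

    # --- distractors strictly outside the cervix box
    for _ in range(spec.n_distractors):
        regions = []
        if box.x > 0.06 * W:
            regions.append((0, 0, box.x, H))
        if W - (box.x + box.w) > 0.06 * W:
            regions.append((box.x + box.w, 0, W - box.x - box.w, H))
        if box.y > 0.06 * H:
            regions.append((0, 0, W, box.y))
        if H - (box.y + box.h) > 0.06 * H:
            regions.append((0, box.y + box.h, W, H - box.y - box.h))
        if not regions:
            break
        rx, ry, rw, rh = regions[int(rng.integers(len(regions)))]
        dw = rng.uniform(0.3, 0.9) * rw
        dh = rng.uniform(0.2, 0.6) * rh
        dx = rng.uniform(rx, rx + rw - dw)
        dy = rng.uniform(ry, ry + rh - dh)
        sel = (xx >= dx) & (xx < dx + dw) & (yy >= dy) & (yy < dy + dh)
        if rng.uniform() < 0.5:  # metallic speculum blade
            color = np.array([185, 188, 192], dtype=np.float32)
        else:  # vaginal-wall fold
            color = np.array([150, 84, 92], dtype=np.float32)
        img[sel] = 0.25 * img[sel] + 0.75 * color

    # --- specular speckles: near-white, low saturation, small
    for _ in range(spec.n_speckles):
        sx_ = cx + rng.uniform(-0.9, 0.9) * a
        sy_ = cy + rng.uniform(-0.9, 0.9) * b
        r = rng.uniform(0.0012, 0.004) * W
        sel = (xx - sx_) ** 2 + (yy - sy_) ** 2 <= r * r
        img[sel] = np.array([252, 250, 249], dtype=np.float32)

    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, img.shape).astype(np.float32)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return AnnotatedImage(image=image, cervix_box=box, lesions=lesions,
                          id=f"scene_{spec.seed:010d}")


# ---------------------------------------------------------------------------
# LabelMe-dialect annotation files

_REQUIRED_KEYS = ("imagePath", "imageHeight", "imageWidth", "shapes")


def write_labelme(ann: AnnotatedImage, path: str | os.PathLike) -> None:
    """Write the annotation JSON (and the image PNG next to it).

    The JSON follows the LabelMe dialect: top-level ``imagePath``,
    ``imageHeight``, ``imageWidth`` and a ``shapes`` list whose entries
    carry ``label``, ``points`` and ``shape_type`` — ``polygon`` for each
    lesion, ``rectangle`` (two corner points) for the cervix box.
    """
    path = os.fspath(path)
    h, w = ann.image.shape[:2]
    image_name = (ann.id or os.path.splitext(os.path.basename(path))[0]) + ".png"
    shapes = [{
        "label": "cervix",
        "points": [[ann.cervix_box.x, ann.cervix_box.y],
                   [ann.cervix_box.x + ann.cervix_box.w,
                    ann.cervix_box.y + ann.cervix_box.h]],
        "shape_type": "rectangle",
    }]
    for poly, label in ann.lesions:
        shapes.append({
            "label": label,
            "points": [[float(x), float(y)] for x, y in np.asarray(poly)],
            "shape_type": "polygon",
        })
    doc = {
        "version": "5.0.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": image_name,
        "imageData": None,
        "imageHeight": h,
        "imageWidth": w,
    }
    save_image(ann.image, os.path.join(os.path.dirname(path) or ".", image_name))
    with open(path, "w") as f:
        json.dump(doc, f, indent=1)


def read_labelme(path: str | os.PathLike) -> AnnotatedImage:
    """Parse a LabelMe-dialect JSON back into an :class:`AnnotatedImage`.

    The cervix rectangle is accepted either as ``shape_type: rectangle``
    with two corners or as a 4-vertex polygon labeled ``cervix``. The
    image is loaded from ``imagePath`` when present on disk; otherwise a
    black canvas of the recorded size stands in.
    """
    path = os.fspath(path)
    with open(path) as f:
        doc = json.load(f)
    missing = [k for k in _REQUIRED_KEYS if k not in doc]
    if missing:
        raise LabelMeError(f"annotation file missing required keys: {missing}")
    h, w = int(doc["imageHeight"]), int(doc["imageWidth"])
    box = None
    lesions: list[tuple[np.ndarray, str]] = []
    for shape in doc["shapes"]:
        for k in ("label", "points", "shape_type"):
            if k not in shape:
                raise LabelMeError(f"shape entry missing required keys: [{k!r}]")
        pts = np.asarray(shape["points"], dtype=np.float64)
        is_rect = shape["shape_type"] == "rectangle"
        if is_rect or (shape["label"] == "cervix" and len(pts) in (2, 4)):
            x0, y0 = pts[:, 0].min(), pts[:, 1].min()
            x1, y1 = pts[:, 0].max(), pts[:, 1].max()
            box = Box(round(x0), round(y0), round(x1 - x0), round(y1 - y0))
        elif shape["shape_type"] == "polygon":
            lesions.append((pts, shape["label"]))
    if box is None:
        raise LabelMeError("no cervix rectangle found in shapes")
    img_path = os.path.join(os.path.dirname(path) or ".", doc["imagePath"])
    image = (load_image(img_path) if os.path.exists(img_path)
             else np.zeros((h, w, 3), dtype=np.uint8))
    ann_id = os.path.splitext(os.path.basename(doc["imagePath"]))[0]
    return AnnotatedImage(image=image, cervix_box=box, lesions=lesions,
                          id=ann_id)
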