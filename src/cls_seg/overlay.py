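"""Mapping segmentation results back to original-image coordinates.

The segmentation mask lives on the canonical square crop; the recorded
cervix box (x, y, w, h) places it back into the original frame. Masks are
restored with nearest-neighbor resampling so they stay binary; everything
outside the box is normal tissue.

The clinician-facing overlay dims the normal region with a translucent
mask (default black at alpha 0.5, which reads as gray) and leaves lesion
pixels byte-identical to the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import Box

__all__ = ["OverlayStyle", "map_to_original", "render_overlay"]


@dataclass
class OverlayStyle:
    mask_color: tuple[int, int, int] = (0, 0, 0)
    alpha: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


def _nearest_index(n_out: int, n_in: int) -> np.ndarray:
    # nearest-neighbor source index for each output sample (half-pixel)
    return np.minimum((np.floor((np.arange(n_out) + 0.5) * n_in / n_out))
                      .astype(np.intp), n_in - 1)


def map_to_original(mask: np.ndarray, box: Box,
                    original_size: tuple[int, int]) -> np.ndarray:
    """Place a crop-space mask into a full-size frame via the box.

    ``original_size`` is (height, width). The mask is resized to
    (box.h, box.w) with nearest-neighbor interpolation and written at
    (box.x, box.y); all pixels outside the box are background.
    """
    oh, ow = original_size
    if box.x < 0 or box.y < 0 or box.x + box.w > ow or box.y + box.h > oh:
        raise ValueError(f"box {box.as_tuple()} outside original bounds "
                         f"{ow}x{oh}")
    mask = np.asarray(mask).astype(bool)
    ri = _nearest_index(box.h, mask.shape[0])
    ci = _nearest_index(box.w, mask.shape[1])
    full = np.zeros((oh, ow), dtype=bool)
    full[box.y: box.y + box.h, box.x: box.x + box.w] = mask[np.ix_(ri, ci)]
    return full


def render_overlay(image: np.ndarray, mask: np.ndarray,
                   style: OverlayStyle | None = None) -> np.ndarray:
    """Dim the normal region, leave the lesion region untouched.

    Normal pixels become (1 - alpha) * pixel + alpha * mask_color, rounded
    half-up to 8 bits; lesion pixels are byte-identical to the input.
    """
    style = style or OverlayStyle()
    image = np.asarray(image, dtype=np.uint8)
    mask = np.asarray(mask).astype(bool)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} "
                         "sizes differ")
    color = np.asarray(style.mask_color, dtype=np.float64)
    blended = np.floor((1.0 - style.alpha) * image.astype(np.float64)
                       + style.alpha * color + 0.5).astype(np.uint8)
    out = np.where(mask[:, :, None], image, blended)
    return out
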