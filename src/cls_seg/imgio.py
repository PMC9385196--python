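"""Small PNG/JPEG helpers shared by the CLI and tests."""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

__all__ = ["load_image", "save_image", "load_mask", "save_mask"]


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as H x W x 3 uint8 RGB."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(image: np.ndarray, path: str | os.PathLike) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask PNG; any nonzero pixel is foreground."""
    with Image.open(path) as im:
        return (np.asarray(im.convert("L")) > 0)


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean/binary mask as a {0, 255} single-channel PNG."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)
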