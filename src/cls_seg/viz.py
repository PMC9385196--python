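"""Activation heatmaps of CLS-Net intermediates.

Each heatmap taps one named intermediate of the forward pass, reduces its
channels to a single plane, min–max normalizes to [0, 1] (a constant
plane maps to all zeros), bilinearly upsamples to the input size and
applies a red-high / blue-low colormap — red marks regions contributing
most to the lesion decision. The cross-layer ablation panel additionally
shows the shallow-fusion variants (80 x 80 / 160 x 160 planes for a
640 x 640 input) when the model is configured with a shallower
``fusion_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .net import CLSNet
from .roi import resize_image

__all__ = ["HeatmapSpec", "feature_heatmap", "ablation_views", "VALID_TAPS"]

VALID_TAPS = ("feature1_projected", "feature2_aspp_up2", "fused",
              "fused_upsampled", "shallow_fused")

_REDUCERS = {"mean": lambda a: a.mean(axis=0), "max": lambda a: a.max(axis=0)}


@dataclass
class HeatmapSpec:
    source: str = "fused"
    reduce: str = "mean"
    colormap: str = "jet"

    def __post_init__(self):
        if self.source not in VALID_TAPS:
            raise ValueError(f"unknown tap {self.source!r}; valid taps: "
                             f"{list(VALID_TAPS)}")
        if self.reduce not in _REDUCERS:
            raise ValueError(f"reduce must be one of {list(_REDUCERS)}")


def _colorize(plane: np.ndarray, cmap_name: str) -> np.ndarray:
    cmap = colormaps[cmap_name]
    rgba = cmap(np.clip(plane, 0.0, 1.0))
    return (rgba[:, :, :3] * 255).astype(np.uint8)


def _normalize(plane: np.ndarray) -> np.ndarray:
    lo, hi = float(plane.min()), float(plane.max())
    if hi - lo < 1e-12:
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def feature_heatmap(model: CLSNet, image: np.ndarray,
                    spec: HeatmapSpec | None = None) -> np.ndarray:
    """RGB heatmap of one tapped intermediate at the input image size.

    Runs the model in evaluation mode; model state (weights, running
    statistics) is left untouched.
    """
    spec = spec or HeatmapSpec()
    model.eval()
    model.predict(image)
    if spec.source not in model.taps:
        raise ValueError(
            f"tap {spec.source!r} not produced by this configuration; "
            f"available: {sorted(model.taps)}")
    plane = _REDUCERS[spec.reduce](model.taps[spec.source][0])
    plane = _normalize(plane)
    h, w = image.shape[:2]
    up = np.clip(resize_image(plane, h, w), 0.0, 1.0)
    return _colorize(up, spec.colormap)


def ablation_views(model: CLSNet, image: np.ndarray,
                   reduce: str = "mean") -> dict[str, np.ndarray]:
    """The full heatmap panel: ASPP output, projected feature1, their sum,
    the upsampled result, and the shallow fusion when configured."""
    model.eval()
    model.predict(image)
    views = {}
    for tap in VALID_TAPS:
        if tap in model.taps:
            views[tap] = feature_heatmap(
                model, image, HeatmapSpec(source=tap, reduce=reduce))
    return views
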