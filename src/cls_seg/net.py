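"""CLS-Net: the cervical-lesion segmentation network.

An end-to-end encoder–decoder. The encoder exposes its two deepest
feature maps, ``feature1`` at 1/16 of the input resolution and
``feature2`` at 1/32 — each defined structurally as the LAST feature map
produced at that stride. ``feature2`` passes through a redesigned atrous
spatial pyramid pooling (ASPP) block with six parallel branches — a 1x1
convolution, 3x3 dilated convolutions at rates {2, 4, 6, 8}, and global
average pooling — whose concatenation is projected down to half the input
channel count. After bilinear x2 upsampling it is fused *additively* with
``feature1`` (projected through a 1x1 convolution + batch normalization to
the same width), and the fused map is projected to class logits and
bilinearly upsampled x16 back to the input size.

The dilation rates are matched to the lesion scale at the 1/32 feature
map: a 3x3 kernel at rates 2/4/6/8 has an effective footprint of
5/9/13/17 pixels, enough to span a 20x20 grid.

Two encoders satisfy the same stride contract: ``efficientnet-b3``
(MBConv blocks with squeeze-excitation and swish, B3 widths/depths,
instantiated only up to the stride-32 stage) and ``tiny``, a small
plain-convolution encoder for CPU-scale training and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Tensor
from ._nn.autodiff import exp as _exp

__all__ = ["NetworkConfig", "EncoderFeatures", "effective_kernel", "CLSNet",
           "TinyEncoder", "EfficientNetB3Encoder", "ASPP", "predict_mask",
           "preprocess"]

_FUSION_SCALES = (1 / 16, 1 / 8, 1 / 4)


def effective_kernel(kernel: int, rate: int) -> int:
    """Spatial extent of a dilated kernel along one axis.

    A k-tap kernel with dilation rate r inserts (r - 1) holes between
    taps, so its footprint is k + (k - 1)(r - 1) pixels.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 1")
    if rate < 1:
        raise ValueError("rate must be >= 1")
    return kernel + (kernel - 1) * (rate - 1)


@dataclass
class NetworkConfig:
    input_side: int = 640
    encoder: str = "efficientnet-b3"
    aspp_rates: tuple[int, ...] = (2, 4, 6, 8)
    fusion_scale: float = 1 / 16
    out_classes: int = 1
    seed: int = 0

    def __post_init__(self):
        self.aspp_rates = tuple(self.aspp_rates)
        self.validate()

    def validate(self) -> None:
        if self.input_side % 32:
            raise ValueError(
                f"input_side must be divisible by 32, got {self.input_side}")
        if self.encoder not in ("efficientnet-b3", "tiny"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if any(r < 1 for r in self.aspp_rates) or \
                any(b <= a for a, b in zip(self.aspp_rates, self.aspp_rates[1:])):
            raise ValueError("aspp_rates must be strictly positive and increasing")
        if not any(abs(self.fusion_scale - s) < 1e-9 for s in _FUSION_SCALES):
            raise ValueError("fusion_scale must be one of 1/16, 1/8, 1/4")
        if self.out_classes < 1:
            raise ValueError("out_classes must be >= 1")


@dataclass
class EncoderFeatures:
    """The two deepest encoder maps: feature1 at 1/16, feature2 at 1/32."""

    feature1: Tensor
    feature2: Tensor


class TinyEncoder(_nn.Module):
    """Five stride-2 conv-BN-ReLU stages; same stride contract as B3."""

    #: channels at strides 2, 4, 8, 16, 32
    widths = (8, 16, 24, 32, 48)

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        chans = (3,) + self.widths
        for i, (ci, co) in enumerate(zip(chans[:-1], chans[1:])):
            setattr(self, f"stage{i + 1}",
                    _nn.ConvBNAct(ci, co, 3, stride=2, rng=rng))
        self.channels = {4: self.widths[1], 8: self.widths[2],
                         16: self.widths[3], 32: self.widths[4]}

    def forward(self, x: Tensor) -> dict[int, Tensor]:
        taps = {}
        stride = 1
        for i in range(5):
            x = getattr(self, f"stage{i + 1}")(x)
            stride *= 2
            taps[stride] = x
        return taps


class _SqueezeExcite(_nn.Module):
    def __init__(self, ch: int, se_ch: int, rng):
        super().__init__()
        self.reduce = _nn.Conv2d(ch, se_ch, 1, rng=rng)
        self.expand = _nn.Conv2d(se_ch, ch, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = _nn.global_avg_pool(x)
        s = _nn.sigmoid(self.expand(_nn.silu(self.reduce(s))))
        return _nn.mul(x, s)


class _MBConv(_nn.Module):
    """Mobile inverted bottleneck with squeeze-excitation (swish)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 expand: int, rng):
        super().__init__()
        mid = in_ch * expand
        self.expand_conv = (_nn.ConvBNAct(in_ch, mid, 1, act="silu", rng=rng)
                            if expand != 1 else None)
        self.dw = _nn.ConvBNAct(mid, mid, kernel, stride=stride, groups=mid,
                                act="silu", rng=rng)
        self.se = _SqueezeExcite(mid, max(1, in_ch // 4), rng)
        self.project = _nn.ConvBNAct(mid, out_ch, 1, act=None, rng=rng)
        self.residual = stride == 1 and in_ch == out_ch

    def forward(self, x: Tensor) -> Tensor:
        h = self.expand_conv(x) if self.expand_conv is not None else x
        h = self.project(self.se(self.dw(h)))
        return _nn.add(h, x) if self.residual else h


class EfficientNetB3Encoder(_nn.Module):
    """EfficientNet-B3 feature extractor, stages up to stride 32 only.

    B3 stage widths/depths (width x1.2, depth x1.4 over the B0 baseline):
    stem 40; then (24 x2, k3 s1), (32 x3, k3 s2), (48 x3, k5 s2),
    (96 x5, k3 s2), (136 x5, k5 s1), (232 x6, k5 s2), (384 x2, k3 s1).
    The classifier head and anything past the last stride-32 block are
    never instantiated.
    """

    _STAGES = [  # (out_ch, depth, kernel, stride, expand)
        (24, 2, 3, 1, 1),
        (32, 3, 3, 2, 6),
        (48, 3, 5, 2, 6),
        (96, 5, 3, 2, 6),
        (136, 5, 5, 1, 6),
        (232, 6, 5, 2, 6),
        (384, 2, 3, 1, 6),
    ]

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stem = _nn.ConvBNAct(3, 40, 3, stride=2, act="silu", rng=rng)
        ch = 40
        blocks = []
        self._stage_strides = []
        stride = 2
        for si, (out_ch, depth, k, s, e) in enumerate(self._STAGES):
            for d in range(depth):
                blk = _MBConv(ch, out_ch, k, s if d == 0 else 1, e, rng)
                blocks.append(blk)
                setattr(self, f"block{len(blocks)}", blk)
                ch = out_ch
            stride *= s
            self._stage_strides.append(stride)
        self.blocks = blocks
        self.channels = {4: 32, 8: 48, 16: 136, 32: 384}

    def forward(self, x: Tensor) -> dict[int, Tensor]:
        x = self.stem(x)
        taps = {2: x}
        stride = 2
        bi = 0
        for (out_ch, depth, k, s, e), st in zip(self._STAGES,
                                                self._stage_strides):
            for _ in range(depth):
                x = self.blocks[bi](x)
                bi += 1
            stride = st
            taps[stride] = x  # last block at this stride overwrites earlier
        return taps


class ASPP(_nn.Module):
    """Six-branch atrous spatial pyramid pooling with channel halving.

    Branches: 1x1 conv, one 3x3 dilated conv per configured rate (padding
    chosen to preserve spatial size), and image-level global average
    pooling broadcast back onto the grid. The concatenation is projected
    by a 1x1 convolution to exactly half the input channels.
    """

    def __init__(self, in_ch: int, rates: tuple[int, ...], rng):
        super().__init__()
        if in_ch % 2:
            raise ValueError(f"ASPP input channels must be even, got {in_ch}")
        self.out_ch = in_ch // 2
        width = self.out_ch
        self.branch_1x1 = _nn.ConvBNAct(in_ch, width, 1, rng=rng)
        self.rates = tuple(rates)
        for r in self.rates:
            setattr(self, f"branch_r{r}",
                    _nn.ConvBNAct(in_ch, width, 3, dilation=r, rng=rng))
        self.branch_pool = _nn.Conv2d(in_ch, width, 1, rng=rng)
        self.project = _nn.ConvBNAct(width * (2 + len(self.rates)),
                                     self.out_ch, 1, rng=rng)

    @property
    def n_branches(self) -> int:
        return 2 + len(self.rates)

    def forward(self, x: Tensor) -> Tensor:
        outs = [self.branch_1x1(x)]
        for r in self.rates:
            outs.append(getattr(self, f"branch_r{r}")(x))
        pooled = _nn.relu(self.branch_pool(_nn.global_avg_pool(x)))
        ones = Tensor(np.ones((1, 1) + x.data.shape[2:], dtype=np.float32))
        outs.append(_nn.mul(pooled, ones))
        cat = _nn.concat(outs, axis=1)
        self.last_concat_channels = cat.data.shape[1]
        return self.project(cat)


def _softmax_channel(x: Tensor) -> Tensor:
    shifted = x - x.data.max(axis=1, keepdims=True)
    e = _exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


class CLSNet(_nn.Module):
    """Encoder + ASPP + additive cross-layer fusion + x16 upsampling.

    ``taps`` is refreshed on every forward pass with detached copies of
    the named intermediates used by the heatmap module.
    """

    def __init__(self, config: NetworkConfig | None = None, **kwargs):
        super().__init__()
        self.config = config or NetworkConfig(**kwargs)
        rng = np.random.default_rng(self.config.seed)
        enc = (TinyEncoder if self.config.encoder == "tiny"
               else EfficientNetB3Encoder)
        self.encoder = enc(rng)
        c2 = self.encoder.channels[32]
        self.aspp = ASPP(c2, self.config.aspp_rates, rng)
        width = self.aspp.out_ch
        # feature1 path: 1x1 convolution + batch normalization, no activation
        self.proj16 = _nn.ConvBNAct(self.encoder.channels[16], width, 1,
                                    act=None, rng=rng)
        fs = self.config.fusion_scale
        # shallower fusion scales (1/8, 1/4) add further cross-layer stages
        if fs >= 1 / 8 - 1e-9:
            self.proj8 = _nn.ConvBNAct(self.encoder.channels[8], width, 1,
                                       act=None, rng=rng)
        if fs >= 1 / 4 - 1e-9:
            self.proj4 = _nn.ConvBNAct(self.encoder.channels[4], width, 1,
                                       act=None, rng=rng)
        self.classifier = _nn.Conv2d(width, self.config.out_classes, 1, rng=rng)
        self.taps: dict[str, np.ndarray] = {}

    # -- spec'd operations -------------------------------------------------
    def encode(self, x: Tensor | np.ndarray) -> EncoderFeatures:
        """Run the encoder and return the 1/16 and 1/32 feature maps."""
        x = self._as_batch(x)
        side = x.data.shape[2]
        if side % 32:
            raise ValueError(f"input side must be divisible by 32, got {side}")
        taps = self.encoder(x)
        self._enc_taps = taps
        return EncoderFeatures(feature1=taps[16], feature2=taps[32])

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        x = self._as_batch(x)
        side = x.data.shape[2]
        feats = self.encode(x)
        a = self.aspp(feats.feature2)
        up2 = _nn.resize_bilinear(a, *self._sides(feats.feature1))
        f1p = self.proj16(feats.feature1)
        if up2.data.shape[1] != f1p.data.shape[1]:
            raise ValueError(  # pragma: no cover - widths fixed by design
                f"fusion channel mismatch: {up2.data.shape} vs {f1p.data.shape}")
        fused = _nn.add(up2, f1p)
        self.taps = {
            "feature2_aspp_up2": up2.data.copy(),
            "feature1_projected": f1p.data.copy(),
            "fused": fused.data.copy(),
        }
        out = fused
        fs = self.config.fusion_scale
        if fs >= 1 / 8 - 1e-9:
            shallow = self.proj8(self._enc_taps[8])
            out = _nn.add(_nn.resize_bilinear(out, *self._sides(shallow)),
                          shallow)
            self.taps["shallow_fused"] = out.data.copy()
        if fs >= 1 / 4 - 1e-9:
            shallow4 = self.proj4(self._enc_taps[4])
            out = _nn.add(_nn.resize_bilinear(out, *self._sides(shallow4)),
                          shallow4)
            self.taps["shallow_fused"] = out.data.copy()
        logits = self.classifier(out)
        logits = _nn.resize_bilinear(logits, side, side)
        if self.config.out_classes == 1:
            probs = _nn.sigmoid(logits)
        else:
            probs = _softmax_channel(logits)
        self.taps["fused_upsampled"] = _nn.resize_bilinear(
            Tensor(self.taps["fused"]), side, side).data
        return probs

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map (H x W) for a single uint8 RGB image."""
        self.eval()
        probs = self.forward(preprocess(image))
        return probs.data[0, 0] if self.config.out_classes == 1 \
            else probs.data[0]

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _sides(t: Tensor) -> tuple[int, int]:
        return t.data.shape[2], t.data.shape[3]

    @staticmethod
    def _as_batch(x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None]
        return Tensor(arr)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        import json
        cfg = dict(input_side=self.config.input_side,
                   encoder=self.config.encoder,
                   aspp_rates=list(self.config.aspp_rates),
                   fusion_scale=self.config.fusion_scale,
                   out_classes=self.config.out_classes,
                   seed=self.config.seed)
        np.savez(path, __config__=json.dumps(cfg), **self.state_dict())

    @classmethod
    def load(cls, path) -> "CLSNet":
        import json
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["__config__"]))
        cfg["aspp_rates"] = tuple(cfg["aspp_rates"])
        model = cls(NetworkConfig(**cfg))
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
        model.eval()
        return model


def preprocess(image: np.ndarray) -> np.ndarray:
    """uint8 H x W x 3 -> normalized float32 (1, 3, H, W)."""
    arr = np.asarray(image, dtype=np.float32) / 255.0 - 0.5
    return arr.transpose(2, 0, 1)[None]


def predict_mask(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a probability map; foreground iff prob > threshold (strict)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return prob > threshold
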