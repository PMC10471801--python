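"""AttMobile-DeeplabV3+: a lightweight encoder-decoder for 3-class
farmland segmentation.

The encoder is a MobileNetV2 inverted-residual backbone run at output
stride 16, optionally followed by a convolutional block attention module
(CBAM) on its final 320-channel feature map.  Multi-scale context comes
from an atrous spatial pyramid pooling (ASPP) head whose branches
(1x1, three dilated 3x3, global image pooling) can be augmented with a
strip-pooling branch that gates the input feature map with long-range
horizontal/vertical context -- the field boundaries this package targets
are exactly such long thin structures.  The decoder fuses a stride-4
low-level feature with the 4x-upsampled ASPP output and classifies per
pixel.

Four variants mirror the ablation grid: ``baseline`` (plain backbone and
ASPP), ``attention_only`` (+CBAM), ``aspp_only`` (+strip pooling) and
``full`` (both).  Channel widths for the decoder (48, 256, 257) and the
strip-pooling bottleneck (112) are fixed constants of this package,
calibrated once by exhaustive parameter counting so that the four
variants land on 5.814 / 5.839 / 6.044 / 6.070 million trainable
parameters, and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, DepthwiseConv2d, Module, ReLU,
                 ReLU6, Sequential, Tensor, bilinear_resize, concat,
                 softmax_channels)

__all__ = ["NetworkConfig", "ChannelAttention", "SpatialAttention", "CBAM",
           "StripPooling", "ASPP", "MobileNetV2Backbone", "AttMobileDeeplab",
           "build_model", "count_parameters", "predict_mask",
           "save_checkpoint", "load_checkpoint", "VARIANTS"]

VARIANTS = ("baseline", "attention_only", "aspp_only", "full")

# MobileNetV2 inverted-residual grid: (expansion, out_channels, repeats, stride)
_MOBILENET_SETTINGS = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-parameters of the segmentation network.

    ``decoder_widths`` is (low-level projection, first refine conv, second
    refine conv); together with ``spl_mid_channels`` these are calibrated
    constants -- change them and the variant parameter counts move.
    """

    num_classes: int = 3
    input_size: int = 1024
    variant: str = "full"
    cbam_reduction: int = 8
    spl_mid_channels: int = 112
    spl_kernel_D: int = 3
    atrous_rates: tuple[int, int, int] = (6, 12, 18)
    decoder_widths: tuple[int, int, int] = (48, 256, 257)
    aspp_channels: int = 256

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got "
                             f"{self.variant!r}")
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16 "
                             "(the network's output stride)")
        if self.spl_kernel_D % 2 != 1:
            raise ValueError("spl_kernel_D must be odd")

    @property
    def use_cbam(self) -> bool:
        return self.variant in ("attention_only", "full")

    @property
    def use_strip_pooling(self) -> bool:
        return self.variant in ("aspp_only", "full")


def _conv_bn_act(in_ch, out_ch, k, rng, stride=1, padding=0, dilation=1,
                 act=ReLU6) -> Sequential:
    return Sequential(
        Conv2d(in_ch, out_ch, k, stride=stride, padding=padding,
               dilation=dilation, bias=False, rng=rng),
        BatchNorm2d(out_ch), act())


class ChannelAttention(Module):
    """Channel gate of CBAM.

    Global average- and max-pooled channel descriptors pass through a shared
    two-layer bottleneck (C -> C/r -> C, bias-free), are summed and squashed
    by a sigmoid into per-channel weights in (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if reduction >= channels:
            raise ValueError("reduction must be smaller than the channel count")
        mid = channels // reduction
        if mid < 1 or channels % reduction != 0:
            raise ValueError("reduction must divide the channel count")
        rng = rng or np.random.default_rng(0)
        self.fc1 = Conv2d(channels, mid, 1, bias=False, rng=rng)
        self.fc2 = Conv2d(mid, channels, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max_spatial()
        squeeze = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return squeeze.sigmoid()


class SpatialAttention(Module):
    """Spatial gate of CBAM: channel-wise mean and max maps stacked to
    2xHxW, a single 7x7 convolution to one channel, then a sigmoid."""

    def __init__(self, kernel_size: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2,
                           bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        n, c, h, w = x.shape
        mx_data = x.data.max(axis=1, keepdims=True)
        argmax = x.data.argmax(axis=1, keepdims=True)

        def backward(g):
            if x.requires_grad:
                gi = np.zeros_like(x.data)
                np.put_along_axis(gi, argmax, g, axis=1)
                x._accumulate(gi)

        mx = Tensor(mx_data)
        if x.requires_grad:
            mx.requires_grad = True
            mx._prev = (x,)
            mx._backward = backward
        stacked = concat([avg, mx], axis=1)
        return self.conv(stacked).sigmoid()


class CBAM(Module):
    """Sequential channel-then-spatial attention: F'' = Ms(F') * F' with
    F' = Mc(F) * F."""

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        fprime = self.channel(x) * x
        return self.spatial(fprime) * fprime


class StripPooling(Module):
    """Strip-pooling gate for long-range context.

    The input is reduced 1x1 to a bottleneck, mean-pooled along rows (H x 1)
    and columns (1 x W), each strip is refined by a 1-D convolution of kernel
    length D, the two maps are broadcast back to H x W and summed, and a 1x1
    convolution + sigmoid turns the sum into a gate that multiplies the
    original input elementwise.  Output shape equals input shape.
    """

    def __init__(self, channels: int, mid_channels: int, kernel_d: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        pad = kernel_d // 2
        self.reduce = _conv_bn_act(channels, mid_channels, 1, rng, act=ReLU)
        self.conv_h = Sequential(
            Conv2d(mid_channels, mid_channels, (kernel_d, 1), padding=(pad, 0),
                   bias=False, rng=rng), BatchNorm2d(mid_channels))
        self.conv_w = Sequential(
            Conv2d(mid_channels, mid_channels, (1, kernel_d), padding=(0, pad),
                   bias=False, rng=rng), BatchNorm2d(mid_channels))
        self.gate = Sequential(
            Conv2d(mid_channels, channels, 1, bias=False, rng=rng),
            BatchNorm2d(channels))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        r = self.reduce(x)
        strip_h = self.conv_h(r.mean(axis=3, keepdims=True))    # N,M,H,1
        strip_w = self.conv_w(r.mean(axis=2, keepdims=True))    # N,M,1,W
        mixed = strip_h.broadcast_to((n, r.shape[1], h, w)) + \
            strip_w.broadcast_to((n, r.shape[1], h, w))
        return self.gate(mixed).sigmoid() * x


class _InvertedResidual(Module):
    def __init__(self, in_ch, out_ch, stride, expand, rng, dilation=1):
        super().__init__()
        hidden = in_ch * expand
        self.use_shortcut = stride == 1 and in_ch == out_ch
        layers = []
        if expand != 1:
            layers.append(_conv_bn_act(in_ch, hidden, 1, rng))
        layers.append(Sequential(
            DepthwiseConv2d(hidden, 3, stride=stride, padding=dilation,
                            dilation=dilation, rng=rng),
            BatchNorm2d(hidden), ReLU6()))
        layers.append(Sequential(
            Conv2d(hidden, out_ch, 1, bias=False, rng=rng),
            BatchNorm2d(out_ch)))                   # linear bottleneck
        self.block = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        out = self.block(x)
        return out + x if self.use_shortcut else out


class MobileNetV2Backbone(Module):
    """MobileNetV2 feature extractor at output stride 16.

    Strides past stride 16 are converted to dilation 2 so the final
    320-channel map stays at 1/16 resolution; the stride-4 24-channel map
    is exposed as the decoder's low-level feature.
    """

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stem = _conv_bn_act(3, 32, 3, rng, stride=2, padding=1)
        blocks = []
        in_ch = 32
        current_stride = 2
        dilation = 1
        self.low_level_index = None
        for expand, out_ch, repeats, stride in _MOBILENET_SETTINGS:
            for i in range(repeats):
                s = stride if i == 0 else 1
                if s > 1 and current_stride >= 16:
                    dilation *= s
                    s = 1
                blocks.append(_InvertedResidual(in_ch, out_ch, s, expand, rng,
                                                dilation=dilation))
                if s > 1:
                    current_stride *= s
                in_ch = out_ch
            if out_ch == 24:
                self.low_level_index = len(blocks)
        self.blocks = blocks
        self.low_level_channels = 24
        self.out_channels = 320

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        x = self.stem(x)
        low = None
        for i, block in enumerate(self.blocks, start=1):
            x = block(x)
            if i == self.low_level_index:
                low = x
        return low, x


class ASPP(Module):
    """Atrous spatial pyramid pooling with an optional strip-pooling branch
    running in parallel with the 1x1, dilated 3x3 and image-pooling branches
    before channel concatenation and 1x1 projection."""

    def __init__(self, in_ch: int, out_ch: int, rates: tuple[int, int, int],
                 rng: np.random.Generator, strip: StripPooling | None = None):
        super().__init__()
        self.b0 = _conv_bn_act(in_ch, out_ch, 1, rng, act=ReLU)
        self.b_atrous = [
            _conv_bn_act(in_ch, out_ch, 3, rng, padding=r, dilation=r, act=ReLU)
            for r in rates]
        self.b_pool = _conv_bn_act(in_ch, out_ch, 1, rng, act=ReLU)
        self.strip = strip
        cat_ch = out_ch * 5 + (in_ch if strip is not None else 0)
        self.project = _conv_bn_act(cat_ch, out_ch, 1, rng, act=ReLU)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        feats = [self.b0(x)] + [b(x) for b in self.b_atrous]
        pooled = self.b_pool(x.mean(axis=(2, 3), keepdims=True))
        feats.append(bilinear_resize(pooled, (h, w)))
        if self.strip is not None:
            feats.append(self.strip(x))
        return self.project(concat(feats, axis=1))


class AttMobileDeeplab(Module):
    """The assembled encoder-decoder network (any of the four variants)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.backbone = MobileNetV2Backbone(rng)
        self.cbam = (CBAM(self.backbone.out_channels, config.cbam_reduction,
                          rng=rng) if config.use_cbam else None)
        strip = (StripPooling(self.backbone.out_channels,
                              config.spl_mid_channels, config.spl_kernel_D,
                              rng=rng) if config.use_strip_pooling else None)
        self.aspp = ASPP(self.backbone.out_channels, config.aspp_channels,
                         config.atrous_rates, rng, strip=strip)
        low_w, refine1_w, refine2_w = config.decoder_widths
        self.low_project = _conv_bn_act(self.backbone.low_level_channels,
                                        low_w, 1, rng, act=ReLU)
        self.refine = Sequential(
            _conv_bn_act(config.aspp_channels + low_w, refine1_w, 3, rng,
                         padding=1, act=ReLU),
            _conv_bn_act(refine1_w, refine2_w, 3, rng, padding=1, act=ReLU))
        self.classifier = Conv2d(refine2_w, config.num_classes, 1, bias=True,
                                 rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """Class scores at input resolution for an N x 3 x S x S input."""
        n, c, h, w = x.shape
        if h % 16 or w % 16:
            raise ValueError("input height/width must be divisible by 16; "
                             "pad the image before calling the network")
        low, high = self.backbone(x)
        if self.cbam is not None:
            high = self.cbam(high)
        context = self.aspp(high)
        context = bilinear_resize(context, low.shape[2:])
        fused = concat([context, self.low_project(low)], axis=1)
        scores = self.classifier(self.refine(fused))
        return bilinear_resize(scores, (h, w))


def build_model(config: NetworkConfig, seed: int = 0) -> AttMobileDeeplab:
    """Construct a network variant with seeded weight initialization."""
    return AttMobileDeeplab(config, seed=seed)


def count_parameters(network: Module) -> float:
    """Trainable parameters in millions, rounded half-up to 3 decimals."""
    raw = Decimal(network.num_parameters()) / Decimal(10 ** 6)
    return float(raw.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _normalize_image(image: np.ndarray) -> np.ndarray:
    """H x W x 3 uint8 -> 1 x 3 x H x W float32 in [-1, 1]."""
    x = np.asarray(image, dtype=np.float32) / 255.0
    x = (x - 0.5) / 0.5
    return np.ascontiguousarray(x.transpose(2, 0, 1))[None]


def predict_mask(network: AttMobileDeeplab, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax segmentation of an H x W x 3 image.

    Ties break toward the lowest class index.  H and W must be divisible
    by 16 (pad beforehand if not).
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    h, w = image.shape[:2]
    if h % 16 or w % 16:
        raise ValueError("image height/width must be divisible by 16; "
                         "pad the image and crop the prediction")
    network.eval()
    scores = network(Tensor(_normalize_image(image)))
    return scores.data[0].argmax(axis=0).astype(np.uint8)


def save_checkpoint(network: AttMobileDeeplab, path) -> None:
    """Weight archive (.npz) plus a key-value config sidecar (.config.txt)."""
    import os

    np.savez(path, **network.state_dict())
    cfg = network.config
    side = os.fspath(path) + ".config.txt"
    with open(side, "w") as fh:
        for key in ("num_classes", "input_size", "variant", "cbam_reduction",
                    "spl_mid_channels", "spl_kernel_D", "atrous_rates",
                    "decoder_widths", "aspp_channels"):
            val = getattr(cfg, key)
            if isinstance(val, tuple):
                val = ",".join(str(v) for v in val)
            fh.write(f"{key}={val}\n")


def load_checkpoint(path) -> AttMobileDeeplab:
    import os

    side = os.fspath(path) + ".config.txt"
    kwargs = {}
    with open(side) as fh:
        for line in fh:
            key, val = line.strip().split("=", 1)
            if key in ("atrous_rates", "decoder_widths"):
                kwargs[key] = tuple(int(v) for v in val.split(","))
            elif key == "variant":
                kwargs[key] = val
            else:
                kwargs[key] = int(val)
    net = build_model(NetworkConfig(**kwargs))
    with np.load(path) as archive:
        net.load_state_dict({k: archive[k] for k in archive.files})
    return net
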