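"""Encoder feature extractors: VGG-19, ResNet50 and MobileNetV2 topologies.

Each encoder drops its classification head and exposes five tap points — one
feature map per distinct spatial resolution. VGG-19's taps (the last
activation of each conv block, before pooling) are natively at
(S, S/2, S/4, S/8, S/16) for an S×S input; ResNet50 and MobileNetV2 start
with a stride-2 stem, so their five taps sit one octave lower and the
lateral projection resizes them onto the canonical grid.

ImageNet-pretrained initialisation is an opt-in hook: construction never
touches the network by default (random He init), and a weights file can be
loaded through ``Module.load_state`` when one is available. A width
multiplier scales every stage uniformly so a miniature profile with the
identical topology can run in test budgets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import BatchNorm2d, Conv2d, ConvBNAct, MaxPool2d, Module, Tensor
from .nn import functional as F

ENCODER_NAMES = ("vgg19", "resnet50", "mobilenetv2")

#: canonical post-projection resolutions for a 224 input (Table-style contract)
def canonical_resolutions(input_size: int = 224) -> tuple:
    return tuple(input_size // 2 ** i for i in range(5))


def relu6(x):
    """min(max(x, 0), 6) — elementwise; accepts scalars, arrays or Tensors."""
    if isinstance(x, Tensor):
        return x.relu6()
    arr = np.asarray(x)
    if not np.all(np.isfinite(arr)):
        raise ValueError("relu6 requires finite input")
    out = np.minimum(np.maximum(arr, 0), 6)
    return out.item() if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class EncoderSpec:
    """Which encoder to build and how."""

    name: str
    pretrained: bool = False
    trainable: bool = True
    width_mult: float = 1.0
    tap_points: tuple = ()

    def __post_init__(self):
        if self.name not in ENCODER_NAMES:
            raise ValueError(f"unknown encoder {self.name!r}; expected one of {ENCODER_NAMES}")
        if not self.tap_points:
            self.tap_points = DEFAULT_TAP_POINTS[self.name]
        if len(self.tap_points) != 5:
            raise ValueError(f"exactly 5 tap points required, got {len(self.tap_points)}")


DEFAULT_TAP_POINTS = {
    "vgg19": ("block1", "block2", "block3", "block4", "block5"),
    "resnet50": ("stem", "layer1", "layer2", "layer3", "layer4"),
    "mobilenetv2": ("expand16", "expand24", "expand32", "expand96", "expand320"),
}


@dataclass
class FeaturePyramid:
    """Ordered five-level feature list, finest first, resolution halving."""

    levels: list

    def __post_init__(self):
        if len(self.levels) != 5:
            raise ValueError(f"a feature pyramid has exactly 5 levels, got {len(self.levels)}")

    @property
    def shapes(self) -> list:
        return [tuple(level.shape) for level in self.levels]

    @property
    def resolutions(self) -> tuple:
        return tuple(level.shape[1] for level in self.levels)

    @property
    def channels(self) -> tuple:
        return tuple(level.shape[-1] for level in self.levels)

    def __iter__(self):
        return iter(self.levels)

    def __getitem__(self, i):
        return self.levels[i]


def _width(c: int, mult: float) -> int:
    return max(4, int(round(c * mult)))


class VGG19Encoder(Module):
    """Five conv blocks of 3×3 convolutions; pooling halves resolution four times."""

    BLOCKS = ((64, 2), (128, 2), (256, 4), (512, 4), (512, 4))

    def __init__(self, width_mult: float = 1.0, in_ch: int = 3, rng=None):
        super().__init__()
        self.blocks = []
        ch = in_ch
        for out_ch, n_convs in self.BLOCKS:
            out_ch = _width(out_ch, width_mult)
            block = [ConvBNAct(ch if i == 0 else out_ch, out_ch, 3, rng=rng)
                     for i in range(n_convs)]
            self.blocks.append(block)
            ch = out_ch
        self.pool = MaxPool2d(2)

    def forward(self, x) -> FeaturePyramid:
        taps = []
        for i, block in enumerate(self.blocks):
            for layer in block:
                x = layer(x)
            taps.append(x)
            if i < 4:
                x = self.pool(x)
        return FeaturePyramid(taps)


class Bottleneck(Module):
    """ResNet 1-3-1 bottleneck with identity or projection skip."""

    def __init__(self, in_ch, mid_ch, out_ch, stride=1, rng=None):
        super().__init__()
        self.conv1 = ConvBNAct(in_ch, mid_ch, 1, rng=rng)
        self.conv2 = ConvBNAct(mid_ch, mid_ch, 3, stride=stride, rng=rng)
        self.conv3 = ConvBNAct(mid_ch, out_ch, 1, act="none", rng=rng)
        if stride != 1 or in_ch != out_ch:
            self.proj = ConvBNAct(in_ch, out_ch, 1, stride=stride, act="none", rng=rng)
        else:
            self.proj = None

    def forward(self, x):
        shortcut = self.proj(x) if self.proj is not None else x
        return (self.conv3(self.conv2(self.conv1(x))) + shortcut).relu()


class ResNet50Encoder(Module):
    """Stem + four bottleneck stages (3, 4, 6, 3 blocks)."""

    STAGES = ((64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2))

    def __init__(self, width_mult: float = 1.0, in_ch: int = 3, rng=None):
        super().__init__()
        stem_ch = _width(64, width_mult)
        self.stem = ConvBNAct(in_ch, stem_ch, 7, stride=2, rng=rng)
        self.pool = MaxPool2d(2)
        self.stages = []
        ch = stem_ch
        for mid, out, n_blocks, stride in self.STAGES:
            mid, out = _width(mid, width_mult), _width(out, width_mult)
            stage = [Bottleneck(ch, mid, out, stride=stride, rng=rng)]
            stage += [Bottleneck(out, mid, out, rng=rng) for _ in range(n_blocks - 1)]
            self.stages.append(stage)
            ch = out

    def forward(self, x) -> FeaturePyramid:
        x = self.stem(x)
        taps = [x]  # S/2
        x = self.pool(x)
        for stage in self.stages:
            for block in stage:
                x = block(x)
            taps.append(x)
        return FeaturePyramid(taps)


class InvertedResidual(Module):
    """MobileNetV2 block: 1×1 expand (ReLU6), 3×3 depthwise (ReLU6), linear 1×1."""

    def __init__(self, in_ch, out_ch, stride, expand_ratio, rng=None):
        super().__init__()
        hidden = in_ch * expand_ratio
        self.expand = (ConvBNAct(in_ch, hidden, 1, act="relu6", rng=rng)
                       if expand_ratio != 1 else None)
        self.depthwise_bn = BatchNorm2d(hidden)
        from .nn import DepthwiseConv2d

        self.depthwise = DepthwiseConv2d(hidden, 3, stride=stride, bias=False, rng=rng)
        self.project = ConvBNAct(hidden, out_ch, 1, act="none", rng=rng)
        self.use_residual = stride == 1 and in_ch == out_ch

    def forward(self, x):
        h = self.expand(x) if self.expand is not None else x
        h = self.depthwise_bn(self.depthwise(h)).relu6()
        h = self.project(h)
        return h + x if self.use_residual else h


class MobileNetV2Encoder(Module):
    """Stride-2 stem plus the standard inverted-residual schedule."""

    # (expand_ratio, channels, repeats, first_stride)
    SETTINGS = ((1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
                (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1))
    # taps after the last block producing each distinct resolution
    TAP_AFTER = {0: 0, 1: 1, 2: 2, 4: 3, 6: 4}

    def __init__(self, width_mult: float = 1.0, in_ch: int = 3, rng=None):
        super().__init__()
        stem_ch = _width(32, width_mult)
        self.stem = ConvBNAct(in_ch, stem_ch, 3, stride=2, act="relu6", rng=rng)
        self.groups = []
        ch = stem_ch
        for t, c, n, s in self.SETTINGS:
            c = _width(c, width_mult)
            group = []
            for i in range(n):
                group.append(InvertedResidual(ch, c, s if i == 0 else 1, t, rng=rng))
                ch = c
            self.groups.append(group)

    def forward(self, x) -> FeaturePyramid:
        x = self.stem(x)
        taps = [None] * 5
        for gi, group in enumerate(self.groups):
            for block in group:
                x = block(x)
            if gi in self.TAP_AFTER:
                taps[self.TAP_AFTER[gi]] = x
        return FeaturePyramid(taps)


_BUILDERS = {
    "vgg19": VGG19Encoder,
    "resnet50": ResNet50Encoder,
    "mobilenetv2": MobileNetV2Encoder,
}


def build_encoder(spec: EncoderSpec | str, rng=None) -> Module:
    """Construct the requested encoder; no network access in any path.

    ``pretrained=True`` requires a local weights file loaded afterwards via
    ``encoder.load_state``; construction itself is always offline.
    ``trainable=False`` freezes every convolution/BN parameter.
    """
    if isinstance(spec, str):
        spec = EncoderSpec(spec)
    encoder = _BUILDERS[spec.name](width_mult=spec.width_mult, rng=rng)
    if not spec.trainable:
        encoder.freeze()
    return encoder


def resize_to(x: Tensor, target: int, upsample_mode: str = "bilinear") -> Tensor:
    """Resize a square NHWC map to ``target`` via stride-2 steps (paper's resize)."""
    while x.shape[1] < target:
        x = (F.upsample_bilinear2x(x) if upsample_mode == "bilinear"
             else F.upsample_nearest2x(x))
    while x.shape[1] > target:
        x = F.maxpool2d(x, 2)
    return x


class LateralProjector(Module):
    """1×1-project each tap to a uniform channel count on the canonical grid.

    Gives every encoder the identical five-level pyramid contract
    (channels uniform, resolutions input, input/2, ..., input/16) that the
    bidirectional pyramid and the cross-encoder fusion require.
    """

    def __init__(self, in_channels: list, channels: int = 32, input_size: int = 224,
                 upsample_mode: str = "bilinear", rng=None):
        super().__init__()
        self.convs = [Conv2d(c, channels, 1, rng=rng) for c in in_channels]
        self.targets = canonical_resolutions(input_size)
        self.upsample_mode = upsample_mode

    def forward(self, pyramid: FeaturePyramid) -> FeaturePyramid:
        out = []
        for conv, level, target in zip(self.convs, pyramid, self.targets):
            out.append(resize_to(conv(level), target, self.upsample_mode))
        return FeaturePyramid(out)


def encoder_tap_channels(name: str, width_mult: float = 1.0) -> list:
    """Channel count at each of the five tap points (finest first)."""
    if name == "vgg19":
        return [_width(c, width_mult) for c, _ in VGG19Encoder.BLOCKS]
    if name == "resnet50":
        return [_width(64, width_mult)] + [_width(c, width_mult)
                                           for _, c, _, _ in ResNet50Encoder.STAGES]
    if name == "mobilenetv2":
        taps = {0: 16, 1: 24, 2: 32, 4: 96, 6: 320}
        return [_width(taps[g], width_mult) for g in sorted(taps)]
    raise ValueError(f"unknown encoder {name!r}")
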