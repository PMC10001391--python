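"""Top-down and bidirectional feature-pyramid fusion.

``fpn_topdown`` is the classic one-way aggregation kept as a reference;
``bifpn_layer`` is the production five-level bidirectional pass. Both are
written as pure recursions over injectable ``conv``/``resize`` callables so
they can be checked against straight-line oracles with stub operators; the
module classes wire in the real learned blocks.

The five-level bidirectional pass computes, with L1 the finest level:

    L4mid = Conv(L4in + Resize(L5in))
    L3mid = Conv(L3in + Resize(L4mid))
    L2mid = Conv(L2in + Resize(L3mid))
    L1out = Conv(L1in + Resize(L2mid))
    L2out = Conv(L2in + L2mid + Resize(L1out))
    L3out = Conv(L3in + L3mid + Resize(L2out))
    L4out = Conv(L4in + L4mid + Resize(L3out))
    L5out = Conv(L5in + Resize(L4out))

Sums are plain (unweighted); each Conv is a depthwise-separable fusion block
(3×3 depthwise + 1×1 pointwise, batch norm and activation after each
convolution); Resize is a stride-2 bilinear upsample going coarse→fine and a
stride-2 max-pool going fine→coarse.
"""

from __future__ import annotations

from dataclasses import dataclass

from .backbones import FeaturePyramid
from .nn import MaxPool2d, Module, SeparableConvBlock, Upsample2x


@dataclass
class BifpnConfig:
    channels: int = 32
    repeats: int = 1
    upsample_mode: str = "bilinear"
    activation: str = "relu"


def fpn_topdown(p_in: list, convs: list, resize_up) -> list:
    """Reference one-way top-down aggregation.

    ``p_in`` is ordered fine→coarse; ``convs`` holds one callable per level;
    ``resize_up`` upsamples a coarser map onto the next finer grid. The
    coarsest output is ``Conv(p_top_in)``; every finer level is
    ``Conv(level_in + Resize(next_coarser_out))``.
    """
    if not p_in:
        raise ValueError("fpn_topdown requires at least one level")
    if len(convs) != len(p_in):
        raise ValueError(f"need {len(p_in)} convs, got {len(convs)}")
    out = [None] * len(p_in)
    out[-1] = convs[-1](p_in[-1])
    for i in range(len(p_in) - 2, -1, -1):
        out[i] = convs[i](p_in[i] + resize_up(out[i + 1]))
    return out


def bifpn_layer(f_in, convs: dict, resize_up, resize_down) -> list:
    """One bidirectional pass over exactly five levels (finest first).

    ``convs`` maps the node names {'mid4','mid3','mid2','out1'..'out5'} to
    callables; ``resize_up``/``resize_down`` move one octave finer/coarser.
    """
    levels = list(f_in)
    if len(levels) != 5:
        raise ValueError(f"the bidirectional pyramid is defined for exactly 5 levels, "
                         f"got {len(levels)}")
    l1, l2, l3, l4, l5 = levels
    m4 = convs["mid4"](l4 + resize_up(l5))
    m3 = convs["mid3"](l3 + resize_up(m4))
    m2 = convs["mid2"](l2 + resize_up(m3))
    o1 = convs["out1"](l1 + resize_up(m2))
    o2 = convs["out2"](l2 + m2 + resize_down(o1))
    o3 = convs["out3"](l3 + m3 + resize_down(o2))
    o4 = convs["out4"](l4 + m4 + resize_down(o3))
    o5 = convs["out5"](l5 + resize_down(o4))
    return [o1, o2, o3, o4, o5]


NODE_NAMES = ("mid4", "mid3", "mid2", "out1", "out2", "out3", "out4", "out5")


class BiFPNLayer(Module):
    """Learned five-level bidirectional pass with separable fusion convs."""

    def __init__(self, channels: int = 32, upsample_mode: str = "bilinear",
                 activation: str = "relu", rng=None):
        super().__init__()
        self.nodes = [SeparableConvBlock(channels, act=activation, rng=rng)
                      for _ in NODE_NAMES]
        self.up = Upsample2x(upsample_mode)
        self.down = MaxPool2d(2)

    def forward(self, pyramid) -> FeaturePyramid:
        levels = list(pyramid)
        convs = dict(zip(NODE_NAMES, self.nodes))
        return FeaturePyramid(bifpn_layer(levels, convs, self.up, self.down))


class BiFPN(Module):
    """``repeats`` stacked bidirectional passes (the paper-equivalent default is 1)."""

    def __init__(self, config: BifpnConfig | None = None, rng=None):
        super().__init__()
        self.config = config or BifpnConfig()
        self.layers = [
            BiFPNLayer(self.config.channels, self.config.upsample_mode,
                       self.config.activation, rng=rng)
            for _ in range(self.config.repeats)
        ]

    def forward(self, pyramid) -> FeaturePyramid:
        for layer in self.layers:
            pyramid = layer(pyramid)
        return pyramid


def depthwise_fuse(channels: int, activation: str = "relu", rng=None) -> SeparableConvBlock:
    """The fusion block: depthwise 3×3 then pointwise 1×1, BN + activation each."""
    return SeparableConvBlock(channels, act=activation, rng=rng)
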