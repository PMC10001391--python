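"""Cross-encoder fusion, attention-gated decoder and full model assembly.

The three per-encoder pyramids are merged level-by-level (channel concat
followed by a 1×1 convolution back to the pyramid width) into one global
pyramid. Its coarsest level is the decoder bottleneck; four UpAtt stages
then each (i) derive a gating signal from the coarser decoder feature,
(ii) rescale the skip level with an additive attention gate,
(iii) upsample ×2, concatenate and apply a double 3×3 convolution at 128
channels; a 1×1 convolution + batch norm + per-pixel softmax emits the
4-class probability map (background, necrotic core, edema/non-enhancing,
enhancing).

The attention coefficient follows the additive-attention reading

    alpha = sigmoid(psi(relu(Wx·x + Wg·g + bg)) + b_psi)

with Wx, Wg, psi all 1×1 channel-wise maps and alpha broadcast over the
skip's channels. Gate parameters use Xavier initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbones import (
    EncoderSpec,
    FeaturePyramid,
    LateralProjector,
    build_encoder,
    canonical_resolutions,
    encoder_tap_channels,
)
from .bifpn import BiFPN, BifpnConfig
from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvBNAct,
    Module,
    Tensor,
    Upsample2x,
    concat,
    no_grad,
)

N_CLASSES = 4

VARIANTS = (
    "vgg19+decoder",
    "resnet50+decoder",
    "mobilenetv2+decoder",
    "3encoder+decoder",
    "3encoder+attdecoder",
    "3encoder+bifpn+decoder",
    "3encoder+bifpn+attdecoder",
)
DEFAULT_VARIANT = "3encoder+bifpn+attdecoder"


@dataclass
class ModelConfig:
    variant: str = DEFAULT_VARIANT
    input_size: int = 224
    pyramid_channels: int = 32
    decoder_channels: int = 128
    attention_channels: int = 128
    encoder_width_mult: float = 1.0
    bifpn_repeats: int = 1
    fusion: str = "concat"           # or "sum"
    upsample_mode: str = "bilinear"
    pretrained: bool = False
    trainable_encoders: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}; "
                             f"expected one of {VARIANTS}")
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16 for a 5-level pyramid")
        if self.fusion not in ("concat", "sum"):
            raise ValueError(f"fusion must be 'concat' or 'sum', got {self.fusion!r}")


def tiny_config(variant: str = DEFAULT_VARIANT, seed: int = 0) -> ModelConfig:
    """Miniature profile (64×64 input, 8-channel pyramid) with identical topology."""
    return ModelConfig(variant=variant, input_size=64, pyramid_channels=8,
                       decoder_channels=16, attention_channels=16,
                       encoder_width_mult=1 / 8, seed=seed)


class PyramidFusion(Module):
    """Merge three same-shape pyramids into one global pyramid.

    'concat' mode concatenates the three C-channel maps per level (3C) and
    projects back to C with a 1×1 convolution; 'sum' averages them (kept as
    a config alternative).
    """

    def __init__(self, channels: int, n_inputs: int = 3, mode: str = "concat", rng=None):
        super().__init__()
        self.mode = mode
        self.n_inputs = n_inputs
        if mode == "concat":
            self.convs = [Conv2d(channels * n_inputs, channels, 1, rng=rng)
                          for _ in range(5)]
        else:
            self.convs = []

    def averaging_init(self):
        """Set each fusion conv to average its inputs (diagnostic initialisation)."""
        for conv in self.convs:
            w = conv.weight.data
            w[:] = 0.0
            c = w.shape[3]
            for k in range(self.n_inputs):
                w[0, 0, k * c + np.arange(c), np.arange(c)] = 1.0 / self.n_inputs
            if conv.bias is not None:
                conv.bias.data[:] = 0.0
        return self

    def forward(self, pyramids: list) -> FeaturePyramid:
        ref = pyramids[0]
        for p in pyramids[1:]:
            if [tuple(x.shape) for x in p] != [tuple(x.shape) for x in ref]:
                raise ValueError("encoder pyramids disagree in shape; cannot fuse")
        out = []
        for i in range(5):
            if self.mode == "concat":
                merged = self.convs[i](concat([p[i] for p in pyramids], axis=-1))
            else:
                merged = pyramids[0][i]
                for p in pyramids[1:]:
                    merged = merged + p[i]
                merged = merged / float(len(pyramids))
            out.append(merged)
        return FeaturePyramid(out)


class AttentionGate(Module):
    """Additive attention gate producing alpha in [0,1] per pixel."""

    def __init__(self, skip_ch: int, gate_ch: int, inter_ch: int = 128, rng=None):
        super().__init__()
        self.wx = Conv2d(skip_ch, inter_ch, 1, bias=False, init="xavier", rng=rng)
        self.wg = Conv2d(gate_ch, inter_ch, 1, bias=True, init="xavier", rng=rng)
        self.psi = Conv2d(inter_ch, 1, 1, bias=True, init="xavier", rng=rng)

    def forward(self, xl: Tensor, g: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (alpha, gated skip). ``g`` must already match ``xl`` spatially."""
        if g.shape[1:3] != xl.shape[1:3]:
            raise ValueError(f"gating signal {g.shape} not resized to skip {xl.shape}")
        alpha = self.psi((self.wx(xl) + self.wg(g)).relu()).sigmoid()
        return alpha, xl * alpha


class UpAttBlock(Module):
    """One decoder stage: attention on the skip, ×2 upsample, double conv.

    With ``attention=False`` the skip is concatenated raw (the plain-decoder
    ablation); the rest of the stage is unchanged.
    """

    def __init__(self, prev_ch: int, skip_ch: int, out_ch: int = 128,
                 attention_ch: int = 128, attention: bool = True,
                 upsample_mode: str = "bilinear", rng=None):
        super().__init__()
        self.attention = attention
        if attention:
            self.gate_conv = Conv2d(prev_ch, skip_ch, 1, rng=rng)
            self.gate_bn = BatchNorm2d(skip_ch)
            self.gate = AttentionGate(skip_ch, skip_ch, attention_ch, rng=rng)
        self.up = Upsample2x(upsample_mode)
        self.conv1 = ConvBNAct(prev_ch + skip_ch, out_ch, 3, rng=rng)
        self.conv2 = ConvBNAct(out_ch, out_ch, 3, rng=rng)
        self.last_alpha = None

    def forward(self, prev: Tensor, skip: Tensor) -> Tensor:
        if skip.shape[1] != 2 * prev.shape[1]:
            raise ValueError(f"skip resolution {skip.shape[1]} must be twice the "
                             f"decoder feature's {prev.shape[1]}")
        if self.attention:
            g = self.up(self.gate_bn(self.gate_conv(prev)))
            alpha, skip = self.gate(skip, g)
            self.last_alpha = alpha
        up = self.up(prev)
        return self.conv2(self.conv1(concat([up, skip], axis=-1)))


class OutputHead(Module):
    """1×1 convolution to 4 channels, batch norm, per-pixel softmax."""

    def __init__(self, in_ch: int, n_classes: int = N_CLASSES, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, n_classes, 1, rng=rng)
        self.bn = BatchNorm2d(n_classes)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).softmax(axis=-1)


class SegmentationModel(Module):
    """The assembled network: encoders → (BiFPN) → fusion → decoder → head."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = cfg = config or ModelConfig()
        rng = np.random.default_rng(cfg.seed)

        if cfg.variant.startswith("3encoder"):
            names = ["vgg19", "resnet50", "mobilenetv2"]
        else:
            names = [cfg.variant.split("+")[0]]
        self.encoder_names = names
        self.use_bifpn = "bifpn" in cfg.variant
        self.use_attention = "attdecoder" in cfg.variant

        self.encoders = [
            build_encoder(EncoderSpec(n, pretrained=cfg.pretrained,
                                      trainable=cfg.trainable_encoders,
                                      width_mult=cfg.encoder_width_mult), rng=rng)
            for n in names
        ]
        self.projectors = [
            LateralProjector(encoder_tap_channels(n, cfg.encoder_width_mult),
                             cfg.pyramid_channels, cfg.input_size,
                             cfg.upsample_mode, rng=rng)
            for n in names
        ]
        if self.use_bifpn:
            self.bifpns = [
                BiFPN(BifpnConfig(cfg.pyramid_channels, cfg.bifpn_repeats,
                                  cfg.upsample_mode), rng=rng)
                for _ in names
            ]
        else:
            self.bifpns = []
        if len(names) > 1:
            self.fusion = PyramidFusion(cfg.pyramid_channels, len(names),
                                        cfg.fusion, rng=rng)
        else:
            self.fusion = None

        c = cfg.pyramid_channels
        d = cfg.decoder_channels
        self.decoder = [
            UpAttBlock(c, c, d, cfg.attention_channels, self.use_attention,
                       cfg.upsample_mode, rng=rng),
            UpAttBlock(d, c, d, cfg.attention_channels, self.use_attention,
                       cfg.upsample_mode, rng=rng),
            UpAttBlock(d, c, d, cfg.attention_channels, self.use_attention,
                       cfg.upsample_mode, rng=rng),
            UpAttBlock(d, c, d, cfg.attention_channels, self.use_attention,
                       cfg.upsample_mode, rng=rng),
        ]
        self.head = OutputHead(d, N_CLASSES, rng=rng)

    # -- forward passes -------------------------------------------------------

    def encode(self, x: Tensor) -> tuple[list[FeaturePyramid], FeaturePyramid]:
        """Per-encoder enriched pyramids and the fused global pyramid."""
        pyramids = []
        for i, (encoder, projector) in enumerate(zip(self.encoders, self.projectors)):
            p = projector(encoder(x))
            if self.use_bifpn:
                p = self.bifpns[i](p)
            pyramids.append(p)
        fused = self.fusion(pyramids) if self.fusion is not None else pyramids[0]
        return pyramids, fused

    def forward(self, x) -> Tensor:
        x = Tensor.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.config.input_size or x.shape[3] != 3:
            raise ValueError(f"expected (N, {self.config.input_size}, "
                             f"{self.config.input_size}, 3) input, got {x.shape}")
        _, fused = self.encode(x)
        feat = fused[4]  # bottleneck: coarsest fused level
        for block, skip_idx in zip(self.decoder, (3, 2, 1, 0)):
            feat = block(feat, fused[skip_idx])
        self.last_decoder_feature = feat
        return self.head(feat)

    def predict_labels(self, x) -> np.ndarray:
        """Argmax class map (internal codes {0..3}) under inference mode."""
        self.eval()
        with no_grad():
            probs = self.forward(x)
        return probs.data.argmax(axis=-1)

    def shape_report(self, batch: int = 1) -> dict:
        """Forward a random batch and report every pyramid-contract shape."""
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(batch, self.config.input_size,
                                    self.config.input_size, 3)).astype(np.float32))
        self.eval()
        with no_grad():
            pyramids, fused = self.encode(x)
            feat = fused[4]
            for block, skip_idx in zip(self.decoder, (3, 2, 1, 0)):
                feat = block(feat, fused[skip_idx])
            out = self.head(feat)
        return {
            "input": tuple(x.shape),
            "encoder_pyramids": {name: p.shapes for name, p in
                                 zip(self.encoder_names, pyramids)},
            "fused_pyramid": fused.shapes,
            "decoder_output": tuple(feat.shape),
            "output": tuple(out.shape),
        }


def build_model(config: ModelConfig | dict | None = None) -> SegmentationModel:
    """Build any ablation variant; the full method is the default."""
    if isinstance(config, dict):
        config = ModelConfig(**config)
    return SegmentationModel(config)
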