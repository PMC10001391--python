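"""Cross-encoder fusion, attention gating, decoder stages and full assembly."""

import numpy as np
import pytest

from brainseg.backbones import FeaturePyramid
from brainseg.model import (
    AttentionGate,
    ModelConfig,
    OutputHead,
    PyramidFusion,
    UpAttBlock,
    VARIANTS,
    build_model,
    tiny_config,
)
from brainseg.nn import Adam, Tensor, no_grad


def _pyramid(rng, base=32, channels=4, batch=1):
    return FeaturePyramid([Tensor(rng.normal(
        size=(batch, base // 2**i, base // 2**i, channels)).astype(np.float32))
        for i in range(5)])


class TestPyramidFusion:
    def test_averaging_init_reproduces_single_input(self, rng):
        fusion = PyramidFusion(channels=4).averaging_init()
        p = _pyramid(rng)
        with no_grad():
            fused = fusion([p, p, p])
        for got, expected in zip(fused, p):
            assert np.allclose(got.data, expected.data, atol=1e-5)

    def test_zero_inputs_zero_output(self):
        fusion = PyramidFusion(channels=4)
        for conv in fusion.convs:
            conv.bias.data[:] = 0.0
        zeros = FeaturePyramid([Tensor(np.zeros((1, 32 // 2**i, 32 // 2**i, 4),
                                                np.float32)) for i in range(5)])
        with no_grad():
            fused = fusion([zeros, zeros, zeros])
        for level in fused:
            assert np.all(level.data == 0)

    def test_shape_mismatch_rejected(self, rng):
        fusion = PyramidFusion(channels=4)
        with pytest.raises(ValueError, match="disagree"):
            fusion([_pyramid(rng, base=32), _pyramid(rng, base=32),
                    _pyramid(rng, base=16)])

    def test_sum_mode_averages(self, rng):
        fusion = PyramidFusion(channels=4, mode="sum")
        p = _pyramid(rng)
        with no_grad():
            fused = fusion([p, p, p])
        for got, expected in zip(fused, p):
            assert np.allclose(got.data, expected.data, atol=1e-6)


class TestAttentionGate:
    def test_alpha_in_unit_interval(self, rng):
        gate = AttentionGate(4, 4, inter_ch=8)
        x = Tensor(rng.normal(size=(2, 8, 8, 4)).astype(np.float32))
        g = Tensor(rng.normal(size=(2, 8, 8, 4)).astype(np.float32))
        alpha, gated = gate(x, g)
        assert alpha.data.min() >= 0.0 and alpha.data.max() <= 1.0
        assert gated.shape == x.shape

    def test_zero_psi_gives_half_gate(self, rng):
        """psi ≡ 0 makes the pre-sigmoid logit 0, so alpha = 0.5 and the
        gated skip is exactly half the input."""
        gate = AttentionGate(4, 4, inter_ch=8)
        gate.psi.weight.data[:] = 0.0
        gate.psi.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 8, 8, 4)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 8, 4)).astype(np.float32))
        alpha, gated = gate(x, g)
        assert np.allclose(alpha.data, 0.5, atol=1e-6)
        assert np.allclose(gated.data, 0.5 * x.data, atol=1e-6)

    def test_output_over_input_equals_alpha(self, rng):
        gate = AttentionGate(4, 4, inter_ch=8)
        x = Tensor(rng.uniform(0.5, 1.5, size=(1, 8, 8, 4)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 8, 4)).astype(np.float32))
        alpha, gated = gate(x, g)
        assert np.allclose(gated.data / x.data, np.broadcast_to(
            alpha.data, x.shape), atol=1e-5)

    def test_strongly_negative_bias_suppresses_skip(self, rng):
        gate = AttentionGate(4, 4, inter_ch=8)
        gate.psi.bias.data[:] = -50.0
        x = Tensor(rng.normal(size=(1, 8, 8, 4)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 8, 4)).astype(np.float32))
        alpha, gated = gate(x, g)
        assert alpha.data.max() < 1e-6
        assert np.abs(gated.data).max() < 1e-5

    def test_unresized_gating_signal_rejected(self, rng):
        gate = AttentionGate(4, 4, inter_ch=8)
        x = Tensor(rng.normal(size=(1, 8, 8, 4)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError, match="resized"):
            gate(x, g)


class TestUpAttBlock:
    def test_doubles_resolution_to_decoder_channels(self, rng):
        block = UpAttBlock(prev_ch=4, skip_ch=4, out_ch=16, attention_ch=8)
        prev = Tensor(rng.normal(size=(1, 14, 14, 4)).astype(np.float32))
        skip = Tensor(rng.normal(size=(1, 28, 28, 4)).astype(np.float32))
        with no_grad():
            out = block(prev, skip)
        assert out.shape == (1, 28, 28, 16)

    def test_four_chained_stages_reach_input_resolution(self, rng):
        blocks = [UpAttBlock(4 if i == 0 else 16, 4, 16, 8) for i in range(4)]
        feat = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        with no_grad():
            for i, block in enumerate(blocks):
                size = 8 * 2**i
                skip = Tensor(rng.normal(size=(1, size, size, 4)).astype(np.float32))
                feat = block(feat, skip)
        assert feat.shape == (1, 64, 64, 16)

    def test_resolution_mismatch_rejected(self, rng):
        block = UpAttBlock(4, 4, 16, 8)
        prev = Tensor(rng.normal(size=(1, 14, 14, 4)).astype(np.float32))
        with pytest.raises(ValueError, match="twice"):
            block(prev, Tensor(rng.normal(size=(1, 56, 56, 4)).astype(np.float32)))

    def test_attention_parameters_train(self, rng):
        """One optimizer step on a toy objective moves Wx, Wg and psi."""
        block = UpAttBlock(4, 4, 16, 8)
        gate = block.gate
        before = [gate.wx.weight.data.copy(), gate.wg.weight.data.copy(),
                  gate.psi.weight.data.copy()]
        opt = Adam(block.parameters(), lr=1e-2)
        prev = Tensor(rng.normal(size=(2, 8, 8, 4)).astype(np.float32))
        skip = Tensor(rng.normal(size=(2, 16, 16, 4)).astype(np.float32))
        out = block(prev, skip)
        (out * out).mean().backward()
        opt.step()
        after = [gate.wx.weight.data, gate.wg.weight.data, gate.psi.weight.data]
        for b, a in zip(before, after):
            assert not np.array_equal(b, a)


class TestOutputHead:
    def test_four_channel_softmax(self, rng):
        head = OutputHead(16)
        x = Tensor(rng.normal(size=(2, 16, 16, 16)).astype(np.float32))
        head.eval()
        with no_grad():
            out = head(x)
        assert out.shape == (2, 16, 16, 4)
        assert np.allclose(out.data.sum(axis=-1), 1.0, atol=1e-5)
        labels = out.data.argmax(axis=-1)
        assert set(np.unique(labels)) <= {0, 1, 2, 3}


class TestBuildModel:
    def test_default_variant_is_full_method(self):
        model = build_model(tiny_config())
        assert model.config.variant == "3encoder+bifpn+attdecoder"
        assert model.use_bifpn and model.use_attention
        assert model.encoder_names == ["vgg19", "resnet50", "mobilenetv2"]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ModelConfig(variant="4encoder+bifpn")

    def test_tiny_profile_resolutions(self):
        model = build_model(tiny_config())
        report = model.shape_report()
        assert [s[1] for s in report["fused_pyramid"]] == [64, 32, 16, 8, 4]
        assert report["output"] == (1, 64, 64, 4)

    def test_attention_suppression_keeps_softmax_valid(self, rng):
        """Driving every gate bias strongly negative zeroes the skips but the
        model still emits a proper probability map."""
        model = build_model(tiny_config())
        for block in model.decoder:
            block.gate.psi.bias.data[:] = -1e4
        x = rng.normal(size=(2, 64, 64, 3)).astype(np.float32)
        model.train()
        with no_grad():
            out = model(Tensor(x))
        for block in model.decoder:
            assert block.last_alpha.data.max() < 1e-6
        assert np.allclose(out.data.sum(axis=-1), 1.0, atol=1e-5)
        assert np.isfinite(out.data).all()


@pytest.mark.parametrize("variant", VARIANTS)
def test_every_ablation_variant_steps_and_reduces_loss(variant, tiny_pairs):
    """Each build configuration completes a training step on a 2-sample toy
    batch without error and its dice loss goes down."""
    from brainseg.training import dice_loss, one_hot

    model = build_model(tiny_config(variant=variant, seed=3))
    X = np.stack([p[0].pixels for p in tiny_pairs[:2]]).astype(np.float32)
    G = Tensor(one_hot(np.stack([p[1].labels for p in tiny_pairs[:2]])))
    opt = Adam(model.parameters(), lr=2e-3)
    model.train()
    first = dice_loss(model(Tensor(X)), G)
    opt.zero_grad()
    first.backward()
    opt.step()
    second = dice_loss(model(Tensor(X)), G)
    assert second.item() < first.item()
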