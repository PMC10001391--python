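"""Assemble the full segmentation network and verify its shape contract.

Three encoders (VGG-19, ResNet50, MobileNetV2) each feed a five-level
bidirectional feature pyramid at 32 channels; the pyramids are fused and
decoded by four attention-gated UpAtt stages at 128 channels into a
224×224×4 per-pixel softmax. This script builds the miniature profile
(64×64 input, same topology) for speed; pass --full for the 224 network.
"""

import sys

from brainseg import ModelConfig, build_model, tiny_config

full = "--full" in sys.argv
config = ModelConfig() if full else tiny_config()
model = build_model(config)
print(f"variant: {config.variant}  input: {config.input_size}  "
      f"parameters: {model.num_parameters():,}")

report = model.shape_report(batch=1)
print("input:", report["input"])
for name, shapes in report["encoder_pyramids"].items():
    print(f"{name:>12} + BiFPN:", [s[1:] for s in shapes])
print("fused pyramid:  ", [s[1:] for s in report["fused_pyramid"]])
print("decoder output: ", report["decoder_output"][1:])
print("softmax output: ", report["output"][1:])
print("Every pyramid level halves resolution and keeps a uniform channel "
      "count; the decoder returns to input resolution.")
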