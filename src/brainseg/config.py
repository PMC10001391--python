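"""YAML pipeline configuration and the per-run reproducibility manifest."""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field

import yaml

from .model import ModelConfig
from .training import TrainConfig


class ConfigError(ValueError):
    pass


#: allowed keys per section (schema of the pipeline config file)
_SCHEMA = {
    "model": {"variant", "input_size", "pyramid_channels", "decoder_channels",
              "attention_channels", "encoder_width_mult", "bifpn_repeats",
              "fusion", "upsample_mode", "pretrained", "trainable_encoders", "seed"},
    "train": {"alpha0", "epochs", "batch_size", "split_ratios", "seed", "loss"},
    "preprocess": {"slice_index", "target", "sigma"},
    "phantom": {"shape", "n_cases", "noise_std", "seed"},
}


@dataclass
class PipelineConfig:
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)

    def model_config(self) -> ModelConfig:
        return ModelConfig(**self.model)

    def train_config(self) -> TrainConfig:
        kwargs = dict(self.train)
        if "split_ratios" in kwargs:
            kwargs["split_ratios"] = tuple(kwargs["split_ratios"])
        return TrainConfig(**kwargs)


def validate_config(raw: dict) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    bad_sections = set(raw) - set(_SCHEMA)
    if bad_sections:
        raise ConfigError(f"unknown config section(s): {sorted(bad_sections)}")
    for section, keys in raw.items():
        if keys is None:
            raw[section] = {}
            continue
        unknown = set(keys) - _SCHEMA[section]
        if unknown:
            raise ConfigError(
                f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    return PipelineConfig(**{k: raw.get(k, {}) or {} for k in _SCHEMA})


def load_config(path: str | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def write_manifest(out_dir: str, command: str, config: PipelineConfig,
                   seed: int, inputs: dict | None = None,
                   outputs: dict | None = None) -> str:
    """Write the run manifest JSON; one per CLI run."""
    from . import __version__

    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": asdict(config),
        "inputs": inputs or {},
        "outputs": outputs or {},
    }
    path = os.path.join(out_dir, f"manifest_{command}.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
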