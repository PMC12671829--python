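"""Single-YAML configuration: model / augment / synthetic / train blocks.

Any block or key may be omitted; omitted keys take the frozen defaults
(the calibrated architecture and the published training recipe)."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .backbone import ModelSpec
from .datapipe import AugmentConfig, SyntheticConfig
from .train import TrainConfig

__all__ = ["default_config", "load_config", "parse_config", "save_config"]


def default_config() -> dict:
    return {
        "model": ModelSpec().to_dict(),
        "augment": asdict(AugmentConfig()),
        "synthetic": asdict(SyntheticConfig()),
        "train": asdict(TrainConfig()),
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown config key: {key}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value)
        else:
            out[key] = value
    return out


def parse_config(raw: dict | None) -> dict:
    """Merge a (possibly partial) raw dict onto the defaults and build the
    typed config objects."""
    merged = _merge(default_config(), raw or {})
    aug = dict(merged["augment"])
    for key in ("crop_scale", "crop_aspect", "occlusion_area",
                "occlusion_fill", "mean", "std"):
        aug[key] = tuple(aug[key])
    return {
        "model": ModelSpec.from_dict(merged["model"]),
        "augment": AugmentConfig(**aug),
        "synthetic": SyntheticConfig(**merged["synthetic"]),
        "train": TrainConfig(**merged["train"]),
    }


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return parse_config(None)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def save_config(config: dict, path: str | Path) -> None:
    out = {
        "model": config["model"].to_dict(),
        "augment": asdict(config["augment"]),
        "synthetic": asdict(config["synthetic"]),
        "train": asdict(config["train"]),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
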