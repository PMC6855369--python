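"""Run configuration: one structured file driving the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .localize import SweepGrid
from .nn.train import TrainConfig
from .nn.unet import NetworkConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full experiment needs, with the protocol's fixed
    settings as defaults: 144-px central crop, label radius up to 3,
    50 epochs, 2-px free zone."""

    modality: str = "confocal"
    crop_size: int = 144
    label_radius: int = 3
    augment_rotations: bool = True
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sweep: SweepGrid = field(default_factory=SweepGrid)
    match_distance: float = 4.0
    free_zone_pad: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("confocal", "split_detector"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.label_radius not in (0, 1, 2, 3):
            raise ValueError("label_radius must be in 0..3")
        if self.free_zone_pad < 0:
            raise ValueError("free_zone_pad must be >= 0")
        if self.crop_size % (2**self.network.depth) != 0:
            raise ValueError("crop_size must be divisible by 2^network.depth")
        if self.modality == "split_detector" and self.augment_rotations:
            raise ValueError(
                "rotational augmentation is only valid for the confocal modality"
            )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run configuration; keyword overrides win."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    for key, cls in (("network", NetworkConfig), ("train", TrainConfig),
                     ("sweep", SweepGrid)):
        if key in raw and isinstance(raw[key], dict):
            sub = raw[key]
            if cls is SweepGrid:
                sub = {k: tuple(v) for k, v in sub.items()}
            raw[key] = cls(**sub)
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
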