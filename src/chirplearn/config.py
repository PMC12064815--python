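"""Run configuration: YAML file + flag overrides, validation, manifests.

Precedence: explicit flag overrides > config file values > defaults.
Every run writes a JSON manifest with the fully resolved configuration and
seeds so any experiment is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .augment import AugmentationConfig
from .frontend import PRESETS
from .transfer import DistillationConfig, STRATEGIES, TrainConfig

__all__ = ["RunConfig", "load_run_config", "write_manifest"]


@dataclass
class RunConfig:
    frontend_preset: str = "tiny"
    strategy: str = "shallow_finetune"
    mode: str = "single"              # single | multi
    use_secondary: bool = False
    seed: int = 0
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    augment: bool = False
    mixup_prob: float = 0.6
    noise_prob: float = 0.5
    lam_weight: float = 0.5
    temperature: float = 1.0
    vocabulary_path: str = ""
    data_dir: str = ""
    output_dir: str = "runs"

    def validate(self) -> None:
        if self.frontend_preset not in PRESETS:
            raise ValueError(
                f"unknown front-end preset {self.frontend_preset!r}; "
                f"choose one of {sorted(PRESETS)}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; "
                             f"choose one of {STRATEGIES}")
        if self.mode not in ("single", "multi"):
            raise ValueError(f"mode must be 'single' or 'multi', got {self.mode!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    def train_config(self) -> TrainConfig:
        aug = None
        if self.augment:
            aug = AugmentationConfig(mixup_prob=self.mixup_prob,
                                     noise_prob=self.noise_prob,
                                     rng_seed=self.seed)
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           learning_rate=self.learning_rate, seed=self.seed,
                           augmentation=aug, multi_label=self.mode == "multi")

    def distill_config(self) -> DistillationConfig:
        if self.mode == "multi":
            return DistillationConfig(self.lam_weight, self.temperature,
                                      "binary_cross_entropy",
                                      "binary_cross_entropy")
        return DistillationConfig(self.lam_weight, self.temperature,
                                  "cross_entropy", "kl_divergence")


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a validated RunConfig from an optional YAML file plus overrides."""
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**values)
    cfg.validate()
    return cfg


def write_manifest(path: str | Path, cfg: RunConfig, extra: dict | None = None) -> None:
    payload = {"run_config": asdict(cfg)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
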