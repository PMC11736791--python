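"""Run configuration: YAML parsing with strict keys and lossless round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig

__all__ = ["RunConfig", "parse_config", "write_config"]


@dataclass
class RunConfig:
    """Command-facing configuration mirroring the training, model,
    fine-tuning and fixture parameter sets. Defaults follow the reference
    configuration (batch 64, learning rate 5e-5, 100 epochs, patience 5,
    2 heads, latent 768, pooling stride 3, decoder width 512)."""

    seed: int | None = None
    out_dir: str = "runs/run"
    arch: str = "bcn"
    task: str = "regression"
    # training
    batch_size: int = 64
    learning_rate: float = 5e-5
    max_epochs: int = 100
    patience: int = 5
    folds: int = 5
    bootstrap_iterations: int = 100
    # model
    d_model: int = 128
    n_layers: int = 3
    heads: int = 2
    latent: int = 768
    stride: int = 3
    ffn_hidden: int = 512
    decoder_hidden: int = 512
    # fine-tuning
    strategy: str = "lora"
    lora_rank: int = 4
    lora_scale: float = 1.0
    # augmentation
    triad_positions: list[int] = field(default_factory=lambda: [105, 187, 224])
    min_distance: float = 20.0
    mutations_per_position: int = 8
    # fixtures
    n_residues: int = 30
    n_proteins: int = 12
    n_samples: int = 300
    effect_size: float = 2.0
    noise_sd: float = 0.5

    def __post_init__(self):
        if self.latent % self.stride != 0:
            raise ValueError(f"latent size {self.latent} not divisible by "
                             f"pooling stride {self.stride}")

    def model_config(self) -> ModelConfig:
        return ModelConfig(arch=self.arch, task=self.task, d_model=self.d_model,
                           n_layers=self.n_layers, heads=self.heads,
                           bcn_latent=self.latent, bcn_stride=self.stride,
                           ffn_hidden=self.ffn_hidden,
                           decoder_hidden=self.decoder_hidden)

    def train_config(self) -> TrainConfig:
        if self.seed is None:
            raise ValueError("a master seed is required")
        return TrainConfig(batch_size=self.batch_size,
                           learning_rate=self.learning_rate,
                           max_epochs=self.max_epochs, patience=self.patience,
                           folds=self.folds, seed=self.seed)


def parse_config(path: str | Path) -> RunConfig:
    """Parse a YAML key/value file; unknown keys and type mismatches are
    rejected by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of keys to values")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys: {sorted(unknown)}")
    for f in fields(RunConfig):
        if f.name in raw and raw[f.name] is not None:
            value = raw[f.name]
            if f.type in ("int", "int | None") and isinstance(value, bool):
                raise ValueError(f"{path}: key {f.name!r} has wrong type")
            if f.type == "int" and not isinstance(value, int):
                raise ValueError(f"{path}: key {f.name!r} must be an integer, "
                                 f"got {type(value).__name__}")
    return RunConfig(**raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
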