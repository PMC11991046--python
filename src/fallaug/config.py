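"""Run configuration: seeds, augmenter choice, hyperparameters, paths.

A :class:`RunConfig` is the single source of truth for one experiment.
All randomness flows from ``seed`` through :func:`child_seed`, which
derives independent per-stage integer seeds (kept below 2**31) from the
master seed and a stage name, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

AUGMENTER_NAMES = ("BL", "DTF", "SMOTE", "AE", "VAE", "DM")

#: (subject, activity, trial) triples dropped by the reader; the known
#: corrupted trials of the target public dataset.
DEFAULT_EXCLUSIONS = ((8, 11, 2), (8, 11, 3))

#: default column mapping for wrist-IMU CSV logs
DEFAULT_COLUMNS = {
    "subject": "subject", "activity": "activity", "trial": "trial",
    "timestamp": "timestamp",
    "channels": ["acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"],
}


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class TrainHyper:
    """Optimizer settings for one trainable component."""

    lr: float = 3e-4
    epochs: int = 100
    batch_size: int = 64

    def __post_init__(self):
        if self.lr <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass
class RunConfig:
    seed: int = 0
    real_fraction: float = 1.0
    synthetic_multiplier: float = 1.0
    augmenter_name: str = "BL"
    n_groups: int = 4
    # per-component training settings (tuned defaults of the study design)
    ae: TrainHyper = field(default_factory=lambda: TrainHyper(lr=3e-4, epochs=100))
    vae: TrainHyper = field(default_factory=lambda: TrainHyper(lr=5e-4, epochs=100))
    ddpm: TrainHyper = field(default_factory=lambda: TrainHyper(lr=3e-4, epochs=300))
    detector: TrainHyper = field(default_factory=lambda: TrainHyper(lr=3e-4, epochs=300))
    timesteps: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    unet_width: int = 64
    smote_k: int = 5
    smote_seed: int = 42
    dropout: float = 0.5
    fc_hidden: int = 128
    latent_jitter_sd: float = 0.1
    exclusions: tuple = DEFAULT_EXCLUSIONS
    columns: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    out_dir: str = "runs"

    def __post_init__(self):
        if self.augmenter_name not in AUGMENTER_NAMES:
            raise ValueError(
                f"unknown augmenter {self.augmenter_name!r}; valid: {AUGMENTER_NAMES}")
        if not (0.0 < self.real_fraction <= 1.0):
            raise ValueError("real_fraction must be in (0, 1]")
        if self.synthetic_multiplier < 0:
            raise ValueError("synthetic_multiplier must be nonnegative")
        if self.timesteps <= 0 or self.unet_width <= 0 or self.smote_k < 1:
            raise ValueError("hyperparameters must be positive")

    def with_tiny_profile(self) -> "RunConfig":
        """Scaled-down settings suitable for laptop-class smoke runs."""
        cfg = RunConfig(**{**asdict_shallow(self)})
        cfg.timesteps = 100
        # beta_end chosen so the T=100 chain keeps the same terminal
        # signal retention (alpha_bar_T < 0.01) as the T=1000 default
        cfg.beta_end = 0.1
        cfg.unet_width = 32
        cfg.ae = TrainHyper(lr=3e-4, epochs=20)
        cfg.vae = TrainHyper(lr=5e-4, epochs=20)
        # small batches trade batch-gradient quality for optimizer steps,
        # which the small per-fold window counts make the binding resource
        cfg.ddpm = TrainHyper(lr=5e-4, epochs=600, batch_size=16)
        cfg.detector = TrainHyper(lr=3e-4, epochs=40)
        return cfg

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("ae", "vae", "ddpm", "detector"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = TrainHyper(**raw[key])
        if "exclusions" in raw:
            raw["exclusions"] = tuple(tuple(t) for t in raw["exclusions"])
        return cls(**raw)


def asdict_shallow(cfg: RunConfig) -> dict:
    out = dict(cfg.__dict__)
    return out
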