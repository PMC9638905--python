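"""Configuration objects for the model, the training loop and the simulator.

Defaults correspond to the pan-cancer analysis scale (embedding 512, attention
size 256, 8 heads, dropout 0.2); desk-scale runs on simulated cohorts pass
smaller values explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the encoder-decoder network."""

    embedding_dim: int = 512
    attention_size: int = 256
    attention_heads: int = 8
    dropout: float = 0.2
    max_alterations: int = 1000
    activation: str = "tanh"  # tanh | relu for the TF layer

    def __post_init__(self) -> None:
        if self.attention_heads < 1:
            raise ValueError("attention_heads must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in ("tanh", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class TrainConfig:
    """Optimisation protocol.

    ``patience`` and ``warmup_evals`` count validation evaluations (one per
    epoch); early stopping is never applied during the first ``warmup_evals``
    evaluations.
    """

    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 100
    patience: int = 30
    warmup_evals: int = 180
    max_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.patience > self.max_iterations:
            raise ValueError("patience must not exceed max_iterations")


@dataclass
class SimConfig:
    """Generative settings for synthetic cohorts with known ground truth.

    The default cohort (600 tumors, 400 expression genes, 30 TFs, 6 drivers,
    driver->TF effect 1.5, expression noise sd 0.5) is the reference condition
    used throughout the test suite.
    """

    n_tumors: int = 600
    n_genes: int = 400
    n_alteration_genes: int = 1000
    n_tfs: int = 30
    n_cancer_types: int = 3
    n_drivers: int = 6
    driver_frequency: Tuple[float, float] = (0.15, 0.40)
    background_density: float = 0.01
    prior_density: float = 0.10
    effect_size: float = 1.5
    tfs_per_driver: int = 3
    cancer_type_sd: float = 1.0
    noise_sd: float = 0.5
    min_alteration_frequency: float = 0.04
    misspecify: bool = False
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_drivers > self.n_alteration_genes:
            raise ValueError("more drivers than alteration genes")
        lo, hi = self.driver_frequency
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("driver_frequency range must satisfy 0 < lo <= hi < 1")
        for name in ("background_density", "prior_density"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


def load_yaml(path: str | Path, cls):
    """Instantiate a config dataclass from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return cls(**raw)


def dump_yaml(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
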