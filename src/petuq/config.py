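"""YAML run configuration.

Schema (all keys optional; defaults follow the training protocol):

    train:
      epochs: 200
      snapshots: 50        # N, the posterior sample size
      lr: 5.0e-4
      weight_decay: 1.0e-10
      batch_size: 64
      seed: 0
    scheduler:
      factor: 0.1
      patience: 10
    noise:
      enabled: true
      track_lr: current    # noise std follows the current or the initial lr
    loss:
      lambda_gm: 1.0
    model:
      widths: [32, 64, 128]
      leaky_slope: 0.01

The weight decay is applied inside the optimizer; gradient noise is added to
the loss gradient only, before the Adam moment updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .losses import LossConfig
from .model import Architecture
from .sgld_training import TrainConfig


@dataclass
class RunConfig:
    train: TrainConfig
    loss: LossConfig
    arch: Architecture


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML; ``overrides`` wins over file values."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for section, vals in overrides.items():
            raw.setdefault(section, {}).update(vals)

    t = raw.get("train", {})
    s = raw.get("scheduler", {})
    n = raw.get("noise", {})
    train = TrainConfig(
        epochs=int(t.get("epochs", 200)),
        snapshots=int(t.get("snapshots", 50)),
        lr=float(t.get("lr", 5e-4)),
        weight_decay=float(t.get("weight_decay", 1e-10)),
        batch_size=int(t.get("batch_size", 64)),
        scheduler_factor=float(s.get("factor", 0.1)),
        scheduler_patience=int(s.get("patience", 10)),
        seed=int(t.get("seed", 0)),
        noise_enabled=bool(n.get("enabled", True)),
        track_lr=str(n.get("track_lr", "current")),
    )
    loss = LossConfig(lambda_gm=float(raw.get("loss", {}).get("lambda_gm", 1.0)))
    m = raw.get("model", {})
    arch = Architecture(
        widths=tuple(m.get("widths", (32, 64, 128))),
        leaky_slope=float(m.get("leaky_slope", 0.01)),
        dropout_p=float(m.get("dropout_p", 0.0)),
        dtype=str(m.get("dtype", "float32")),
    )
    return RunConfig(train=train, loss=loss, arch=arch)
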