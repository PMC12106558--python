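"""Monte Carlo dropout benchmark.

The same residual U-Net with spatial dropout (p = 0.2) after each encoder
and decoder level activation, trained with the identical loop, schedule and
seed contract as the SGLD model but without gradient noise; only the final
epoch's weights are retained. Uncertainty comes from stochastic forward
passes at test time (see ``inference.ensemble_predict_dropout``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import LossConfig
from .model import Architecture, ReconModel
from .phantom_sim import DosePair
from .sgld_training import TrainConfig, run_training

DROPOUT_P = 0.2


@dataclass
class DropoutCheckpoint:
    """Final weights of the benchmark model plus what is needed to run it."""

    arch: Architecture
    arrays: list[np.ndarray]
    scale: float

    def build(self) -> ReconModel:
        model = ReconModel(self.arch, seed=0)
        model.load_state_arrays(self.arrays)
        return model

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {"arch": self.arch.to_dict(), "scale": self.scale, "version": 1}
        (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
        np.savez(out_dir / "final.npz", *self.arrays)

    @classmethod
    def load(cls, in_dir: str | Path) -> "DropoutCheckpoint":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "meta.json").read_text())
        with np.load(in_dir / "final.npz") as z:
            arrays = [z[k] for k in z.files]
        return cls(
            arch=Architecture.from_dict(meta["arch"]),
            arrays=arrays,
            scale=float(meta["scale"]),
        )


@dataclass
class DropoutTrainResult:
    checkpoint: DropoutCheckpoint
    history: pd.DataFrame


def dropout_architecture(base: Architecture | None = None) -> Architecture:
    """The benchmark architecture: the SGLD backbone with p=0.2 dropout."""
    base = base or Architecture()
    return Architecture(
        widths=base.widths,
        kernel=base.kernel,
        leaky_slope=base.leaky_slope,
        dropout_p=DROPOUT_P,
        dtype=base.dtype,
    )


def train_dropout(
    model: ReconModel,
    data: dict[str, list[DosePair]],
    cfg: TrainConfig,
    loss_cfg: LossConfig = LossConfig(),
    scale: float | None = None,
) -> DropoutTrainResult:
    """Train the dropout benchmark; keeps only the final epoch's weights."""
    if model.arch.dropout_p <= 0.0:
        raise ValueError("the benchmark model must have dropout probability > 0")
    result = run_training(
        model,
        data,
        cfg,
        loss_cfg,
        noise_enabled=False,
        n_snapshots=1,
        dropout_train=True,
        scale=scale,
    )
    _, arrays = result.buffer.snapshots[-1]
    checkpoint = DropoutCheckpoint(arch=model.arch, arrays=arrays, scale=result.scale)
    return DropoutTrainResult(checkpoint=checkpoint, history=result.history)
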