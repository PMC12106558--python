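"""SGLD-style Bayesian training of the reconstruction network.

Stochastic gradient Langevin dynamics is approximated by adding zero-mean
Gaussian noise to the loss gradients at every epoch before the Adam update;
the noise standard deviation s_t tracks the (plateau-scheduled) learning
rate. The weight vectors of the last N epochs are kept in a snapshot buffer
and act as an empirical sample from the posterior over network weights:
feeding one low-dose image through all N snapshots yields an ensemble of
reconstructions whose mean is the estimate and whose pixel-wise standard
deviation is the uncertainty map.

With noise disabled the loop reduces exactly to plain Adam training (the
Monte Carlo dropout benchmark reuses this same loop), which is exploited by
the equivalence tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .losses import LossConfig, total_loss
from .model import Architecture, ReconModel, pad_to_multiple
from .phantom_sim import DosePair


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes NaN; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (NaN loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the training protocol."""

    epochs: int = 200
    snapshots: int = 50
    lr: float = 5e-4
    weight_decay: float = 1e-10
    batch_size: int = 64
    scheduler_factor: float = 0.1
    scheduler_patience: int = 10
    seed: int = 0
    noise_enabled: bool = True
    track_lr: str = "current"  # noise std follows "current" or "initial" lr

    def __post_init__(self):
        if self.snapshots > self.epochs:
            raise ValueError("snapshot count cannot exceed epoch count")
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("rates and sizes must be positive")
        if self.track_lr not in ("current", "initial"):
            raise ValueError("track_lr must be 'current' or 'initial'")


@dataclass
class SnapshotBuffer:
    """The last N epoch-end weight vectors (the posterior sample)."""

    arch: Architecture
    scale: float
    capacity: int
    snapshots: list[tuple[int, list[np.ndarray]]] = field(default_factory=list)

    def append(self, epoch: int, arrays: list[np.ndarray]) -> None:
        self.snapshots.append((epoch, arrays))
        if len(self.snapshots) > self.capacity:
            raise RuntimeError("snapshot buffer overfilled")

    def __len__(self) -> int:
        return len(self.snapshots)

    def epochs(self) -> list[int]:
        return [e for e, _ in self.snapshots]

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "arch": self.arch.to_dict(),
            "scale": self.scale,
            "capacity": self.capacity,
            "epochs": self.epochs(),
            "version": 1,
        }
        (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
        for epoch, arrays in self.snapshots:
            np.savez(out_dir / f"snapshot_{epoch:04d}.npz", *arrays)

    @classmethod
    def load(cls, in_dir: str | Path) -> "SnapshotBuffer":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "meta.json").read_text())
        buf = cls(
            arch=Architecture.from_dict(meta["arch"]),
            scale=float(meta["scale"]),
            capacity=int(meta["capacity"]),
        )
        for epoch in meta["epochs"]:
            with np.load(in_dir / f"snapshot_{epoch:04d}.npz") as z:
                arrays = [z[k] for k in z.files]
            buf.append(int(epoch), arrays)
        return buf


@dataclass
class TrainResult:
    """Output of a training run."""

    buffer: SnapshotBuffer
    history: pd.DataFrame
    model: ReconModel
    scale: float


# ---------------------------------------------------------------------------
# optimizer and scheduler


class Adam:
    """Adam with coupled L2 weight decay (decay added to the gradient)."""

    def __init__(self, params, lr, weight_decay=0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without relative improvement of the monitored (validation) loss."""

    def __init__(self, optimizer: Adam, factor=0.1, patience=10, threshold=1e-4):
        self.optimizer = optimizer
        self.factor = float(factor)
        self.patience = int(patience)
        self.threshold = float(threshold)
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric: float) -> bool:
        """Returns True when a reduction fired."""
        if metric < self.best * (1.0 - self.threshold):
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad > self.patience:
            self.optimizer.lr *= self.factor
            self.num_bad = 0
            return True
        return False


# ---------------------------------------------------------------------------


def noisy_gradient(g_t, s_t: float, rng: np.random.Generator):
    """Add elementwise N(0, s_t^2) noise to a gradient collection.

    Accepts a single array or a list of arrays; ``s_t = 0`` returns the
    input unchanged (bit-identical).
    """
    if s_t < 0:
        raise ValueError("noise scale must be nonnegative")
    single = isinstance(g_t, np.ndarray)
    gs = [g_t] if single else list(g_t)
    if s_t == 0.0:
        return g_t
    out = [g + rng.normal(0.0, s_t, size=g.shape).astype(g.dtype) for g in gs]
    return out[0] if single else out


def _stack_pairs(
    pairs: list[DosePair], scale: float, dtype, factor: int = 1, min_side: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    shapes = {p.fd.image.shape for p in pairs}
    if len(shapes) != 1:
        raise ValueError("all images in a training set must share a shape")
    lds, fds = [], []
    for p in pairs:
        ld_p, _ = pad_to_multiple(p.ld / scale, factor, min_side)
        fd_p, _ = pad_to_multiple(p.fd.image / scale, factor, min_side)
        lds.append(ld_p)
        fds.append(fd_p)
    # NHWC with a single channel
    return (
        np.asarray(lds, dtype=dtype)[..., None],
        np.asarray(fds, dtype=dtype)[..., None],
    )


def normalization_scale(train_pairs: list[DosePair], q: float = 99.9) -> float:
    """Dataset-level intensity scale: the q-th percentile of training FD."""
    vals = np.concatenate([p.fd.image.ravel() for p in train_pairs])
    s = float(np.percentile(vals, q))
    if s <= 0:
        raise ValueError("degenerate training intensities; cannot normalize")
    return s


def run_training(
    model,
    data: dict[str, list[DosePair]],
    cfg: TrainConfig,
    loss_cfg: LossConfig = LossConfig(),
    *,
    noise_enabled: bool | None = None,
    n_snapshots: int | None = None,
    dropout_train: bool = False,
    scale: float | None = None,
) -> TrainResult:
    """Shared training loop for the SGLD model and the dropout benchmark.

    ``model`` must expose ``parameters()`` and ``forward(Tensor, ...)``; the
    per-epoch batch order and the gradient-noise draws come from independent
    child streams of ``cfg.seed``, so disabling noise does not perturb the
    batch order and runs are bit-reproducible.
    """
    train_pairs = data["train"]
    val_pairs = data.get("val") or train_pairs
    if not train_pairs:
        raise ValueError("training data is empty")
    noise_enabled = cfg.noise_enabled if noise_enabled is None else noise_enabled
    n_snapshots = cfg.snapshots if n_snapshots is None else n_snapshots

    arch = getattr(model, "arch", None)
    dtype = np.dtype(arch.dtype) if arch is not None else np.float64
    if scale is None:
        scale = normalization_scale(train_pairs)

    factor = int(getattr(model, "DOWN_FACTOR", 1))
    min_side = int(getattr(model, "MIN_SIDE", 0))
    train_ld, train_fd = _stack_pairs(train_pairs, scale, dtype, factor, min_side)
    val_ld, val_fd = _stack_pairs(val_pairs, scale, dtype, factor, min_side)

    ss = np.random.SeedSequence(cfg.seed)
    shuffle_ss, noise_ss, drop_ss = ss.spawn(3)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    noise_rng = np.random.default_rng(noise_ss)
    drop_rng = np.random.default_rng(drop_ss)

    params = model.parameters()
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, cfg.scheduler_factor, cfg.scheduler_patience)

    buffer = SnapshotBuffer(
        arch=arch if arch is not None else Architecture(),
        scale=scale,
        capacity=n_snapshots,
    )

    n = len(train_pairs)
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        s_t = opt.lr if cfg.track_lr == "current" else cfg.lr
        order = shuffle_rng.permutation(n)
        loss_sum = 0.0
        noise_n, noise_sum, noise_sq = 0, 0.0, 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = nn.Tensor(train_ld[idx])
            yb = nn.Tensor(train_fd[idx])
            with nn.buffer_reuse():
                nn.reset_slots()  # the previous step's graph is garbage here
                if dropout_train:
                    pred = model.forward(xb, train_mode=True, dropout_rng=drop_rng)
                else:
                    pred = model.forward(xb)
                loss = total_loss(pred, yb, loss_cfg)
                model.zero_grad()
                loss.backward()
                grads = [p.grad for p in params]
                if noise_enabled and s_t > 0:
                    noisy = []
                    for g in grads:
                        e = noise_rng.normal(0.0, s_t, size=g.shape).astype(g.dtype)
                        noise_n += e.size
                        noise_sum += float(e.sum())
                        noise_sq += float((e * e).sum())
                        noisy.append(g + e)
                    grads = noisy
                opt.step(grads)
            loss_sum += loss.item() * len(idx)
            pred = loss = grads = None
        train_loss = loss_sum / n
        if not np.isfinite(train_loss):
            raise TrainingDivergedError(epoch)

        with nn.no_grad(), nn.buffer_reuse():
            nn.reset_slots()
            val_pred = model.forward(nn.Tensor(val_ld))
            val_loss = float(total_loss(val_pred, nn.Tensor(val_fd), loss_cfg).item())
            val_pred = None

        if noise_n > 1:
            mean_e = noise_sum / noise_n
            noise_std = float(np.sqrt(max(noise_sq / noise_n - mean_e**2, 0.0)))
        else:
            noise_std = 0.0
        rows.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "s_t": s_t if noise_enabled else 0.0,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "noise_std": noise_std,
                "noise_n": noise_n,
            }
        )
        if epoch > cfg.epochs - n_snapshots:
            buffer.append(epoch, model.state_arrays())
        sched.step(val_loss)

    history = pd.DataFrame(rows)
    return TrainResult(buffer=buffer, history=history, model=model, scale=scale)


def train_sgld(
    model,
    data: dict[str, list[DosePair]],
    cfg: TrainConfig,
    loss_cfg: LossConfig = LossConfig(),
    scale: float | None = None,
) -> TrainResult:
    """SGLD training: noisy-gradient Adam with a last-N snapshot buffer."""
    arch = getattr(model, "arch", None)
    if arch is not None and arch.dropout_p != 0.0:
        raise ValueError("the SGLD model must have dropout probability 0")
    return run_training(model, data, cfg, loss_cfg, dropout_train=False, scale=scale)
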