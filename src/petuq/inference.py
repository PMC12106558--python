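"""Ensemble inference: posterior-mean reconstruction and uncertainty map.

One low-dose image is pushed through every weight snapshot (SGLD posterior
sample) or through N stochastic dropout passes; the resulting ensemble is
reduced to its pixel-wise mean (the reconstruction) and pixel-wise
population standard deviation (the uncertainty map), both reported in
original intensity units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ReconModel, build_model
from .sgld_training import SnapshotBuffer


@dataclass
class PosteriorEnsemble:
    """N reconstructed images for one low-dose input, in original units."""

    samples: list[np.ndarray]
    source: str  # "sgld" | "dropout"
    input_id: str = ""

    def __post_init__(self):
        if not self.samples:
            raise ValueError("ensemble must contain at least one sample")
        shapes = {s.shape for s in self.samples}
        if len(shapes) != 1:
            raise ValueError("ensemble samples must share a shape")


@dataclass
class ReconResult:
    """Posterior mean image and pixel-wise std uncertainty map."""

    mean_image: np.ndarray
    std_map: np.ndarray
    n_samples: int


def ensemble_predict_sgld(
    buffer: SnapshotBuffer, ld: np.ndarray, input_id: str = ""
) -> PosteriorEnsemble:
    """One deterministic forward pass per weight snapshot (dropout off)."""
    if len(buffer) == 0:
        raise ValueError("snapshot buffer is empty")
    model = build_model(buffer.arch, seed=0)
    ld_norm = np.asarray(ld, dtype=float) / buffer.scale
    samples = []
    for _, arrays in buffer.snapshots:
        try:
            model.load_state_arrays(arrays)
        except ValueError as exc:
            raise ValueError(f"snapshot/architecture mismatch: {exc}") from exc
        samples.append(model.predict(ld_norm).astype(float) * buffer.scale)
    return PosteriorEnsemble(samples=samples, source="sgld", input_id=input_id)


def ensemble_predict_dropout(
    model: ReconModel,
    ld: np.ndarray,
    n: int,
    seed: int,
    scale: float = 1.0,
    input_id: str = "",
) -> PosteriorEnsemble:
    """N stochastic forward passes with dropout sampling active."""
    if model.arch.dropout_p <= 0.0:
        raise ValueError("dropout ensemble requires dropout probability > 0")
    if n < 1:
        raise ValueError("need at least one forward pass")
    rng = np.random.default_rng(seed)
    ld_norm = np.asarray(ld, dtype=float) / scale
    samples = [
        model.predict(ld_norm, train_mode=True, dropout_rng=rng).astype(float) * scale
        for _ in range(n)
    ]
    return PosteriorEnsemble(samples=samples, source="dropout", input_id=input_id)


def ensemble_predict_sgld_batch(
    buffer: SnapshotBuffer, lds: list[np.ndarray], input_ids: list[str] | None = None
) -> list[PosteriorEnsemble]:
    """SGLD ensembles for many same-shaped images, batched per snapshot."""
    if len(buffer) == 0:
        raise ValueError("snapshot buffer is empty")
    input_ids = input_ids or [""] * len(lds)
    model = build_model(buffer.arch, seed=0)
    stack = np.asarray(lds, dtype=float) / buffer.scale
    per_image: list[list[np.ndarray]] = [[] for _ in lds]
    for _, arrays in buffer.snapshots:
        model.load_state_arrays(arrays)
        preds = model.predict_batch(stack).astype(float) * buffer.scale
        for k in range(len(lds)):
            per_image[k].append(preds[k])
    return [
        PosteriorEnsemble(samples=s, source="sgld", input_id=i)
        for s, i in zip(per_image, input_ids)
    ]


def ensemble_predict_dropout_batch(
    model: ReconModel,
    lds: list[np.ndarray],
    n: int,
    seed: int,
    scale: float = 1.0,
    input_ids: list[str] | None = None,
) -> list[PosteriorEnsemble]:
    """Dropout ensembles for many same-shaped images, batched per pass."""
    if model.arch.dropout_p <= 0.0:
        raise ValueError("dropout ensemble requires dropout probability > 0")
    input_ids = input_ids or [""] * len(lds)
    rng = np.random.default_rng(seed)
    stack = np.asarray(lds, dtype=float) / scale
    per_image: list[list[np.ndarray]] = [[] for _ in lds]
    for _ in range(n):
        preds = model.predict_batch(stack, train_mode=True, dropout_rng=rng)
        preds = preds.astype(float) * scale
        for k in range(len(lds)):
            per_image[k].append(preds[k])
    return [
        PosteriorEnsemble(samples=s, source="dropout", input_id=i)
        for s, i in zip(per_image, input_ids)
    ]


def reduce_ensemble(ensemble: PosteriorEnsemble) -> ReconResult:
    """Pixel-wise mean and population (1/N) standard deviation."""
    stack = np.asarray(ensemble.samples, dtype=float)
    # anchor on the first sample so identical samples give an exact zero std
    return ReconResult(
        mean_image=stack.mean(axis=0),
        std_map=(stack - stack[0]).std(axis=0, ddof=0),
        n_samples=stack.shape[0],
    )


def sweep_snapshot_count(
    buffer: SnapshotBuffer, ld: np.ndarray, counts: list[int]
) -> dict[int, ReconResult]:
    """Reconstructions using only the last n snapshots, for each n in counts.

    Mirrors the hyper-parameter study over the ensemble size N: larger N
    trades inference cost for a more stable posterior mean and std map.
    """
    results = {}
    full = ensemble_predict_sgld(buffer, ld)
    for c in counts:
        if not 1 <= c <= len(full.samples):
            raise ValueError(f"snapshot count {c} outside [1, {len(full.samples)}]")
        sub = PosteriorEnsemble(
            samples=full.samples[-c:], source="sgld", input_id=full.input_id
        )
        results[c] = reduce_ensemble(sub)
    return results
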