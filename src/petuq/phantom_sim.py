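"""Synthetic PET activity phantoms and Poisson dose-reduction simulation.

Full-dose phantoms emulate whole-body FDG slices at a quantitative activity
scale of roughly [0, 1e4] counts: an elliptical "body" of low, smoothly
varying background activity, a few smooth high-uptake organ regions, and
small focal hot lesions with a prescribed Weber contrast against a local
background annulus.

Dose reduction by a factor DRF is modelled as Poisson thinning with
rescaling: ld = DRF * Poisson(fd / DRF). This preserves the expectation
(E[ld] = fd) and scales the per-pixel variance linearly with dose reduction
(Var[ld] = DRF * fd), the count-statistics behaviour the uncertainty
analysis relies on. No projection-space physics (attenuation, scatter,
randoms) is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class ActivityPhantom:
    """A full-dose activity image with lesion/background ROI annotations."""

    image: np.ndarray
    lesion_masks: list[np.ndarray] = field(default_factory=list)
    background_masks: list[np.ndarray] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.image < 0):
            raise ValueError("activity image must be nonnegative")
        for les, bg in zip(self.lesion_masks, self.background_masks):
            if not les.any():
                raise ValueError("lesion mask is empty")
            if np.any(les & bg):
                raise ValueError("lesion and background masks overlap")


@dataclass
class DosePair:
    """A full-dose phantom with one simulated low-dose counterpart."""

    fd: ActivityPhantom
    ld: np.ndarray
    drf: int
    seed: int
    phantom_id: int = 0

    def __post_init__(self):
        if self.fd.image.shape != self.ld.shape:
            raise ValueError("FD and LD images must share a shape")
        if self.drf < 1:
            raise ValueError("DRF must be >= 1")
        if np.any(self.ld < 0):
            raise ValueError("LD image must be nonnegative")


# ---------------------------------------------------------------------------


def _disk(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def generate_phantom(
    shape: tuple[int, int] = (64, 64),
    n_lesions: int = 2,
    lesion_contrast_range: tuple[float, float] = (1.0, 3.0),
    seed: int = 0,
) -> ActivityPhantom:
    """Generate a synthetic full-dose activity phantom.

    Lesions are hot disks whose Weber contrast against a 2-pixel-dilated
    annulus of local background falls in ``lesion_contrast_range``; the
    contrast is exact by construction because lesion pixels are set from the
    measured annulus mean. Deterministic given ``seed``.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2 or min(shape) < 32:
        raise ValueError("shape must be 2-D with sides >= 32")
    if n_lesions < 0:
        raise ValueError("n_lesions must be nonnegative")
    lo, hi = float(lesion_contrast_range[0]), float(lesion_contrast_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError("lesion contrast range must be positive and ordered")

    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[:h, :w]

    # elliptical body of low background activity with smooth spatial texture
    cy, cx = h / 2, w / 2
    ry = h * rng.uniform(0.36, 0.44)
    rx = w * rng.uniform(0.36, 0.44)
    body = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    base = rng.uniform(800.0, 1500.0)
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=min(h, w) / 10)
    texture = texture / (np.abs(texture).max() + 1e-12)
    image = np.where(body, base * (1.0 + 0.25 * texture), 0.0)

    # 2-5 smooth elliptical high-uptake "organs"
    n_organs = int(rng.integers(2, 6))
    for _ in range(n_organs):
        oc = (rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.25 * w, 0.75 * w))
        orady = rng.uniform(0.06, 0.18) * h
        oradx = rng.uniform(0.06, 0.18) * w
        amp = rng.uniform(1500.0, 6500.0)
        bump = np.exp(-(((yy - oc[0]) / orady) ** 2 + ((xx - oc[1]) / oradx) ** 2))
        image += np.where(body, amp * bump, 0.0)

    image = np.clip(image, 0.0, None)

    # focal hot lesions placed fully inside the body, pairwise separated
    lesion_masks: list[np.ndarray] = []
    background_masks: list[np.ndarray] = []
    contrasts: list[float] = []
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(lesion_masks) < n_lesions:
        attempts += 1
        if attempts > 500 * max(1, n_lesions):
            raise RuntimeError("could not place all lesions; too crowded")
        radius = float(rng.uniform(2.0, 4.0))
        c = (rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w))
        if any((c[0] - p[0]) ** 2 + (c[1] - p[1]) ** 2 < (4 * radius) ** 2 for p in centers):
            continue
        lesion = _disk(shape, c, radius)
        annulus = ndimage.binary_dilation(lesion, iterations=2) & ~lesion
        if not body[lesion].all() or not body[annulus].all():
            continue
        bg_mean = float(image[annulus].mean())
        if bg_mean <= 0:
            continue
        contrast = float(rng.uniform(lo, hi))
        image[lesion] = bg_mean * (1.0 + contrast)
        lesion_masks.append(lesion)
        background_masks.append(annulus)
        contrasts.append(contrast)
        centers.append(c)

    return ActivityPhantom(
        image=image,
        lesion_masks=lesion_masks,
        background_masks=background_masks,
        meta={
            "seed": seed,
            "shape": shape,
            "n_organs": n_organs,
            "lesion_contrasts": contrasts,
            "lesion_contrast_range": (lo, hi),
        },
    )


def simulate_low_dose(fd: np.ndarray, drf: int, seed: int) -> np.ndarray:
    """Simulate a low-dose image by Poisson thinning with rescaling.

    Each pixel is drawn as ``drf * Poisson(fd / drf)``, so the expectation
    equals the full-dose value and the variance equals ``drf * fd``.
    """
    fd = np.asarray(fd, dtype=float)
    if np.any(fd < 0):
        raise ValueError("full-dose image must be nonnegative")
    if int(drf) < 1:
        raise ValueError("DRF must be >= 1")
    rng = np.random.default_rng(seed)
    return float(drf) * rng.poisson(fd / float(drf)).astype(float)


# ---------------------------------------------------------------------------


def _split_counts(n: int, fracs: tuple[float, float, float]) -> list[int]:
    # largest-remainder apportionment so counts sum exactly to n
    raw = [f * n for f in fracs]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def make_dataset(
    n_phantoms: int,
    drfs: list[int],
    split_fracs: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    n_lesions: int = 2,
    lesion_contrast_range: tuple[float, float] = (1.0, 3.0),
    out_dir: str | Path | None = None,
) -> dict[str, list[DosePair]]:
    """Build train/val/eval collections of dose pairs.

    Every phantom lands in exactly one split and contributes one pair per
    requested DRF. When ``out_dir`` is given, images are written as NIfTI
    with NPZ mirrors and a CSV manifest alongside.
    """
    if n_phantoms < 3:
        raise ValueError("need at least 3 phantoms to populate all splits")
    if abs(sum(split_fracs) - 1.0) > 1e-8:
        raise ValueError("split fractions must sum to 1")
    if any(int(d) < 1 for d in drfs):
        raise ValueError("DRFs must be >= 1")

    ss = np.random.SeedSequence(seed)
    phantom_seeds = ss.generate_state(n_phantoms)
    rng = np.random.default_rng(ss.spawn(1)[0])

    counts = _split_counts(n_phantoms, tuple(split_fracs))
    order = rng.permutation(n_phantoms)
    assignment = {}
    idx = 0
    for split, c in zip(("train", "val", "eval"), counts):
        for pid in order[idx : idx + c]:
            assignment[int(pid)] = split
        idx += c

    splits: dict[str, list[DosePair]] = {"train": [], "val": [], "eval": []}
    for pid in range(n_phantoms):
        pseed = int(phantom_seeds[pid] % (2**31))
        phantom = generate_phantom(shape, n_lesions, lesion_contrast_range, seed=pseed)
        for j, drf in enumerate(drfs):
            ld_seed = int((int(phantom_seeds[pid]) * 1000003 + j) % (2**31))
            ld = simulate_low_dose(phantom.image, int(drf), seed=ld_seed)
            splits[assignment[pid]].append(
                DosePair(fd=phantom, ld=ld, drf=int(drf), seed=ld_seed, phantom_id=pid)
            )

    if out_dir is not None:
        write_dataset(splits, out_dir)
    return splits


def write_dataset(splits: dict[str, list[DosePair]], out_dir: str | Path) -> Path:
    """Write images (NIfTI + NPZ), ROI masks (NPZ) and a CSV manifest."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, pairs in splits.items():
        for pair in pairs:
            stem = f"p{pair.phantom_id:04d}_drf{pair.drf:03d}"
            fd_path = out_dir / f"{stem}_fd.nii.gz"
            ld_path = out_dir / f"{stem}_ld.nii.gz"
            roi_path = out_dir / f"p{pair.phantom_id:04d}_rois.npz"
            affine = np.eye(4)
            nib.save(nib.Nifti1Image(pair.fd.image.astype(np.float32), affine), fd_path)
            nib.save(nib.Nifti1Image(pair.ld.astype(np.float32), affine), ld_path)
            np.savez(out_dir / f"{stem}_fd.npz", image=pair.fd.image)
            np.savez(out_dir / f"{stem}_ld.npz", image=pair.ld)
            if not roi_path.exists():
                np.savez(
                    roi_path,
                    lesions=np.array(pair.fd.lesion_masks, dtype=bool),
                    backgrounds=np.array(pair.fd.background_masks, dtype=bool),
                )
            rows.append(
                {
                    "phantom_id": pair.phantom_id,
                    "split": split,
                    "drf": pair.drf,
                    "fd_path": fd_path.name,
                    "ld_path": ld_path.name,
                    "roi_path": roi_path.name,
                    "seed": pair.seed,
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(out_dir: str | Path) -> dict[str, list[DosePair]]:
    """Load a dataset previously written by :func:`write_dataset`."""
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    splits: dict[str, list[DosePair]] = {"train": [], "val": [], "eval": []}
    for _, row in manifest.iterrows():
        fd = np.load(out_dir / row["fd_path"].replace(".nii.gz", ".npz"))["image"]
        ld = np.load(out_dir / row["ld_path"].replace(".nii.gz", ".npz"))["image"]
        rois = np.load(out_dir / row["roi_path"])
        phantom = ActivityPhantom(
            image=fd,
            lesion_masks=list(rois["lesions"]),
            background_masks=list(rois["backgrounds"]),
            meta={"phantom_id": int(row["phantom_id"])},
        )
        splits[row["split"]].append(
            DosePair(
                fd=phantom,
                ld=ld,
                drf=int(row["drf"]),
                seed=int(row["seed"]),
                phantom_id=int(row["phantom_id"]),
            )
        )
    return splits
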