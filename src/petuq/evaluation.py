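"""Reconstruction-quality and uncertainty evaluation protocol.

Global fidelity against the full-dose reference is measured with SSIM
(11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03 — the original SSIM
constants), PSNR and range-normalized RMSE. Lesion-level accuracy uses the
mean absolute error and Weber contrast, (mean_lesion - mean_bg) / mean_bg,
on annotated ROIs. Uncertainty maps are summarized per image by their 95th
percentile and mean, per DRF by the median across images, and the clinical
usefulness of the map is scored by the r^2 of an ordinary least-squares fit
of the per-DRF median score against DRF. Method comparisons use two-sided
paired t-tests, run per DRF without multiple-testing correction (a
reporting caveat: five DRFs mean five uncorrected tests per metric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import (
    normalized_root_mse,
    peak_signal_noise_ratio,
    structural_similarity,
)


class DegenerateInputError(ValueError):
    """Raised for inputs on which a metric is mathematically undefined."""


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def ssim(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """Mean structural similarity with a Gaussian window."""
    a, b = _check_shapes(a, b)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def psnr(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    a, b = _check_shapes(a, b)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if np.array_equal(a, b):
        return float("inf")
    return float(peak_signal_noise_ratio(a, b, data_range=data_range))


def nrmse(a: np.ndarray, ref: np.ndarray) -> float:
    """RMSE normalized by the dynamic range of the reference."""
    a, ref = _check_shapes(a, ref)
    if np.ptp(ref) == 0:
        raise DegenerateInputError("reference image is constant; NRMSE undefined")
    return float(normalized_root_mse(ref, a, normalization="min-max"))


def lesion_mae(recon: np.ndarray, fd: np.ndarray, lesion_mask: np.ndarray) -> float:
    """Mean absolute error restricted to lesion pixels, in original units."""
    recon, fd = _check_shapes(recon, fd)
    mask = np.asarray(lesion_mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty lesion mask")
    return float(np.abs(recon[mask] - fd[mask]).mean())


def weber_contrast(img: np.ndarray, lesion_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """(mean_lesion - mean_background) / mean_background."""
    img = np.asarray(img, dtype=float)
    les = np.asarray(lesion_mask, dtype=bool)
    bg = np.asarray(bg_mask, dtype=bool)
    if not les.any() or not bg.any():
        raise DegenerateInputError("empty ROI mask")
    if np.any(les & bg):
        raise ValueError("lesion and background masks must be disjoint")
    mean_bg = float(img[bg].mean())
    if mean_bg <= 0:
        raise DegenerateInputError("background mean must be positive")
    return (float(img[les].mean()) - mean_bg) / mean_bg


def uncertainty_scores(
    std_maps: dict[tuple[str, int], np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image p95/mean of the std map, and per-DRF medians of each score.

    ``std_maps`` is keyed by (image_id, drf). Percentiles use linear
    interpolation between order statistics.
    """
    if not std_maps:
        raise ValueError("no uncertainty maps supplied")
    rows = []
    for (image_id, drf), m in std_maps.items():
        m = np.asarray(m, dtype=float)
        if np.any(m < 0):
            raise ValueError("uncertainty maps must be nonnegative")
        rows.append(
            {
                "image_id": image_id,
                "drf": int(drf),
                "p95_std": float(np.percentile(m, 95)),
                "mean_std": float(m.mean()),
            }
        )
    per_image = pd.DataFrame(rows)
    per_drf = (
        per_image.groupby("drf")[["p95_std", "mean_std"]]
        .median()
        .rename(columns={"p95_std": "median_p95_std", "mean_std": "median_mean_std"})
        .reset_index()
    )
    return per_image, per_drf


def drf_fit(drfs, scores) -> tuple[float, float, float]:
    """OLS fit of an uncertainty score against DRF; returns slope, intercept, r^2."""
    drfs = np.asarray(drfs, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if drfs.shape != scores.shape or len(np.unique(drfs)) < 3:
        raise DegenerateInputError("need scores at >= 3 distinct DRFs")
    if np.var(scores) == 0:
        raise DegenerateInputError("zero score variance; r^2 undefined")
    fit = stats.linregress(drfs, scores)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on a - b; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    if np.var(d, ddof=1) == 0:
        raise DegenerateInputError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# the end-to-end protocol


@dataclass
class MetricsReport:
    """All evaluation tables for one run."""

    per_image: pd.DataFrame
    per_lesion: pd.DataFrame
    uncertainty: pd.DataFrame
    fits: pd.DataFrame
    tests: pd.DataFrame


def evaluate_run(eval_pairs, recon_by_method: dict[str, dict[str, object]]) -> MetricsReport:
    """Assemble the full metrics report for an evaluation split.

    ``recon_by_method`` maps a method name ("sgld", "dropout") to a dict
    from image id (see :func:`image_id`) to a ``ReconResult``. The raw
    low-dose input is always evaluated as the reference method "ld".
    """
    img_rows, lesion_rows = [], []
    std_maps: dict[str, dict[tuple[str, int], np.ndarray]] = {m: {} for m in recon_by_method}

    for pair in eval_pairs:
        iid = image_id(pair)
        fd = pair.fd.image
        rng_fd = float(np.ptp(fd))
        candidates = {"ld": pair.ld}
        for method, recons in recon_by_method.items():
            if iid not in recons:
                raise KeyError(f"method {method!r} is missing a reconstruction for {iid}")
            candidates[method] = recons[iid].mean_image
            std_maps[method][(iid, pair.drf)] = recons[iid].std_map
        for method, img in candidates.items():
            img_rows.append(
                {
                    "image_id": iid,
                    "drf": pair.drf,
                    "method": method,
                    "ssim": ssim(img, fd, rng_fd),
                    "psnr": psnr(img, fd, rng_fd),
                    "nrmse": nrmse(img, fd),
                }
            )
            for k, (les, bg) in enumerate(
                zip(pair.fd.lesion_masks, pair.fd.background_masks)
            ):
                try:
                    wc = weber_contrast(img, les, bg)
                except DegenerateInputError:
                    wc = float("nan")  # undefined when the recon background is <= 0
                lesion_rows.append(
                    {
                        "lesion_id": f"{iid}_lesion{k}",
                        "image_id": iid,
                        "drf": pair.drf,
                        "method": method,
                        "mae": lesion_mae(img, fd, les),
                        "weber_contrast": wc,
                    }
                )

    per_image = pd.DataFrame(img_rows)
    per_lesion = pd.DataFrame(lesion_rows)

    unc_frames, fit_rows = [], []
    for method, maps in std_maps.items():
        per_img_unc, per_drf = uncertainty_scores(maps)
        per_img_unc = per_img_unc.assign(method=method)
        unc_frames.append(per_img_unc)
        for score in ("median_p95_std", "median_mean_std"):
            try:
                slope, intercept, r2 = drf_fit(per_drf["drf"], per_drf[score])
            except DegenerateInputError:
                continue  # fewer than three DRFs in this run
            fit_rows.append(
                {
                    "method": method,
                    "score": score,
                    "slope": slope,
                    "intercept": intercept,
                    "r2": r2,
                }
            )
    uncertainty = (
        pd.concat(unc_frames, ignore_index=True) if unc_frames else pd.DataFrame()
    )
    fits = pd.DataFrame(fit_rows)

    test_rows = []
    methods = [m for m in ("sgld", "dropout") if m in recon_by_method]
    if len(methods) == 2:
        for metric in ("ssim", "psnr", "nrmse"):
            for drf, grp in per_image.groupby("drf"):
                a = grp[grp["method"] == methods[0]].sort_values("image_id")[metric]
                b = grp[grp["method"] == methods[1]].sort_values("image_id")[metric]
                if len(a) < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
                    continue
                try:
                    t, p = paired_ttest(a.to_numpy(), b.to_numpy())
                except DegenerateInputError:
                    continue
                test_rows.append(
                    {
                        "metric": metric,
                        "drf": drf,
                        "method_a": methods[0],
                        "method_b": methods[1],
                        "t": t,
                        "p": p,
                        "n": len(a),
                    }
                )
    tests = pd.DataFrame(test_rows)

    return MetricsReport(
        per_image=per_image,
        per_lesion=per_lesion,
        uncertainty=uncertainty,
        fits=fits,
        tests=tests,
    )


def image_id(pair) -> str:
    return f"p{pair.phantom_id:04d}_drf{pair.drf:03d}"
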