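"""Image-quality metrics, uncertainty scores, fits and significance tests."""

import numpy as np
import pytest
from scipy import ndimage

from petuq import evaluation as ev


class TestSSIM:
    def test_identity_is_one(self, rng):
        img = rng.random((16, 16))
        assert ev.ssim(img, img, data_range=1.0) == pytest.approx(1.0)

    def test_huge_data_range_drives_value_to_one(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert ev.ssim(a, b, data_range=1e9) == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_gaussian_window_oracle(self, rng):
        """Re-derive SSIM from its published formula (11x11 Gaussian window,
        sigma 1.5, K1=0.01, K2=0.03, weighted covariances) and compare."""
        a = rng.random((16, 16))
        b = np.clip(a + 0.1 * rng.normal(size=(16, 16)), 0, 1.5)
        dr = 1.5
        sigma, truncate = 1.5, 3.5
        c1, c2 = (0.01 * dr) ** 2, (0.03 * dr) ** 2

        def g(x):
            return ndimage.gaussian_filter(x, sigma=sigma, truncate=truncate)

        ua, ub = g(a), g(b)
        va = g(a * a) - ua * ua
        vb = g(b * b) - ub * ub
        cov = g(a * b) - ua * ub
        s = ((2 * ua * ub + c1) * (2 * cov + c2)) / ((ua**2 + ub**2 + c1) * (va + vb + c2))
        pad = int(truncate * sigma + 0.5)  # 11x11 window radius
        expected = s[pad:-pad, pad:-pad].mean()
        assert ev.ssim(a, b, dr) == pytest.approx(expected, abs=1e-8)

    def test_symmetry(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert ev.ssim(a, b, 1.0) == pytest.approx(ev.ssim(b, a, 1.0), abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ev.ssim(np.zeros((8, 8)), np.zeros((8, 9)), 1.0)


class TestPSNR:
    def test_identity_is_infinite(self, rng):
        img = rng.random((8, 8))
        assert ev.psnr(img, img, 1.0) == float("inf")

    def test_closed_form_twenty_db(self):
        a = np.zeros((10, 10))
        b = a + 0.1  # MSE = 0.01
        assert ev.psnr(a, b, data_range=1.0) == pytest.approx(20.0)

    def test_halving_mse_adds_three_db(self, rng):
        a = rng.random((10, 10))
        p1 = ev.psnr(a, a + 0.1, 1.0)
        p2 = ev.psnr(a, a + 0.1 / np.sqrt(2), 1.0)
        assert p2 - p1 == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_monotone_against_nrmse(self, rng):
        """For a fixed reference, growing perturbations strictly decrease
        PSNR and increase NRMSE."""
        ref = rng.random((12, 12)) * 10
        dr = float(np.ptp(ref))
        psnrs, nrmses = [], []
        for eps in (0.1, 0.5, 1.0, 2.0):
            psnrs.append(ev.psnr(ref + eps, ref, dr))
            nrmses.append(ev.nrmse(ref + eps, ref))
        assert all(a > b for a, b in zip(psnrs, psnrs[1:]))
        assert all(a < b for a, b in zip(nrmses, nrmses[1:]))


class TestNRMSE:
    def test_identity_zero(self, rng):
        img = rng.random((8, 8))
        assert ev.nrmse(img, img) == 0.0

    def test_range_normalization_closed_form(self):
        ref = np.linspace(0, 10, 64).reshape(8, 8)
        assert ev.nrmse(ref + 1.0, ref) == pytest.approx(0.1)

    def test_scale_invariance(self, rng):
        ref = rng.random((8, 8)) * 5
        a = ref + rng.normal(size=(8, 8))
        assert ev.nrmse(3.7 * a, 3.7 * ref) == pytest.approx(ev.nrmse(a, ref))

    def test_constant_reference_rejected(self):
        with pytest.raises(ev.DegenerateInputError):
            ev.nrmse(np.ones((4, 4)), np.ones((4, 4)))


class TestLesionMetrics:
    def test_mae_identity_and_offset(self, rng):
        fd = rng.random((16, 16)) * 100
        mask = np.zeros((16, 16), bool)
        mask[5:8, 5:8] = True
        assert ev.lesion_mae(fd, fd, mask) == 0.0
        shifted = fd.copy()
        shifted[mask] += 5.0
        assert ev.lesion_mae(shifted, fd, mask) == pytest.approx(5.0)

    def test_mae_matches_loop_oracle(self, rng):
        fd = rng.random((16, 16))
        recon = rng.random((16, 16))
        mask = np.zeros((16, 16), bool)
        pix = rng.choice(256, 10, replace=False)
        mask.ravel()[pix] = True
        expected = sum(abs(recon.ravel()[p] - fd.ravel()[p]) for p in pix) / 10
        assert ev.lesion_mae(recon, fd, mask) == pytest.approx(expected)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ev.DegenerateInputError):
            ev.lesion_mae(rng.random((4, 4)), rng.random((4, 4)), np.zeros((4, 4), bool))

    def test_weber_contrast_formula_and_invariance(self):
        img = np.ones((8, 8))
        les = np.zeros((8, 8), bool)
        bg = np.zeros((8, 8), bool)
        les[2:4, 2:4] = True
        bg[6:8, 6:8] = True
        img[les] = 3.0
        assert ev.weber_contrast(img, les, bg) == pytest.approx(2.0)
        assert ev.weber_contrast(5.5 * img, les, bg) == pytest.approx(2.0)
        img[les] = 1.0
        assert ev.weber_contrast(img, les, bg) == pytest.approx(0.0)

    def test_weber_contrast_degenerate_background(self):
        img = np.zeros((8, 8))
        les = np.zeros((8, 8), bool)
        bg = np.zeros((8, 8), bool)
        les[0, 0] = True
        bg[1, 1] = True
        with pytest.raises(ev.DegenerateInputError):
            ev.weber_contrast(img, les, bg)
        with pytest.raises(ValueError):
            ev.weber_contrast(img, les, les)


class TestUncertaintyScores:
    def test_all_zero_maps_score_zero(self):
        per_image, per_drf = ev.uncertainty_scores(
            {("a", 4): np.zeros((8, 8)), ("b", 20): np.zeros((8, 8))}
        )
        assert (per_image[["p95_std", "mean_std"]] == 0).all().all()
        assert (per_drf[["median_p95_std", "median_mean_std"]] == 0).all().all()

    def test_p95_uses_linear_interpolation(self):
        grid = np.arange(1, 101, dtype=float).reshape(10, 10)
        per_image, _ = ev.uncertainty_scores({("a", 4): grid})
        assert per_image["p95_std"].iloc[0] == pytest.approx(95.05)

    def test_p95_at_least_p5(self, rng):
        for _ in range(5):
            m = np.abs(rng.normal(size=(12, 12)))
            per_image, _ = ev.uncertainty_scores({("x", 10): m})
            assert per_image["p95_std"].iloc[0] >= np.percentile(m, 5)

    def test_median_across_images_per_drf(self):
        maps = {
            ("a", 4): np.full((4, 4), 1.0),
            ("b", 4): np.full((4, 4), 3.0),
            ("c", 4): np.full((4, 4), 10.0),
        }
        _, per_drf = ev.uncertainty_scores(maps)
        assert per_drf["median_mean_std"].iloc[0] == pytest.approx(3.0)


class TestDrfFit:
    def test_perfectly_linear_scores(self):
        slope, intercept, r2 = ev.drf_fit([4, 10, 20, 50, 100], [8, 20, 40, 100, 200])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = np.array([4.0, 10.0, 20.0, 50.0, 100.0])
        y = rng.random(5) * 10
        # hand-solved normal equations
        n = len(x)
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        ss_res = ((y - slope * x - intercept) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        fs, fi, fr2 = ev.drf_fit(x, y)
        assert fs == pytest.approx(slope, abs=1e-10)
        assert fi == pytest.approx(intercept, abs=1e-10)
        assert fr2 == pytest.approx(r2, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ev.DegenerateInputError):
            ev.drf_fit([4, 10], [1, 2])
        with pytest.raises(ev.DegenerateInputError):
            ev.drf_fit([4, 10, 20], [5, 5, 5])


class TestPairedTTest:
    def test_textbook_five_difference_example(self):
        """Differences 1..5: t = mean(d) / (sd(d)/sqrt(n)) = 3*sqrt(5)/sqrt(2.5)."""
        b = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        a = b + np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, p = ev.paired_ttest(a, b)
        expected = 3.0 * np.sqrt(5) / np.sqrt(2.5)
        assert t == pytest.approx(expected, abs=1e-10)
        assert 0 < p < 1

    def test_zero_variance_differences_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ev.DegenerateInputError):
            ev.paired_ttest(a, a)
        with pytest.raises(ev.DegenerateInputError):
            ev.paired_ttest(a + 2.0, a)

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            ev.paired_ttest(np.ones(3), np.ones(4))


class TestEvaluateRun:
    def test_report_has_one_row_per_image_drf_method_and_no_nan(self, tiny_dataset):
        from petuq import ReconResult

        pairs = [p for s in ("val", "eval") for p in tiny_dataset[s]]
        rng = np.random.default_rng(0)
        recon = {"sgld": {}, "dropout": {}}
        for p in pairs:
            iid = ev.image_id(p)
            for m in recon:
                noise = rng.normal(scale=50.0, size=p.fd.image.shape)
                recon[m][iid] = ReconResult(
                    mean_image=p.fd.image + noise,
                    std_map=np.abs(noise),
                    n_samples=3,
                )
        report = ev.evaluate_run(pairs, recon)
        expected_rows = len(pairs) * 3  # ld + two methods
        assert len(report.per_image) == expected_rows
        assert not report.per_image[["ssim", "psnr", "nrmse"]].isna().any().any()
        key = report.per_image.groupby(["image_id", "drf", "method"]).size()
        assert (key == 1).all()
        assert (report.uncertainty["p95_std"] >= 0).all()
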