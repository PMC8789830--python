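"""Evaluation metrics, connectivity, reports and the acquisition model."""

import numpy as np
import pandas as pd
import pytest

from octarec import baselines
from octarec.metrics import (AcquisitionModel, acquisition_speedup,
                             equivalent_step_size, evaluate_pairs, ms_ssim,
                             psnr, rms_contrast, ssim, vessel_connectivity)


class TestPsnr:
    def test_analytic_values(self):
        y = np.zeros((10, 10))
        yh = np.full((10, 10), 0.1)   # MSE 0.01 -> 20 dB
        assert psnr(y, yh) == pytest.approx(20.0)
        assert psnr(np.zeros((4, 4)), np.ones((4, 4))) == pytest.approx(0.0)

    def test_identical_images_flagged_infinite(self):
        with pytest.warns(RuntimeWarning):
            assert np.isinf(psnr(np.ones((4, 4)), np.ones((4, 4))))

    def test_matches_direct_formula(self, rng):
        y, yh = rng.uniform(0, 1, (16, 16)), rng.uniform(0, 1, (16, 16))
        expected = 10 * np.log10(1.0 / np.mean((y - yh) ** 2))
        assert psnr(y, yh) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_in_mse(self):
        y = np.zeros((8, 8))
        assert psnr(y, np.full((8, 8), 0.1)) > psnr(y, np.full((8, 8), 0.2))


class TestSsim:
    def test_identical_images_give_one(self, rng):
        y = rng.uniform(0, 1, (32, 32))
        assert ssim(y, y) == pytest.approx(1.0)
        assert ms_ssim(y, y, scales=2) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        y = rng.uniform(0, 1, (32, 32))
        yh = np.clip(y + rng.normal(0, 0.1, y.shape), 0, 1)
        assert ssim(y, yh) == pytest.approx(ssim(yh, y), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        """Fixed pattern vs noisy copy against scikit-image's SSIM."""
        from skimage.metrics import structural_similarity
        yy, xx = np.mgrid[0:64, 0:64]
        y = 0.5 + 0.5 * np.sin(yy / 5.0) * np.cos(xx / 7.0)
        yh = np.clip(y + rng.normal(0, 0.05, y.shape), 0, 1)
        ref = structural_similarity(y, yh, win_size=11, gaussian_weights=True,
                                    sigma=1.5, use_sample_covariance=False,
                                    data_range=1.0)
        assert ssim(y, yh) == pytest.approx(ref, abs=1e-12)
        # the single-scale multiscale path follows the same conventions up
        # to taking means of the luminance and contrast terms separately
        assert ms_ssim(y, yh, scales=1) == pytest.approx(ref, abs=1e-4)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))
        with pytest.raises(ValueError):
            ms_ssim(np.zeros((32, 32)), np.zeros((32, 32)), scales=5)


class TestContrast:
    def test_constant_image_zero(self):
        assert rms_contrast(np.full((8, 8), 0.3)) == 0.0

    def test_half_and_half_analytic(self):
        img = np.concatenate([np.zeros((4, 8)), np.ones((4, 8))])
        assert rms_contrast(img) == pytest.approx(0.5)

    def test_matches_std_oracle(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        assert rms_contrast(img) == pytest.approx(img.std(), abs=1e-12)


class TestConnectivity:
    def test_single_line_fully_connected(self):
        img = np.zeros((60, 60))
        img[30, 5:55] = 1.0
        assert vessel_connectivity(img, binarize=0.5) == 1.0

    def test_isolated_specks_lower_the_ratio(self):
        """50-pixel line plus 10 isolated pixels: ratio 50/60 by construction."""
        img = np.zeros((60, 60))
        img[30, 5:55] = 1.0
        rng = np.random.default_rng(0)
        placed = 0
        while placed < 10:
            y, x = rng.integers(0, 60, 2)
            region = img[max(0, y - 2):y + 3, max(0, x - 2):x + 3]
            if region.sum() == 0:
                img[y, x] = 1.0
                placed += 1
        value = vessel_connectivity(img, binarize=0.5, min_component=5)
        assert value == pytest.approx(50 / 60)

    def test_empty_foreground_flagged(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(vessel_connectivity(np.zeros((16, 16)),
                                                binarize=0.5))

    def test_bounded_in_unit_interval(self, small_series):
        from octarec.angio import compute_angiogram, mip
        img = mip(compute_angiogram(small_series))
        value = vessel_connectivity(img)
        assert 0.0 <= value <= 1.0


class TestEvaluatePairs:
    def test_ground_truth_scores_perfectly(self, small_pairs):
        pairs = small_pairs[:3]
        methods = {"oracle": lambda px, _p=iter(pairs): next(_p).hr_hq.pixels}
        report = evaluate_pairs(pairs, methods)
        assert np.allclose(report.per_image["ssim"], 1.0)
        assert np.allclose(report.per_image["ms_ssim"], 1.0)
        contrasts = [rms_contrast(p.hr_hq.pixels) for p in pairs]
        assert np.allclose(report.per_image["rms_contrast"], contrasts)

    def test_row_count_is_methods_times_images(self, small_pairs):
        pairs = small_pairs[:4]
        methods = {
            "nearest": lambda px: baselines.interpolate_upsample(px, 2, "nearest"),
            "bicubic": lambda px: baselines.interpolate_upsample(px, 2, "bicubic"),
        }
        report = evaluate_pairs(pairs, methods)
        assert len(report.per_image) == 2 * 4
        assert report.summary.shape[0] == 2

    def test_summary_matches_per_image_recomputation(self, small_pairs):
        pairs = small_pairs[:4]
        methods = {"bicubic":
                   lambda px: baselines.interpolate_upsample(px, 2, "bicubic")}
        report = evaluate_pairs(pairs, methods)
        manual = report.per_image["ssim"].mean()
        assert report.summary[("mean", "ssim")].iloc[0] == \
            pytest.approx(manual, abs=1e-12)

    def test_order_invariance(self, small_pairs):
        pairs = list(small_pairs[:5])
        methods = {"nearest":
                   lambda px: baselines.interpolate_upsample(px, 2, "nearest")}
        a = evaluate_pairs(pairs, methods).summary
        b = evaluate_pairs(pairs[::-1], methods).summary
        pd.testing.assert_frame_equal(a, b)


class TestAcquisitionModel:
    def test_paper_protocol_speedups(self):
        model = AcquisitionModel()
        assert acquisition_speedup(model, 2, 2) == (16.0, 1.1)
        assert acquisition_speedup(model, 4, 2) == (64.0, 0.28)
        assert acquisition_speedup(model, 8, 2) == (256.0, 0.07)

    def test_identity_protocol(self):
        model = AcquisitionModel()
        assert acquisition_speedup(model, 1, 8) == (1.0, 17.8)
        # speedup * time equals the base time exactly before rounding
        factor, _ = acquisition_speedup(model, 4, 4)
        assert model.base_time_s / factor * factor == \
            pytest.approx(model.base_time_s)

    def test_equivalent_step_sizes(self):
        model = AcquisitionModel()
        assert equivalent_step_size(model, 1) == 10.0
        assert equivalent_step_size(model, 4) == 40.0
        assert equivalent_step_size(model, 8) == 80.0

    def test_invalid_protocols_rejected(self):
        model = AcquisitionModel()
        with pytest.raises(ValueError):
            acquisition_speedup(model, 0, 2)
        with pytest.raises(ValueError):
            acquisition_speedup(model, 2, 9)
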