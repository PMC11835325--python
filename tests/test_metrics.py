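"""PSNR / RMSE / SSIM / TV against closed forms and the scikit-image SSIM."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from endostitch import metrics as me


@pytest.fixture()
def pair(rng):
    a = rng.uniform(0.2, 0.8, size=(48, 48, 3))
    return a, np.clip(a + 0.1, None, 1.0)


class TestRMSE:
    def test_identical_zero(self, pair):
        a, _ = pair
        assert me.rmse(a, a) == 0.0

    def test_constant_difference(self, pair):
        a, b = pair
        assert me.rmse(a, b) == pytest.approx(0.1, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        a, b = rng.random((16, 16, 3)), rng.random((16, 16, 3))
        direct = float(np.sqrt(((a - b) ** 2).mean()))
        assert me.rmse(a, b) == pytest.approx(direct, abs=1e-12)

    def test_masked(self, rng):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        b[:4] = 0.2
        mask = np.zeros((8, 8), bool)
        mask[:4] = True
        assert me.rmse(a, b, mask) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            me.rmse(a, b, np.zeros((8, 8), bool))

    def test_sum_of_squares_accumulation(self, rng):
        a, b = rng.random((20, 20)), rng.random((20, 20))
        r = me.rmse(a, b)
        assert r * r * a.size == pytest.approx(((a - b) ** 2).sum(), abs=1e-9)


class TestPSNR:
    def test_identical_infinite(self, pair):
        a, _ = pair
        assert me.psnr(a, a) == float("inf")

    def test_constant_difference_20db(self, pair):
        a, b = pair
        assert me.psnr(a, b) == pytest.approx(20.0, abs=1e-9)

    def test_relation_to_rmse(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert me.psnr(a, b) == pytest.approx(
            20.0 * np.log10(1.0 / me.rmse(a, b)), abs=1e-9
        )

    def test_monotone_in_noise(self, rng):
        a = rng.random((32, 32))
        prev = np.inf
        for sigma in (0.01, 0.05, 0.1):
            b = np.clip(a + rng.normal(0, sigma, a.shape), 0, 1)
            cur = me.psnr(a, b)
            assert cur < prev
            prev = cur


class TestSSIM:
    def test_identical_one(self, rng):
        a = rng.random((32, 32))
        assert me.ssim(a, a) == 1.0

    def test_inversion_negative(self):
        a = np.zeros((32, 32))
        a[:, ::2] = 1.0
        assert me.ssim(a, 1.0 - a) < 0.0

    def test_matches_reference_implementation(self, rng):
        for _ in range(3):
            a = rng.random((48, 64))
            b = np.clip(a + rng.normal(0, 0.08, a.shape), 0, 1)
            ref = structural_similarity(
                a, b, win_size=11, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=1.0,
            )
            assert me.ssim(a, b) == pytest.approx(ref, abs=1e-6)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            me.ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestTV:
    def test_constant_zero(self):
        assert me.tv(np.full((16, 16, 3), 0.5)) == 0.0

    def test_ramp_closed_form(self):
        ramp = np.tile(np.arange(32) * 0.01, (32, 1))
        assert me.tv(ramp) == pytest.approx(0.01, abs=1e-12)

    def test_blur_reduces_tv(self, rng):
        from scipy.ndimage import gaussian_filter

        a = rng.random((64, 64))
        assert me.tv(gaussian_filter(a, 2.0)) <= me.tv(a)


class TestChannelPermutation:
    def test_all_metrics_invariant(self, rng):
        a, b = rng.random((32, 32, 3)), rng.random((32, 32, 3))
        perm = [2, 0, 1]
        ap, bp = a[:, :, perm], b[:, :, perm]
        assert me.rmse(a, b) == pytest.approx(me.rmse(ap, bp), abs=1e-12)
        assert me.psnr(a, b) == pytest.approx(me.psnr(ap, bp), abs=1e-9)
        assert me.tv(a) == pytest.approx(me.tv(ap), abs=1e-12)


class TestEvaluateStitch:
    def test_perfect_fusion_sentinels(self, sample_canvas):
        from endostitch.fusion import StitchOutput

        out = StitchOutput(
            fused=sample_canvas.warped_reference,
            low_res=sample_canvas.warped_reference,
            residual=np.zeros_like(sample_canvas.warped_reference),
        )
        rep = me.evaluate_stitch(out, sample_canvas)
        assert rep.psnr == float("inf")
        assert rep.rmse == 0.0
        assert rep.ssim == pytest.approx(1.0)
        assert rep.region == "overlap"

    def test_report_ranges(self, sample_canvas, rng):
        from endostitch.fusion import StitchOutput

        fused = np.clip(
            sample_canvas.warped_reference
            + rng.normal(0, 0.05, sample_canvas.warped_reference.shape),
            0, 1,
        ).astype(np.float32)
        out = StitchOutput(fused=fused, low_res=fused, residual=np.zeros_like(fused))
        for region in ("overlap", "union", "full"):
            rep = me.evaluate_stitch(out, sample_canvas, region=region)
            assert np.isfinite(rep.psnr)
            assert 0 <= rep.rmse <= 1
            assert -1 <= rep.ssim <= 1
            assert rep.tv >= 0
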