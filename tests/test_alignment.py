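"""Multiscale homography estimation: stacking, pyramids, correlation, the
differentiable DLT, and the unsupervised ablation loss."""

import numpy as np
import pytest

from endostitch import alignment as al
from endostitch import geometry as geo
from endostitch import nn
from endostitch import synthetic as syn
from endostitch.nn import ops


@pytest.fixture(scope="module")
def pair128():
    tex = syn.generate_texture(3, 200)
    h = np.array([[1.0, 0, 8], [0, 1.0, 0], [0, 0, 1.0]])
    return syn.render_pair(tex, h, 128)


class TestStackPair:
    def test_shape_and_order(self, pair128):
        x = al.stack_pair(pair128.reference, pair128.target)
        assert x.shape == (128, 128, 6)
        assert np.array_equal(x[:, :, :3], pair128.reference)
        assert np.array_equal(x[:, :, 3:], pair128.target)

    def test_same_image_halves_identical(self, pair128):
        x = al.stack_pair(pair128.reference, pair128.reference)
        assert np.array_equal(x[:, :, :3], x[:, :, 3:])

    def test_unnormalised_rejected(self):
        a = np.full((32, 32, 3), 200.0)
        with pytest.raises(ValueError):
            al.stack_pair(a, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            al.stack_pair(np.zeros((32, 32, 3)), np.zeros((64, 64, 3)))


class TestFeaturePyramid:
    def test_level_shapes(self, pair128):
        net = al.AlignmentNet(seed=0)
        levels = al.build_feature_pyramid(pair128.reference, net)
        assert [f.shape[0] for f in levels] == [64, 32, 16]
        assert [f.shape[2] for f in levels] == [16, 24, 32]  # non-decreasing depth

    def test_deterministic(self, pair128):
        net = al.AlignmentNet(seed=0)
        a = al.build_feature_pyramid(pair128.reference, net)
        b = al.build_feature_pyramid(pair128.reference, net)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            al.build_feature_pyramid(np.zeros((100, 100, 3), np.float32))


class TestCorrelate:
    def test_self_correlation_maximal_at_centre(self, rng):
        f = rng.normal(size=(8, 8, 16)).astype(np.float32)
        corr = al.correlate(f, f, radius=2)
        assert corr.shape == (8, 8, 25)
        centre = corr[:, :, 12]
        assert np.allclose(centre, 1.0, atol=1e-5)
        assert np.all(corr <= centre[:, :, None] + 1e-5)

    def test_orthogonal_features_zero(self):
        a = np.zeros((4, 4, 2), np.float32)
        b = np.zeros((4, 4, 2), np.float32)
        a[:, :, 0] = 1.0
        b[:, :, 1] = 1.0
        corr = al.correlate(a, b, radius=1)
        assert np.abs(corr[1:-1, 1:-1]).max() < 1e-6

    def test_matches_bruteforce_on_normalised_maps(self, rng):
        a = rng.normal(size=(5, 5, 3))
        b = rng.normal(size=(5, 5, 3))
        an = a / np.linalg.norm(a, axis=2, keepdims=True)
        bn = b / np.linalg.norm(b, axis=2, keepdims=True)
        corr = al.correlate(a, b, radius=1)
        for yy in range(1, 4):
            for xx in range(1, 4):
                for d, (dy, dx) in enumerate(
                    [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
                ):
                    ref = float((an[yy, xx] * bn[yy + dy, xx + dx]).sum())
                    assert abs(corr[yy, xx, d] - ref) < 1e-5


class TestRegressionHead:
    def test_zero_init_emits_zero(self, rng):
        corr = rng.normal(size=(16, 16, 81)).astype(np.float32)
        out = al.regress_offsets(corr)
        assert np.allclose(out, 0.0)
        assert out.shape == (8,)


class TestTensorDLT:
    def test_examples(self):
        assert np.allclose(al.tensor_dlt(np.zeros(8), 128), np.eye(3))
        h = al.tensor_dlt(np.tile([10.0, 0.0], 4), 128)
        assert np.allclose(h, [[1, 0, 10], [0, 1, 0], [0, 0, 1]], atol=1e-9)


class TestAblationLoss:
    def test_perfect_alignment_zero(self, pair128):
        full = np.ones((128, 128), np.float32)
        assert al.ablation_loss(pair128.reference, pair128.reference, full) == 0.0

    def test_constant_difference_closed_form(self):
        a = np.full((32, 32, 3), 0.5, np.float32)
        b = np.full((32, 32, 3), 0.6, np.float32)
        full = np.ones((32, 32), np.float32)
        assert al.ablation_loss(a, b, full) == pytest.approx(0.1, abs=1e-6)

    def test_empty_mask_rejected(self, pair128):
        with pytest.raises(ValueError):
            al.ablation_loss(
                pair128.reference, pair128.target, np.zeros((128, 128), np.float32)
            )

    def test_gradient_wrt_corner_offsets(self, rng):
        """Numeric vs analytic gradients through warp + DLT, 1e-3 relative."""
        img = rng.uniform(size=(1, 3, 16, 16))
        tgt = rng.uniform(size=(1, 3, 16, 16))
        off0 = rng.uniform(-2, 2, size=(1, 8)) + 0.017

        def loss_of(off_arr):
            off = nn.Tensor(np.asarray(off_arr, np.float64), requires_grad=True)
            h = ops.dlt_solve(off, 16)
            grid = ops.homography_grid(h, (16, 16), invert=True)
            ones = nn.Tensor(np.ones((1, 1, 16, 16)))
            w = ops.grid_sample(
                nn.concat([nn.Tensor(np.asarray(tgt)), ones], axis=1), grid
            )
            return al._abl(w[:, :3], nn.Tensor(np.asarray(img)), w[:, 3:4]), off

        loss, off = loss_of(off0)
        loss.backward()
        analytic = off.grad.copy()
        eps = 1e-5
        for i in range(8):
            p = off0.copy()
            p[0, i] += eps
            lp, _ = loss_of(p)
            p[0, i] -= 2 * eps
            lm, _ = loss_of(p)
            num = (lp.item() - lm.item()) / (2 * eps)
            assert abs(num - analytic[0, i]) / (abs(num) + 1e-6) < 1e-3


class TestMultiscaleLoss:
    def test_identity_pair_zero_estimate(self, pair128):
        x = al.stack_pair(pair128.reference, pair128.reference)[None]
        net = al.AlignmentNet(seed=0)
        loss, total, h = al.multiscale_alignment_loss(
            nn.Tensor(x.transpose(0, 3, 1, 2)), net, 32.0
        )
        assert np.allclose(total.data, 0.0)
        assert loss.item() == pytest.approx(0.0, abs=1e-5)

    def test_nonnegative(self, pair128):
        x = al.stack_pair(pair128.reference, pair128.target)[None]
        net = al.AlignmentNet(seed=1)
        loss, _, _ = al.multiscale_alignment_loss(
            nn.Tensor(x.transpose(0, 3, 1, 2)), net, 32.0
        )
        assert loss.item() >= 0.0

    def test_translation_sweep_minimised_at_truth(self, pair128):
        """Photometric loss dips exactly at the true 8-px offset."""
        x = al.stack_pair(pair128.reference, pair128.target)[None].transpose(0, 3, 1, 2)
        ref, tgt = nn.Tensor(x[:, :3]), nn.Tensor(x[:, 3:])
        ones = nn.Tensor(np.ones((1, 1, 128, 128), np.float32))

        def loss_at(dx):
            off = nn.Tensor(np.tile([dx, 0.0], 4)[None].astype(np.float32))
            h = ops.dlt_solve(off, 128)
            grid = ops.homography_grid(h, (128, 128), invert=True)
            w = ops.grid_sample(nn.concat([tgt, ones], axis=1), grid)
            return al._abl(w[:, :3], ref, w[:, 3:4]).item()

        sweep = [loss_at(d) for d in (0, 2, 4, 6, 8, 10, 12)]
        assert np.argmin(sweep) == 4  # dx = 8
        assert all(a > b for a, b in zip(sweep[:4], sweep[1:5]))
        assert all(a < b for a, b in zip(sweep[4:], sweep[5:]))


class TestAligner:
    def test_untrained_predicts_identity(self, pair128):
        alg = al.HomographyAligner(seed=0)
        alg._ensure_model(3)
        x = al.stack_pair(pair128.reference, pair128.target)[None]
        h = alg.predict(x)[0]
        assert np.allclose(h, np.eye(3), atol=1e-6)

    def test_predictions_bit_stable(self, pair128):
        alg = al.HomographyAligner(seed=0)
        alg._ensure_model(3)
        x = al.stack_pair(pair128.reference, pair128.target)[None]
        est1 = alg._estimates(x)[0]
        est2 = alg._estimates(x)[0]
        assert np.array_equal(est1.total_offsets, est2.total_offsets)

    def test_estimate_structure(self, pair128, trained_aligner):
        est = al.estimate_homography((pair128.reference, pair128.target), trained_aligner)
        assert len(est.per_scale_offsets) == 3
        assert est.total_offsets.shape == (8,)
        assert est.h[2, 2] == pytest.approx(1.0)
        # residuals rescaled sum to the (clamped) total
        clamp = trained_aligner.offset_clamp_frac * 128
        acc = np.zeros(8)
        for r in est.per_scale_offsets:
            acc = np.clip(acc + r, -clamp, clamp)
        assert np.allclose(acc, est.total_offsets, atol=1e-4)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            al.HomographyAligner().fit(np.zeros((0, 32, 32, 6), np.float32))
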