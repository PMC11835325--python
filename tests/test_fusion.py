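"""Mask construction, the two fusion branches, and the seam-aware loss."""

import warnings

import numpy as np
import pytest

from endostitch import fusion as fu
from endostitch import synthetic as syn
from endostitch.warping import double_h_transform


class TestMasks:
    def test_partition_of_union(self, sample_canvas):
        masks = fu.build_masks(sample_canvas)
        overlap = sample_canvas.overlap_mask
        union = np.maximum(sample_canvas.mask_reference, sample_canvas.mask_target)
        part = masks.content_reference + masks.content_target + overlap
        assert np.array_equal(part, union)
        assert set(np.unique(masks.content_reference)) <= {0.0, 1.0}
        assert np.all(masks.content_reference * masks.content_target == 0)
        assert np.all(masks.content_reference * overlap == 0)

    def test_seam_interior_is_one(self, sample_canvas):
        from scipy.ndimage import binary_erosion

        masks = fu.build_masks(sample_canvas, seam_sigma=5.0)
        assert masks.seam.min() >= 0.0 and masks.seam.max() <= 1.0
        interior = binary_erosion(sample_canvas.overlap_mask > 0.5, iterations=16)
        if interior.any():
            assert masks.seam[interior].min() > 0.999

    def test_identity_canvas_all_overlap(self):
        img = syn.generate_texture(0, 64)
        canvas = double_h_transform((img, img), np.eye(3))
        masks = fu.build_masks(canvas)
        assert masks.content_reference.sum() == 0
        assert masks.content_target.sum() == 0
        assert masks.seam.max() == 1.0

    def test_disjoint_canvas_warns_zero_seam(self):
        img = syn.generate_texture(0, 64)
        h = np.array([[1.0, 0, 300], [0, 1.0, 0], [0, 0, 1.0]])
        canvas = double_h_transform((img, img), h)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            masks = fu.build_masks(canvas)
        assert rec
        assert masks.seam.sum() == 0
        assert np.array_equal(masks.content_reference, canvas.mask_reference)


class TestBranches:
    def test_output_shapes_and_ranges(self, sample_canvas):
        net = fu.FusionNet(seed=0)
        out = fu.fuse(sample_canvas, net)
        assert out.fused.shape == sample_canvas.warped_reference.shape
        assert out.low_res.shape == out.fused.shape  # small canvas: no downscale
        assert 0.0 <= out.fused.min() and out.fused.max() <= 1.0
        assert 0.0 <= out.low_res.min() and out.low_res.max() <= 1.0

    def test_zero_initialised_refinement_residual(self, sample_canvas):
        net = fu.FusionNet(seed=0)
        out = fu.fuse(sample_canvas, net)
        assert np.allclose(out.residual, 0.0)
        assert np.allclose(out.fused, np.clip(out.low_res, 0, 1), atol=1e-6)

    def test_deterministic(self, sample_canvas):
        net = fu.FusionNet(seed=0)
        a = fu.fuse(sample_canvas, net)
        b = fu.fuse(sample_canvas, net)
        assert np.array_equal(a.fused, b.fused)

    def test_working_resolution_cap(self):
        img = syn.generate_texture(1, 128)
        canvas = double_h_transform((img, img), np.eye(3))
        net = fu.FusionNet(seed=0)
        out = fu.fuse(canvas, net, max_side=64)
        assert out.low_res.shape[0] == 64
        assert out.fused.shape == (128, 128, 3)


class TestFusionLoss:
    def test_perfect_composite_zero(self):
        img = syn.generate_texture(2, 64)
        canvas = double_h_transform((img, img), np.eye(3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masks = fu.build_masks(canvas)
        out = fu.StitchOutput(fused=canvas.warped_reference,
                              low_res=canvas.warped_reference,
                              residual=np.zeros_like(canvas.warped_reference))
        assert fu.fusion_loss(out, canvas, masks) == pytest.approx(0.0, abs=1e-7)

    def test_nonnegative_random(self, sample_canvas, rng):
        masks = fu.build_masks(sample_canvas)
        fused = rng.random(sample_canvas.warped_reference.shape).astype(np.float32)
        out = fu.StitchOutput(fused=fused, low_res=fused, residual=np.zeros_like(fused))
        assert fu.fusion_loss(out, sample_canvas, masks) >= 0.0

    def test_hard_cut_has_higher_seam_term_than_feathered(self, sample_canvas):
        masks = fu.build_masks(sample_canvas)

        def seam_term(img):
            out = fu.StitchOutput(fused=img, low_res=img, residual=np.zeros_like(img))
            return fu.fusion_loss(out, sample_canvas, masks,
                                  content_weight=0.0, seam_weight=1.0,
                                  overlap_weight=0.0)

        hard = fu.hard_cut_composite(sample_canvas)
        feathered = fu.average_blend(sample_canvas)
        assert seam_term(hard) > seam_term(feathered)


class TestSeamBand:
    def test_band_surrounds_overlap_boundary(self, sample_canvas):
        band = fu.seam_band(sample_canvas, width=5)
        assert band.any()
        union = (sample_canvas.mask_reference + sample_canvas.mask_target) > 0.5
        assert not (band & ~union).any()

    def test_no_overlap_no_band(self):
        img = syn.generate_texture(0, 64)
        h = np.array([[1.0, 0, 300], [0, 1.0, 0], [0, 0, 1.0]])
        canvas = double_h_transform((img, img), h)
        assert not fu.seam_band(canvas).any()


class TestTraining:
    def test_loss_moving_average_decreases(self, trained_fusion):
        """First 200 steps of the scaled run trend downward."""
        hist = np.asarray(trained_fusion.loss_history_[:200])
        smooth = np.convolve(hist, np.ones(25) / 25, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_smoke_short_fit(self, noiseless_samples):
        canvases = [
            double_h_transform((s.reference, s.target), s.h_true)
            for s in noiseless_samples[:3]
        ]
        sf = fu.SeamFusion(seed=0, lr=1e-3, n_epochs=2, max_steps=4)
        sf.fit(canvases)
        assert sf.n_steps_ == 4
        assert np.isfinite(sf.loss_history_).all()
        out = sf.transform(canvases[0])
        assert out.fused.shape == canvases[0].warped_reference.shape
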