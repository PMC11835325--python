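"""Synthetic endoscope-pair generator: determinism, grade control, geometry
self-consistency."""

import json
import warnings
from collections import Counter

import numpy as np
import pytest

from endostitch import geometry as geo
from endostitch import synthetic as syn


class TestTexture:
    def test_deterministic_and_bounded(self):
        a = syn.generate_texture(0, 128)
        b = syn.generate_texture(0, 128)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0
        assert a.shape == (128, 128, 3)

    def test_seed_sensitivity(self):
        a = syn.generate_texture(0, 128)
        b = syn.generate_texture(1, 128)
        assert (a != b).mean() > 0.01

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_texture(0, 16)


class TestVignette:
    def test_hard_edge_preserves_inside(self):
        img = syn.generate_texture(2, 64)
        out = syn.apply_vignette(img, radius=1.0, falloff=0.0)
        assert np.array_equal(out[32, 32], img[32, 32])  # centre unchanged
        assert np.all(out[0, 0] == 0)  # corner outside inscribed circle

    def test_attenuation_only(self):
        img = syn.generate_texture(2, 64)
        out = syn.apply_vignette(img, radius=0.9)
        assert out.mean() <= img.mean()
        assert np.all(out <= img + 1e-6)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            syn.apply_vignette(np.zeros((32, 32, 3)), radius=0.0)


class TestCornerSampling:
    @pytest.mark.parametrize("grade", syn.GRADES)
    def test_offsets_hit_requested_grade(self, grade):
        rng = np.random.default_rng(3)
        for _ in range(5):
            off = syn.sample_corner_offsets(grade, 57.0, rng, 128)
            assert np.abs(off).max() <= 57.0
            h = geo.homography_from_offsets(off, 128)
            assert syn.grade_of(geo.overlap_rate(h, 128)) == grade

    def test_zero_offsets_are_large_grade(self):
        h = geo.homography_from_offsets(np.zeros(8), 128)
        assert geo.overlap_rate(h, 128) == 1.0
        assert syn.grade_of(1.0) == "large"

    def test_deterministic_under_seed(self):
        a = syn.sample_corner_offsets("medium", 57.0, np.random.default_rng(9), 128)
        b = syn.sample_corner_offsets("medium", 57.0, np.random.default_rng(9), 128)
        assert np.array_equal(a, b)

    def test_unreachable_grade_raises(self):
        with pytest.raises(RuntimeError):
            # 4 px of corner perturbation cannot reach sub-40% overlap
            syn.sample_corner_offsets("small", 4.0, np.random.default_rng(0), 128)

    def test_budget_precondition(self):
        with pytest.raises(ValueError):
            syn.sample_corner_offsets("large", 64.0, np.random.default_rng(0), 128)


class TestRenderPair:
    def test_identity_bitwise(self):
        tex = syn.generate_texture(4, 200)
        s = syn.render_pair(tex, np.eye(3), 128)
        assert np.array_equal(s.reference, s.target)
        assert s.grade == "large"

    def test_translation_overlap_closed_form(self):
        tex = syn.generate_texture(4, 200)
        h = np.array([[1.0, 0, 16], [0, 1.0, 0], [0, 0, 1.0]])
        s = syn.render_pair(tex, h, 128)
        assert s.overlap == pytest.approx((128 - 16) / 128, abs=1e-12)

    def test_invariants_hold(self):
        tex = syn.generate_texture(4, 220)
        rng = np.random.default_rng(1)
        off = syn.sample_corner_offsets("medium", 40.0, rng, 128)
        h = geo.homography_from_offsets(off, 128)
        s = syn.render_pair(tex, h, 128, rng=rng, brightness_jitter=0.1,
                            blur_sigma_range=(0.0, 1.0))
        s.validate()
        assert s.reference.shape == s.target.shape == (128, 128, 3)
        assert 0.0 <= s.target.min() and s.target.max() <= 1.0

    def test_singular_homography_rejected(self):
        tex = syn.generate_texture(4, 200)
        with pytest.raises(ValueError):
            syn.render_pair(tex, np.zeros((3, 3)), 128)

    def test_corner_recovery_from_projected_points(self):
        """Estimating h from matched h-projected corners recovers h exactly."""
        rng = np.random.default_rng(2)
        off = syn.sample_corner_offsets("medium", 40.0, rng, 128)
        h = geo.homography_from_offsets(off, 128)
        base = geo.corner_points(128)
        h_rec = geo.svd_dlt(base, geo.apply_homography(h, base))
        assert np.abs(h_rec - h).max() < 1e-6


class TestDataset:
    def test_grade_counts_and_rounding(self):
        counts = syn._grade_counts(100, (1 / 3, 1 / 3, 1 / 3))
        assert counts == {"small": 33, "medium": 33, "large": 34}

    def test_reproducible_manifest_and_grades(self, tmp_path):
        cfg = syn.DatasetConfig(n_pairs=6, seed=3, image_size=64,
                                max_corner_perturbation=28.0)
        samples, manifest = syn.make_dataset(cfg, out_dir=tmp_path / "d")
        _, manifest2 = syn.make_dataset(cfg)
        assert manifest == manifest2
        assert Counter(s.grade for s in samples) == {"small": 2, "medium": 2, "large": 2}
        on_disk = json.loads((tmp_path / "d" / "manifest.json").read_text())
        assert len(on_disk["samples"]) == 6
        assert (tmp_path / "d" / "000000_ref.png").exists()
        # grade re-derived from the stored homography matches the manifest
        for rec in on_disk["samples"]:
            h = np.array(rec["h_true"]).reshape(3, 3)
            assert syn.grade_of(geo.overlap_rate(h, 64)) == rec["grade"]

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            syn.DatasetConfig(n_pairs=0)
        with pytest.raises(ValueError):
            syn.DatasetConfig(image_size=16)
        with pytest.raises(ValueError):
            syn.DatasetConfig(grade_mix=(0.5, 0.5, 0.5))


class TestFrameSampler:
    @pytest.fixture()
    def frames_dir(self, tmp_path):
        import imageio.v3 as iio

        for i in range(21):
            img = (syn.generate_texture(i, 32) * 255).astype(np.uint8)
            iio.imwrite(tmp_path / f"frame_{i:03d}.png", img)
        return tmp_path

    @pytest.mark.parametrize("interval,expected", [(20, 1), (5, 16), (10, 11)])
    def test_pair_counts(self, frames_dir, interval, expected):
        pairs = syn.frame_sampler(frames_dir, interval)
        assert len(pairs) == expected
        ref, tgt = pairs[0]
        assert ref.dtype == np.float32 and ref.max() <= 1.0

    def test_too_few_frames_warns_empty(self, tmp_path):
        import imageio.v3 as iio

        for i in range(3):
            iio.imwrite(tmp_path / f"f{i}.png", np.zeros((16, 16, 3), np.uint8))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            assert syn.frame_sampler(tmp_path, 5) == []
        assert rec
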