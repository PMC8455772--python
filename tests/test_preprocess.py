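import numpy as np
import pytest

from ettcascade.geometry import CropWindow, Frame, PixelSpacing, Point, map_point
from ettcascade.preprocess import (
    AugmentParams,
    augment,
    extract_crop,
    preprocess,
    sample_augment,
)


class TestPreprocess:
    def test_output_shape_and_scale(self, rng):
        img = rng.normal(size=(600, 400)).astype(np.float32)
        res = preprocess(img, PixelSpacing(0.5, 0.5), model_size=512)
        assert res.image.shape == (512, 512)
        assert res.to_model.scale_y == pytest.approx(512 / 600)
        assert res.to_model.scale_x == pytest.approx(512 / 600)
        assert res.to_model.src_frame == Frame.ORIGINAL
        assert res.to_model.dst_frame == Frame.MODEL
        assert res.spacing.row_mm_per_px == pytest.approx(0.5 * 600 / 512)

    def test_z_score(self, rng):
        img = rng.normal(3.0, 2.0, size=(300, 300)).astype(np.float32)
        res = preprocess(img, model_size=256)
        assert abs(float(res.image.mean())) < 1e-5
        assert abs(float(res.image.std()) - 1.0) < 1e-5

    def test_identity_passthrough(self, rng):
        img = rng.normal(size=(512, 512)).astype(np.float32)
        res = preprocess(img)
        assert res.to_model.scale_y == 1.0 and res.to_model.offset_y == 0.0
        z = (img - img.mean()) / img.std()
        assert np.allclose(res.image, z, atol=1e-5)

    def test_constant_image_flagged(self):
        res = preprocess(np.full((64, 64), 7.0, dtype=np.float32), model_size=64)
        assert res.constant_input
        assert res.std == 1.0
        assert np.allclose(res.image, 0.0)

    def test_deterministic(self, rng):
        img = rng.normal(size=(200, 150)).astype(np.float32)
        a = preprocess(img, model_size=128)
        b = preprocess(img, model_size=128)
        assert np.array_equal(a.image, b.image)

    def test_landmark_follows_map(self, rng):
        # a bright dot placed at a landmark stays on it through preprocessing
        img = np.zeros((600, 400), dtype=np.float32)
        img[330:336, 198:204] = 100.0
        res = preprocess(img, model_size=512)
        p = map_point(Point(332.5, 200.5, Frame.ORIGINAL), res.to_model)
        ys, xs = np.mgrid[0:512, 0:512]
        mass = np.clip(res.image - res.image.min(), 0, None)
        mass = np.where(res.image > res.image.mean() + 3 * res.image.std(),
                        res.image, 0.0)
        cy = (ys * mass).sum() / mass.sum()
        cx = (xs * mass).sum() / mass.sum()
        assert abs(cy - p.y) < 1.0 and abs(cx - p.x) < 1.0

    @pytest.mark.parametrize("bad", [np.zeros((0, 4)), np.zeros((3, 4, 5))])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            preprocess(bad.astype(np.float32))

    def test_nonfinite_rejected(self):
        img = np.ones((8, 8), dtype=np.float32)
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            preprocess(img)


class TestAugment:
    def test_identity_params(self, rng):
        img = rng.normal(size=(64, 64)).astype(np.float32)
        params = AugmentParams(jitter_lo=1.0, jitter_hi=1.0, max_disp_px=0)
        p = Point(30.0, 20.0, Frame.MODEL)
        out, pts, rec = augment(img, [p], params, rng)
        assert np.allclose(out, img, atol=1e-6)
        assert pts[0].y == pytest.approx(30.0) and pts[0].x == pytest.approx(20.0)
        assert rec.scale == 1.0 and rec.ty == 0 and rec.tx == 0

    def test_scale_bounds_512(self, rng):
        # 1 +/- 14/256 for a 512-px frame
        lo, hi = 1 - 14 / 256, 1 + 14 / 256
        assert lo == pytest.approx(0.9453125)
        assert hi == pytest.approx(1.0546875)
        scales = [sample_augment(rng, AugmentParams(), 512, 512).scale
                  for _ in range(2000)]
        assert min(scales) >= lo and max(scales) <= hi

    def test_displacement_and_jitter_bounds(self):
        rng = np.random.default_rng(0)
        params = AugmentParams()
        worst_disp, worst_jit = 0.0, 0.0
        for _ in range(10_000):
            rec = sample_augment(rng, params, 512, 512)
            worst_disp = max(worst_disp, rec.max_corner_displacement(512, 512))
            worst_jit = max(worst_jit, rec.jitter)
            assert 0.90 <= rec.jitter <= 1.10
        assert worst_disp <= 14.0
        assert worst_disp > 10.0  # the budget is actually used

    def test_landmark_consistency_property(self):
        # dot centroid tracks the transformed landmark within 1 px (200 draws)
        rng = np.random.default_rng(7)
        params = AugmentParams(max_disp_px=6)
        ys, xs = np.mgrid[0:64, 0:64]
        for _ in range(200):
            ly, lx = rng.uniform(24, 40, size=2)
            img = np.exp(-((ys - ly) ** 2 + (xs - lx) ** 2) / 4.0).astype(np.float32)
            out, pts, _ = augment(img, [Point(ly, lx, Frame.MODEL)], params, rng)
            mass = np.clip(out, 0, None)
            cy = (ys * mass).sum() / mass.sum()
            cx = (xs * mass).sum() / mass.sum()
            assert abs(cy - pts[0].y) < 1.0
            assert abs(cx - pts[0].x) < 1.0

    def test_same_seed_same_stream(self):
        img = np.random.default_rng(1).normal(size=(32, 32)).astype(np.float32)
        params = AugmentParams()
        recs1 = [augment(img, [], params, np.random.default_rng(5))[2]
                 for _ in range(1)]
        a = [sample_augment(np.random.default_rng(5), params, 32, 32)
             for _ in range(1)]
        s1 = [sample_augment(np.random.default_rng(9), params, 64, 64).scale
              for _ in range(10)]
        s2 = [sample_augment(np.random.default_rng(9), params, 64, 64).scale
              for _ in range(10)]
        s3 = [sample_augment(np.random.default_rng(10), params, 64, 64).scale
              for _ in range(10)]
        assert s1 == s2
        assert s1 != s3

    def test_jitter_applied_to_stats(self, rng):
        raw = np.random.default_rng(2).normal(10.0, 4.0, size=(64, 64))
        mu, sigma = float(raw.mean()), float(raw.std())
        z = ((raw - mu) / sigma).astype(np.float32)
        params = AugmentParams(jitter_lo=1.1, jitter_hi=1.1, max_disp_px=0)
        out, _, rec = augment(z, [], params, rng, norm_stats=(mu, sigma))
        f = rec.jitter
        expected = (raw - f * mu) / (f * sigma)
        assert np.allclose(out, expected, atol=1e-5)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            AugmentParams(jitter_lo=0.0)
        with pytest.raises(ValueError):
            AugmentParams(jitter_lo=1.2, jitter_hi=1.0)
        with pytest.raises(ValueError):
            AugmentParams(max_disp_px=-1)


class TestExtractCrop:
    def test_exact_subgrid(self, rng):
        img = rng.normal(size=(512, 512)).astype(np.float32)
        w = CropWindow(100, 356, 200, 328, 256, 128)
        crop = extract_crop(img, w)
        assert np.array_equal(crop, img[100:356, 200:328])

    def test_zero_fill_top(self, rng):
        img = rng.normal(size=(512, 512)).astype(np.float32)
        w = CropWindow(-68, 188, 0, 128, 256, 128)
        crop = extract_crop(img, w)
        assert np.all(crop[:68] == 0.0)
        assert np.array_equal(crop[68:], img[:188, :128])

    def test_whole_image_identity(self, rng):
        img = rng.normal(size=(64, 32)).astype(np.float32)
        w = CropWindow(0, 64, 0, 32, 64, 32)
        assert np.array_equal(extract_crop(img, w), img)

    def test_resampled_output_shape(self, rng):
        img = rng.normal(size=(128, 128)).astype(np.float32)
        w = CropWindow(0, 64, 0, 32, 256, 128)
        assert extract_crop(img, w).shape == (256, 128)
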