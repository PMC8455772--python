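import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ettcascade.geometry import (
    AffineMap,
    Frame,
    FrameMismatchError,
    NoSpacingError,
    PixelSpacing,
    Point,
    crop_window_for_carina,
    denormalize_coords,
    distance_cm,
    map_point,
    normalize_coords,
    pad_to_square_map,
    resample_map,
    unmap_point,
)

finite = st.floats(-1e4, 1e4, allow_nan=False, allow_infinity=False)


class TestPadToSquare:
    def test_portrait(self):
        m, side = pad_to_square_map(600, 400)
        assert side == 600
        assert (m.offset_y, m.offset_x, m.scale_y, m.scale_x) == (0, 0, 1, 1)

    def test_already_square(self):
        m, side = pad_to_square_map(512, 512)
        assert side == 512
        p = Point(10.0, 20.0, Frame.ORIGINAL)
        assert map_point(p, m) == Point(10.0, 20.0, Frame.PADDED)

    def test_round_trip(self):
        m, _ = pad_to_square_map(600, 400)
        p = Point(10.0, 20.0, Frame.ORIGINAL)
        back = unmap_point(map_point(p, m), m)
        assert (back.y, back.x) == (10.0, 20.0)

    def test_symmetric_offsets(self):
        m, side = pad_to_square_map(400, 600, symmetric=True)
        assert side == 600
        assert (m.offset_y, m.offset_x) == (100, 0)

    @pytest.mark.parametrize("h,w", [(0, 5), (5, 0), (-2, 3)])
    def test_invalid_dims(self, h, w):
        with pytest.raises(ValueError):
            pad_to_square_map(h, w)


class TestResample:
    def test_600_to_512(self):
        m, _ = resample_map(600, 600, 512, 512)
        p = map_point(Point(300.0, 200.0, Frame.PADDED), m)
        assert p.y == pytest.approx(256.0, abs=1e-12)
        assert p.x == pytest.approx(200 * 512 / 600, abs=1e-12)

    def test_spacing_rescale(self):
        _, eff = resample_map(600, 600, 512, 512, PixelSpacing(0.5, 0.5))
        assert eff.row_mm_per_px == pytest.approx(0.5 * 600 / 512, abs=1e-12)
        assert eff.row_mm_per_px == pytest.approx(0.5859375, abs=1e-7)

    def test_identity(self):
        m, eff = resample_map(512, 512, 512, 512, PixelSpacing(0.7, 0.7))
        assert m.scale_y == m.scale_x == 1.0
        assert eff == PixelSpacing(0.7, 0.7)

    def test_spacing_conservation_exact(self):
        # spacing_eff * dst == spacing * src per axis, exactly
        sp = PixelSpacing(0.631, 0.717)
        _, eff = resample_map(600, 480, 512, 512, sp)
        assert eff.row_mm_per_px * 512 == sp.row_mm_per_px * 600
        assert eff.col_mm_per_px * 512 == sp.col_mm_per_px * 480


class TestCropWindow:
    def test_centered_default(self):
        w = crop_window_for_carina(Point(300.0, 256.0, Frame.MODEL), 512, 512)
        assert (w.row_start, w.row_stop) == (172, 428)
        assert (w.col_start, w.col_stop) == (192, 320)
        assert (w.out_h, w.out_w) == (256, 128)

    def test_out_of_bounds_allowed(self):
        w = crop_window_for_carina(Point(60.0, 40.0, Frame.MODEL), 512, 512)
        assert (w.row_start, w.row_stop) == (-68, 188)
        assert (w.col_start, w.col_stop) == (-24, 104)

    def test_shape_is_half_by_quarter(self):
        w = crop_window_for_carina(Point(256.0, 256.0, Frame.MODEL), 512, 512)
        assert w.height == 256 and w.width == 128
        assert w.out_h / w.out_w == 2  # 2:1 aspect under defaults

    def test_wrong_frame(self):
        with pytest.raises(FrameMismatchError):
            crop_window_for_carina(Point(1.0, 1.0, Frame.ORIGINAL), 512, 512)

    @given(cy=st.floats(0, 511), cx=st.floats(0, 511))
    @settings(max_examples=100, deadline=None)
    def test_carina_at_centre(self, cy, cx):
        w = crop_window_for_carina(Point(cy, cx, Frame.MODEL), 512, 512)
        assert abs((w.row_start + w.row_stop) / 2 - cy) <= 0.5
        assert abs((w.col_start + w.col_stop) / 2 - cx) <= 0.5

    def test_vertical_offset(self):
        w0 = crop_window_for_carina(Point(300.0, 256.0, Frame.MODEL), 512, 512)
        w1 = crop_window_for_carina(Point(300.0, 256.0, Frame.MODEL), 512, 512,
                                    v_offset_px=-16)
        assert w1.row_start == w0.row_start - 16
        assert w1.col_start == w0.col_start


class TestMapPoint:
    def test_identity(self):
        m = AffineMap(1, 1, 0, 0, Frame.MODEL, Frame.MODEL)
        p = Point(123.4, 56.7, Frame.MODEL)
        assert map_point(p, m) == p

    def test_crop_offset(self):
        w = crop_window_for_carina(Point(300.0, 256.0, Frame.MODEL), 512, 512)
        m = w.to_model_map()
        p = map_point(Point(10.0, 5.0, Frame.CROP), m)
        assert (p.y, p.x) == (182.0, 197.0)

    def test_frame_mismatch(self):
        m = AffineMap(1, 1, 0, 0, Frame.CROP, Frame.MODEL)
        with pytest.raises(FrameMismatchError):
            map_point(Point(1.0, 1.0, Frame.MODEL), m)

    @given(y=finite, x=finite,
           sy=st.floats(0.01, 100), sx=st.floats(0.01, 100),
           oy=finite, ox=finite)
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, y, x, sy, sx, oy, ox):
        m = AffineMap(sy, sx, oy, ox, Frame.MODEL, Frame.CROP)
        p = Point(y, x, Frame.MODEL)
        back = unmap_point(map_point(p, m), m)
        assert math.isclose(back.y, y, abs_tol=1e-9 + 1e-9 * abs(y))
        assert math.isclose(back.x, x, abs_tol=1e-9 + 1e-9 * abs(x))

    def test_compose(self):
        a = AffineMap(2, 2, 1, 1, Frame.ORIGINAL, Frame.PADDED)
        b = AffineMap(0.5, 0.5, -3, -3, Frame.PADDED, Frame.MODEL)
        c = a.compose(b)
        p = Point(10.0, 20.0, Frame.ORIGINAL)
        via = map_point(map_point(p, a), b)
        direct = map_point(p, c)
        assert (via.y, via.x) == (direct.y, direct.x)
        with pytest.raises(FrameMismatchError):
            b.compose(a)


class TestNormalize:
    @pytest.mark.parametrize("p,h,w,expected", [
        (Point(256.0, 256.0, Frame.MODEL), 512, 512, (0.5, 0.5)),
        (Point(0.0, 0.0, Frame.MODEL), 512, 512, (0.0, 0.0)),
        (Point(128.0, 64.0, Frame.CROP), 256, 128, (0.5, 0.5)),
    ])
    def test_examples(self, p, h, w, expected):
        assert normalize_coords(p, h, w) == expected

    @given(y=finite, x=finite)
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, y, x):
        ny, nx = normalize_coords(Point(y, x, Frame.MODEL), 512, 512)
        p = denormalize_coords(ny, nx, 512, 512, Frame.MODEL)
        assert math.isclose(p.y, y, abs_tol=1e-9 + 1e-12 * abs(y))
        assert math.isclose(p.x, x, abs_tol=1e-9 + 1e-12 * abs(x))


class TestDistance:
    def test_hand_computed(self):
        sp = PixelSpacing(0.7, 0.7)
        d = distance_cm(Point(300.0, 256.0, Frame.MODEL),
                        Point(220.0, 250.0, Frame.MODEL), sp)
        assert d == pytest.approx(5.615736, abs=1e-5)

    def test_zero(self):
        p = Point(5.0, 5.0, Frame.MODEL)
        assert distance_cm(p, p, PixelSpacing(0.5, 0.5)) == 0.0

    def test_anisotropic(self):
        d = distance_cm(Point(0.0, 0.0, Frame.MODEL),
                        Point(0.0, 10.0, Frame.MODEL), PixelSpacing(1.0, 0.5))
        assert d == pytest.approx(0.5, abs=1e-12)

    def test_frame_mismatch(self):
        with pytest.raises(FrameMismatchError):
            distance_cm(Point(0, 0, Frame.MODEL), Point(0, 0, Frame.CROP),
                        PixelSpacing(1, 1))

    def test_missing_spacing(self):
        with pytest.raises(NoSpacingError):
            distance_cm(Point(0, 0, Frame.MODEL), Point(1, 1, Frame.MODEL), None)

    @given(st.lists(st.tuples(finite, finite), min_size=3, max_size=3))
    @settings(max_examples=200, deadline=None)
    def test_metric_properties(self, pts):
        sp = PixelSpacing(0.8, 0.6)
        a, b, c = (Point(y, x, Frame.MODEL) for y, x in pts)
        dab = distance_cm(a, b, sp)
        assert dab >= 0
        assert dab == distance_cm(b, a, sp)
        assert dab <= distance_cm(a, c, sp) + distance_cm(c, b, sp) + 1e-9

    def test_zero_iff_identical(self):
        a = Point(1.0, 2.0, Frame.MODEL)
        b = Point(1.0, 2.0000001, Frame.MODEL)
        assert distance_cm(a, b, PixelSpacing(1, 1)) > 0


class TestValidation:
    def test_spacing_positive(self):
        with pytest.raises(ValueError):
            PixelSpacing(0.0, 0.5)
        with pytest.raises(ValueError):
            PixelSpacing(0.5, float("nan"))

    def test_point_finite(self):
        with pytest.raises(ValueError):
            Point(float("inf"), 0.0, Frame.MODEL)

    def test_affine_nonzero_scale(self):
        with pytest.raises(ValueError):
            AffineMap(0, 1, 0, 0, Frame.MODEL, Frame.CROP)
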