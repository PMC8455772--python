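"""Coordinate frames and the invertible maps between them.

Every landmark the cascade handles lives in one of four frames:

* ``ORIGINAL`` — the raw radiograph grid as acquired,
* ``PADDED``   — after zero-padding to a square matrix,
* ``MODEL``    — after resampling the square image to the network input size,
* ``CROP``     — inside the hard-attention window cut around the carina.

Coordinates are 0-based ``(row, col)`` = ``(y, x)`` pairs with the origin at
the top-left pixel centre.  Frame-to-frame conversions are per-axis affine
maps; composing a map with its inverse is the identity to better than 1e-9,
which the rest of the package (and the test suite) relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class Frame(str, Enum):
    """The four coordinate frames of the cascade."""

    ORIGINAL = "ORIGINAL"
    PADDED = "PADDED"
    MODEL = "MODEL"
    CROP = "CROP"


class FrameMismatchError(ValueError):
    """A point was used with a map or peer in a different frame."""


class NoSpacingError(ValueError):
    """Physical distance requested but no pixel spacing is available."""


@dataclass(frozen=True)
class PixelSpacing:
    """Physical pixel size in millimetres per pixel, per axis."""

    row_mm_per_px: float
    col_mm_per_px: float

    def __post_init__(self) -> None:
        for v in (self.row_mm_per_px, self.col_mm_per_px):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"pixel spacing must be positive and finite, got {v!r}")

    @property
    def isotropic(self) -> bool:
        return self.row_mm_per_px == self.col_mm_per_px


@dataclass(frozen=True)
class Point:
    """A landmark coordinate tagged with its frame."""

    y: float
    x: float
    frame: Frame

    def __post_init__(self) -> None:
        if not (math.isfinite(self.y) and math.isfinite(self.x)):
            raise ValueError(f"point coordinates must be finite, got ({self.y}, {self.x})")
        if not isinstance(self.frame, Frame):
            object.__setattr__(self, "frame", Frame(self.frame))


@dataclass(frozen=True)
class AffineMap:
    """Per-axis affine transform ``y' = y*scale_y + offset_y`` between frames."""

    scale_y: float
    scale_x: float
    offset_y: float
    offset_x: float
    src_frame: Frame
    dst_frame: Frame

    def __post_init__(self) -> None:
        if self.scale_y == 0 or self.scale_x == 0:
            raise ValueError("affine map scales must be nonzero")

    def apply(self, p: Point) -> Point:
        if p.frame != self.src_frame:
            raise FrameMismatchError(
                f"point in frame {p.frame.value}, map expects {self.src_frame.value}"
            )
        return Point(
            p.y * self.scale_y + self.offset_y,
            p.x * self.scale_x + self.offset_x,
            self.dst_frame,
        )

    def invert(self) -> "AffineMap":
        return AffineMap(
            1.0 / self.scale_y,
            1.0 / self.scale_x,
            -self.offset_y / self.scale_y,
            -self.offset_x / self.scale_x,
            self.dst_frame,
            self.src_frame,
        )

    def compose(self, other: "AffineMap") -> "AffineMap":
        """Return the map applying ``self`` first, then ``other``."""
        if self.dst_frame != other.src_frame:
            raise FrameMismatchError(
                f"cannot chain {self.dst_frame.value} into {other.src_frame.value}"
            )
        return AffineMap(
            self.scale_y * other.scale_y,
            self.scale_x * other.scale_x,
            self.offset_y * other.scale_y + other.offset_y,
            self.offset_x * other.scale_x + other.offset_x,
            self.src_frame,
            other.dst_frame,
        )


def map_point(p: Point, m: AffineMap) -> Point:
    """Apply ``m`` to ``p`` (forward direction)."""
    return m.apply(p)


def unmap_point(p: Point, m: AffineMap) -> Point:
    """Apply the inverse of ``m`` to ``p``."""
    return m.invert().apply(p)


@dataclass(frozen=True)
class CropWindow:
    """Half-open pixel bounds of the attention window in the MODEL frame.

    Bounds may extend past the image; extraction zero-fills out-of-bounds
    regions.  ``out_h``/``out_w`` give the matrix shape after resampling.
    """

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    out_h: int
    out_w: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("crop window bounds must be non-empty")
        if self.out_h < 1 or self.out_w < 1:
            raise ValueError("crop output shape must be positive")

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    def to_model_map(self) -> AffineMap:
        """CROP -> MODEL map (output-pixel coordinates back to model pixels)."""
        return AffineMap(
            self.height / self.out_h,
            self.width / self.out_w,
            float(self.row_start),
            float(self.col_start),
            Frame.CROP,
            Frame.MODEL,
        )


def pad_to_square_map(h: int, w: int, symmetric: bool = False) -> tuple[AffineMap, int]:
    """Map from ORIGINAL into the zero-padded square frame.

    Default convention pads right/bottom only, so coordinates are unchanged.
    ``symmetric=True`` splits the padding evenly (extra pixel goes to the
    bottom/right) and shifts coordinates accordingly.
    """
    if h < 1 or w < 1:
        raise ValueError(f"image dimensions must be positive, got {h}x{w}")
    side = max(h, w)
    if symmetric:
        off_y = (side - h) // 2
        off_x = (side - w) // 2
    else:
        off_y = off_x = 0
    m = AffineMap(1.0, 1.0, float(off_y), float(off_x), Frame.ORIGINAL, Frame.PADDED)
    return m, side


def resample_map(
    src_h: int,
    src_w: int,
    dst_h: int,
    dst_w: int,
    spacing: PixelSpacing | None = None,
    src_frame: Frame = Frame.PADDED,
    dst_frame: Frame = Frame.MODEL,
) -> tuple[AffineMap, PixelSpacing | None]:
    """Map for resampling a ``src_h x src_w`` grid to ``dst_h x dst_w``.

    Also rescales the pixel spacing so that physical extents are preserved:
    ``spacing_eff * dst == spacing * src`` exactly, per axis.
    """
    if min(src_h, src_w, dst_h, dst_w) < 1:
        raise ValueError("all dimensions must be >= 1")
    m = AffineMap(dst_h / src_h, dst_w / src_w, 0.0, 0.0, src_frame, dst_frame)
    eff = None
    if spacing is not None:
        eff = PixelSpacing(
            spacing.row_mm_per_px * src_h / dst_h,
            spacing.col_mm_per_px * src_w / dst_w,
        )
    return m, eff


def crop_window_for_carina(
    carina: Point,
    model_h: int,
    model_w: int,
    frac_h: float = 0.50,
    frac_w: float = 0.25,
    out_h: int | None = None,
    out_w: int | None = None,
    v_offset_px: float = 0.0,
) -> CropWindow:
    """Attention window centred on the (predicted) carina.

    The window spans ``frac_h``/``frac_w`` of the model input per axis
    (defaults give the 2:1, 50%/25% rectangle -> 256x128 from a 512 input).
    ``v_offset_px`` shifts the window centre vertically (negative = up);
    the default keeps the carina at the exact centre.  Bounds may fall
    outside the image; extraction zero-fills.
    """
    if carina.frame != Frame.MODEL:
        raise FrameMismatchError(
            f"carina must be in MODEL frame, got {carina.frame.value}"
        )
    height = round(frac_h * model_h)
    width = round(frac_w * model_w)
    cy = carina.y + v_offset_px
    row_start = round(cy - height / 2)
    col_start = round(carina.x - width / 2)
    return CropWindow(
        row_start=row_start,
        row_stop=row_start + height,
        col_start=col_start,
        col_stop=col_start + width,
        out_h=height if out_h is None else out_h,
        out_w=width if out_w is None else out_w,
    )


def normalize_coords(p: Point, h: int, w: int) -> tuple[float, float]:
    """Pixel coordinates -> fractions of the frame size, in [0, 1] in-bounds."""
    if h < 1 or w < 1:
        raise ValueError("frame dimensions must be >= 1")
    return p.y / h, p.x / w


def denormalize_coords(ny: float, nx: float, h: int, w: int, frame: Frame) -> Point:
    if h < 1 or w < 1:
        raise ValueError("frame dimensions must be >= 1")
    return Point(ny * h, nx * w, frame)


def distance_px(p1: Point, p2: Point) -> float:
    if p1.frame != p2.frame:
        raise FrameMismatchError(
            f"points in different frames: {p1.frame.value} vs {p2.frame.value}"
        )
    return math.hypot(p1.y - p2.y, p1.x - p2.x)


def distance_cm(p1: Point, p2: Point, spacing: PixelSpacing | None) -> float:
    """Physical Euclidean distance in centimetres.

    Per-axis mm scaling is applied before the norm so anisotropic spacing is
    handled correctly.  ``spacing`` must be the effective spacing of the
    frame both points live in.
    """
    if p1.frame != p2.frame:
        raise FrameMismatchError(
            f"points in different frames: {p1.frame.value} vs {p2.frame.value}"
        )
    if spacing is None:
        raise NoSpacingError(
            "no pixel spacing available; request pixel units explicitly instead"
        )
    dy_mm = (p1.y - p2.y) * spacing.row_mm_per_px
    dx_mm = (p1.x - p2.x) * spacing.col_mm_per_px
    return math.hypot(dy_mm, dx_mm) / 10.0
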