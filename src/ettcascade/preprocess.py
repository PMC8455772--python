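"""Image-side preprocessing and training-time augmentation.

``preprocess`` squares an image by zero-padding (right/bottom by default,
so ORIGINAL and PADDED coordinates coincide), resamples it to the model
input size and z-scores it.  ``augment`` applies random integer
translations and isotropic scales plus normalization-statistics jitter,
transforming any landmarks with the same geometric map.

Displacement accounting: the scale factor is drawn on
``1 ± max_disp_px/(side/2)`` so scaling alone never moves an image corner
more than ``max_disp_px``; the per-axis translation range is then reduced
by the scale-induced corner motion, keeping the total per-axis corner
displacement within ``max_disp_px`` for every draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .geometry import (
    AffineMap,
    CropWindow,
    Frame,
    PixelSpacing,
    Point,
    pad_to_square_map,
    resample_map,
)


@dataclass(frozen=True)
class AugmentParams:
    """Bounds for the stochastic training augmentations."""

    jitter_lo: float = 0.90
    jitter_hi: float = 1.10
    max_disp_px: int = 14
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.jitter_lo <= self.jitter_hi):
            raise ValueError("need 0 < jitter_lo <= jitter_hi")
        if self.max_disp_px < 0:
            raise ValueError("max_disp_px must be >= 0")


@dataclass(frozen=True)
class AugmentRecord:
    """The transform actually applied by one augmentation draw."""

    ty: int
    tx: int
    scale: float
    jitter: float

    def apply_to_point(self, p: Point, h: int, w: int) -> Point:
        cy, cx = h / 2.0, w / 2.0
        return Point(
            (p.y - cy) * self.scale + cy + self.ty,
            (p.x - cx) * self.scale + cx + self.tx,
            p.frame,
        )

    def max_corner_displacement(self, h: int, w: int) -> float:
        """Largest per-axis (Chebyshev) displacement of the four image corners."""
        cy, cx = h / 2.0, w / 2.0
        dy = abs(self.scale - 1.0) * cy + abs(self.ty)
        dx = abs(self.scale - 1.0) * cx + abs(self.tx)
        return max(dy, dx)


@dataclass(frozen=True)
class PreprocessResult:
    image: np.ndarray            # model_size x model_size, z-scored float32
    to_model: AffineMap          # composite ORIGINAL -> MODEL map
    spacing: PixelSpacing | None  # effective spacing in the MODEL frame
    mean: float                  # intensity statistics used for the z-score
    std: float
    constant_input: bool         # std was 0; unit std substituted


def preprocess(
    image: np.ndarray,
    spacing: PixelSpacing | None = None,
    model_size: int = 512,
    pad_symmetric: bool = False,
) -> PreprocessResult:
    """Zero-pad to square, resample to ``model_size``², z-score.

    Deterministic: identical input bytes give identical output.  A constant
    image gets unit standard deviation substituted and is flagged.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image values must be finite")
    h, w = image.shape

    pad_map, side = pad_to_square_map(h, w, symmetric=pad_symmetric)
    if side != h or side != w:
        off_y = int(pad_map.offset_y)
        off_x = int(pad_map.offset_x)
        padded = np.zeros((side, side), dtype=np.float32)
        padded[off_y:off_y + h, off_x:off_x + w] = image
    else:
        padded = image

    rs_map, eff_spacing = resample_map(side, side, model_size, model_size, spacing)
    if side != model_size:
        model = resize(padded, (model_size, model_size), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True).astype(np.float32)
    else:
        model = padded.astype(np.float32, copy=True)

    mean = float(model.mean())
    std = float(model.std())
    constant = std == 0.0
    if constant:
        std = 1.0
    model = (model - mean) / std

    return PreprocessResult(
        image=model,
        to_model=pad_map.compose(rs_map),
        spacing=eff_spacing,
        mean=mean,
        std=std,
        constant_input=constant,
    )


def sample_augment(rng: np.random.Generator, params: AugmentParams,
                   h: int, w: int | None = None) -> AugmentRecord:
    """Draw one augmentation transform (no image needed; used for audits too)."""
    if w is None:
        w = h
    d = params.max_disp_px
    half = max(h, w) / 2.0
    if d == 0 or half == 0:
        scale = 1.0
    else:
        scale = float(rng.uniform(1.0 - d / half, 1.0 + d / half))
    budget_y = max(0, math.floor(d - abs(scale - 1.0) * h / 2.0))
    budget_x = max(0, math.floor(d - abs(scale - 1.0) * w / 2.0))
    ty = int(rng.integers(-budget_y, budget_y + 1)) if budget_y else 0
    tx = int(rng.integers(-budget_x, budget_x + 1)) if budget_x else 0
    jitter = float(rng.uniform(params.jitter_lo, params.jitter_hi))
    return AugmentRecord(ty=ty, tx=tx, scale=scale, jitter=jitter)


def augment(
    image: np.ndarray,
    landmarks: list[Point],
    params: AugmentParams,
    rng: np.random.Generator,
    norm_stats: tuple[float, float] | None = None,
) -> tuple[np.ndarray, list[Point], AugmentRecord]:
    """Apply one random translation+scale (+ normalization jitter) draw.

    Landmarks receive exactly the geometric transform applied to the image.
    If ``norm_stats`` = (mean, std) of the z-scored ``image`` is given, the
    jitter factor rescales those stored statistics (the image is re-expressed
    as if it had been normalized with jittered mean and std).
    """
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape
    rec = sample_augment(rng, params, h, w)

    if rec.scale == 1.0 and rec.ty == 0 and rec.tx == 0:
        out = image.copy()
    else:
        cy, cx = h / 2.0, w / 2.0
        # output coord -> input coord: in = (out - c - t)/s + c
        inv_s = 1.0 / rec.scale
        offset = (cy - (cy + rec.ty) * inv_s, cx - (cx + rec.tx) * inv_s)
        out = ndimage.affine_transform(
            image, np.array([inv_s, inv_s]), offset=offset, order=1,
            mode="constant", cval=0.0, output=np.float32,
        )

    if norm_stats is not None and rec.jitter != 1.0:
        mu, sigma = norm_stats
        if sigma <= 0:
            raise ValueError("norm_stats std must be positive")
        f = rec.jitter
        out = out / f + (mu * (1.0 - f)) / (f * sigma)

    new_landmarks = [rec.apply_to_point(p, h, w) for p in landmarks]
    return out, new_landmarks, rec


def extract_crop(image: np.ndarray, window: CropWindow) -> np.ndarray:
    """Cut ``window`` out of ``image``, zero-filling out-of-bounds regions,
    then resample bilinearly to ``(out_h, out_w)`` (identity if same size)."""
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape
    patch = np.zeros((window.height, window.width), dtype=np.float32)
    r0, r1 = max(window.row_start, 0), min(window.row_stop, h)
    c0, c1 = max(window.col_start, 0), min(window.col_stop, w)
    if r0 < r1 and c0 < c1:
        patch[r0 - window.row_start:r1 - window.row_start,
              c0 - window.col_start:c1 - window.col_start] = image[r0:r1, c0:c1]
    if (window.out_h, window.out_w) == (window.height, window.width):
        return patch
    return resize(patch, (window.out_h, window.out_w), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True).astype(np.float32)
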