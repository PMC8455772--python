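"""Synthetic radiograph-like exams with exact ground truth.

Renders square-ish grayscale images containing a dark, slightly curved
trachea band that bifurcates at a carina landmark, optionally a bright
endotracheal-tube line whose distal tip sits a sampled physical distance
above the carina, optional distractor tube lines, per-exam pixel spacing,
and a paired report sentence consistent with the geometry.  The tip–carina
distance is drawn from a lognormal with median 4.10 cm and log-sd 0.3807,
matching the reference distribution (quartiles ≈ 3.17/5.30 cm, mean ≈ 4.41).

Everything is deterministic under a seed; images are written as 16-bit PNG
with a JSON sidecar, or kept in memory for training harnesses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import Frame, PixelSpacing, Point

MANIFEST_COLUMNS = [
    "exam_id", "patient_id", "path", "label", "carina_y", "carina_x",
    "tip_y", "tip_x", "spacing_row_mm", "spacing_col_mm", "report_text",
]


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the generator; defaults emulate the reference cohort."""

    image_h: int = 512
    image_w: int = 512
    spacing_lo: float = 0.6      # mm/px, isotropic by default
    spacing_hi: float = 0.8
    anisotropic: bool = False
    ett_prevalence: float = 0.5
    dist_median_cm: float = 4.10
    dist_log_sd: float = 0.3807
    dist_lo_cm: float = 0.5
    dist_hi_cm: float = 9.0
    noise_sd: float = 0.03
    distractor_prob: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.ett_prevalence <= 1.0):
            raise ValueError("ett_prevalence must be in [0, 1]")
        if not (0 < self.dist_lo_cm < self.dist_hi_cm):
            raise ValueError("distance bounds must be positive and ordered")
        if self.spacing_lo <= 0 or self.spacing_hi < self.spacing_lo:
            raise ValueError("bad spacing range")


@dataclass(frozen=True)
class Anatomy:
    """Patient-level geometry shared across repeat exams."""

    carina_y: float
    carina_x: float
    curve_amp: float       # lateral bow of the trachea at the top margin, px
    trachea_width: float   # px
    branch_angle_l: float  # degrees from vertical
    branch_angle_r: float
    tube_width: float      # px, used when an ETT is rendered

    def centerline_x(self, y: np.ndarray | float) -> np.ndarray | float:
        """Column of the trachea centreline at row(s) ``y`` (y <= carina_y)."""
        t = (self.carina_y - np.asarray(y, dtype=float)) / max(self.carina_y, 1.0)
        return self.carina_x + self.curve_amp * t * t


@dataclass(frozen=True)
class SynthExam:
    image: np.ndarray           # float32 in [0, 1], ORIGINAL frame
    spacing: PixelSpacing
    patient_id: str
    exam_id: str
    ett_present: bool
    carina: Point               # ORIGINAL frame
    ett_tip: Point | None       # ORIGINAL frame, None iff no ETT
    distance_cm: float | None   # sampled ground-truth tip–carina distance
    report_text: str


def sample_distance_cm(rng: np.random.Generator, params: SynthParams,
                       max_cm: float | None = None) -> float:
    """One tip–carina distance draw; out-of-bounds values are resampled."""
    hi = params.dist_hi_cm if max_cm is None else min(params.dist_hi_cm, max_cm)
    if hi <= params.dist_lo_cm:
        return params.dist_lo_cm
    mu = math.log(params.dist_median_cm)
    while True:
        d = float(rng.lognormal(mu, params.dist_log_sd))
        if params.dist_lo_cm <= d <= hi:
            return d


def sample_cohort(n: int, rng: np.random.Generator,
                  params: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-exam (ett_present, distance_cm) draws without rendering.

    This is the same sampling layer ``render_exam`` uses; distances for
    ETT-negative exams are NaN.
    """
    present = rng.random(n) < params.ett_prevalence
    dists = np.full(n, np.nan)
    for i in np.nonzero(present)[0]:
        dists[i] = sample_distance_cm(rng, params)
    return present, dists


def sample_anatomy(rng: np.random.Generator, params: SynthParams) -> Anatomy:
    """Carina strictly inside the central region; widths scale with image size."""
    h, w = params.image_h, params.image_w
    s = h / 512.0
    return Anatomy(
        carina_y=float(rng.uniform(0.45, 0.65) * h),
        carina_x=float(rng.uniform(0.45, 0.55) * w),
        curve_amp=float(rng.uniform(-0.04, 0.04) * w),
        trachea_width=float(rng.uniform(8.0, 14.0) * s),
        branch_angle_l=float(rng.uniform(25.0, 40.0)),
        branch_angle_r=float(rng.uniform(25.0, 40.0)),
        tube_width=max(3.5, float(rng.uniform(3.0, 5.0) * s)),
    )


def _stamp_band(canvas: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                half_width: float, value: float) -> None:
    """Add ``value`` to pixels within ``half_width`` columns of a path.

    The path is given per integer row; a soft half-pixel edge keeps the
    rendered boundary sub-pixel accurate.
    """
    h, w = canvas.shape
    cols = np.arange(w, dtype=float)
    for y, x in zip(ys, xs):
        if 0 <= y < h:
            d = np.abs(cols - x)
            weight = np.clip(half_width + 0.5 - d, 0.0, 1.0)
            canvas[int(y)] += value * weight


def _stamp_segment(canvas: np.ndarray, y0: float, x0: float, y1: float, x1: float,
                   half_width: float, value: float) -> None:
    """Add ``value`` inside a thick line segment using a distance transform."""
    h, w = canvas.shape
    length = math.hypot(y1 - y0, x1 - x0)
    n = max(int(length * 2), 2)
    ts = np.linspace(0.0, 1.0, n)
    yy = y0 + (y1 - y0) * ts
    xx = x0 + (x1 - x0) * ts
    r0 = max(int(min(y0, y1) - half_width - 2), 0)
    r1 = min(int(max(y0, y1) + half_width + 3), h)
    c0 = max(int(min(x0, x1) - half_width - 2), 0)
    c1 = min(int(max(x0, x1) + half_width + 3), w)
    if r0 >= r1 or c0 >= c1:
        return
    gy, gx = np.mgrid[r0:r1, c0:c1]
    d2 = np.full(gy.shape, np.inf)
    for y, x in zip(yy, xx):
        d2 = np.minimum(d2, (gy - y) ** 2 + (gx - x) ** 2)
    weight = np.clip(half_width + 0.5 - np.sqrt(d2), 0.0, 1.0)
    canvas[r0:r1, c0:c1] += value * weight


def _tip_position(anatomy: Anatomy, d_px: float) -> tuple[float, float]:
    """Point on the trachea centreline at Euclidean distance ``d_px`` above
    the carina (solved by scanning + interpolating the sampled centreline)."""
    ys = np.arange(anatomy.carina_y, -0.26, -0.25)
    xs = np.asarray(anatomy.centerline_x(ys), dtype=float)
    dist = np.hypot(ys - anatomy.carina_y, xs - anatomy.carina_x)
    idx = np.searchsorted(dist, d_px)
    if idx >= len(dist):
        raise ValueError("distance exceeds available trachea length")
    if idx == 0:
        return float(ys[0]), float(xs[0])
    f = (d_px - dist[idx - 1]) / max(dist[idx] - dist[idx - 1], 1e-9)
    y = ys[idx - 1] + (ys[idx] - ys[idx - 1]) * f
    x = xs[idx - 1] + (xs[idx] - xs[idx - 1]) * f
    return float(y), float(x)


def render_exam(
    rng: np.random.Generator,
    params: SynthParams,
    anatomy: Anatomy | None = None,
    patient_id: str = "P00000",
    exam_id: str = "P00000_E0",
    ett_present: bool | None = None,
) -> SynthExam:
    """Render one exam.  ``ett_present``/``anatomy`` may be fixed by the
    caller (patient-level cohort structure); otherwise they are drawn here."""
    h, w = params.image_h, params.image_w
    if anatomy is None:
        anatomy = sample_anatomy(rng, params)
    if ett_present is None:
        ett_present = bool(rng.random() < params.ett_prevalence)

    if params.anisotropic:
        spacing = PixelSpacing(
            float(rng.uniform(params.spacing_lo, params.spacing_hi)),
            float(rng.uniform(params.spacing_lo, params.spacing_hi)),
        )
    else:
        s = float(rng.uniform(params.spacing_lo, params.spacing_hi))
        spacing = PixelSpacing(s, s)

    # Low-frequency background blob field.
    coarse = rng.normal(0.0, 1.0, (max(h // 16, 4), max(w // 16, 4)))
    bg = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    bg = ndimage.gaussian_filter(bg, sigma=h / 40.0)
    if bg.std() > 0:
        bg = bg / bg.std()
    img = (0.45 + 0.06 * bg).astype(np.float64)

    # Dark trachea band from the top margin down to the carina.
    rows = np.arange(0, int(anatomy.carina_y) + 1)
    cols = np.asarray(anatomy.centerline_x(rows), dtype=float)
    _stamp_band(img, rows, cols, anatomy.trachea_width / 2.0, -0.22)

    # Bronchial branches below the carina.
    branch_len = 0.16 * h
    bw = anatomy.trachea_width * 0.35
    for sign, ang in ((-1.0, anatomy.branch_angle_l), (1.0, anatomy.branch_angle_r)):
        rad = math.radians(ang)
        _stamp_segment(
            img, anatomy.carina_y, anatomy.carina_x,
            anatomy.carina_y + branch_len * math.cos(rad),
            anatomy.carina_x + sign * branch_len * math.sin(rad),
            bw, -0.18,
        )

    carina = Point(anatomy.carina_y, anatomy.carina_x, Frame.ORIGINAL)
    tip: Point | None = None
    d_cm: float | None = None
    if ett_present:
        # Resample the distance until the tip stays below the top margin.
        margin_px = 4.0
        max_cm = (anatomy.carina_y - margin_px) * spacing.row_mm_per_px / 10.0
        d_cm = sample_distance_cm(rng, params, max_cm=max_cm)
        d_px = d_cm * 10.0 / spacing.row_mm_per_px  # isotropic rows dominate
        tip_y, tip_x = _tip_position(anatomy, d_px)
        tip = Point(tip_y, tip_x, Frame.ORIGINAL)
        tube_rows = np.arange(0, int(math.floor(tip_y)) + 1)
        tube_cols = np.asarray(anatomy.centerline_x(tube_rows), dtype=float)
        _stamp_band(img, tube_rows, tube_cols, anatomy.tube_width / 2.0, 0.38)
        # Fractional last row keeps the rendered terminus on the landmark.
        frac = tip_y - math.floor(tip_y)
        if frac > 0 and int(math.floor(tip_y)) + 1 < h:
            y_next = int(math.floor(tip_y)) + 1
            x_next = float(anatomy.centerline_x(y_next))
            colsd = np.abs(np.arange(w, dtype=float) - x_next)
            wgt = np.clip(anatomy.tube_width / 2.0 + 0.5 - colsd, 0.0, 1.0)
            img[y_next] += 0.38 * frac * wgt

    has_distractor = bool(rng.random() < params.distractor_prob)
    if has_distractor:
        # NG-tube-like bright line: enters near the trachea but passes well
        # beyond the carina, so its terminus is never near the landmark.
        x_top = anatomy.carina_x + float(rng.uniform(0.06, 0.15) * w) * (
            1.0 if rng.random() < 0.5 else -1.0)
        y_end = min(float(anatomy.carina_y + rng.uniform(0.15, 0.25) * h), h - 4.0)
        x_end = x_top + float(rng.uniform(-0.05, 0.05) * w)
        _stamp_segment(img, 0.0, x_top, y_end, x_end, anatomy.tube_width / 2.0, 0.30)

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    if ett_present:
        report = (f"Endotracheal tube tip terminates {d_cm:.1f} cm above "
                  f"the carina.")
    else:
        report = "No endotracheal tube is seen."
    if has_distractor:
        report += " A nasogastric tube is noted."

    return SynthExam(
        image=img, spacing=spacing, patient_id=patient_id, exam_id=exam_id,
        ett_present=ett_present, carina=carina, ett_tip=tip,
        distance_cm=d_cm, report_text=report,
    )


def iter_simulated_exams(
    n_patients: int,
    params: SynthParams,
    seed: int = 0,
    exams_per_patient: tuple[int, int] = (1, 1),
):
    """Yield exams patient by patient (repeat exams share shifted anatomy)."""
    rng = np.random.default_rng(seed)
    lo, hi = exams_per_patient
    for i in range(n_patients):
        patient_id = f"P{i:05d}"
        ett = bool(rng.random() < params.ett_prevalence)
        anatomy = sample_anatomy(rng, params)
        n_exams = int(rng.integers(lo, hi + 1))
        for j in range(n_exams):
            a = anatomy
            if j > 0:
                dy, dx = rng.uniform(-6.0, 6.0, size=2) * params.image_h / 512.0
                a = Anatomy(
                    carina_y=min(max(anatomy.carina_y + dy, 0.3 * params.image_h),
                                 0.75 * params.image_h),
                    carina_x=min(max(anatomy.carina_x + dx, 0.3 * params.image_w),
                                 0.7 * params.image_w),
                    curve_amp=anatomy.curve_amp,
                    trachea_width=anatomy.trachea_width,
                    branch_angle_l=anatomy.branch_angle_l,
                    branch_angle_r=anatomy.branch_angle_r,
                    tube_width=anatomy.tube_width,
                )
            yield render_exam(rng, params, anatomy=a, patient_id=patient_id,
                              exam_id=f"{patient_id}_E{j}", ett_present=ett)


def simulate_exams(n_patients: int, params: SynthParams, seed: int = 0,
                   exams_per_patient: tuple[int, int] = (1, 1)) -> list[SynthExam]:
    return list(iter_simulated_exams(n_patients, params, seed, exams_per_patient))


def exam_sidecar(exam: SynthExam) -> dict:
    return {
        "exam_id": exam.exam_id,
        "patient_id": exam.patient_id,
        "image_h": int(exam.image.shape[0]),
        "image_w": int(exam.image.shape[1]),
        "spacing_row_mm": exam.spacing.row_mm_per_px,
        "spacing_col_mm": exam.spacing.col_mm_per_px,
        "ett_present": exam.ett_present,
        "carina_y": exam.carina.y,
        "carina_x": exam.carina.x,
        "tip_y": None if exam.ett_tip is None else exam.ett_tip.y,
        "tip_x": None if exam.ett_tip is None else exam.ett_tip.x,
        "distance_cm": exam.distance_cm,
        "report_text": exam.report_text,
    }


def write_exam(exam: SynthExam, out_dir: str | Path) -> Path:
    """Write a 16-bit PNG + JSON sidecar; returns the PNG path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    png_path = out_dir / f"{exam.exam_id}.png"
    arr = np.round(exam.image * 65535.0).astype(np.uint16)
    iio.imwrite(png_path, arr)
    png_path.with_suffix(".json").write_text(
        json.dumps(exam_sidecar(exam), indent=1))
    return png_path


def generate_dataset(
    n_patients: int,
    out_dir: str | Path,
    params: SynthParams | None = None,
    seed: int = 0,
    exams_per_patient: tuple[int, int] = (1, 2),
) -> pd.DataFrame:
    """Write a full synthetic dataset and its manifest CSV; returns the manifest."""
    params = params if params is not None else SynthParams()
    out_dir = Path(out_dir)
    rows = []
    for exam in iter_simulated_exams(n_patients, params, seed, exams_per_patient):
        png_path = write_exam(exam, out_dir)
        rows.append({
            "exam_id": exam.exam_id,
            "patient_id": exam.patient_id,
            "path": str(png_path),
            "label": int(exam.ett_present),
            "carina_y": exam.carina.y,
            "carina_x": exam.carina.x,
            "tip_y": np.nan if exam.ett_tip is None else exam.ett_tip.y,
            "tip_x": np.nan if exam.ett_tip is None else exam.ett_tip.x,
            "spacing_row_mm": exam.spacing.row_mm_per_px,
            "spacing_col_mm": exam.spacing.col_mm_per_px,
            "report_text": exam.report_text,
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
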