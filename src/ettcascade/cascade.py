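"""End-to-end inference: coarse carina -> crop -> ETT call -> refinement.

Stage 1 regresses the carina on the full model input and its prediction
places the attention window.  Stage 2 classifies ETT presence on the crop.
Stage 3 runs only for ETT-positive exams (configurable) and refines the
carina while localizing the tube tip; the tip–carina distance is reported
in centimetres using the MODEL frame's effective pixel spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import Backbone, softmax
from .geometry import (
    AffineMap,
    CropWindow,
    Frame,
    NoSpacingError,
    Point,
    crop_window_for_carina,
    denormalize_coords,
    distance_cm,
    distance_px,
)
from .io import ExamRecord
from .preprocess import extract_crop, preprocess

PREDICTION_SCHEMA_VERSION = 1

PREDICTION_COLUMNS = [
    "exam_id", "patient_id", "ett_probability", "ett_present",
    "carina_y", "carina_x", "tip_y", "tip_x", "distance_cm", "distance_px",
]


@dataclass(frozen=True)
class CropSpec:
    """Geometry of the attention window (fractions of the model input)."""

    frac_h: float = 0.50
    frac_w: float = 0.25
    out_h: int | None = None
    out_w: int | None = None
    v_offset_px: float = 0.0


@dataclass
class CascadeModels:
    stage1: Backbone
    stage2: Backbone
    stage3: Backbone

    @property
    def model_size(self) -> int:
        return self.stage1.config.input_h


@dataclass
class CascadePrediction:
    exam_id: str
    patient_id: str
    carina_coarse: Point                 # MODEL frame
    ett_probability: float
    ett_present: bool
    carina_refined: Point | None         # MODEL frame; None when stage 3 skipped
    ett_tip: Point | None                # MODEL frame; None when no ETT
    tip_carina_distance_cm: float | None
    tip_carina_distance_px: float | None
    to_model: AffineMap                  # ORIGINAL -> MODEL provenance
    window: CropWindow

    @property
    def carina_final(self) -> Point:
        return self.carina_refined if self.carina_refined is not None else self.carina_coarse

    def __post_init__(self) -> None:
        if (self.ett_tip is None) != (self.tip_carina_distance_cm is None
                                      and self.tip_carina_distance_px is None):
            raise ValueError("distance must be present iff the tip is present")

    def point_in_original(self, p: Point) -> Point:
        return self.to_model.invert().apply(p)

    def to_row(self) -> dict:
        carina_orig = self.point_in_original(self.carina_final)
        tip_orig = None if self.ett_tip is None else self.point_in_original(self.ett_tip)
        return {
            "exam_id": self.exam_id,
            "patient_id": self.patient_id,
            "ett_probability": self.ett_probability,
            "ett_present": int(self.ett_present),
            "carina_y": carina_orig.y,
            "carina_x": carina_orig.x,
            "tip_y": np.nan if tip_orig is None else tip_orig.y,
            "tip_x": np.nan if tip_orig is None else tip_orig.x,
            "distance_cm": (np.nan if self.tip_carina_distance_cm is None
                            else self.tip_carina_distance_cm),
            "distance_px": (np.nan if self.tip_carina_distance_px is None
                            else self.tip_carina_distance_px),
        }

    def to_json_dict(self) -> dict:
        def pt(p: Point | None):
            return None if p is None else {"y": p.y, "x": p.x, "frame": p.frame.value}

        return {
            "schema_version": PREDICTION_SCHEMA_VERSION,
            "exam_id": self.exam_id,
            "patient_id": self.patient_id,
            "ett_probability": self.ett_probability,
            "ett_present": self.ett_present,
            "carina_coarse": pt(self.carina_coarse),
            "carina_refined": pt(self.carina_refined),
            "carina_final": pt(self.carina_final),
            "ett_tip": pt(self.ett_tip),
            "tip_carina_distance_cm": self.tip_carina_distance_cm,
            "tip_carina_distance_px": self.tip_carina_distance_px,
            "frames": {
                "original_to_model": {
                    "scale_y": self.to_model.scale_y,
                    "scale_x": self.to_model.scale_x,
                    "offset_y": self.to_model.offset_y,
                    "offset_x": self.to_model.offset_x,
                },
                "crop_window": {
                    "row_start": self.window.row_start,
                    "row_stop": self.window.row_stop,
                    "col_start": self.window.col_start,
                    "col_stop": self.window.col_stop,
                    "out_h": self.window.out_h,
                    "out_w": self.window.out_w,
                },
            },
        }


def run_stage1(model: Backbone, model_image: np.ndarray) -> Point:
    """Coarse carina estimate, denormalized and clamped into the model frame."""
    h, w = model.config.input_h, model.config.input_w
    logits = model.forward(model_image[None], train=False)[0]
    p = denormalize_coords(float(logits[0]), float(logits[1]), h, w, Frame.MODEL)
    return Point(float(np.clip(p.y, 0.0, h - 1)), float(np.clip(p.x, 0.0, w - 1)),
                 Frame.MODEL)


def run_stage2(model: Backbone, crop_image: np.ndarray) -> float:
    """Probability that the crop contains an ETT (softmax class-1 component)."""
    logits = model.forward(crop_image[None], train=False)[0]
    return float(softmax(logits.astype(np.float64))[1])


def run_stage3(model: Backbone, crop_image: np.ndarray,
               window: CropWindow) -> tuple[Point, Point]:
    """Refined carina and tube tip, mapped from the CROP to the MODEL frame."""
    logits = model.forward(crop_image[None], train=False)[0]
    to_model = window.to_model_map()
    carina_c = denormalize_coords(float(logits[0]), float(logits[1]),
                                  window.out_h, window.out_w, Frame.CROP)
    tip_c = denormalize_coords(float(logits[2]), float(logits[3]),
                               window.out_h, window.out_w, Frame.CROP)
    return to_model.apply(carina_c), to_model.apply(tip_c)


def run_cascade(
    models: CascadeModels,
    exam: ExamRecord,
    threshold: float = 0.5,
    crop_spec: CropSpec = CropSpec(),
    allow_pixel_units: bool = False,
    refine_when_absent: bool = False,
) -> CascadePrediction:
    if exam.image is None:
        raise ValueError("exam has no pixel data")
    size = models.model_size
    prep = preprocess(exam.image, spacing=exam.spacing, model_size=size)

    carina_coarse = run_stage1(models.stage1, prep.image)
    window = crop_window_for_carina(
        carina_coarse, size, size,
        frac_h=crop_spec.frac_h, frac_w=crop_spec.frac_w,
        out_h=crop_spec.out_h, out_w=crop_spec.out_w,
        v_offset_px=crop_spec.v_offset_px,
    )
    crop = extract_crop(prep.image, window)
    prob = run_stage2(models.stage2, crop)
    present = prob >= threshold

    carina_refined: Point | None = None
    tip: Point | None = None
    dist_cm: float | None = None
    dist_px: float | None = None
    if present or refine_when_absent:
        carina_refined, tip3 = run_stage3(models.stage3, crop, window)
        # Clamp out-of-range regression outputs into the model frame.
        clamp = lambda p: Point(float(np.clip(p.y, 0.0, size - 1)),
                                float(np.clip(p.x, 0.0, size - 1)), p.frame)
        carina_refined, tip3 = clamp(carina_refined), clamp(tip3)
        if present:
            tip = tip3
            if prep.spacing is not None:
                dist_cm = distance_cm(tip, carina_refined, prep.spacing)
                dist_px = distance_px(tip, carina_refined)
            elif allow_pixel_units:
                dist_px = distance_px(tip, carina_refined)
            else:
                raise NoSpacingError(
                    f"exam {exam.exam_id}: no pixel spacing; pass "
                    "allow_pixel_units=True for pixel-unit distances"
                )

    return CascadePrediction(
        exam_id=exam.exam_id,
        patient_id=exam.patient_id,
        carina_coarse=carina_coarse,
        ett_probability=prob,
        ett_present=present,
        carina_refined=carina_refined,
        ett_tip=tip,
        tip_carina_distance_cm=dist_cm,
        tip_carina_distance_px=dist_px,
        to_model=prep.to_model,
        window=window,
    )


def predictions_to_frame(preds: list[CascadePrediction]) -> pd.DataFrame:
    return pd.DataFrame([p.to_row() for p in preds], columns=PREDICTION_COLUMNS)


def predictions_to_json(preds: list[CascadePrediction]) -> str:
    return json.dumps([p.to_json_dict() for p in preds], indent=1)
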