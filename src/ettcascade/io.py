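"""Exam records and readers/writers for the formats the tool touches."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import Frame, PixelSpacing, Point
from .synthetic import MANIFEST_COLUMNS, SynthExam


class View(str, Enum):
    FRONTAL = "FRONTAL"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


@dataclass
class ExamRecord:
    """One radiograph plus whatever metadata and ground truth exist for it."""

    exam_id: str
    patient_id: str
    image: np.ndarray
    spacing: PixelSpacing | None = None
    view: View = View.UNKNOWN
    ett_present: bool | None = None
    carina: Point | None = None
    ett_tip: Point | None = None
    report_text: str | None = None
    distance_cm: float | None = None

    def __post_init__(self) -> None:
        if self.image is None or np.asarray(self.image).ndim != 2:
            raise ValueError("exam record requires a 2-D image")
        if self.ett_tip is not None and self.ett_present is False:
            raise ValueError("tip coordinates present but ETT label is negative")


def from_synth(exam: SynthExam) -> ExamRecord:
    return ExamRecord(
        exam_id=exam.exam_id,
        patient_id=exam.patient_id,
        image=exam.image,
        spacing=exam.spacing,
        view=View.FRONTAL,
        ett_present=exam.ett_present,
        carina=exam.carina,
        ett_tip=exam.ett_tip,
        report_text=exam.report_text,
        distance_cm=exam.distance_cm,
    )


def read_synth(png_path: str | Path, sidecar_path: str | Path | None = None) -> ExamRecord:
    """Read a generated PNG + JSON sidecar back into an :class:`ExamRecord`."""
    png_path = Path(png_path)
    sidecar_path = (png_path.with_suffix(".json") if sidecar_path is None
                    else Path(sidecar_path))
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    arr = iio.imread(png_path)
    image = arr.astype(np.float32) / 65535.0
    if image.shape != (meta["image_h"], meta["image_w"]):
        raise ValueError(
            f"sidecar says {meta['image_h']}x{meta['image_w']} "
            f"but image is {image.shape[0]}x{image.shape[1]}"
        )
    present = bool(meta["ett_present"])
    tip = None
    if meta.get("tip_y") is not None:
        if not present:
            raise ValueError("sidecar has tip coordinates but ett_present is false")
        tip = Point(meta["tip_y"], meta["tip_x"], Frame.ORIGINAL)
    return ExamRecord(
        exam_id=meta["exam_id"],
        patient_id=meta["patient_id"],
        image=image,
        spacing=PixelSpacing(meta["spacing_row_mm"], meta["spacing_col_mm"]),
        view=View.FRONTAL,
        ett_present=present,
        carina=Point(meta["carina_y"], meta["carina_x"], Frame.ORIGINAL),
        ett_tip=tip,
        report_text=meta.get("report_text"),
        distance_cm=meta.get("distance_cm"),
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def record_from_manifest_row(row) -> ExamRecord:
    """Load the exam a manifest row points at (PNG + sidecar)."""
    rec = read_synth(row["path"])
    # Ground truth in the manifest wins (single source for training labels).
    if not math.isnan(row["carina_y"]):
        rec.carina = Point(row["carina_y"], row["carina_x"], Frame.ORIGINAL)
    rec.ett_present = bool(row["label"])
    if rec.ett_present and not math.isnan(row.get("tip_y", float("nan"))):
        rec.ett_tip = Point(row["tip_y"], row["tip_x"], Frame.ORIGINAL)
    return rec


def iter_manifest_records(manifest: pd.DataFrame):
    for _, row in manifest.iterrows():
        yield record_from_manifest_row(row)
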