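"""Stage-wise training, patient-grouped folds, and the scaled recovery run.

The schedule follows the published recipe: Adam at 5e-4 with batch 12 for
3 epochs, then one fine-tuning epoch at the rate divided by 10.  Folds are
assigned at the patient level (shuffle patients with the seed, deal
round-robin) so repeat exams never straddle train and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .backbone import (
    Backbone,
    BackboneConfig,
    Stage,
    build,
    classification_loss,
    classification_loss_grad,
    regression_loss,
    regression_loss_grad,
    test_scale_config,
)
from .cascade import CascadeModels, CropSpec, run_cascade
from .geometry import Frame, Point, crop_window_for_carina, distance_px
from .io import from_synth
from .preprocess import AugmentParams, augment, extract_crop, preprocess
from .synthetic import SynthParams, iter_simulated_exams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainSchedule:
    """3 epochs at lr_initial, then epochs_finetune at lr_initial/10."""

    lr_initial: float = 5e-4
    batch_size: int = 12
    epochs_initial: int = 3
    epochs_finetune: int = 1
    lr_finetune: float | None = None  # defaults to lr_initial / 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_initial, self.batch_size, self.epochs_initial) <= 0:
            raise ValueError("schedule values must be positive")
        if self.lr_finetune is not None and self.lr_finetune <= 0:
            raise ValueError("lr_finetune must be positive")

    @property
    def finetune_lr(self) -> float:
        return self.lr_initial / 10.0 if self.lr_finetune is None else self.lr_finetune

    @property
    def total_epochs(self) -> int:
        return self.epochs_initial + self.epochs_finetune


@dataclass
class FoldAssignment:
    exam_to_fold: dict[str, int]
    patient_to_fold: dict[str, int]
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"exam_id": e, "fold": f} for e, f in sorted(self.exam_to_fold.items())]
        )

    def train_test_exams(self, fold: int) -> tuple[list[str], list[str]]:
        train = [e for e, f in self.exam_to_fold.items() if f != fold]
        test = [e for e, f in self.exam_to_fold.items() if f == fold]
        return train, test


def make_folds(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Patient-grouped folds: shuffle patients, deal round-robin."""
    if manifest["patient_id"].isna().any():
        raise ValueError("every exam needs a patient id")
    patients = sorted(manifest["patient_id"].astype(str).unique())
    if k > len(patients):
        raise ValueError(f"k={k} exceeds number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    patient_to_fold = {patients[j]: i % k for i, j in enumerate(order)}
    exam_to_fold = {
        str(row.exam_id): patient_to_fold[str(row.patient_id)]
        for row in manifest.itertuples()
    }
    return FoldAssignment(exam_to_fold, patient_to_fold, k)


# dataset assembly --------------------------------------------------------

@dataclass
class StageData:
    """In-memory training set for one stage.

    ``targets_px`` are landmark pixel coordinates in the image's own frame
    (normalization to [0,1] happens at batch time, after augmentation).
    """

    kind: Stage
    images: np.ndarray                   # (N, h, w) z-scored float32
    targets_px: np.ndarray | None = None  # (N, 2) or (N, 4)
    labels: np.ndarray | None = None      # (N,) int for classification
    stats: np.ndarray | None = None       # (N, 2) stored (mean, std)

    def __len__(self) -> int:
        return len(self.images)


def build_stage1_data(exams, model_size: int) -> StageData:
    """Full model images + carina targets; exams lacking a carina are skipped."""
    images, targets, stats = [], [], []
    skipped = 0
    for exam in exams:
        if exam.carina is None:
            skipped += 1
            continue
        prep = preprocess(exam.image, spacing=exam.spacing, model_size=model_size)
        carina = prep.to_model.apply(exam.carina)
        images.append(prep.image)
        targets.append([carina.y, carina.x])
        stats.append([prep.mean, prep.std])
    if skipped:
        logger.info("stage1 data: skipped %d exams without carina annotation", skipped)
    if not images:
        raise ValueError("no usable exams for stage 1")
    return StageData(
        kind=Stage.STAGE1,
        images=np.stack(images),
        targets_px=np.asarray(targets, dtype=np.float64),
        stats=np.asarray(stats, dtype=np.float64),
    )


@dataclass
class CropData:
    """Crops centred on (jittered) ground-truth carina, with both stage-2
    labels and stage-3 coordinate targets (NaN where no tip exists)."""

    crops: np.ndarray
    labels: np.ndarray
    targets_px: np.ndarray  # (N, 4): carina_y, carina_x, tip_y, tip_x in CROP px
    stats: np.ndarray

    def stage2_data(self) -> StageData:
        return StageData(kind=Stage.STAGE2, images=self.crops,
                         labels=self.labels, stats=self.stats)

    def stage3_data(self) -> StageData:
        keep = self.labels == 1
        if not keep.any():
            raise ValueError("no ETT-positive exams for stage 3")
        return StageData(
            kind=Stage.STAGE3,
            images=self.crops[keep],
            targets_px=self.targets_px[keep],
            stats=self.stats[keep],
        )


def make_stage23_crops(
    exams,
    model_size: int,
    crop_spec: CropSpec = CropSpec(),
    jitter_sigma_px: float = 8.0,
    rng: np.random.Generator | None = None,
    crops_per_exam: int = 1,
) -> CropData:
    """Training crops centred on ground-truth carina + Gaussian jitter
    (simulating stage-1 error); stage-3 targets re-expressed in CROP pixels.

    ``crops_per_exam`` > 1 draws several independently jittered windows per
    exam (offline augmentation that also lengthens the crop stages' short
    optimization schedule)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    crops, labels, targets, stats = [], [], [], []
    for exam in exams:
        if exam.carina is None:
            continue
        prep = preprocess(exam.image, spacing=exam.spacing, model_size=model_size)
        carina = prep.to_model.apply(exam.carina)
        for _ in range(crops_per_exam):
            jy, jx = (rng.normal(0.0, jitter_sigma_px, size=2)
                      if jitter_sigma_px > 0 else (0.0, 0.0))
            centre = Point(carina.y + jy, carina.x + jx, Frame.MODEL)
            window = crop_window_for_carina(
                centre, model_size, model_size,
                frac_h=crop_spec.frac_h, frac_w=crop_spec.frac_w,
                out_h=crop_spec.out_h, out_w=crop_spec.out_w,
                v_offset_px=crop_spec.v_offset_px,
            )
            crops.append(extract_crop(prep.image, window))
            labels.append(int(bool(exam.ett_present)))
            to_crop = window.to_model_map().invert()
            carina_c = to_crop.apply(carina)
            if exam.ett_tip is not None:
                tip_c = to_crop.apply(prep.to_model.apply(exam.ett_tip))
                targets.append([carina_c.y, carina_c.x, tip_c.y, tip_c.x])
            else:
                targets.append([carina_c.y, carina_c.x, np.nan, np.nan])
            stats.append([prep.mean, prep.std])
    if not crops:
        raise ValueError("no usable exams with carina ground truth")
    return CropData(
        crops=np.stack(crops),
        labels=np.asarray(labels, dtype=int),
        targets_px=np.asarray(targets, dtype=np.float64),
        stats=np.asarray(stats, dtype=np.float64),
    )


# training loop -----------------------------------------------------------

def _assemble_batch(data: StageData, idx: np.ndarray,
                    augment_params: AugmentParams | None,
                    rng: np.random.Generator):
    h, w = data.images.shape[1:]
    xs = np.empty((len(idx), h, w), dtype=np.float32)
    regression = data.targets_px is not None
    tgt = np.empty((len(idx), data.targets_px.shape[1]), dtype=np.float64) \
        if regression else None
    for row, i in enumerate(idx):
        img = data.images[i]
        if regression:
            coords = data.targets_px[i]
            pts = [Point(coords[2 * j], coords[2 * j + 1], Frame.MODEL)
                   for j in range(len(coords) // 2)]
        else:
            pts = []
        if augment_params is not None:
            stats = tuple(data.stats[i]) if data.stats is not None else None
            img, pts, _ = augment(img, pts, augment_params, rng, norm_stats=stats)
        xs[row] = img
        if regression:
            for j, p in enumerate(pts):
                tgt[row, 2 * j] = p.y / h
                tgt[row, 2 * j + 1] = p.x / w
    if regression:
        return xs, tgt
    return xs, data.labels[idx]


def train_stage(
    stage: Stage,
    data: StageData,
    schedule: TrainSchedule,
    config: BackboneConfig,
    augment_params: AugmentParams | None = None,
) -> tuple[Backbone, list[dict]]:
    """Run the 3+1-epoch schedule on one stage; returns (model, epoch log)."""
    stage = Stage(stage)
    if len(data) == 0:
        raise ValueError("empty training set")
    if data.kind != stage:
        raise ValueError(f"dataset built for {data.kind.value}, not {stage.value}")
    regression = config.head.kind == "regression"
    if regression and data.targets_px is None:
        raise ValueError("regression stage needs coordinate targets")
    if not regression and data.labels is None:
        raise ValueError("classification stage needs labels")
    if (data.images.shape[1], data.images.shape[2]) != (config.input_h, config.input_w):
        raise ValueError("dataset image shape does not match config input shape")

    model = build(config, seed=schedule.seed)
    opt = nn.Adam(model.params(), lr=schedule.lr_initial)
    rng = np.random.default_rng(schedule.seed + 1)
    n = len(data)
    log: list[dict] = []
    for epoch in range(schedule.total_epochs):
        if epoch == schedule.epochs_initial:
            opt.lr = schedule.finetune_lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, schedule.batch_size):
            idx = order[start:start + schedule.batch_size]
            xb, tb = _assemble_batch(data, idx, augment_params, rng)
            logits = model.forward(xb, train=True)
            if regression:
                loss = regression_loss(logits, tb)
                dy = regression_loss_grad(logits.astype(np.float64), tb)
            else:
                loss = classification_loss(logits, tb)
                dy = classification_loss_grad(logits.astype(np.float64), tb)
            opt.zero_grad()
            model.backward(dy.astype(np.float32))
            opt.step()
            losses.append(loss)
        log.append({"epoch": epoch, "lr": opt.lr,
                    "mean_loss": float(np.mean(losses))})
        logger.info("%s epoch %d lr %.2e mean loss %.5f",
                    stage.value, epoch, opt.lr, float(np.mean(losses)))
    return model, log


# scaled end-to-end recovery ----------------------------------------------

@dataclass
class RecoveryResult:
    coarse_err_px: np.ndarray      # MODEL-frame carina error, all test exams
    refined_err_px: np.ndarray     # MODEL-frame carina error, true+predicted positives
    coarse_err_px_pos: np.ndarray  # coarse error restricted to the same exams
    scores: np.ndarray
    labels: np.ndarray
    dist_pred_cm: np.ndarray       # predicted tip–carina distances (TP exams)
    dist_true_cm: np.ndarray
    logs: dict[str, list[dict]]

    @property
    def dist_abs_err_cm(self) -> np.ndarray:
        return np.abs(self.dist_pred_cm - self.dist_true_cm)


def parameter_recovery_run(
    n_train: int = 1000,
    n_test: int = 300,
    seed: int = 7,
    image_size: int = 256,
    model_size: int = 128,
    jitter_sigma_px: float = 4.0,
    use_augmentation: bool = True,
) -> RecoveryResult:
    """Generate, train the three stages at test scale, and evaluate.

    The crop window is shifted 16 px up (v_offset) so the tube tip stays
    inside the window at this scale; see the module docs.
    """
    params = SynthParams(image_h=image_size, image_w=image_size)
    schedule = TrainSchedule(seed=seed)
    crop_spec = CropSpec(v_offset_px=-model_size / 8.0)
    scale = model_size / 512.0
    aug_full = AugmentParams(max_disp_px=max(1, round(14 * scale))) \
        if use_augmentation else None
    aug_crop = AugmentParams(max_disp_px=max(1, round(7 * scale))) \
        if use_augmentation else None

    train_exams = [from_synth(e)
                   for e in iter_simulated_exams(n_train, params, seed=seed)]
    test_exams = [from_synth(e)
                  for e in iter_simulated_exams(n_test, params, seed=seed + 1)]

    logs: dict[str, list[dict]] = {}
    s1 = build_stage1_data(train_exams, model_size)
    m1, logs["stage1"] = train_stage(Stage.STAGE1, s1,
                                     schedule, test_scale_config(Stage.STAGE1),
                                     augment_params=aug_full)
    crop_rng = np.random.default_rng(seed + 2)
    crops = make_stage23_crops(train_exams, model_size, crop_spec,
                               jitter_sigma_px=jitter_sigma_px, rng=crop_rng,
                               crops_per_exam=3)
    m2, logs["stage2"] = train_stage(Stage.STAGE2, crops.stage2_data(),
                                     schedule, test_scale_config(Stage.STAGE2),
                                     augment_params=aug_crop)
    m3, logs["stage3"] = train_stage(Stage.STAGE3, crops.stage3_data(),
                                     schedule, test_scale_config(Stage.STAGE3),
                                     augment_params=aug_crop)
    models = CascadeModels(m1, m2, m3)

    coarse_err, coarse_err_pos, refined_err = [], [], []
    scores, labels = [], []
    dist_pred, dist_true = [], []
    for exam in test_exams:
        pred = run_cascade(models, exam, crop_spec=crop_spec)
        gt_carina = pred.to_model.apply(exam.carina)
        err1 = distance_px(pred.carina_coarse, gt_carina)
        coarse_err.append(err1)
        scores.append(pred.ett_probability)
        labels.append(int(bool(exam.ett_present)))
        if exam.ett_present and pred.ett_present:
            refined_err.append(distance_px(pred.carina_refined, gt_carina))
            coarse_err_pos.append(err1)
            dist_pred.append(pred.tip_carina_distance_cm)
            dist_true.append(exam.distance_cm)
    return RecoveryResult(
        coarse_err_px=np.asarray(coarse_err),
        refined_err_px=np.asarray(refined_err),
        coarse_err_px_pos=np.asarray(coarse_err_pos),
        scores=np.asarray(scores),
        labels=np.asarray(labels),
        dist_pred_cm=np.asarray(dist_pred),
        dist_true_cm=np.asarray(dist_true),
        logs=logs,
    )
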