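import numpy as np
import pandas as pd
import pytest

from ettcascade.backbone import BackboneConfig, HeadSpec, Stage
from ettcascade.cascade import CropSpec
from ettcascade.geometry import Frame, Point
from ettcascade.io import ExamRecord, from_synth
from ettcascade.preprocess import AugmentParams
from ettcascade.synthetic import SynthParams, simulate_exams
from ettcascade.train import (
    StageData,
    TrainSchedule,
    build_stage1_data,
    make_folds,
    make_stage23_crops,
    train_stage,
)


def manifest_frame(n_patients=10, exams_per_patient=1):
    rows = []
    for i in range(n_patients):
        for j in range(exams_per_patient):
            rows.append({"exam_id": f"P{i}_E{j}", "patient_id": f"P{i}"})
    return pd.DataFrame(rows)


class TestSchedule:
    def test_defaults_match_published_recipe(self):
        s = TrainSchedule()
        assert s.lr_initial == 5e-4
        assert s.batch_size == 12
        assert s.epochs_initial == 3 and s.epochs_finetune == 1
        assert s.total_epochs == 4
        assert s.finetune_lr == pytest.approx(5e-5)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainSchedule(lr_initial=0)
        with pytest.raises(ValueError):
            TrainSchedule(lr_finetune=-1)


class TestFolds:
    def test_two_patients_per_fold(self):
        folds = make_folds(manifest_frame(10), k=5, seed=0)
        counts = np.bincount(list(folds.patient_to_fold.values()), minlength=5)
        assert (counts == 2).all()

    def test_patient_grouping(self):
        folds = make_folds(manifest_frame(8, exams_per_patient=3), k=4, seed=1)
        df = folds.to_frame()
        df["patient"] = df["exam_id"].str.split("_").str[0]
        assert (df.groupby("patient")["fold"].nunique() == 1).all()

    def test_fold_sizes_balanced(self):
        folds = make_folds(manifest_frame(13), k=5, seed=2)
        counts = np.bincount(list(folds.patient_to_fold.values()), minlength=5)
        assert counts.max() - counts.min() <= 1

    def test_same_seed_identical(self):
        m = manifest_frame(20)
        assert make_folds(m, seed=3).exam_to_fold == make_folds(m, seed=3).exam_to_fold
        assert make_folds(m, seed=3).exam_to_fold != make_folds(m, seed=4).exam_to_fold

    def test_k_exceeds_patients(self):
        with pytest.raises(ValueError):
            make_folds(manifest_frame(3), k=5)

    def test_train_test_disjoint_every_fold(self):
        m = manifest_frame(11, exams_per_patient=2)
        folds = make_folds(m, k=5, seed=0)
        for fold in range(5):
            train, test = folds.train_test_exams(fold)
            train_patients = {e.split("_")[0] for e in train}
            test_patients = {e.split("_")[0] for e in test}
            assert not train_patients & test_patients
            assert len(train) + len(test) == len(m)


@pytest.fixture(scope="module")
def crop_exams():
    params = SynthParams(image_h=128, image_w=128)
    return [from_synth(e) for e in simulate_exams(30, params, seed=5)]


class TestStage23Crops:
    def test_zero_jitter_centres_on_carina(self, crop_exams):
        crops = make_stage23_crops(crop_exams, 128, jitter_sigma_px=0.0)
        # carina target of a centred crop is the crop centre (up to the
        # 0.5-px rounding of integer window bounds)
        cy = crops.targets_px[:, 0] / crops.crops.shape[1]
        cx = crops.targets_px[:, 1] / crops.crops.shape[2]
        assert np.abs(cy - 0.5).max() <= 0.5 / crops.crops.shape[1] + 1e-9
        assert np.abs(cx - 0.5).max() <= 0.5 / crops.crops.shape[2] + 1e-9

    def test_crop_shape_from_fractions(self, crop_exams):
        crops = make_stage23_crops(crop_exams, 128, jitter_sigma_px=0.0)
        assert crops.crops.shape[1:] == (64, 32)  # 50% / 25% of 128

    def test_jitter_three_sigma(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0.0, 8.0, size=(1000, 2))
        frac = (np.abs(draws) < 24).all(axis=1).mean()
        assert frac >= 0.985  # ~99.7% per coordinate at 3 sigma

    def test_stage3_subset_positives_only(self, crop_exams):
        crops = make_stage23_crops(crop_exams, 128, jitter_sigma_px=2.0,
                                   rng=np.random.default_rng(1))
        s3 = crops.stage3_data()
        assert np.isfinite(s3.targets_px).all()
        assert len(s3) == int(crops.labels.sum())

    def test_crops_per_exam(self, crop_exams):
        crops = make_stage23_crops(crop_exams, 128, jitter_sigma_px=3.0,
                                   rng=np.random.default_rng(2),
                                   crops_per_exam=3)
        assert len(crops.crops) == 3 * len(crop_exams)
        # labels replicate per crop; jitter differs between the copies
        assert (crops.labels[0::3] == crops.labels[1::3]).all()
        assert not np.allclose(crops.targets_px[0], crops.targets_px[1])

    def test_border_carina_still_valid(self):
        # carina close to the border: window extends outside, crop zero-fills
        img = np.random.default_rng(0).uniform(size=(128, 128)).astype(np.float32)
        exam = ExamRecord(exam_id="e", patient_id="p", image=img,
                          carina=Point(10.0, 5.0, Frame.ORIGINAL),
                          ett_present=False)
        crops = make_stage23_crops([exam], 128, jitter_sigma_px=0.0)
        assert crops.crops.shape == (1, 64, 32)


TINY1 = BackboneConfig(((2, 4), (2, 6)), HeadSpec("regression", 2), 32, 32,
                       head_pool="flatten", head_bias=0.5, head_init_scale=0.0)
TINY2 = BackboneConfig(((2, 4), (2, 6)), HeadSpec("classification", 2), 32, 32)


def _dot_dataset(n=36, size=32, seed=0):
    """Bright dot on noise; target = dot location (easy regression task)."""
    rng = np.random.default_rng(seed)
    ys, xs = np.mgrid[0:size, 0:size]
    images, targets = [], []
    for _ in range(n):
        ly, lx = rng.uniform(8, size - 8, size=2)
        img = rng.normal(0, 0.1, size=(size, size))
        img += 3.0 * np.exp(-((ys - ly) ** 2 + (xs - lx) ** 2) / 8.0)
        img = (img - img.mean()) / img.std()
        images.append(img.astype(np.float32))
        targets.append([ly, lx])
    return StageData(kind=Stage.STAGE1, images=np.stack(images),
                     targets_px=np.asarray(targets),
                     stats=np.tile([0.0, 1.0], (n, 1)))


class TestTrainStage:
    def test_loss_decreases(self):
        data = _dot_dataset()
        model, log = train_stage(Stage.STAGE1, data, TrainSchedule(seed=0), TINY1)
        losses = [e["mean_loss"] for e in log]
        assert len(losses) == 4
        assert losses[-1] < losses[0]
        # at most one non-monotone step on this easy problem
        assert sum(b > a for a, b in zip(losses, losses[1:])) <= 1

    def test_finetune_lr_is_tenth(self):
        data = _dot_dataset(n=12)
        _, log = train_stage(Stage.STAGE1, data, TrainSchedule(seed=0), TINY1)
        assert log[0]["lr"] == pytest.approx(5e-4)
        assert log[3]["lr"] == pytest.approx(5e-5)

    def test_seeded_reproducibility(self):
        data = _dot_dataset()
        _, log_a = train_stage(Stage.STAGE1, data, TrainSchedule(seed=1), TINY1)
        _, log_b = train_stage(Stage.STAGE1, data, TrainSchedule(seed=1), TINY1)
        assert log_a[-1]["mean_loss"] == pytest.approx(
            log_b[-1]["mean_loss"], rel=1e-4)

    def test_augmentation_path_runs(self):
        data = _dot_dataset(n=24)
        _, log = train_stage(Stage.STAGE1, data, TrainSchedule(seed=0), TINY1,
                             augment_params=AugmentParams(max_disp_px=2))
        assert log[-1]["mean_loss"] < log[0]["mean_loss"]

    def test_empty_set_rejected(self):
        data = _dot_dataset(n=1)
        data.images = data.images[:0]
        data.targets_px = data.targets_px[:0]
        with pytest.raises(ValueError):
            train_stage(Stage.STAGE1, data, TrainSchedule(), TINY1)

    def test_stage_dataset_mismatch(self):
        data = _dot_dataset(n=6)
        with pytest.raises(ValueError):
            train_stage(Stage.STAGE2, data, TrainSchedule(), TINY2)

    def test_classification_training(self):
        rng = np.random.default_rng(0)
        n = 36
        labels = rng.integers(0, 2, n)
        images = rng.normal(size=(n, 32, 32)).astype(np.float32)
        images[labels == 1] += 1.5  # separable by mean intensity
        data = StageData(kind=Stage.STAGE2, images=images, labels=labels)
        model, log = train_stage(Stage.STAGE2, data, TrainSchedule(seed=0), TINY2)
        assert log[-1]["mean_loss"] < log[0]["mean_loss"]
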