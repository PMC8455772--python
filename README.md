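# ettcascade

Cascaded convolutional localization of the **carina** and **endotracheal
tube (ETT) tip** on frontal chest radiographs, reporting the tip–carina
distance in centimetres.

The pipeline chains three independently trained CNNs sharing one backbone
(30 blocks of 3×3 conv + batch norm + LeakyReLU, 7 stride-2 subsamplings,
channels 48→128):

1. **Stage 1 — coarse carina regression** on the 512×512 preprocessed
   radiograph (zero-pad to square → resample → per-image z-score).
2. **Stage 2 — ETT presence classification** on a hard-attention crop: a
   2:1 rectangle spanning 50% × 25% of the model input, centred on the
   stage-1 carina and resampled to 256×128.
3. **Stage 3 — refinement** (ETT-positive exams only): refined carina +
   tube-tip coordinates on the same crop, converted to centimetres via the
   exam's pixel spacing.

Training follows the published recipe: Xavier-uniform init, Adam at 5e-4,
batch 12, 3 epochs + 1 fine-tuning epoch at 5e-5, with translation/scale
augmentation (≤14 px corner displacement) and 90–110% normalization-
statistics jitter. Evaluation uses patient-grouped five-fold
cross-validation, cm error summaries (mean/median/IQR) and classification
metrics with 95% CIs (Wilson score; seeded bootstrap for AUROC).

Because no GPU/deep-learning framework is assumed, the network engine is a
compact numpy implementation (`ettcascade.nn`) with exact hand-written
backprop, verified by finite-difference gradient checks.

Also included:

* **Synthetic radiograph generator** (`ettcascade.synthetic`): images with
  a dark bifurcating trachea, optional bright ETT line with exact tip
  ground truth, distractor tubes, per-exam pixel spacing, and paired report
  sentences. Tip–carina distances follow a lognormal with median 4.10 cm
  (quartiles ≈ 3.2/5.3 cm) at ~50% ETT prevalence.
* **Report parser** (`ettcascade.reports`): regex ETT presence/absence with
  sentence-scoped negation, and documented tip–carina distance extraction
  (cm/mm).
* **DICOM reading** (uncompressed little-endian; PixelSpacing /
  ImagerPixelSpacing, ViewPosition frontal gating, MONOCHROME1 inversion)
  plus 16-bit PNG + JSON sidecar I/O for synthetic data.

## CLI

```bash
ettcascade simulate --n 200 --seed 1 --out data/            # synthetic dataset
ettcascade make-folds --manifest data/manifest.csv --k 5 --seed 1 --out folds.csv
ettcascade train --stage 1 --manifest data/manifest.csv --scale test \
    --seed 1 --out ckpt/s1.npz                               # likewise stages 2, 3
ettcascade predict --stage1 ckpt/s1.npz --stage2 ckpt/s2.npz --stage3 ckpt/s3.npz \
    --manifest data/manifest.csv --out preds.csv --json-out preds.json
ettcascade evaluate --predictions preds.csv --manifest data/manifest.csv \
    --out report.json
ettcascade parse-reports --in reports.csv --out parsed.csv
```

Predictions are emitted as CSV (ORIGINAL-frame coordinates, probability,
decision, distance_cm) and as JSON with full frame provenance (schema
version 1). Exams without pixel spacing yield no cm distance unless
`--allow-pixel-units` is passed.

## Layout

```
src/ettcascade/
  geometry.py    coordinate frames, affine maps, crop windows, cm distances
  preprocess.py  pad/resample/z-score + landmark-consistent augmentation
  nn.py          numpy conv/bn/relu/linear layers, Adam, Xavier init
  backbone.py    backbone topology, heads, losses, checkpoints
  cascade.py     three-stage inference pipeline and prediction schema
  train.py       schedules, patient-grouped folds, stage training, recovery run
  metrics.py     error summaries, Wilson CIs, rank AUROC + bootstrap
  reports.py     regex report labeling and distance extraction
  synthetic.py   synthetic exam generator (images, sidecars, manifests)
  io.py/dicomio.py  exam records, PNG+sidecar and DICOM readers
  cli.py         click command-line interface
```
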