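"""Evaluation summaries: cm-error statistics and classification metrics.

Quantiles use the linear-interpolation convention.  Proportion confidence
intervals use the Wilson score; the AUROC interval uses a seeded percentile
bootstrap (2,000 resamples by default) — the CI methods are this package's
choices and are documented, not claimed to match any external analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import rankdata

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ErrorSummary:
    mean: float
    median: float
    q25: float
    q75: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def error_summary(errors_cm) -> ErrorSummary:
    """Mean/median/quartiles of non-negative error magnitudes."""
    x = np.asarray(errors_cm, dtype=float)
    if x.size == 0:
        raise ValueError("error_summary requires at least one value")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("errors must be finite and non-negative")
    return ErrorSummary(
        mean=float(x.mean()),
        median=float(np.median(x)),
        q25=float(np.quantile(x, 0.25)),
        q75=float(np.quantile(x, 0.75)),
        n=int(x.size),
    )


def wilson_ci(k: int, n: int, z: float = Z95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = k / n
    denom = 1.0 + z * z / n
    centre = p + z * z / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    lo = (centre - half) / denom
    hi = (centre + half) / denom
    # guard float rounding at p = 0 or 1 so the estimate stays inside
    return max(0.0, min(lo, p)), min(1.0, max(hi, p))


def auroc(scores, labels) -> float:
    """Rank-based AUROC (Mann–Whitney, ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_auroc_ci(scores, labels, n_boot: int = 2000,
                       seed: int = 0) -> tuple[float, float]:
    """Seeded percentile bootstrap over exams; degenerate resamples skipped."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    n = len(labels)
    stats = []
    while len(stats) < n_boot:
        idx = rng.integers(0, n, size=n)
        lb = labels[idx]
        if lb.min() == lb.max():
            continue
        stats.append(auroc(scores[idx], lb))
    return (float(np.quantile(stats, 0.025)), float(np.quantile(stats, 0.975)))


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auroc: float
    accuracy_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    auroc_ci: tuple[float, float]
    tp: int
    fn: int
    tn: int
    fp: int

    def as_dict(self) -> dict:
        return asdict(self)


def classification_report(decisions, labels, scores,
                          n_boot: int = 2000, seed: int = 0) -> ClassificationReport:
    """Confusion-count metrics with Wilson CIs, plus bootstrap AUROC CI."""
    decisions = np.asarray(decisions).astype(int)
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not (len(decisions) == len(labels) == len(scores)):
        raise ValueError("decisions, labels and scores must have equal length")
    tp = int(np.sum((decisions == 1) & (labels == 1)))
    fn = int(np.sum((decisions == 0) & (labels == 1)))
    tn = int(np.sum((decisions == 0) & (labels == 0)))
    fp = int(np.sum((decisions == 1) & (labels == 0)))
    n = tp + fn + tn + fp

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    auc = auroc(scores, labels)
    return ClassificationReport(
        accuracy=ratio(tp + tn, n),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        auroc=auc,
        accuracy_ci=wilson_ci(tp + tn, n),
        sensitivity_ci=wilson_ci(tp, tp + fn),
        specificity_ci=wilson_ci(tn, tn + fp),
        ppv_ci=wilson_ci(tp, tp + fp),
        npv_ci=wilson_ci(tn, tn + fn),
        auroc_ci=bootstrap_auroc_ci(scores, labels, n_boot=n_boot, seed=seed),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def distance_agreement(predicted_cm, reference_cm) -> tuple[ErrorSummary, int]:
    """Summary of |predicted − reference|; missing references excluded & counted."""
    pred = np.asarray(predicted_cm, dtype=float)
    ref = np.asarray(reference_cm, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(ref) & np.isfinite(pred)
    n_missing = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no usable pairs")
    return error_summary(np.abs(pred[keep] - ref[keep])), n_missing


def report_to_json(localization: dict[str, ErrorSummary],
                   classification: ClassificationReport | None) -> str:
    payload: dict = {
        "localization_cm": {k: v.as_dict() for k, v in localization.items()},
    }
    if classification is not None:
        payload["classification"] = classification.as_dict()
    return json.dumps(payload, indent=1)


def report_to_text(localization: dict[str, ErrorSummary],
                   classification: ClassificationReport | None) -> str:
    """Aligned plain-text tables mirroring the published row structure."""
    lines = ["Localization error (cm)",
             f"{'Task':<38}{'Mean':>8}{'Median':>8}{'q25':>8}{'q75':>8}{'n':>8}"]
    for name, s in localization.items():
        lines.append(f"{name:<38}{s.mean:>8.2f}{s.median:>8.2f}"
                     f"{s.q25:>8.2f}{s.q75:>8.2f}{s.n:>8d}")
    if classification is not None:
        c = classification
        lines += ["", "Binary classification",
                  f"{'Statistic':<28}{'Value':>10}{'95% CI':>22}"]
        for name, v, ci in [
            ("Accuracy", c.accuracy, c.accuracy_ci),
            ("Sensitivity", c.sensitivity, c.sensitivity_ci),
            ("Specificity", c.specificity, c.specificity_ci),
            ("Positive predictive value", c.ppv, c.ppv_ci),
            ("Negative predictive value", c.npv, c.npv_ci),
            ("AUROC", c.auroc, c.auroc_ci),
        ]:
            lines.append(f"{name:<28}{100 * v:>9.2f}%"
                         f"{100 * ci[0]:>10.2f} to {100 * ci[1]:.2f}%")
    return "\n".join(lines)
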