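"""Pixel-level segmentation evaluation and the HSIL+ recall statistic.

Convention: the lesion region is positive, the normal region negative.
From the per-pixel confusion counts (TP, TN, FP, FN):

    Dice        = 2 TP / (FP + FN + 2 TP)
    Accuracy    = (TP + TN) / (TP + FP + TN + FN)
    Recall      = TP / (TP + FN)
    Precision   = TP / (TP + FP)
    Specificity = TN / (TN + FP)
    Score       = (Dice + Recall) / 2

Zero-denominator policy: with empty truth *and* empty prediction,
dice = recall = precision = 1 (perfect agreement on "nothing there");
with empty truth but a nonempty prediction, recall is undefined and the
image is excluded from the recall mean while dice follows the formula.
The evaluation protocol only feeds images with nonempty truth, so the
policy exists for robustness.

The HSIL+ recall HR of one case is the fraction of the HSIL+
ground-truth region covered by the predicted lesion region,
|A_H ∩ A_a| / |A_H|; cases are reported binned into
(0.9, 1.0], (0.8, 0.9], (0.7, 0.8], (0.6, 0.7] and (0, 0.6]
(half-open on the left; hr = 0 falls in the lowest bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "HRRecord", "confusion", "dice", "accuracy",
           "recall", "precision", "specificity", "score", "evaluate_set",
           "hsil_recall", "hr_table", "HR_BINS"]

#: (lower-exclusive, upper-inclusive) HR bins, highest first
HR_BINS = ((0.9, 1.0), (0.8, 0.9), (0.7, 0.8), (0.6, 0.7), (0.0, 0.6))


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class HRRecord:
    case_id: str
    hr: float

    @property
    def bin(self) -> tuple[float, float]:
        return _hr_bin(self.hr)


def _hr_bin(hr: float) -> tuple[float, float]:
    if not 0.0 <= hr <= 1.0:
        raise ValueError(f"HR must be in [0, 1], got {hr}")
    for lo, hi in HR_BINS:
        if lo < hr <= hi:
            return (lo, hi)
    return HR_BINS[-1]  # hr == 0 closes the lowest bin


def _check_pair(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs "
                         f"truth {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts of a binary prediction against truth."""
    pred, truth = _check_pair(pred, truth)
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def dice(c: ConfusionCounts) -> float:
    den = c.FP + c.FN + 2 * c.TP
    return 2 * c.TP / den if den else 1.0


def accuracy(c: ConfusionCounts) -> float:
    return (c.TP + c.TN) / c.total


def recall(c: ConfusionCounts) -> float | None:
    den = c.TP + c.FN
    if den == 0:
        return 1.0 if c.FP == 0 else None  # undefined with FP but no truth
    return c.TP / den


def precision(c: ConfusionCounts) -> float:
    den = c.TP + c.FP
    return c.TP / den if den else 1.0


def specificity(c: ConfusionCounts) -> float:
    den = c.TN + c.FP
    return c.TN / den if den else 1.0


def score(dice_value: float, recall_value: float) -> float:
    """Model-selection score: arithmetic mean of Dice and Recall."""
    if not (0 <= dice_value <= 1 and 0 <= recall_value <= 1):
        raise ValueError("dice and recall must be in [0, 1]")
    return (dice_value + recall_value) / 2


def evaluate_set(preds, truths) -> dict:
    """Summarize a paired set of predictions as mean ± std per metric.

    Dice/precision/recall/specificity are averaged over images with the
    population (÷ n) standard deviation; accuracy is pooled over all
    pixels, reported as a single number (per-image accuracies are also
    returned). Images where recall is undefined are excluded from the
    recall mean.
    """
    preds, truths = list(preds), list(truths)
    if not preds or len(preds) != len(truths):
        raise ValueError(f"paired nonempty sets required, got {len(preds)} "
                         f"predictions and {len(truths)} truths")
    per = {"dice": [], "precision": [], "recall": [], "specificity": [],
           "accuracy": []}
    pooled = ConfusionCounts(0, 0, 0, 0)
    for p, t in zip(preds, truths):
        c = confusion(p, t)
        pooled = ConfusionCounts(pooled.TP + c.TP, pooled.TN + c.TN,
                                 pooled.FP + c.FP, pooled.FN + c.FN)
        per["dice"].append(dice(c))
        per["precision"].append(precision(c))
        r = recall(c)
        if r is not None:
            per["recall"].append(r)
        per["specificity"].append(specificity(c))
        per["accuracy"].append(accuracy(c))
    report = {"n_images": len(preds), "accuracy": accuracy(pooled)}
    for name in ("dice", "precision", "recall", "specificity"):
        vals = np.asarray(per[name], dtype=np.float64)
        report[name] = (float(vals.mean()), float(vals.std()))  # population std
    report["per_image_accuracy"] = per["accuracy"]
    return report


def hsil_recall(pred: np.ndarray, hsil_truth: np.ndarray) -> float:
    """HR = |A_H ∩ A_a| / |A_H| for one case; errors on empty A_H."""
    pred, truth = _check_pair(pred, hsil_truth)
    area_h = np.count_nonzero(truth)
    if area_h == 0:
        raise ValueError("HR is undefined for an empty HSIL+ truth region")
    return float(np.count_nonzero(pred & truth) / area_h)


def hr_table(hrs) -> list[dict]:
    """Bin HR values; rows of (bin, count, percentage to 2 decimals)."""
    hrs = list(hrs)
    counts = {b: 0 for b in HR_BINS}
    for hr in hrs:
        counts[_hr_bin(hr)] += 1
    total = max(len(hrs), 1)
    return [{"bin": b, "count": counts[b],
             "percentage": round(100.0 * counts[b] / total, 2)}
            for b in HR_BINS]
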