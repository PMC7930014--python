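"""Evaluation of pipeline output against expert labels.

Two kinds of comparison are supported:

* **2x2 confusion matrices** between expert labels and pipeline labels on a
  common set of units (clips, or grid squares), with accuracy and
  best-threshold selection.  The package bundles the case-study reference
  matrices — expert vs. aggregated citizen-scientist clip classifications
  of 2,594 clips at 40/60/80% agreement, and expert vs. machine square
  classifications of 132 grid squares at detector confidence 0.5/0.7/0.9 —
  as plain CSV fixtures.

* **Detection metrics** (precision, recall, F1, AP@0.5) for box predictions
  against ground-truth boxes, with greedy confidence-ordered IoU matching
  and all-point interpolated average precision, plus an exhaustive
  assignment-enumeration oracle for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .boxes import BBox, iou
from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Expert-vs-pipeline contingency table.

    Rows are the expert label (positive / negative), columns the pipeline
    label: ``tp`` expert-positive & pipeline-positive, ``fn``
    expert-positive & pipeline-negative, ``fp`` expert-negative &
    pipeline-positive, ``tn`` both negative.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    ap50: float


def confusion_2x2(
    expert: Mapping[str, str],
    predicted: Mapping[str, str],
    positive_label: str,
) -> ConfusionMatrix2x2:
    """Tabulate per-unit expert vs. pipeline labels into a 2x2 matrix.

    Both maps must cover exactly the same units; any label other than
    ``positive_label`` counts as negative.
    """
    if set(expert) != set(predicted):
        diff = sorted(set(expert) ^ set(predicted))
        raise ValidationError(f"unit sets differ; symmetric difference: {diff}")
    tp = fn = fp = tn = 0
    for unit, exp_label in expert.items():
        e = exp_label == positive_label
        p = predicted[unit] == positive_label
        if e and p:
            tp += 1
        elif e:
            fn += 1
        elif p:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix2x2(tp, fn, fp, tn)


def accuracy(m: ConfusionMatrix2x2) -> float:
    """Fraction of units on which pipeline and expert agree."""
    if m.total == 0:
        raise ValidationError("accuracy undefined for an empty matrix")
    return (m.tp + m.tn) / m.total


def best_threshold(matrices: Mapping[float, ConfusionMatrix2x2]) -> float:
    """Threshold with maximal accuracy; ties go to the higher threshold.

    The conservative tie rule prefers the setting with fewer false
    positives, mirroring the survey design goal of minimising spurious
    species records.
    """
    if not matrices:
        raise ValidationError("best_threshold requires at least one matrix")
    return max(matrices, key=lambda t: (accuracy(matrices[t]), t))


# ---------------------------------------------------------------------------
# bundled case-study matrices

CLIP_AGREEMENT_FIXTURE = "clip_agreement_matrices.csv"
ML_CONFIDENCE_FIXTURE = "ml_confidence_matrices.csv"


def _load_matrix_table(
    df: pd.DataFrame, threshold_col: str, positive_label: str
) -> dict[float, ConfusionMatrix2x2]:
    out = {}
    for thr, g in df.groupby(threshold_col):
        cells = {
            (row["expert_label"], row["predicted_label"]): int(row["count"])
            for _, row in g.iterrows()
        }
        neg = sorted({l for pair in cells for l in pair if l != positive_label})
        if len(neg) != 1:
            raise ValidationError(
                f"expected one negative label besides {positive_label!r}, got {neg}"
            )
        n = neg[0]
        out[float(thr)] = ConfusionMatrix2x2(
            tp=cells[(positive_label, positive_label)],
            fn=cells[(positive_label, n)],
            fp=cells[(n, positive_label)],
            tn=cells[(n, n)],
        )
    return out


def read_matrices_csv(
    path: Union[str, Path], threshold_col: str, positive_label: str = "Coral"
) -> dict[float, ConfusionMatrix2x2]:
    """Read per-threshold confusion matrices from a long-format CSV.

    Expected columns: ``<threshold_col>,expert_label,predicted_label,count``.
    """
    return _load_matrix_table(pd.read_csv(path), threshold_col, positive_label)


def load_clip_agreement_matrices() -> dict[float, ConfusionMatrix2x2]:
    """Bundled expert-vs-citizen clip matrices (2,594 clips; thresholds 0.4/0.6/0.8)."""
    with resources.files("rovannot.data").joinpath(CLIP_AGREEMENT_FIXTURE).open() as f:
        return _load_matrix_table(pd.read_csv(f), "agreement_threshold", "Coral")


def load_ml_confidence_matrices() -> dict[float, ConfusionMatrix2x2]:
    """Bundled expert-vs-machine square matrices (132 squares; confidences 0.5/0.7/0.9)."""
    with resources.files("rovannot.data").joinpath(ML_CONFIDENCE_FIXTURE).open() as f:
        return _load_matrix_table(pd.read_csv(f), "conf_threshold", "Coral")


# ---------------------------------------------------------------------------
# detection metrics


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _ap_all_point(flags: Sequence[bool], n_truth: int) -> float:
    """All-point interpolated AP from confidence-ordered TP/FP flags."""
    if n_truth == 0:
        return 1.0 if not flags else 0.0
    if not flags:
        return 0.0
    tps = np.cumsum([1 if f else 0 for f in flags])
    fps = np.cumsum([0 if f else 1 for f in flags])
    recalls = tps / n_truth
    precisions = tps / (tps + fps)
    # precision envelope: p_interp(r) = max precision at recall >= r
    env = np.maximum.accumulate(precisions[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def match_predictions(
    predicted: Sequence[tuple[BBox, float]],
    truth: Sequence[BBox],
    iou_min: float = 0.5,
) -> list[bool]:
    """Greedy confidence-ordered matching; returns a TP flag per prediction.

    Predictions are visited in descending confidence (stable on ties); each
    is matched to the unmatched truth box of highest IoU provided that IoU
    reaches ``iou_min``.
    """
    order = sorted(range(len(predicted)), key=lambda i: (-predicted[i][1], i))
    taken: set[int] = set()
    flags = [False] * len(predicted)
    for i in order:
        box = predicted[i][0]
        best_j, best_v = -1, 0.0
        for j, t in enumerate(truth):
            if j in taken:
                continue
            v = iou(box, t)
            if v >= iou_min and v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            taken.add(best_j)
            flags[i] = True
    return flags


def detection_metrics(
    predicted: Sequence[tuple[BBox, float]],
    truth: Sequence[BBox],
    iou_min: float = 0.5,
) -> DetectionMetrics:
    """Precision / recall / F1 at the full prediction set, plus AP@``iou_min``.

    Edge conventions: with no truth and no predictions everything is 1.0
    (vacuously perfect); with predictions but no truth, precision is 0;
    with truth but no predictions, recall is 0.
    """
    if not truth and not predicted:
        return DetectionMetrics(1.0, 1.0, 1.0, 1.0)
    flags = match_predictions(predicted, truth, iou_min)
    order = sorted(range(len(predicted)), key=lambda i: (-predicted[i][1], i))
    ordered_flags = [flags[i] for i in order]
    tp = sum(flags)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return DetectionMetrics(
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        ap50=_ap_all_point(ordered_flags, len(truth)),
    )


def detection_metrics_oracle(
    predicted: Sequence[tuple[BBox, float]],
    truth: Sequence[BBox],
    iou_min: float = 0.5,
) -> DetectionMetrics:
    """Exhaustive-assignment reference for :func:`detection_metrics`.

    Enumerates every injective assignment of predictions to truth boxes with
    IoU >= ``iou_min`` and keeps the best under the lexicographic objective
    (most matches, then highest total matched confidence, then highest total
    IoU); metrics are computed from that assignment's TP flags.  Intended
    for instances of at most ~5 boxes a side.
    """
    if not truth and not predicted:
        return DetectionMetrics(1.0, 1.0, 1.0, 1.0)
    n_p, n_t = len(predicted), len(truth)
    if n_p > 6 or n_t > 6:
        raise ValidationError("oracle is exponential; limit instances to 6 boxes")
    eligible = [
        [j for j in range(n_t) if iou(predicted[i][0], truth[j]) >= iou_min]
        for i in range(n_p)
    ]
    best_key: Optional[tuple] = None
    best_flags = [False] * n_p
    preds = list(range(n_p))
    for r in range(min(n_p, n_t), -1, -1):
        for chosen in itertools.combinations(preds, r):
            for assignment in itertools.permutations(range(n_t), r):
                if any(
                    assignment[k] not in eligible[chosen[k]] for k in range(r)
                ):
                    continue
                conf_sum = sum(predicted[i][1] for i in chosen)
                iou_sum = sum(
                    iou(predicted[chosen[k]][0], truth[assignment[k]])
                    for k in range(r)
                )
                key = (r, conf_sum, iou_sum)
                if best_key is None or key > best_key:
                    best_key = key
                    flags = [False] * n_p
                    for i in chosen:
                        flags[i] = True
                    best_flags = flags
        if best_key is not None and best_key[0] == r:
            break  # larger matchings already exhausted
    tp = sum(best_flags)
    precision = tp / n_p if n_p else 1.0
    recall = tp / n_t if n_t else 1.0
    order = sorted(range(n_p), key=lambda i: (-predicted[i][1], i))
    ordered_flags = [best_flags[i] for i in order]
    return DetectionMetrics(
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        ap50=_ap_all_point(ordered_flags, n_t),
    )
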