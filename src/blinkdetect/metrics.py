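"""Blink-level detection metrics via interval-IOU correspondence matrices.

Event-level evaluation of blink detectors is subtle because predictions
and ground truth need not match one-to-one: a single long predicted
blink can overlap several true blinks and vice versa. The scheme here
builds a binary correspondence matrix ``R`` (rows = true blinks,
columns = predicted blinks) marking pairs whose interval IOU reaches a
cutoff (default 0.2), then derives:

* ``FN``  = number of all-zero rows (missed true blinks),
* ``a``   = row excess: extra predictions matching one true blink,
* ``b``   = column excess: extra true blinks matched by one prediction,
* ``c``   = entries counted in both ``a`` and ``b`` (subtracted once),
* ``FP``  = a + b - c + number of all-zero columns,
* ``TP``  = sum(R) - FP.

Accuracy and F1 summarize the counts as percentages (true negatives are
undefined for event detection, so accuracy is TP / (TP + FP + FN)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import BlinkInterval

logger = logging.getLogger(__name__)


def interval_iou(x: BlinkInterval, y: BlinkInterval) -> float:
    """Intersection-over-union of two inclusive frame intervals.

    Frames are counted inclusively: [1, 12] vs [7, 18] share 6 frames
    (7..12) out of 18 (1..18), giving IOU = 1/3.
    """
    inter = min(x.end, y.end) - max(x.start, y.start) + 1
    if inter <= 0:
        return 0.0
    union = x.duration + y.duration - inter
    return inter / union


@dataclass
class CorrespondenceMatrix:
    """Binary truth x prediction match matrix at a given IOU threshold."""

    entries: np.ndarray  # shape (G, P), values in {0, 1}
    iou_threshold: float = 0.2

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int64)
        if self.entries.ndim != 2:
            raise ValueError("correspondence matrix must be 2-D")
        if self.entries.size and not np.isin(self.entries, (0, 1)).all():
            raise ValueError("correspondence matrix entries must be binary")

    @property
    def n_truth(self) -> int:
        return self.entries.shape[0]

    @property
    def n_pred(self) -> int:
        return self.entries.shape[1]


def build_correspondence_matrix(
    truth: Sequence[BlinkInterval],
    pred: Sequence[BlinkInterval],
    iou_threshold: float = 0.2,
) -> CorrespondenceMatrix:
    """R[i, j] = 1 iff IOU(truth_i, pred_j) >= iou_threshold."""
    entries = np.zeros((len(truth), len(pred)), dtype=np.int64)
    for i, t in enumerate(truth):
        for j, p in enumerate(pred):
            if interval_iou(t, p) >= iou_threshold:
                entries[i, j] = 1
    return CorrespondenceMatrix(entries=entries, iou_threshold=iou_threshold)


def count_fn(R: CorrespondenceMatrix) -> int:
    """False negatives: rows of R whose sum is zero (unmatched true blinks)."""
    if R.n_truth == 0:
        return 0
    return int((R.entries.sum(axis=1) == 0).sum())


def excess_row(R: CorrespondenceMatrix) -> int:
    """Row excess ``a``: sum of (row-sum - 1) over rows with sum > 1."""
    sums = R.entries.sum(axis=1)
    return int((sums[sums > 1] - 1).sum())


def excess_col(R: CorrespondenceMatrix) -> int:
    """Column excess ``b``: sum of (column-sum - 1) over columns with sum > 1."""
    sums = R.entries.sum(axis=0)
    return int((sums[sums > 1] - 1).sum())


def double_counted(R: CorrespondenceMatrix) -> int:
    """Correction ``c``: unit entries whose row sum and column sum both exceed 1."""
    row_sums = R.entries.sum(axis=1, keepdims=True)
    col_sums = R.entries.sum(axis=0, keepdims=True)
    return int((R.entries * (row_sums > 1) * (col_sums > 1)).sum())


def count_fp(R: CorrespondenceMatrix) -> int:
    """False positives: a + b - c + number of all-zero columns."""
    empty_cols = int((R.entries.sum(axis=0) == 0).sum()) if R.n_pred else 0
    return excess_row(R) + excess_col(R) - double_counted(R) + empty_cols


def count_tp(R: CorrespondenceMatrix) -> int:
    """True positives: sum(R) - FP.

    On matrices built from real detections this is non-negative; on
    adversarial dense matrices it can go negative, which is flagged but
    returned as defined.
    """
    tp = int(R.entries.sum()) - count_fp(R)
    if tp < 0:
        warnings.warn(
            f"TP = sum(R) - FP is negative ({tp}); the correspondence "
            "matrix is pathological (dense many-to-many matches)",
            RuntimeWarning,
            stacklevel=2,
        )
    return tp


@dataclass
class DetectionCounts:
    """Event-level confusion counts plus the intermediate excess terms."""

    tp: int
    fp: int
    fn: int
    a: int = 0
    b: int = 0
    c: int = 0

    @classmethod
    def from_matrix(cls, R: CorrespondenceMatrix) -> "DetectionCounts":
        """Derive counts from a correspondence matrix.

        ``TP = sum(R) - FP`` taken literally goes negative on matrices
        with unmatched predictions but no matches at all (e.g. no truth
        blinks); since a count of correctly predicted blinks cannot be
        negative, TP is floored at zero here (the raw value remains
        available through :func:`count_tp`, which warns).
        """
        return cls(
            tp=max(0, count_tp(R)),
            fp=count_fp(R),
            fn=count_fn(R),
            a=excess_row(R),
            b=excess_col(R),
            c=double_counted(R),
        )

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            a=self.a + other.a,
            b=self.b + other.b,
            c=self.c + other.c,
        )


@dataclass
class DetectionScores:
    """Accuracy and F1 of event-level detection, as percentages."""

    accuracy: float
    f1: float


def detection_scores(counts: DetectionCounts) -> DetectionScores:
    """Accuracy = 100 TP/(TP+FP+FN); F1 = 100 * 2TP/(2TP+FP+FN)."""
    total = counts.tp + counts.fp + counts.fn
    if total == 0:
        raise ValueError("detection scores undefined: TP + FP + FN = 0")
    accuracy = 100.0 * counts.tp / total
    f1 = 100.0 * 2 * counts.tp / (2 * counts.tp + counts.fp + counts.fn)
    return DetectionScores(accuracy=accuracy, f1=f1)


def evaluate_detections(
    truth: Sequence[BlinkInterval],
    pred: Sequence[BlinkInterval],
    iou_threshold: float = 0.2,
) -> DetectionCounts:
    """Match intervals at the IOU cutoff and derive TP/FP/FN counts."""
    R = build_correspondence_matrix(truth, pred, iou_threshold)
    counts = DetectionCounts.from_matrix(R)
    logger.info(
        "evaluated %d truth vs %d predicted blinks at IOU>=%.2f: "
        "TP=%d FP=%d FN=%d (a=%d b=%d c=%d)",
        len(truth), len(pred), iou_threshold,
        counts.tp, counts.fp, counts.fn, counts.a, counts.b, counts.c,
    )
    return counts


def blinkwise_report(
    truth: Sequence[BlinkInterval],
    pred: Sequence[BlinkInterval],
    iou_threshold: float = 0.2,
):
    """Per-eye counts and scores plus a ``total`` row, as a DataFrame.

    Eyes are evaluated independently and the counts summed for the
    total, so a left-eye prediction can never match a right-eye truth.
    """
    import pandas as pd

    from .types import Eye

    rows = []
    total = DetectionCounts(0, 0, 0)
    sides = sorted(
        {b.side for b in truth} | {b.side for b in pred}, key=lambda e: e.value
    ) or [Eye.LEFT]
    for side in sides:
        counts = evaluate_detections(
            [b for b in truth if b.side == side],
            [b for b in pred if b.side == side],
            iou_threshold,
        )
        total = total + counts
        rows.append((side.value, counts))
    rows.append(("total", total))
    records = []
    for name, counts in rows:
        have_events = counts.tp + counts.fp + counts.fn > 0
        scores = detection_scores(counts) if have_events else None
        records.append(
            {
                "eye": name,
                "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
                "a": counts.a, "b": counts.b, "c": counts.c,
                "accuracy": round(scores.accuracy, 2) if scores else float("nan"),
                "f1": round(scores.f1, 2) if scores else float("nan"),
            }
        )
    return pd.DataFrame.from_records(records)


def frame_accuracy(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Percentage of frames whose binary blink label matches."""
    pred_mask = np.asarray(pred_mask)
    truth_mask = np.asarray(truth_mask)
    if pred_mask.shape != truth_mask.shape:
        raise ValueError(
            f"mask shapes differ: {pred_mask.shape} vs {truth_mask.shape}"
        )
    if pred_mask.size == 0:
        raise ValueError("cannot compute frame accuracy of empty masks")
    return 100.0 * float((pred_mask == truth_mask).mean())
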