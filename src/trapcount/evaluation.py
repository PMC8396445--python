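"""Counting and the detection/counting metric suite.

A detection is "correct" for a ground-truth object when the class
labels match and the detection covers at least half of the annotation
(IoGT >= 0.5).  Each detection is assigned to the annotation it covers
best; per annotation, only the highest-IoGT correct detection counts as
a true positive, any others are false positives.  From the TP/FP/FN
counts: DR (detection rate) = recall, FDR (false detection rate)
= 1 - precision, and F1 is their harmonic-mean combination

    F1 = 2 * DR * (1 - FDR) / (DR + (1 - FDR)).

Counting accuracy is scored by the mean absolute and mean squared
error between predicted and true per-image insect counts.
"""

from __future__ import annotations

from typing import Sequence

from .geometry import iogt
from .structures import Detection, GroundTruthBox, MetricsReport

MATCH_IOGT_THRESHOLD = 0.5


def count(dets: Sequence[Detection]) -> int:
    """Insect count of one image: one suppressed detection per insect."""
    return len(dets)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruthBox],
    iogt_threshold: float = MATCH_IOGT_THRESHOLD,
) -> tuple[int, int, int]:
    """(TP, FP, FN) for one image.

    Order-invariant: assignments depend only on IoGT values (ties broken
    by annotation order, then by detection IoGT).
    """
    # assign each detection to the gt it covers best among class-correct
    # gts with IoGT above threshold
    assigned: dict[int, list[tuple[float, int]]] = {}
    n_unmatched = 0
    for d_idx, det in enumerate(dets):
        best_j, best_v = None, 0.0
        for j, gt in enumerate(gts):
            if det.label != gt.label:
                continue
            v = iogt(det.box, gt.box)
            if v >= iogt_threshold and v > best_v:
                best_j, best_v = j, v
        if best_j is None:
            n_unmatched += 1
        else:
            assigned.setdefault(best_j, []).append((best_v, d_idx))
    tp = len(assigned)  # one TP per annotation with >= 1 correct detection
    fp = n_unmatched + sum(len(v) - 1 for v in assigned.values())
    fn = len(gts) - tp
    return tp, fp, fn


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """(P, R); zero when the respective denominator is zero."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    return p, r


def f1(dr: float, fdr: float) -> float:
    """F1 from detection rate and false detection rate, both in [0, 1]."""
    if not (0.0 <= dr <= 1.0 and 0.0 <= fdr <= 1.0):
        raise ValueError("DR and FDR must lie in [0, 1]")
    p = 1.0 - fdr
    if dr + p == 0.0:
        return 0.0
    return 2.0 * dr * p / (dr + p)


def mae_mse(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Mean absolute / mean squared error of (predicted, true) counts."""
    if len(pairs) == 0:
        raise ValueError("need at least one (predicted, true) pair")
    diffs = [true - pred for pred, true in pairs]
    mae = sum(abs(d) for d in diffs) / len(diffs)
    mse = sum(d * d for d in diffs) / len(diffs)
    return mae, mse


def evaluate(
    detections_per_image: Sequence[Sequence[Detection]],
    gts_per_image: Sequence[Sequence[GroundTruthBox]],
    target_class: str | None = None,
) -> MetricsReport:
    """Aggregate metrics over a set of images.

    ``target_class`` restricts counting (MAE/MSE) to one insect class,
    mirroring evaluation against a single pest species; detection
    metrics always use all classes.
    """
    if len(detections_per_image) != len(gts_per_image):
        raise ValueError("detections and ground truths must cover the same images")
    tp = fp = fn = 0
    pairs: list[tuple[int, int]] = []
    for dets, gts in zip(detections_per_image, gts_per_image):
        t, f, n = match_detections(dets, gts)
        tp, fp, fn = tp + t, fp + f, fn + n
        if target_class is None:
            pairs.append((count(list(dets)), len(gts)))
        else:
            pairs.append(
                (
                    count([d for d in dets if d.label == target_class]),
                    sum(1 for g in gts if g.label == target_class),
                )
            )
    p, r = precision_recall(tp, fp, fn)
    mae, mse = mae_mse(pairs)
    return MetricsReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=p,
        recall=r,
        dr=r,
        fdr=1.0 - p,
        f1=f1(r, 1.0 - p),
        mae=mae,
        mse=mse,
        per_image_counts=pairs,
    )
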