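"""Redundancy elimination: conventional NMS and the improved NMS (INMS).

Many proposals can cover one insect, so the classifier emits clusters
of overlapping detections.  Conventional NMS keeps only the most
confident box of each overlapping pair, which mis-fires when a
wrong-class box happens to carry the highest confidence.  INMS first
*merges* overlapping same-class detections — walking the working set in
ascending box area, combining the smallest box into the first
overlapping same-class partner — which pools their evidence and raises
the confidence of repeatedly-detected objects; conventional NMS and a
final confidence threshold ``gamma`` are then applied to the merged set.

Merging combines geometry by confidence-weighted coordinate averaging
and confidence by the noisy-OR rule ``1 - (1-c0)(1-c1)``, so a merged
detection is always at least as confident as its parts.
"""

from __future__ import annotations

import math
from typing import Sequence

from .geometry import Box, iou
from .structures import Detection


def _area_key(d: Detection):
    # ascending area; ties broken (xmin, ymin, confidence), then the
    # remaining fields for a total order
    return (d.box.area, d.box.xmin, d.box.ymin, d.confidence, d.box.ymax, d.box.xmax, d.label)


def _conf_key(d: Detection):
    return (-d.confidence, d.box.xmin, d.box.ymin, d.box.xmax, d.box.ymax, d.label)


def nms(dets: Sequence[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Greedy class-agnostic non-maximum suppression.

    Repeatedly keeps the most confident remaining detection and removes
    every other detection overlapping it with IoU above the threshold.
    Output sorted by confidence, descending.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    remaining = sorted(dets, key=_conf_key)
    kept: list[Detection] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [d for d in remaining if iou(best.box, d.box) <= iou_threshold]
    return kept


def merge(b0: Detection, b1: Detection) -> Detection:
    """Merge two same-class detections into one.

    Coordinates: confidence-weighted average, rounded to integers.
    Confidence: noisy-OR, so two independent sightings reinforce each
    other and the merged confidence never drops below either input.
    """
    if b0.label != b1.label:
        raise ValueError(f"cannot merge detections of classes {b0.label!r} and {b1.label!r}")
    w0, w1 = b0.confidence, b1.confidence
    total = w0 + w1
    if total == 0:
        w0 = w1 = 0.5
        total = 1.0
    coords = tuple(
        int(math.floor((w0 * c0 + w1 * c1) / total + 0.5))
        for c0, c1 in zip(b0.box, b1.box)
    )
    confidence = 1.0 - (1.0 - b0.confidence) * (1.0 - b1.confidence)
    return Detection(box=Box(*coords).validate(), label=b0.label, confidence=confidence)


def merge_overlapping(
    dets: Sequence[Detection], merge_iou_threshold: float = 0.5
) -> list[Detection]:
    """The merge phase of INMS on its own.

    The working set is kept sorted in ascending box area.  The smallest
    box b0 is compared against the rest in that order; the first
    same-class partner with IoU above the merge threshold absorbs b0
    (and the set is re-sorted), otherwise b0 is final and moves to the
    holding set.  Terminates when the working set is empty.
    """
    if not 0.0 < merge_iou_threshold < 1.0:
        raise ValueError(
            f"merge_iou_threshold must lie in (0, 1), got {merge_iou_threshold}"
        )
    work = sorted(dets, key=_area_key)
    held: list[Detection] = []
    while work:
        b0 = work.pop(0)
        for i, bi in enumerate(work):
            if bi.label == b0.label and iou(b0.box, bi.box) > merge_iou_threshold:
                work[i] = merge(b0, bi)
                work.sort(key=_area_key)
                break
        else:
            held.append(b0)
    return held


def inms(
    dets: Sequence[Detection],
    merge_iou_threshold: float = 0.5,
    nms_iou_threshold: float = 0.5,
    gamma: float = 0.5,
) -> list[Detection]:
    """Improved NMS: merge, suppress, then confidence-threshold.

    Returns the detections surviving conventional NMS on the merged set
    whose confidence is at least ``gamma``, sorted by confidence
    descending.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    held = merge_overlapping(dets, merge_iou_threshold)
    suppressed = nms(held, nms_iou_threshold)
    return [d for d in suppressed if d.confidence >= gamma]
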