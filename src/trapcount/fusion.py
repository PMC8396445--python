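"""Dual-path fusion of an external detector with the saliency pipeline.

The saliency-based counter has a low false-detection rate but misses
insects that sit close together (their activation regions fuse), while
a dense sliding-window detector such as Faster R-CNN finds those but
produces more false positives.  The fusion rule keeps an external
detection only if it overlaps (IoU > 0) at least one detection from the
saliency pipeline; everything else is treated as a false detection and
dropped.  Confidences are left unchanged — no re-scoring is applied.
"""

from __future__ import annotations

from typing import Sequence

from .geometry import iou
from .structures import Detection


def fuse(
    external_dets: Sequence[Detection],
    proposed_dets: Sequence[Detection],
    union_mode: bool = False,
) -> list[Detection]:
    """Validate external detections against the saliency pipeline's.

    Returns the external detections overlapping at least one proposed
    detection.  With ``union_mode`` the proposed detections that no
    external detection overlaps are appended as well, so neither path's
    unique finds are lost.
    """
    validated = [
        bf
        for bf in external_dets
        if any(iou(bf.box, bp.box) > 0.0 for bp in proposed_dets)
    ]
    if not union_mode:
        return validated
    unmatched = [
        bp
        for bp in proposed_dets
        if not any(iou(bf.box, bp.box) > 0.0 for bf in external_dets)
    ]
    return validated + unmatched
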