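"""Axis-aligned box geometry in pixel coordinates.

Boxes are 0-based and half-open: ``[xmin, xmax) x [ymin, ymax)`` with x
running along image columns and y along rows.  All overlap measures used
by the pipeline (IoU for suppression/labelling, IoGT for region gating
and true-positive matching) live here.
"""

from __future__ import annotations

from typing import NamedTuple


class Box(NamedTuple):
    """Axis-aligned rectangle; ``xmin < xmax`` and ``ymin < ymax``."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(xc, yc) of the continuous rectangle."""
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    def validate(self) -> "Box":
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"degenerate box {self}")
        return self


def intersection_area(a: Box, b: Box) -> int:
    w = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    h = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if w <= 0 or h <= 0:
        return 0
    return w * h


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    inter = intersection_area(a, b)
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def iogt(a: Box, gt: Box) -> float:
    """Intersection area divided by the ground-truth box area.

    The asymmetric overlap measure used both to gate activation regions
    against annotations and to decide whether a detection "covers" a
    ground-truth object.
    """
    return intersection_area(a, gt) / gt.area


def clip_box(box: Box, image_height: int, image_width: int) -> Box | None:
    """Clip a box to image bounds; ``None`` if nothing remains."""
    xmin = max(box.xmin, 0)
    ymin = max(box.ymin, 0)
    xmax = min(box.xmax, image_width)
    ymax = min(box.ymax, image_height)
    if xmin >= xmax or ymin >= ymax:
        return None
    return Box(xmin, ymin, xmax, ymax)
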