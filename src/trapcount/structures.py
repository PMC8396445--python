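"""Shared record types passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import Box


@dataclass(frozen=True)
class GroundTruthBox:
    """An annotated object: tight box plus class name."""

    box: Box
    label: str


@dataclass(frozen=True)
class ActivationRegion:
    """Connected foreground component of the thresholded saliency mask."""

    box: Box
    pixel_count: int
    center: tuple[float, float]  # (xc, yc), pixel-count centroid

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("activation region must contain at least one pixel")
        if self.pixel_count > self.box.area:
            raise ValueError("pixel_count exceeds bounding-box area")


@dataclass(frozen=True)
class RegionProposal:
    """A box submitted to the object classifier.

    ``scale_index`` 0 is the activation region's own bounding box;
    1..k are the preset-scale tune-up boxes centred on the anchor.
    """

    box: Box
    anchor: tuple[float, float]
    scale_index: int


@dataclass(frozen=True)
class Detection:
    """Classified box: geometry, class label and confidence in [0, 1]."""

    box: Box
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class MetricsReport:
    """Detection and counting metrics for a set of images.

    DR (detection rate) equals recall; FDR (false detection rate)
    equals 1 - precision.  MAE/MSE are errors of the per-image counts.
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    dr: float
    fdr: float
    f1: float
    mae: float
    mse: float
    per_image_counts: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "DR": self.dr,
            "FDR": self.fdr,
            "F1": self.f1,
            "MAE": self.mae,
            "MSE": self.mse,
            "per_image_counts": [list(p) for p in self.per_image_counts],
        }
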