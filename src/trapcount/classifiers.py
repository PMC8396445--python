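"""Patch-classifier contract, training-label construction and a
deterministic colour-rule classifier.

Two classifiers drive the pipeline: C1 decides background vs foreground
for activation regions, C2 assigns the insect class to each region
proposal.  Both consume fixed-size RGB patches cropped from the trap
image; crops reaching past the border are padded with white pixels so
the apparent object size is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.transform import resize

from .geometry import Box, iou
from .structures import GroundTruthBox, RegionProposal

WHITE = np.array([255, 255, 255], dtype=np.uint8)
BACKGROUND_LABEL = "background"


@runtime_checkable
class PatchClassifier(Protocol):
    """Contract shared by C1 and C2: predict a label and a confidence
    for one RGB patch."""

    classes: Sequence[str]

    def predict_patch(self, patch: np.ndarray) -> tuple[str, float]:
        ...


def crop_with_padding(image: np.ndarray, box: Box) -> np.ndarray:
    """Crop ``box`` out of ``image``; pixels outside the image are white.

    The returned patch always has exactly the box's dimensions.  Raises
    if the box does not overlap the image at all.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if box.xmax <= 0 or box.ymax <= 0 or box.xmin >= w or box.ymin >= h:
        raise ValueError(f"box {box} lies fully outside the {h}x{w} image")
    patch = np.empty((box.height, box.width, 3), dtype=np.uint8)
    patch[:] = WHITE
    x0, y0 = max(box.xmin, 0), max(box.ymin, 0)
    x1, y1 = min(box.xmax, w), min(box.ymax, h)
    patch[y0 - box.ymin : y1 - box.ymin, x0 - box.xmin : x1 - box.xmin] = image[y0:y1, x0:x1]
    return patch


def resize_patch(patch: np.ndarray, side: int) -> np.ndarray:
    """Resize a patch to ``side x side`` uint8 RGB."""
    out = resize(patch, (side, side, 3), preserve_range=True, anti_aliasing=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class TrainingExample:
    patch: np.ndarray
    label: str


def make_c2_labels(
    proposals: Sequence[RegionProposal],
    gts: Sequence[GroundTruthBox],
    image: np.ndarray,
    iou_threshold: float = 0.5,
    patch_side: int = 64,
) -> list[TrainingExample]:
    """Label each proposal with the class of its best-overlapping
    annotation.

    A proposal takes the class of the ground-truth box maximising
    IoU with it, provided that maximum reaches ``iou_threshold``;
    otherwise it is labelled background.  Patches are cropped (white
    padding) and resized to the classifier input side.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1], got {iou_threshold}")
    examples: list[TrainingExample] = []
    for prop in proposals:
        label = BACKGROUND_LABEL
        best = 0.0
        for gt in gts:
            overlap = iou(prop.box, gt.box)
            if overlap > best:
                best = overlap
                if overlap >= iou_threshold:
                    label = gt.label
        if best < iou_threshold:
            label = BACKGROUND_LABEL
        patch = resize_patch(crop_with_padding(image, prop.box), patch_side)
        examples.append(TrainingExample(patch=patch, label=label))
    return examples


@dataclass(frozen=True)
class ColorRule:
    """Maps patches whose central mean colour is within ``max_distance``
    (Euclidean RGB) of ``color`` to ``label``."""

    label: str
    color: tuple[float, float, float]
    max_distance: float


class ColorRuleClassifier:
    """Deterministic classifier driven by mean colour of the central
    half of the patch.

    Intended as a test double and as an oracle for synthetic scenes:
    prediction is exact and confidence is always 1.0.  Patches matching
    no rule (e.g. straddling an insect edge) are background.  Rules
    whose colour balls overlap are rejected at construction.
    """

    def __init__(self, rules: Sequence[ColorRule], background_label: str = BACKGROUND_LABEL):
        for i, a in enumerate(rules):
            for b in rules[i + 1 :]:
                gap = float(np.linalg.norm(np.subtract(a.color, b.color)))
                if gap < a.max_distance + b.max_distance:
                    raise ValueError(f"overlapping colour rules: {a.label!r} and {b.label!r}")
        self.rules = list(rules)
        self.background_label = background_label
        self.classes = [r.label for r in rules] + [background_label]

    def predict_patch(self, patch: np.ndarray) -> tuple[str, float]:
        patch = np.asarray(patch, dtype=np.float64)
        h, w = patch.shape[:2]
        r0, r1 = h // 4, h - h // 4
        c0, c1 = w // 4, w - w // 4
        mean = patch[r0:max(r1, r0 + 1), c0:max(c1, c0 + 1)].reshape(-1, 3).mean(axis=0)
        for rule in self.rules:
            if np.linalg.norm(mean - np.asarray(rule.color)) <= rule.max_distance:
                return rule.label, 1.0
        return self.background_label, 1.0


def default_c1_oracle() -> ColorRuleClassifier:
    """Background–foreground oracle for the synthetic scene palette.

    A single broad rule: any crop whose central mean colour is dark
    (near the insect colours rather than the yellow card) is
    foreground.  The wide tolerance makes the gate robust to crops
    whose central window mixes insect and background.
    """
    return ColorRuleClassifier([ColorRule("foreground", (40.0, 35.0, 30.0), 90.0)])


def default_c2_oracle() -> ColorRuleClassifier:
    """Category oracle for the synthetic scene palette.

    Tight per-class tolerances: a view field only fires when its
    central window is essentially pure insect.  The tolerance (14) is
    below the closest approach of background-mixed colours of one
    class to the other class's colour, so partially-filled views
    cannot flip class.
    """
    return ColorRuleClassifier(
        [
            ColorRule("diamondback moth", (60.0, 50.0, 40.0), 14.0),
            ColorRule("others", (20.0, 20.0, 20.0), 14.0),
        ]
    )


class ConstantClassifier:
    """Always predicts one label; useful for open/closed-gate tests."""

    def __init__(self, label: str, confidence: float = 1.0):
        self.classes = [label]
        self._label = label
        self._confidence = confidence

    def predict_patch(self, patch: np.ndarray) -> tuple[str, float]:
        return self._label, self._confidence
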