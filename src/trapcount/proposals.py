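"""Region proposals from a thresholded saliency mask.

Pipeline: connected components of the binary mask become activation
regions; small regions are discarded (area filter ``beta``); each
surviving region is gated background/foreground — by overlap with the
annotations during training, or by a patch classifier at inference —
and every foreground region emits its own bounding box plus ``k``
preset-scale "tune-up" boxes centred on the region centroid, giving the
object classifier several view fields around one anchor.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import ndimage

from .geometry import Box, clip_box, iogt
from .structures import ActivationRegion, GroundTruthBox, RegionProposal

if TYPE_CHECKING:  # pragma: no cover
    from .classifiers import PatchClassifier
    from .config import PipelineConfig

# clipped tune-up boxes below this area are dropped rather than kept
MIN_CLIPPED_AREA = 4


def connected_components(mask: np.ndarray, connectivity: int = 8) -> list[ActivationRegion]:
    """Activation regions: maximal connected sets of 1-pixels.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    Regions are returned sorted by (xmin, ymin) of their bounding box;
    the centre is the pixel-count centroid, not the box centre.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(mask != 0, structure=structure)
    regions: list[ActivationRegion] = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        box = Box(int(cc.min()), int(rr.min()), int(cc.max()) + 1, int(rr.max()) + 1)
        regions.append(
            ActivationRegion(
                box=box,
                pixel_count=int(rr.size),
                center=(float(cc.mean()), float(rr.mean())),
            )
        )
    regions.sort(key=lambda r: (r.box.xmin, r.box.ymin))
    return regions


def area_filter(regions: Sequence[ActivationRegion], beta: float) -> list[ActivationRegion]:
    """Keep regions whose bounding-box area is >= beta (order preserved)."""
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    return [r for r in regions if r.box.area >= beta]


def label_region_fg_bg(
    region: ActivationRegion,
    gts: Sequence[GroundTruthBox],
    iogt_threshold: float = 0.5,
) -> str:
    """Training-mode gate: 'foreground' iff the region covers at least
    ``iogt_threshold`` of some ground-truth box, else 'background'."""
    if not 0.0 < iogt_threshold <= 1.0:
        raise ValueError(f"iogt_threshold must lie in (0, 1], got {iogt_threshold}")
    if any(iogt(region.box, gt.box) >= iogt_threshold for gt in gts):
        return "foreground"
    return "background"


def tuneup_boxes(
    center: tuple[float, float],
    scales: Sequence[tuple[int, int]],
    image_size: tuple[int, int],
) -> list[Box]:
    """One box per (width, height) scale, centred on the anchor and
    clipped to image bounds; clipped boxes smaller than 4 px^2 are dropped.
    """
    height, width = image_size
    xc, yc = center
    if not (0 <= xc < width and 0 <= yc < height):
        raise ValueError(f"center {center} outside image of size {image_size}")
    boxes: list[Box] = []
    for w, h in scales:
        if w < 2 or h < 2:
            raise ValueError(f"tune-up scale dimensions must be >= 2, got {(w, h)}")
        xmin = int(math.floor(xc - w / 2.0 + 0.5))
        ymin = int(math.floor(yc - h / 2.0 + 0.5))
        clipped = clip_box(Box(xmin, ymin, xmin + w, ymin + h), height, width)
        if clipped is not None and clipped.area >= MIN_CLIPPED_AREA:
            boxes.append(clipped)
    return boxes


def regions_from_image(image: np.ndarray, config: "PipelineConfig") -> list[ActivationRegion]:
    """Saliency -> normalise -> mask -> components -> area filter."""
    from .saliency import compute_saliency, normalize_saliency, threshold_mask

    saliency = normalize_saliency(compute_saliency(image, sigma=config.sigma))
    mask = threshold_mask(saliency, config.alpha)
    regions = connected_components(mask, connectivity=config.connectivity)
    return area_filter(regions, config.beta)


def generate_proposals(
    image: np.ndarray,
    config: "PipelineConfig",
    gts: Sequence[GroundTruthBox] | None = None,
    classifier: "PatchClassifier | None" = None,
) -> list[RegionProposal]:
    """End-to-end proposal generation.

    Exactly one of ``gts`` (training mode: gate regions by overlap with
    annotations) or ``classifier`` (inference mode: gate by the
    background–foreground classifier C1 on the region crop) must be
    given.  Each foreground region emits its own box (scale_index 0)
    plus the configured tune-up boxes (scale_index 1..k).
    """
    if (gts is None) == (classifier is None):
        raise ValueError("provide exactly one of gts (training) or classifier (inference)")
    image = np.asarray(image)
    h, w = image.shape[:2]
    proposals: list[RegionProposal] = []
    for region in regions_from_image(image, config):
        if gts is not None:
            is_foreground = label_region_fg_bg(region, gts, config.iogt_threshold) == "foreground"
        else:
            from .classifiers import crop_with_padding

            label, _ = classifier.predict_patch(crop_with_padding(image, region.box))
            is_foreground = label != config.background_label
        if not is_foreground:
            continue
        proposals.append(RegionProposal(box=region.box, anchor=region.center, scale_index=0))
        for i, box in enumerate(
            tuneup_boxes(region.center, config.tuneup_scales, (h, w)), start=1
        ):
            proposals.append(RegionProposal(box=box, anchor=region.center, scale_index=i))
    return proposals
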