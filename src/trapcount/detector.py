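"""End-to-end detector: saliency proposals -> patch classifier -> INMS.

:class:`SaliencyPestDetector` is a scikit-learn style estimator.  Fitting
trains the two patch classifiers — C1 (background/foreground gate, from
activation-region crops labelled by overlap with the annotations) and
C2 (insect class, from proposal crops labelled by the IoU rule) — unless
pre-built classifiers are supplied, in which case fit only validates and
installs them.  ``predict`` runs the full pipeline per image and returns
the suppressed detections; ``predict_counts`` returns per-image insect
counts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .classifiers import PatchClassifier, TrainingExample, crop_with_padding, make_c2_labels, resize_patch
from .cnn import CNNPatchClassifier
from .config import PipelineConfig
from .proposals import generate_proposals, label_region_fg_bg, regions_from_image
from .structures import Detection, GroundTruthBox
from .suppression import inms


class SaliencyPestDetector(BaseEstimator):
    """Insect pest detector and counter for sticky-trap images.

    Parameters
    ----------
    config : PipelineConfig, optional
        All pipeline tunables; defaults used when omitted.
    c1, c2 : PatchClassifier, optional
        Pre-built background–foreground and category classifiers
        (e.g. colour-rule oracles or loaded CNN checkpoints).  When
        omitted, ``fit`` trains lightweight CNNs.
    """

    def __init__(
        self,
        config: PipelineConfig | None = None,
        c1: PatchClassifier | None = None,
        c2: PatchClassifier | None = None,
    ):
        self.config = config
        self.c1 = c1
        self.c2 = c2

    def _config(self) -> PipelineConfig:
        return self.config if self.config is not None else PipelineConfig()

    def fit(
        self,
        X: Sequence[np.ndarray] | None = None,
        y: Sequence[Sequence[GroundTruthBox]] | None = None,
    ) -> "SaliencyPestDetector":
        cfg = self._config()
        if self.c1 is not None and self.c2 is not None:
            self.c1_, self.c2_ = self.c1, self.c2
            return self
        if X is None or y is None:
            raise ValueError("training images and annotations are required to fit the CNNs")
        c1_examples: list[TrainingExample] = []
        c2_examples: list[TrainingExample] = []
        for image, gts in zip(X, y):
            image = np.asarray(image)
            for region in regions_from_image(image, cfg):
                label = label_region_fg_bg(region, gts, cfg.iogt_threshold)
                patch = resize_patch(crop_with_padding(image, region.box), cfg.patch_side)
                c1_examples.append(TrainingExample(patch=patch, label=label))
            proposals = generate_proposals(image, cfg, gts=gts)
            c2_examples.extend(
                make_c2_labels(proposals, gts, image, cfg.iou_label_threshold, cfg.patch_side)
            )
        self.c1_ = self.c1 or self._train(c1_examples, cfg, seed_offset=0)
        self.c2_ = self.c2 or self._train(c2_examples, cfg, seed_offset=1)
        return self

    @staticmethod
    def _train(
        examples: list[TrainingExample], cfg: PipelineConfig, seed_offset: int
    ) -> CNNPatchClassifier:
        if not examples:
            raise ValueError("no training examples produced; check the data and thresholds")
        est = CNNPatchClassifier(
            patch_side=cfg.patch_side,
            n_steps=cfg.train_steps,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            init_std=cfg.init_std,
            random_state=cfg.seed + seed_offset,
        )
        patches = np.stack([e.patch for e in examples])
        labels = np.array([e.label for e in examples])
        return est.fit(patches, labels)

    def detect(self, image: np.ndarray) -> list[Detection]:
        """Full pipeline on one image: proposals, C2, INMS."""
        cfg = self._config()
        image = np.asarray(image)
        raw: list[Detection] = []
        for prop in generate_proposals(image, cfg, classifier=self.c1_):
            patch = crop_with_padding(image, prop.box)
            label, confidence = self.c2_.predict_patch(patch)
            if label != cfg.background_label:
                raw.append(Detection(box=prop.box, label=label, confidence=confidence))
        return inms(
            raw,
            merge_iou_threshold=cfg.merge_iou_threshold,
            nms_iou_threshold=cfg.nms_iou_threshold,
            gamma=cfg.gamma,
        )

    def predict(self, X: Sequence[np.ndarray]) -> list[list[Detection]]:
        return [self.detect(image) for image in X]

    def predict_counts(
        self, X: Sequence[np.ndarray], target_class: str | None = None
    ) -> list[int]:
        counts = []
        for dets in self.predict(X):
            if target_class is not None:
                dets = [d for d in dets if d.label == target_class]
            counts.append(len(dets))
        return counts
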