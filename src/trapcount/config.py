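"""Pipeline configuration: every tunable in one validated record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All pipeline tunables.

    Saliency/proposals: ``sigma`` (blur scale, px), ``alpha`` (mask
    threshold on the [0,1]-normalised saliency map), ``beta`` (minimum
    activation-region box area, px^2), ``connectivity`` (4 or 8),
    ``iogt_threshold`` (training-mode foreground gate),
    ``tuneup_scales`` (k preset (width, height) view fields).
    Classification: ``iou_label_threshold`` (proposal labelling),
    ``patch_side``, ``init_std`` and the optimisation settings.
    Suppression: ``merge_iou_threshold``, ``nms_iou_threshold``,
    ``gamma`` (minimum surviving confidence).  Fusion: ``union_mode``.

    The tune-up scales form a geometric ladder (area ratio ~0.69
    between neighbours) so that same-class detections of one insect at
    successive view fields always overlap above the merge threshold
    and collapse to a single box; the merge threshold of 0.35 keeps
    elongated region boxes mergeable with the square view fields.
    """

    sigma: float = 3.0
    alpha: float = 0.10
    beta: float = 30.0
    connectivity: int = 8
    iogt_threshold: float = 0.5
    tuneup_scales: list[tuple[int, int]] = field(
        default_factory=lambda: [(16, 16), (19, 19), (23, 23), (27, 27), (32, 32), (38, 38), (45, 45)]
    )
    iou_label_threshold: float = 0.5
    merge_iou_threshold: float = 0.35
    nms_iou_threshold: float = 0.5
    gamma: float = 0.5
    classes: list[str] = field(default_factory=lambda: ["diamondback moth", "others"])
    background_label: str = "background"
    union_mode: bool = False
    patch_side: int = 64
    init_std: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    train_steps: int = 300
    c1_path: str | None = None
    c2_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        for name in ("iogt_threshold", "iou_label_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("merge_iou_threshold", "nms_iou_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        self.tuneup_scales = [tuple(s) for s in self.tuneup_scales]
        if any(w < 2 or h < 2 for w, h in self.tuneup_scales):
            raise ValueError("tune-up scale dimensions must be >= 2")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        data = self.to_dict()
        data["tuneup_scales"] = [list(s) for s in data["tuneup_scales"]]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
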