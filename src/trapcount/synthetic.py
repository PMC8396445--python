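"""Seeded generator of synthetic sticky-trap scenes with annotations.

Real monitoring images are near-uniform yellow cards dotted with small
dark insects of a target class ("diamondback moth") and a catch-all
class ("others").  The generator emulates exactly those features —
noisy yellow background, filled rotated ellipses in two dark colours,
tight bounding-box annotations, and an optional fraction of insects
deliberately placed touching/near a neighbour to exercise the
fused-activation-region failure mode.  Colours and sizes are synthetic
stand-ins, not measurements of real specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .geometry import Box
from .structures import GroundTruthBox

MAX_PLACEMENT_RETRIES = 500


@dataclass(frozen=True)
class InsectClassSpec:
    """Appearance of one insect class: fill colour and side-length range."""

    color: tuple[int, int, int]
    side_range: tuple[int, int] = (12, 36)


def default_class_specs() -> dict[str, InsectClassSpec]:
    return {
        "diamondback moth": InsectClassSpec(color=(60, 50, 40)),
        "others": InsectClassSpec(color=(20, 20, 20)),
    }


@dataclass
class SceneParams:
    """Parameters of one synthetic trap scene.

    ``adjacency_fraction`` is the fraction of insects placed closer
    than ``min_spacing`` to an existing insect (touching or nearly so);
    the rest respect the pairwise spacing minimum.
    """

    height: int = 320
    width: int = 320
    background_color: tuple[int, int, int] = (230, 200, 40)
    noise_std: float = 5.0
    insect_count_range: tuple[int, int] = (3, 8)
    class_specs: dict[str, InsectClassSpec] = field(default_factory=default_class_specs)
    min_spacing: float = 60.0
    adjacency_fraction: float = 0.0
    color_jitter: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.insect_count_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid insect count range {self.insect_count_range}")
        if not 0.0 <= self.adjacency_fraction <= 1.0:
            raise ValueError("adjacency_fraction must lie in [0, 1]")
        for name, spec in self.class_specs.items():
            if spec.side_range[0] < 4:
                raise ValueError(f"insect sides must be >= 4 px ({name})")
            if not all(0 <= c <= 255 for c in spec.color):
                raise ValueError(f"colour out of range for class {name}")


def _radial_intercept(a: float, b: float, theta: float, phi: float) -> float:
    """Distance from an ellipse's centre to its boundary along direction
    ``phi`` (image frame); ``a``/``b`` are the row/column semi-axes and
    ``theta`` the rotation."""
    # the drawing routine rotates the long axis to angle -theta in the
    # (x=col, y=row) frame, hence phi + theta in the local frame
    psi = phi + theta
    return 1.0 / np.hypot(np.cos(psi) / b, np.sin(psi) / a)


def _place_insects(params: SceneParams, rng: np.random.Generator):
    """Choose class, semi-axes, rotation and centre for every insect."""
    labels = sorted(params.class_specs)
    lo, hi = params.insect_count_range
    n = int(rng.integers(lo, hi + 1))
    n_adjacent = int(round(params.adjacency_fraction * n))
    placements: list[dict] = []
    for idx in range(n):
        label = labels[int(rng.integers(len(labels)))]
        anchor: dict | None = None
        adjacent = idx >= n - n_adjacent and placements
        if adjacent:
            # clustered insects are conspecific: the documented miss
            # mode is two insects of the same class fusing into one
            # activation region
            anchor = placements[int(rng.integers(len(placements)))]
            label = anchor["label"]
        spec = params.class_specs[label]
        w = int(rng.integers(spec.side_range[0], spec.side_range[1] + 1))
        h = int(rng.integers(spec.side_range[0], spec.side_range[1] + 1))
        theta = float(rng.uniform(0, np.pi))
        radius = max(w, h) / 2.0
        margin = radius + 2
        for _ in range(MAX_PLACEMENT_RETRIES):
            if adjacent:
                # centre distance: 75% of the two radial supports along
                # the connecting direction, so the ellipses overlap into
                # one blob, as touching insects do on a real trap
                phi = rng.uniform(0, 2 * np.pi)
                d = 0.75 * (
                    _radial_intercept(anchor["a"], anchor["b"], anchor["theta"], phi)
                    + _radial_intercept(h / 2.0, w / 2.0, theta, phi + np.pi)
                )
                xc = anchor["xc"] + d * np.cos(phi)
                yc = anchor["yc"] + d * np.sin(phi)
                if not (margin <= xc < params.width - margin and margin <= yc < params.height - margin):
                    continue
                break
            xc = rng.uniform(margin, params.width - margin)
            yc = rng.uniform(margin, params.height - margin)
            if all(
                np.hypot(p["xc"] - xc, p["yc"] - yc) >= params.min_spacing
                for p in placements
            ):
                break
        else:
            raise RuntimeError(
                f"could not place insect {idx} after {MAX_PLACEMENT_RETRIES} retries; "
                "reduce counts, sizes or min_spacing"
            )
        color = np.clip(
            np.asarray(spec.color, dtype=float) + rng.normal(0, params.color_jitter, 3),
            0,
            255,
        )
        placements.append(
            dict(label=label, xc=xc, yc=yc, a=h / 2.0, b=w / 2.0, theta=theta,
                 radius=radius, color=color)
        )
    return placements


def generate_scene(params: SceneParams) -> tuple[np.ndarray, list[GroundTruthBox]]:
    """Render one scene; deterministic for a given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    placements = _place_insects(params, rng)
    image = np.clip(
        np.asarray(params.background_color, dtype=float)[None, None, :]
        + rng.normal(0, params.noise_std, (params.height, params.width, 3)),
        0,
        255,
    )
    gts: list[GroundTruthBox] = []
    for p in placements:
        rr, cc = ellipse(
            p["yc"], p["xc"], p["a"], p["b"], rotation=p["theta"],
            shape=(params.height, params.width),
        )
        image[rr, cc] = p["color"]
        box = Box(int(cc.min()), int(rr.min()), int(cc.max()) + 1, int(rr.max()) + 1)
        gts.append(GroundTruthBox(box=box, label=p["label"]))
    return image.astype(np.uint8), gts


def generate_dataset(
    n_images: int, params: SceneParams, out_dir: str | Path
) -> pd.DataFrame:
    """Write ``n_images`` scenes as PNG + PASCAL VOC XML + manifest CSV.

    Per-image seeds are derived deterministically from ``params.seed``,
    so regeneration with the same master seed is byte-identical.
    """
    from dataclasses import replace

    from .io import write_voc

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        child_seed = (params.seed * 100_003 + i) % (2**31)
        scene_params = replace(params, seed=child_seed)
        image, gts = generate_scene(scene_params)
        stem = f"scene_{i:04d}"
        image_path = out_dir / f"{stem}.png"
        xml_path = out_dir / f"{stem}.xml"
        iio.imwrite(image_path, image)
        write_voc(xml_path, f"{stem}.png", image.shape[:2], gts)
        rows.append(
            {"image": image_path.name, "annotation": xml_path.name,
             "n_insects": len(gts), "seed": child_seed}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
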