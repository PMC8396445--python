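"""Readers/writers for the formats the pipeline exchanges.

PASCAL VOC XML (LabelImg dialect) stores 1-based inclusive pixel
coordinates; internally boxes are 0-based half-open, so reading maps
``(xmin, ymin, xmax, ymax) -> (xmin-1, ymin-1, xmax, ymax)`` and
writing inverts that.  Detections travel as CSV or JSON with columns
``image, xmin, ymin, xmax, ymax, label, confidence``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from lxml import etree

from .geometry import Box
from .structures import Detection, GroundTruthBox

DETECTION_COLUMNS = ["image", "xmin", "ymin", "xmax", "ymax", "label", "confidence"]


def read_image(path: str | Path) -> np.ndarray:
    """Load a JPEG/PNG as an H x W x 3 uint8 RGB array."""
    image = iio.imread(path)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    return np.ascontiguousarray(image[:, :, :3])


def read_voc(path: str | Path) -> tuple[str, list[GroundTruthBox]]:
    """Parse one VOC XML file: (image filename, annotations)."""
    path = Path(path)
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML in {path}: {exc}") from exc
    filename = root.findtext("filename") or path.stem
    gts: list[GroundTruthBox] = []
    for obj in root.iterfind("object"):
        name = obj.findtext("name")
        bndbox = obj.find("bndbox")
        if name is None or bndbox is None:
            raise ValueError(f"object without name/bndbox in {path}")
        try:
            xmin, ymin, xmax, ymax = (
                int(round(float(bndbox.findtext(tag))))
                for tag in ("xmin", "ymin", "xmax", "ymax")
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"incomplete bndbox in {path}") from exc
        box = Box(xmin - 1, ymin - 1, xmax, ymax).validate()
        gts.append(GroundTruthBox(box=box, label=name))
    return filename, gts


def write_voc(
    path: str | Path,
    image_filename: str,
    image_size: tuple[int, int],
    gts: Sequence[GroundTruthBox],
) -> None:
    """Write annotations in the LabelImg VOC dialect (deterministic)."""
    height, width = image_size
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = image_filename
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(width)
    etree.SubElement(size, "height").text = str(height)
    etree.SubElement(size, "depth").text = "3"
    etree.SubElement(root, "segmented").text = "0"
    for gt in gts:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = gt.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bndbox = etree.SubElement(obj, "bndbox")
        etree.SubElement(bndbox, "xmin").text = str(gt.box.xmin + 1)
        etree.SubElement(bndbox, "ymin").text = str(gt.box.ymin + 1)
        etree.SubElement(bndbox, "xmax").text = str(gt.box.xmax)
        etree.SubElement(bndbox, "ymax").text = str(gt.box.ymax)
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def read_voc_dir(directory: str | Path) -> dict[str, list[GroundTruthBox]]:
    """All VOC files of a directory, keyed by image filename."""
    out: dict[str, list[GroundTruthBox]] = {}
    for xml_path in sorted(Path(directory).glob("*.xml")):
        filename, gts = read_voc(xml_path)
        out[filename] = gts
    return out


def _detections_frame(dets_by_image: Mapping[str, Sequence[Detection]]) -> pd.DataFrame:
    rows = [
        {
            "image": image,
            "xmin": d.box.xmin,
            "ymin": d.box.ymin,
            "xmax": d.box.xmax,
            "ymax": d.box.ymax,
            "label": d.label,
            "confidence": d.confidence,
        }
        for image, dets in dets_by_image.items()
        for d in dets
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_detections_csv(
    dets_by_image: Mapping[str, Sequence[Detection]], path: str | Path
) -> None:
    _detections_frame(dets_by_image).to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> dict[str, list[Detection]]:
    frame = pd.read_csv(path, dtype={"label": str})
    out: dict[str, list[Detection]] = {}
    for row in frame.itertuples(index=False):
        box = Box(int(row.xmin), int(row.ymin), int(row.xmax), int(row.ymax)).validate()
        out.setdefault(str(row.image), []).append(
            Detection(box=box, label=str(row.label), confidence=float(row.confidence))
        )
    return out


def write_detections_json(
    dets_by_image: Mapping[str, Sequence[Detection]], path: str | Path
) -> None:
    payload = {
        image: [
            {
                "xmin": d.box.xmin,
                "ymin": d.box.ymin,
                "xmax": d.box.xmax,
                "ymax": d.box.ymax,
                "label": d.label,
                "confidence": d.confidence,
            }
            for d in dets
        ]
        for image, dets in dets_by_image.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_detections_json(path: str | Path) -> dict[str, list[Detection]]:
    payload = json.loads(Path(path).read_text())
    return {
        image: [
            Detection(
                box=Box(d["xmin"], d["ymin"], d["xmax"], d["ymax"]).validate(),
                label=d["label"],
                confidence=d["confidence"],
            )
            for d in dets
        ]
        for image, dets in payload.items()
    }


def read_detections(path: str | Path) -> dict[str, list[Detection]]:
    """Dispatch on extension: .json or .csv."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_detections_json(path)
    return read_detections_csv(path)


def write_proposals_csv(proposals, path: str | Path) -> None:
    """Region proposals as CSV: box, anchor and scale index per row."""
    rows = [
        {
            "xmin": p.box.xmin,
            "ymin": p.box.ymin,
            "xmax": p.box.xmax,
            "ymax": p.box.ymax,
            "anchor_x": p.anchor[0],
            "anchor_y": p.anchor[1],
            "scale_index": p.scale_index,
        }
        for p in proposals
    ]
    columns = ["xmin", "ymin", "xmax", "ymax", "anchor_x", "anchor_y", "scale_index"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def save_saliency(saliency: np.ndarray, path: str | Path) -> None:
    """Export a saliency map for inspection.

    ``.png`` writes a 16-bit greyscale image scaled to the full range;
    any other extension writes the raw values as flat CSV.
    """
    path = Path(path)
    saliency = np.asarray(saliency, dtype=np.float64)
    if path.suffix.lower() == ".png":
        peak = saliency.max(initial=0.0)
        scaled = saliency / peak if peak > 0 else saliency
        iio.imwrite(path, np.round(scaled * 65535).astype(np.uint16))
    else:
        pd.DataFrame(saliency).to_csv(path, index=False, header=False)
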