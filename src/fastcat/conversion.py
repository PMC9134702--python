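"""Annotation interchange: DSV (configurable flat files), YOLO, VOC, COCO.

Different training pipelines want different formats, so the box subset of an
annotation set converts to a delimiter-separated-values file whose
delimiter, column order and coordinate style are driven by a small JSON
config, and back.  Class ranges and freeze frames are not representable in
a flat box table; they survive only through the native JSON schema.

Coordinate styles:

* ``xywh_abs``  top-left x, y, width, height in pixels (native);
* ``xyxy_abs``  corner pair x0, y0, x1, y1 in pixels;
* ``yolo_norm`` class cx cy w h with center and extent normalized to [0, 1]
  by the frame dimensions (requires frame size; round-trips within 1 px of
  quantization).

VOC-XML and COCO-JSON exporters are included as export-only extensions.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from .annotation_model import AnnotationSet, BoxAnnotation

__all__ = ["DSVConfig", "to_dsv", "from_dsv", "to_yolo", "to_voc_xml", "to_coco"]

CoordStyle = Literal["xywh_abs", "xyxy_abs", "yolo_norm"]

_GEOM_COLS = {
    "xywh_abs": ["x", "y", "w", "h"],
    "xyxy_abs": ["x0", "y0", "x1", "y1"],
    "yolo_norm": ["cx", "cy", "wn", "hn"],
}


@dataclass
class DSVConfig:
    """Shape of the flat export; loadable from a JSON config file."""

    delimiter: str = ","
    coordinate_style: CoordStyle = "xywh_abs"
    columns: list[str] = field(default_factory=list)  # empty -> defaults
    header: bool = True

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")
        if self.coordinate_style not in _GEOM_COLS:
            raise ValueError(f"unknown coordinate_style {self.coordinate_style!r}")
        if not self.columns:
            self.columns = ["frame", "label", *_GEOM_COLS[self.coordinate_style],
                            "provenance", "score"]
        missing = [c for c in _GEOM_COLS[self.coordinate_style] if c not in self.columns]
        if missing:
            raise ValueError(
                f"columns must include the {self.coordinate_style} geometry "
                f"columns; missing {missing}"
            )

    @classmethod
    def from_file(cls, path: "str | Path") -> "DSVConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**raw)


def _geom_fields(box: BoxAnnotation, style: CoordStyle, frame_size) -> dict:
    if style == "xywh_abs":
        return {"x": box.x, "y": box.y, "w": box.w, "h": box.h}
    if style == "xyxy_abs":
        x0, y0, x1, y1 = box.xyxy
        return {"x0": x0, "y0": y0, "x1": x1, "y1": y1}
    W, H = frame_size
    return {
        "cx": f"{(box.x + box.w / 2) / W:.6f}",
        "cy": f"{(box.y + box.h / 2) / H:.6f}",
        "wn": f"{box.w / W:.6f}",
        "hn": f"{box.h / H:.6f}",
    }


def _box_from_row(row: dict, style: CoordStyle, frame_size) -> BoxAnnotation:
    if style == "xywh_abs":
        x, y, w, h = (int(row[c]) for c in ("x", "y", "w", "h"))
    elif style == "xyxy_abs":
        x0, y0, x1, y1 = (int(row[c]) for c in ("x0", "y0", "x1", "y1"))
        x, y, w, h = x0, y0, x1 - x0, y1 - y0
    else:
        W, H = frame_size
        cx, cy, wn, hn = (float(row[c]) for c in ("cx", "cy", "wn", "hn"))
        w = max(1, round(wn * W))
        h = max(1, round(hn * H))
        x = round(cx * W - w / 2)
        y = round(cy * H - h / 2)
    score = row.get("score") or None
    return BoxAnnotation(
        frame=int(row["frame"]), x=x, y=y, w=w, h=h,
        label=row.get("label", "polyp"),
        provenance=row.get("provenance", "non_expert"),
        score=float(score) if score is not None else None,
        note=row.get("note") or None,
    )


def _frame_size(aset: AnnotationSet, config: DSVConfig):
    if config.coordinate_style != "yolo_norm":
        return None
    if aset.video is None:
        raise ValueError(
            "yolo_norm coordinates need frame dimensions: AnnotationSet.video is unset"
        )
    return aset.video.width, aset.video.height


def to_dsv(aset: AnnotationSet, path: "str | Path", config: DSVConfig | None = None) -> None:
    """Write one DSV row per box, shaped by ``config``."""
    config = config or DSVConfig()
    size = _frame_size(aset, config)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=config.delimiter)
        if config.header:
            writer.writerow(config.columns)
        for box in aset.boxes:
            fields = {
                "frame": box.frame, "label": box.label,
                "provenance": box.provenance,
                "score": "" if box.score is None else box.score,
                "note": box.note or "",
                **_geom_fields(box, config.coordinate_style, size),
            }
            writer.writerow([fields.get(c, "") for c in config.columns])


def from_dsv(
    path: "str | Path",
    config: DSVConfig | None = None,
    video=None,
) -> AnnotationSet:
    """Read a DSV file back into an AnnotationSet (box subset only).

    ``video`` (a VideoMeta) is required for ``yolo_norm`` coordinates and is
    attached to the result when given.  Malformed rows raise ``ValueError``
    naming the 1-based row number.
    """
    config = config or DSVConfig()
    if config.coordinate_style == "yolo_norm" and video is None:
        raise ValueError("yolo_norm coordinates need frame dimensions: pass video=")
    size = (video.width, video.height) if video is not None else None

    boxes: list[BoxAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=config.delimiter)
        rows = list(reader)
    start = 1 if config.header else 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(config.columns):
            raise ValueError(
                f"{path}: row {lineno}: expected {len(config.columns)} columns, "
                f"got {len(row)}"
            )
        mapped = dict(zip(config.columns, row))
        try:
            boxes.append(_box_from_row(mapped, config.coordinate_style, size))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    return AnnotationSet(stage="final", video=video, boxes=boxes)


def to_yolo(aset: AnnotationSet, out_dir: "str | Path",
            class_map: dict[str, int] | None = None) -> dict[str, int]:
    """Write the YOLO txt-per-frame dialect: ``<class> cx cy w h`` normalized.

    One ``<frame index>.txt`` per annotated frame.  Returns the label ->
    class-id map used (alphabetical when not supplied); it is also written
    to ``classes.txt`` one label per line in id order.
    """
    if aset.video is None:
        raise ValueError("YOLO export needs frame dimensions: AnnotationSet.video is unset")
    W, H = aset.video.width, aset.video.height
    if class_map is None:
        class_map = {lbl: i for i, lbl in enumerate(sorted({b.label for b in aset.boxes}))}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_frame: dict[int, list[str]] = {}
    for b in aset.boxes:
        line = (
            f"{class_map[b.label]} {(b.x + b.w / 2) / W:.6f} {(b.y + b.h / 2) / H:.6f} "
            f"{b.w / W:.6f} {b.h / H:.6f}"
        )
        per_frame.setdefault(b.frame, []).append(line)
    for frame, lines in per_frame.items():
        (out_dir / f"{frame:06d}.txt").write_text("\n".join(lines) + "\n")
    (out_dir / "classes.txt").write_text(
        "\n".join(lbl for lbl, _ in sorted(class_map.items(), key=lambda kv: kv[1])) + "\n"
    )
    return class_map


def to_voc_xml(aset: AnnotationSet, out_dir: "str | Path") -> None:
    """Export one Pascal-VOC XML file per annotated frame (export only)."""
    if aset.video is None:
        raise ValueError("VOC export needs frame dimensions: AnnotationSet.video is unset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames: dict[int, list[BoxAnnotation]] = {}
    for b in aset.boxes:
        frames.setdefault(b.frame, []).append(b)
    for frame, boxes in frames.items():
        root = ET.Element("annotation")
        ET.SubElement(root, "filename").text = f"{frame:06d}.png"
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(aset.video.width)
        ET.SubElement(size, "height").text = str(aset.video.height)
        ET.SubElement(size, "depth").text = "3"
        for b in boxes:
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = b.label
            ET.SubElement(obj, "provenance").text = b.provenance
            bb = ET.SubElement(obj, "bndbox")
            x0, y0, x1, y1 = b.xyxy
            ET.SubElement(bb, "xmin").text = str(x0)
            ET.SubElement(bb, "ymin").text = str(y0)
            ET.SubElement(bb, "xmax").text = str(x1)
            ET.SubElement(bb, "ymax").text = str(y1)
        ET.ElementTree(root).write(out_dir / f"{frame:06d}.xml")


def to_coco(aset: AnnotationSet, path: "str | Path") -> None:
    """Export COCO detection JSON (export only)."""
    if aset.video is None:
        raise ValueError("COCO export needs frame dimensions: AnnotationSet.video is unset")
    labels = sorted({b.label for b in aset.boxes})
    cat_ids = {lbl: i + 1 for i, lbl in enumerate(labels)}
    frames = aset.annotated_frames()
    img_ids = {f: i + 1 for i, f in enumerate(frames)}
    doc = {
        "images": [
            {
                "id": img_ids[f],
                "file_name": f"{f:06d}.png",
                "width": aset.video.width,
                "height": aset.video.height,
            }
            for f in frames
        ],
        "categories": [{"id": cid, "name": lbl} for lbl, cid in cat_ids.items()],
        "annotations": [
            {
                "id": i + 1,
                "image_id": img_ids[b.frame],
                "category_id": cat_ids[b.label],
                "bbox": [b.x, b.y, b.w, b.h],
                "area": b.w * b.h,
                "iscrowd": 0,
                "attributes": {"provenance": b.provenance},
            }
            for i, b in enumerate(aset.boxes)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
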