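"""Two-tier annotation data model with JSON serialization.

The annotation workflow has two stages.  An expert produces the
*intermediate* output: detected freeze frames, class ranges (frame intervals
carrying a frame-level class such as polyp presence or a Paris type, each
parented to a freeze frame) and a few exemplary bounding boxes.  A
non-expert, assisted by AI prelabeling and tracking, completes the boxes on
every in-between frame and produces the *final* output.

Every box carries a provenance tag so automatically created annotations stay
distinguishable from manual ones end to end.

JSON schema (version 1), all frame indices 0-based, boxes as top-left
x, y, w, h in integer pixels with the half-open pixel interval [x, x+w):

    {
      "schema_version": 1,
      "stage": "expert_intermediate" | "final",
      "video": {path, fps, frame_count, width, height, frames_dir} | null,
      "freeze_frames": [int, ...],
      "class_ranges": [{class_label, start_frame, end_frame, parent_freeze}, ...],
      "boxes": [{frame, x, y, w, h, label, provenance, score?, note?}, ...],
      "frame_notes": {"<frame>": "text", ...}
    }
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Literal, Optional

from pydantic import BaseModel, Field, ValidationError, model_validator

from .video_io import VideoMeta

__all__ = [
    "Provenance",
    "BoxAnnotation",
    "ClassRange",
    "AnnotationSet",
    "AnnotationSchemaError",
    "assign_class_range",
    "frames_with_class",
    "read_annotations",
    "write_annotations",
]

SCHEMA_VERSION = 1

Provenance = Literal["expert", "non_expert", "ai", "tracker", "duplicated"]


class AnnotationSchemaError(ValueError):
    """Raised when an annotation file violates the JSON schema."""


class BoxAnnotation(BaseModel):
    """One bounding box on one frame, with label and provenance."""

    frame: int = Field(ge=0)
    x: int
    y: int
    w: int = Field(gt=0)
    h: int = Field(gt=0)
    label: str
    provenance: Provenance
    score: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    note: Optional[str] = None

    def clamped(self, width: int, height: int) -> "BoxAnnotation":
        """Clamp the box to frame bounds, preserving at least 1 px extent."""
        x0 = min(max(self.x, 0), width - 1)
        y0 = min(max(self.y, 0), height - 1)
        x1 = min(max(self.x + self.w, x0 + 1), width)
        y1 = min(max(self.y + self.h, y0 + 1), height)
        return self.model_copy(update={"x": x0, "y": y0, "w": x1 - x0, "h": y1 - y0})

    @property
    def xyxy(self) -> tuple[int, int, int, int]:
        return self.x, self.y, self.x + self.w, self.y + self.h


class ClassRange(BaseModel):
    """An inclusive frame interval carrying one frame-level class.

    Every range is parented to a freeze frame: class assignment in the
    expert view happens in the context of a selected freeze frame, and the
    parent link preserves that hierarchy.  A single-frame class (the
    key-hold entry style) is a range with start == end.
    """

    class_label: str
    start_frame: int = Field(ge=0)
    end_frame: int = Field(ge=0)
    parent_freeze: int = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "ClassRange":
        if self.start_frame > self.end_frame:
            raise ValueError(
                f"start_frame {self.start_frame} > end_frame {self.end_frame}"
            )
        return self

    def frames(self) -> range:
        return range(self.start_frame, self.end_frame + 1)


class AnnotationSet(BaseModel):
    """Per-video container for freeze frames, class ranges and boxes."""

    schema_version: int = SCHEMA_VERSION
    stage: Literal["expert_intermediate", "final"] = "expert_intermediate"
    video: Optional[VideoMeta] = None
    freeze_frames: List[int] = Field(default_factory=list)
    class_ranges: List[ClassRange] = Field(default_factory=list)
    boxes: List[BoxAnnotation] = Field(default_factory=list)
    frame_notes: Dict[int, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _referential_integrity(self) -> "AnnotationSet":
        known = set(self.freeze_frames)
        for r in self.class_ranges:
            if r.parent_freeze not in known:
                raise ValueError(
                    f"class range {r.class_label}[{r.start_frame},{r.end_frame}] "
                    f"references unknown freeze frame {r.parent_freeze}"
                )
        return self

    def boxes_on(self, frame: int, label: str | None = None) -> list[BoxAnnotation]:
        return [
            b for b in self.boxes
            if b.frame == frame and (label is None or b.label == label)
        ]

    def annotated_frames(self) -> list[int]:
        """Frames with at least one box — the final-output frame list."""
        return sorted({b.frame for b in self.boxes})


def assign_class_range(
    aset: AnnotationSet,
    class_label: str,
    start_frame: int,
    end_frame: int,
    parent_freeze: int,
) -> AnnotationSet:
    """Assign a class to every frame in [start_frame, end_frame].

    This is the expert's start/end entry style: mark the first and last
    frame of a pathology and all frames in between inherit the class.
    Returns a new set; the input is not mutated.
    """
    if start_frame > end_frame:
        raise ValueError(f"start_frame {start_frame} > end_frame {end_frame}")
    if parent_freeze not in aset.freeze_frames:
        raise KeyError(
            f"parent_freeze {parent_freeze} is not a known freeze frame"
        )
    rng = ClassRange(
        class_label=class_label,
        start_frame=start_frame,
        end_frame=end_frame,
        parent_freeze=parent_freeze,
    )
    return aset.model_copy(update={"class_ranges": [*aset.class_ranges, rng]})


def frames_with_class(aset: AnnotationSet, class_label: str) -> list[int]:
    """Sorted deduplicated frame indices covered by ranges of this class."""
    out: set[int] = set()
    for r in aset.class_ranges:
        if r.class_label == class_label:
            out.update(r.frames())
    return sorted(out)


def write_annotations(aset: AnnotationSet, path: "str | Path") -> None:
    """Serialize an AnnotationSet to the versioned JSON schema."""
    Path(path).write_text(
        json.dumps(aset.model_dump(mode="json"), indent=2) + "\n", encoding="utf-8"
    )


def read_annotations(path: "str | Path") -> AnnotationSet:
    """Load and validate an annotation JSON file.

    Raises :class:`AnnotationSchemaError` naming the offending field on any
    schema violation (missing provenance, unknown provenance value,
    non-positive box extent, dangling parent_freeze, ...).
    """
    try:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise AnnotationSchemaError(f"{path}: not valid JSON: {exc}") from exc
    try:
        return AnnotationSet.model_validate(raw)
    except ValidationError as exc:
        raise AnnotationSchemaError(f"{path}: {exc}") from exc
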