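"""Bounding-box propagation across frames.

Two assistance modes speed up the non-expert's frame-by-frame work:

* duplication — copy the previous frame's boxes forward and nudge them,
  cheaper than redrawing when the scene barely moves;
* object tracking — follow the lesion automatically through consecutive
  frames, with the user correcting misaligned boxes as they go.

The reference tracker is normalized cross-correlation (NCC) template
matching at fixed box size: deterministic, dependency-light, and enough to
exercise the reinitialization policies.  Trackers in general drift or lose
lesions under endoscopy conditions (unsteady camera, polyps colored like
the surrounding mucosa), so two reinitialization policies keep the template
fresh from the user's corrections:

* ``reinit_every_frame`` — rebuild the template from every frame's
  (possibly corrected) box, so the tracker always holds the latest visual
  appearance of the lesion;
* ``reinit_on_resize`` — rebuild only when a user correction changed the
  box width or height (pure translation does not retrigger).

Any third-party tracker can be plugged in through the same
``init(frame, box) / update(frame)`` contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Protocol, Sequence, Tuple

import numpy as np
from skimage.feature import match_template

from .annotation_model import AnnotationSet, BoxAnnotation
from .video_io import Frame

__all__ = [
    "TrackerPolicy",
    "NCCTracker",
    "duplicate_box",
    "track",
    "reference_tracker",
    "fill_gaps_with_tracker",
]

DEFAULT_SEARCH_RADIUS = 32
DEFAULT_LOST_SCORE_FLOOR = 0.3

PolicyMode = Literal["none", "reinit_every_frame", "reinit_on_resize"]


@dataclass(frozen=True)
class TrackerPolicy:
    mode: PolicyMode = "none"

    def __post_init__(self) -> None:
        if self.mode not in ("none", "reinit_every_frame", "reinit_on_resize"):
            raise ValueError(f"unknown tracker policy mode: {self.mode}")


class Tracker(Protocol):
    """Contract third-party trackers plug into."""

    def init(self, frame: "Frame | np.ndarray", box: Tuple[int, int, int, int]) -> None: ...

    def update(self, frame: "Frame | np.ndarray") -> Tuple[Tuple[int, int, int, int], float]: ...


def _pixels(frame: "Frame | np.ndarray") -> np.ndarray:
    return frame.pixels if isinstance(frame, Frame) else np.asarray(frame)


def _gray(img: np.ndarray) -> np.ndarray:
    return img.astype(np.float64).mean(axis=2) if img.ndim == 3 else img.astype(np.float64)


def reference_tracker(
    template: np.ndarray,
    frame: "Frame | np.ndarray",
    prev_box: Tuple[int, int, int, int],
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> Tuple[Tuple[int, int, int, int], float]:
    """Locate ``template`` in ``frame`` near ``prev_box`` by NCC.

    The search window is the previous box dilated by ``search_radius`` px,
    clamped to the frame.  Returns the best-match box (same w, h as the
    template) and the correlation peak in [-1, 1].
    """
    img = _gray(_pixels(frame))
    tmpl = _gray(template)
    th, tw = tmpl.shape
    H, W = img.shape
    if th > H or tw > W:
        raise ValueError("template larger than frame")

    x, y, w, h = prev_box
    x0 = max(0, x - search_radius)
    y0 = max(0, y - search_radius)
    x1 = min(W, x + w + search_radius)
    y1 = min(H, y + h + search_radius)
    # window must fit the template
    if x1 - x0 < tw:
        x0, x1 = max(0, min(x0, W - tw)), min(W, max(x1, tw))
    if y1 - y0 < th:
        y0, y1 = max(0, min(y0, H - th)), min(H, max(y1, th))
    window = img[y0:y1, x0:x1]

    corr = match_template(window, tmpl)
    if np.isnan(corr).all():
        return (x, y, tw, th), 0.0
    peak = np.unravel_index(np.nanargmax(corr), corr.shape)
    score = float(corr[peak])
    best = (x0 + int(peak[1]), y0 + int(peak[0]), tw, th)
    return best, score


class NCCTracker:
    """Reference tracker satisfying the pluggable contract."""

    def __init__(
        self,
        search_radius: int = DEFAULT_SEARCH_RADIUS,
        lost_score_floor: float = DEFAULT_LOST_SCORE_FLOOR,
    ) -> None:
        self.search_radius = search_radius
        self.lost_score_floor = lost_score_floor
        self._template: np.ndarray | None = None
        self._box: Tuple[int, int, int, int] | None = None
        self.init_count = 0  # reinitialization events are auditable

    def init(self, frame: "Frame | np.ndarray", box: Tuple[int, int, int, int]) -> None:
        self.init_count += 1
        img = _pixels(frame)
        x, y, w, h = (int(v) for v in box)
        H, W = img.shape[:2]
        x = max(0, min(x, W - 1))
        y = max(0, min(y, H - 1))
        w = max(1, min(w, W - x))
        h = max(1, min(h, H - y))
        self._template = img[y : y + h, x : x + w].copy()
        self._box = (x, y, w, h)

    def update(self, frame: "Frame | np.ndarray") -> Tuple[Tuple[int, int, int, int], float]:
        if self._template is None or self._box is None:
            raise RuntimeError("tracker not initialized")
        box, score = reference_tracker(
            self._template, frame, self._box, self.search_radius
        )
        if score >= self.lost_score_floor:
            self._box = box  # keep searching from the last confident hit
        return box, score


def duplicate_box(
    aset: AnnotationSet, from_frame: int, to_frame: int
) -> AnnotationSet:
    """Copy every box on ``from_frame`` to ``to_frame`` as duplicates.

    Copies keep geometry and label but carry provenance ``duplicated``;
    boxes already on the target frame are left in place.  With no source
    boxes this is a warning no-op.
    """
    source = aset.boxes_on(from_frame)
    if not source:
        import warnings

        warnings.warn(
            f"frame {from_frame} has no boxes to duplicate", stacklevel=2
        )
        return aset
    copies = [
        b.model_copy(update={"frame": to_frame, "provenance": "duplicated", "score": None})
        for b in source
    ]
    return aset.model_copy(update={"boxes": [*aset.boxes, *copies]})


def track(
    frames: Sequence["Frame | np.ndarray"],
    init_box: BoxAnnotation,
    policy: TrackerPolicy = TrackerPolicy("none"),
    corrections: Mapping[int, BoxAnnotation] | None = None,
    tracker: Tracker | None = None,
    lost_score_floor: float = DEFAULT_LOST_SCORE_FLOOR,
) -> list[BoxAnnotation]:
    """Track one object through ``frames``, returning one box per frame.

    ``init_box`` sits on ``frames[0]`` (its ``frame`` field names the video
    frame index of ``frames[0]``; output indices run consecutively from it).
    ``corrections`` maps video frame index -> user-corrected box; a
    correction replaces the tracker's output on its frame (emitted with the
    corrector's provenance) and feeds reinitialization per ``policy``.
    Frames where the match score drops below ``lost_score_floor`` are
    flagged ``lost`` in the note field and tracking continues from the last
    confident box.
    """
    if not frames:
        return []
    corrections = dict(corrections or {})
    trk = tracker or NCCTracker(lost_score_floor=lost_score_floor)
    base = init_box.frame

    current = corrections.get(base, init_box)
    trk.init(frames[0], (current.x, current.y, current.w, current.h))
    out = [
        current.model_copy(
            update={"provenance": current.provenance if base in corrections else "tracker"}
        )
    ]

    for offset in range(1, len(frames)):
        fidx = base + offset
        (bx, by, bw, bh), score = trk.update(frames[offset])
        lost = score < lost_score_floor

        if fidx in corrections:
            corr = corrections[fidx]
            resized = corr.w != out[-1].w or corr.h != out[-1].h
            out.append(corr.model_copy(update={"frame": fidx}))
            if policy.mode == "reinit_every_frame" or (
                policy.mode == "reinit_on_resize" and resized
            ):
                trk.init(frames[offset], (corr.x, corr.y, corr.w, corr.h))
            continue

        out.append(
            BoxAnnotation(
                frame=fidx, x=bx, y=by, w=bw, h=bh,
                label=init_box.label, provenance="tracker",
                note="lost" if lost else None,
            )
        )
        if policy.mode == "reinit_every_frame" and not lost:
            trk.init(frames[offset], (bx, by, bw, bh))

    return out


def fill_gaps_with_tracker(
    aset: AnnotationSet,
    frames: Sequence["Frame | np.ndarray"],
    label: str,
    start: int,
    end: int,
    policy: TrackerPolicy = TrackerPolicy("reinit_every_frame"),
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    lost_score_floor: float = DEFAULT_LOST_SCORE_FLOOR,
) -> AnnotationSet:
    """Fill unannotated frames in [start, end] by tracking between anchors.

    Frames that already carry a ``label`` box (expert, non-expert or ai)
    act as anchors: the earliest anchor initializes the tracker and every
    later anchor feeds it as a correction under ``policy``.  Only frames
    without any ``label`` box gain a box, with provenance ``tracker``.
    ``frames[i]`` must be video frame ``start + i``.

    With no anchor in range this is a warning no-op.
    """
    anchors: dict[int, BoxAnnotation] = {}
    for f in range(start, end + 1):
        existing = aset.boxes_on(f, label)
        if existing:
            anchors[f] = existing[0]
    if not anchors:
        import warnings

        warnings.warn(
            f"no {label!r} box in frames [{start}, {end}]; nothing to track",
            stacklevel=2,
        )
        return aset

    first = min(anchors)
    init = anchors[first]
    tracked = track(
        frames[first - start : end - start + 1],
        init_box=init.model_copy(update={"frame": first}),
        policy=policy,
        corrections=anchors,
        tracker=NCCTracker(search_radius=search_radius, lost_score_floor=lost_score_floor),
        lost_score_floor=lost_score_floor,
    )
    new = [b for b in tracked if b.frame not in anchors]
    return aset.model_copy(update={"boxes": [*aset.boxes, *new]})
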