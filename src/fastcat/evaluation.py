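"""Annotation-quality and speed metrics.

Quality is measured against reference boxes with the detection-literature
protocol: per-frame one-to-one matching of predicted to ground-truth boxes,
a true positive requiring an overlap of at least 70% (IoU by default), and
precision / recall / F1 over the resulting TP/FP/FN counts.  Annotation
speed is seconds per frame (SPF): active annotation time, with pauses
excluded, divided by the number of annotated frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence, Tuple

from .annotation_model import BoxAnnotation
from .freeze_detection import FreezeSegment

__all__ = [
    "MatchResult",
    "box_overlap",
    "match_annotations",
    "f1",
    "annotation_speed",
    "evaluate_freeze_detection",
]

DEFAULT_OVERLAP_THRESHOLD = 0.7

BoxLike = "BoxAnnotation | tuple[float, float, float, float]"
OverlapMode = Literal["iou", "coverage"]


def _xyxy(box) -> Tuple[float, float, float, float]:
    if isinstance(box, BoxAnnotation):
        return box.xyxy
    x, y, w, h = box
    return x, y, x + w, y + h


def box_overlap(a, b, mode: OverlapMode = "iou") -> float:
    """Overlap of two boxes (top-left x, y, w, h or BoxAnnotation).

    ``iou``       intersection over union, the standard measure;
    ``coverage``  intersection over the area of ``b`` (how much of the
                  ground-truth box the prediction covers) — provided because
                  a bare "70% overlap" criterion admits either reading.
    """
    ax0, ay0, ax1, ay1 = _xyxy(a)
    bx0, by0, bx1, by1 = _xyxy(b)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if mode == "coverage":
        return inter / area_b
    return inter / (area_a + area_b - inter)


@dataclass
class MatchResult:
    """TP/FP/FN counts plus the matched (prediction, ground-truth) pairs."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    pairs: list = field(default_factory=list)  # (pred, gt, overlap)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn,
            self.pairs + other.pairs,
        )


def _match_one_frame(
    pred: Sequence, gt: Sequence, threshold: float, mode: OverlapMode
) -> MatchResult:
    # greedy one-to-one by descending overlap, the usual detection protocol
    cands = []
    for i, p in enumerate(pred):
        for j, g in enumerate(gt):
            ov = box_overlap(p, g, mode=mode)
            if ov >= threshold:
                cands.append((ov, i, j))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for ov, i, j in cands:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        pairs.append((pred[i], gt[j], ov))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(pred) - tp, fn=len(gt) - tp, pairs=pairs)


def match_annotations(
    pred: Mapping[int, Sequence],
    gt: Mapping[int, Sequence],
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    mode: OverlapMode = "iou",
) -> MatchResult:
    """Match predicted to ground-truth boxes frame by frame.

    ``pred`` and ``gt`` map frame index -> boxes.  Within each frame,
    matching is greedy one-to-one by descending overlap; a pair counts as a
    true positive when its overlap is at least ``threshold`` (>= 0.7 by
    default).  Unmatched predictions are false positives, unmatched
    ground-truth boxes false negatives.
    """
    result = MatchResult()
    for frame in sorted(set(pred) | set(gt)):
        result = result + _match_one_frame(
            pred.get(frame, ()), gt.get(frame, ()), threshold, mode
        )
    return result


def f1(match: MatchResult) -> Tuple[float, float, float]:
    """Precision, recall and F1 from match counts.

    F1 is the harmonic mean of precision and recall, equivalently
    2*TP / (2*TP + FP + FN).
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp + fp + fn == 0:
        raise ValueError("F1 undefined: no predictions and no ground truth")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    score = 2.0 * tp / (2.0 * tp + fp + fn)
    return precision, recall, score


def annotation_speed(
    events: Sequence[Tuple[int, float]],
    pauses: Iterable[Tuple[float, float]] = (),
) -> float:
    """Seconds-per-frame annotation speed.

    ``events`` lists (frame index, wall-clock seconds spent); ``pauses``
    lists [start, end) wall-clock intervals during which the annotator hit
    the pause button — their total length is subtracted from the active
    time.  Speed = active seconds / number of distinct annotated frames.
    """
    if not events:
        raise ValueError("no annotation events: speed undefined")
    if any(d < 0 for _, d in events):
        raise ValueError("event durations must be >= 0")
    total = sum(d for _, d in events)
    paused = sum(e - s for s, e in pauses)
    if paused < 0 or paused > total:
        raise ValueError("pause time must lie within total time")
    n_frames = len({f for f, _ in events})
    return (total - paused) / n_frames


def evaluate_freeze_detection(
    pred: Sequence[FreezeSegment],
    gt: Sequence[FreezeSegment],
    boundary_tol: int = 10,
) -> Tuple[float, float]:
    """Segment-level precision and recall of freeze detection.

    A predicted segment is a true positive when it overlaps a ground-truth
    segment and both boundaries agree within ``boundary_tol`` frames;
    matching is greedy one-to-one by descending frame overlap.  Empty
    prediction or ground truth yields the conventional 1.0 for the
    undefended side (nothing to get wrong).
    """
    cands = []
    for i, p in enumerate(pred):
        for j, g in enumerate(gt):
            ov = (
                min(p.end_frame, g.end_frame) - max(p.start_frame, g.start_frame) + 1
            )
            if (
                ov > 0
                and abs(p.start_frame - g.start_frame) <= boundary_tol
                and abs(p.end_frame - g.end_frame) <= boundary_tol
            ):
                cands.append((ov, i, j))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    tp = 0
    for _, i, j in cands:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        tp += 1
    precision = tp / len(pred) if pred else 1.0
    recall = tp / len(gt) if gt else 1.0
    return precision, recall
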