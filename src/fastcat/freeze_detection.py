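"""Freeze-frame detection.

During colonoscopy the endoscopist freezes the live feed to capture a still
photo of suspicious tissue; the recorded video then repeats (nearly)
identical frames for a short run.  Those runs mark the clinically relevant
moments, so detecting them lets an expert jump straight to them instead of
reviewing the whole video.

Detection works on consecutive-frame differences: the absolute RGB
difference image of each frame and its successor is converted to HSV and the
mean Euclidean norm of the saturation and value channels is taken (hue of a
near-black difference image is numerically meaningless noise, so it is
excluded).  A trailing moving average over a batch of comparisons smooths
single-frame flukes; hysteresis thresholds (a low start threshold, a higher
end threshold) keep segment boundaries from flickering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .video_io import Frame

__all__ = [
    "FreezeSegment",
    "FreezeConfig",
    "frame_difference_norm",
    "detect_freezes",
    "freeze_frames_to_relevant",
]


@dataclass(frozen=True, order=True)
class FreezeSegment:
    """A detected [start_frame, end_frame] (inclusive) frozen interval."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError(
                f"start_frame {self.start_frame} > end_frame {self.end_frame}"
            )

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame + 1

    def overlaps(self, other: "FreezeSegment") -> bool:
        return self.start_frame <= other.end_frame and other.start_frame <= self.end_frame


@dataclass
class FreezeConfig:
    """Tuning knobs for freeze detection.

    window        trailing moving-average batch size (comparisons)
    start_threshold   average norm below this starts a freeze (0-255 scale)
    end_threshold     average norm above this ends it; >= start_threshold
                      so boundaries do not flicker (hysteresis)
    min_length    segments shorter than this many frames are dropped
    """

    window: int = 10
    start_threshold: float = 3.0
    end_threshold: float = 6.0
    min_length: int = 5

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.start_threshold <= 0:
            raise ValueError("start_threshold must be > 0")
        if self.end_threshold < self.start_threshold:
            raise ValueError("end_threshold must be >= start_threshold")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def _pixels(frame: "Frame | np.ndarray") -> np.ndarray:
    return frame.pixels if isinstance(frame, Frame) else np.asarray(frame)


def frame_difference_norm(a: "Frame | np.ndarray", b: "Frame | np.ndarray") -> float:
    """Mean S/V norm of the HSV-converted absolute RGB difference of two frames.

    The per-pixel absolute RGB difference image is converted to HSV; the
    Euclidean norm of the (saturation, value) pair, both on the 0-255 scale,
    is averaged over all pixels.  Identical frames give exactly 0; the
    measure is symmetric in its arguments.
    """
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"frame shape mismatch: {pa.shape} vs {pb.shape}")
    diff = np.abs(pa.astype(np.int16) - pb.astype(np.int16))
    # S and V of the HSV conversion, computed directly (hue is not used):
    # V = max(R,G,B), S = (max-min)/max, both scaled to 0-255
    v = np.maximum.reduce(diff, axis=2).astype(np.float64)
    mn = np.minimum.reduce(diff, axis=2).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(v > 0, (v - mn) / v, 0.0) * 255.0
    return float(np.mean(np.hypot(s, v)))


def detect_freezes(
    frames: Sequence["Frame | np.ndarray"],
    config: FreezeConfig | None = None,
) -> list[FreezeSegment]:
    """Detect frozen intervals in a frame sequence.

    Each frame is compared with its successor via
    :func:`frame_difference_norm`; a trailing mean over the last
    ``config.window`` comparisons is tracked.  Once a full window is
    available, a freeze starts at the current frame when the mean falls below
    ``start_threshold`` and ends when it exceeds ``end_threshold``.  Segments
    shorter than ``min_length`` frames are discarded.

    Returns sorted, non-overlapping segments.
    """
    config = config or FreezeConfig()
    n = len(frames)
    if n < config.window + 1:
        raise ValueError(
            f"need at least window+1 = {config.window + 1} frames, got {n}"
        )

    diffs = np.empty(n - 1)
    for i in range(n - 1):
        diffs[i] = frame_difference_norm(frames[i], frames[i + 1])
    return detect_freezes_from_diffs(diffs, config)


def detect_freezes_from_diffs(
    diffs: "Sequence[float] | np.ndarray", config: FreezeConfig | None = None
) -> list[FreezeSegment]:
    """Run the hysteresis state machine on precomputed consecutive-frame norms.

    ``diffs[i]`` is the difference norm between frames i and i+1.  Split out
    so the norms (the expensive part) can be computed once and the thresholds
    explored cheaply.
    """
    config = config or FreezeConfig()
    diffs = np.asarray(diffs, dtype=float)
    w = config.window

    segments: list[FreezeSegment] = []
    in_freeze = False
    start = 0
    for i in range(w - 1, len(diffs)):
        m = diffs[i - w + 1 : i + 1].mean()
        if not in_freeze and m < config.start_threshold:
            in_freeze = True
            start = i
        elif in_freeze and m > config.end_threshold:
            segments.append(FreezeSegment(start, i))
            in_freeze = False
    if in_freeze:
        segments.append(FreezeSegment(start, len(diffs)))  # runs to last frame

    return [s for s in segments if s.length >= config.min_length]


def freeze_frames_to_relevant(
    segments: Iterable[FreezeSegment],
    manual: Iterable[int] = (),
) -> list[int]:
    """Collapse freeze segments to one representative frame index each.

    The representative is the segment's first frame.  Manually entered
    relevant frame indices (typed in as frame numbers or timestamps) are
    merged in; the result is sorted and deduplicated, ready for the expert
    view's jump list.
    """
    indices = {s.start_frame for s in segments}
    indices.update(int(m) for m in manual)
    return sorted(indices)
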