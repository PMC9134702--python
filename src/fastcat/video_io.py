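"""Video and frame I/O: extraction, caching, timestamp math, preload scheduling.

Frames are cached on disk as losslessly-compressed PNG files named by
zero-padded 0-based index (``000000.png`` ...).  Lossless caching matters:
freeze detection relies on consecutive cached frames of a frozen feed being
bit-identical, which a lossy cache would destroy.

All in-memory frames are H x W x 3 uint8 arrays in RGB channel order.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import imageio.v3 as iio
import numpy as np
from pydantic import BaseModel, Field

__all__ = [
    "VideoMeta",
    "Frame",
    "extract_frames",
    "load_frame",
    "iter_frames",
    "timestamp_to_frame",
    "frame_to_timestamp",
    "preload_pause_ms",
]

FRAME_NAME_FMT = "{:06d}.png"
_FRAME_NAME_RE = re.compile(r"^\d{6}\.png$")

# Guard against double-precision dust when t was itself derived from a frame
# index at fractional fps (29.97 and friends): t*fps/1000 can land a hair
# below the integer it mathematically equals.
_FLOOR_EPS = 1e-6


class VideoMeta(BaseModel):
    """Per-video metadata and provenance of the on-disk frame cache."""

    path: str
    fps: float = Field(gt=0)
    frame_count: int = Field(ge=0)
    width: int = Field(gt=0)
    height: int = Field(gt=0)
    frames_dir: Optional[str] = None


@dataclass
class Frame:
    """One decoded video frame: 0-based index plus RGB uint8 pixels."""

    index: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"frame index must be >= 0, got {self.index}")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")


def _as_rgb_u8(img: np.ndarray) -> np.ndarray:
    """Normalize a decoded image to H x W x 3 uint8 RGB."""
    arr = np.asarray(img)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def _cached_frame_files(frames_dir: Path) -> list[Path]:
    return sorted(p for p in frames_dir.iterdir() if _FRAME_NAME_RE.match(p.name))


def extract_frames(video: "VideoMeta | str | Path", out_dir: "str | Path",
                   fps: float = 30.0) -> VideoMeta:
    """Extract every frame of a video into ``out_dir`` as PNG files.

    Accepts either a :class:`VideoMeta` or a bare path (then ``fps`` supplies
    the nominal frame rate, since still-image containers carry none).
    Idempotent: when ``out_dir`` already holds the expected number of cached
    frames they are reused; a partial cache (count mismatch) is discarded and
    re-extracted.

    Returns a :class:`VideoMeta` with ``frames_dir`` set.
    """
    if isinstance(video, VideoMeta):
        path = Path(video.path)
        fps = video.fps
    else:
        path = Path(video)
    if not path.exists():
        raise IOError(f"video file not readable: {path}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    expected = video.frame_count if isinstance(video, VideoMeta) else None
    cached = _cached_frame_files(out_dir)
    if cached and (expected is None or len(cached) == expected):
        first = _as_rgb_u8(iio.imread(cached[0]))
        return VideoMeta(
            path=str(path), fps=fps, frame_count=len(cached),
            width=first.shape[1], height=first.shape[0], frames_dir=str(out_dir),
        )
    if cached and expected is not None and len(cached) != expected:
        import warnings

        warnings.warn(
            f"partial frame cache in {out_dir} ({len(cached)} files, "
            f"expected {expected}); re-extracting", stacklevel=2,
        )
        for p in cached:
            p.unlink()

    def _iter_decoded():
        # some plugins (tifffile) yield a whole stack as one 4-D array;
        # flatten such stacks into individual frames
        for img in iio.imiter(path):
            arr = np.asarray(img)
            if arr.ndim == 4:
                yield from arr
            else:
                yield arr

    try:
        count = 0
        width = height = None
        for i, img in enumerate(_iter_decoded()):
            arr = _as_rgb_u8(img)
            if width is None:
                height, width = arr.shape[:2]
            iio.imwrite(out_dir / FRAME_NAME_FMT.format(i), arr)
            count = i + 1
    except Exception as exc:  # decoder errors vary by backend
        raise IOError(f"cannot decode video container {path}: {exc}") from exc

    if count == 0:
        # degenerate 0-frame video: empty cache, nominal 1x1 geometry
        width = width or 1
        height = height or 1
    return VideoMeta(
        path=str(path), fps=fps, frame_count=count,
        width=width, height=height, frames_dir=str(out_dir),
    )


def load_frame(meta: VideoMeta, index: int) -> Frame:
    """Load one cached frame by index."""
    if meta.frames_dir is None:
        raise ValueError("VideoMeta has no frames_dir; run extract_frames first")
    if not 0 <= index < meta.frame_count:
        raise ValueError(f"frame index {index} outside [0, {meta.frame_count})")
    arr = _as_rgb_u8(iio.imread(Path(meta.frames_dir) / FRAME_NAME_FMT.format(index)))
    return Frame(index=index, pixels=arr)


def iter_frames(meta: VideoMeta) -> Iterator[Frame]:
    """Iterate all cached frames in index order."""
    for i in range(meta.frame_count):
        yield load_frame(meta, i)


def timestamp_to_frame(t_ms: float, fps: float) -> int:
    """Map a timestamp in milliseconds to the frame displayed at that time.

    Implements f = t[ms] * FPS / 1000, floored to the frame currently on
    screen.
    """
    if t_ms < 0:
        raise ValueError(f"timestamp must be >= 0 ms, got {t_ms}")
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    return int(math.floor(t_ms * fps / 1000.0 + _FLOOR_EPS))


def frame_to_timestamp(f: int, fps: float) -> float:
    """Inverse of :func:`timestamp_to_frame`: start time of frame ``f`` in ms."""
    if f < 0:
        raise ValueError(f"frame index must be >= 0, got {f}")
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    return f * 1000.0 / fps


def preload_pause_ms(capacity: float) -> float:
    """Pause between frame loads as a function of preload-queue capacity.

    The frame viewer keeps upcoming frames in a RAM queue; to stop the queue
    from draining faster than the disk refills it, playback waits

        ms = 50 * (1 - capacity) ** 2.75

    between frames, where ``capacity`` is the filled fraction of the queue.
    A full queue (1.0) waits 0 ms; an empty queue (0.0) waits 50 ms.
    """
    if not 0.0 <= capacity <= 1.0:
        raise ValueError(f"capacity must lie in [0, 1], got {capacity}")
    return 50.0 * (1.0 - capacity) ** 2.75
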