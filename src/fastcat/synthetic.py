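"""Deterministic endoscopy-like video fixtures with known ground truth.

Real colonoscopy footage cannot ship with a test suite, so this module
renders the features the rest of the toolkit exercises:

* a smooth reddish mucosa-like texture that drifts a few pixels per frame
  (unsteady camera) with per-pixel Gaussian sensor noise;
* elliptical "polyp" blobs of controlled contrast moving at a constant
  velocity, with the exact bounding box of every blob on every frame;
* freeze segments — runs of frames that exactly repeat the segment's first
  frame, emulating the mechanically stabilized feed while the examiner
  captures a still (`freeze_noise_sigma` can add sub-threshold noise to
  stress the hysteresis thresholds).

Everything is a pure function of the spec (including its seed), so two runs
produce byte-identical frames.

What it does not emulate: specular highlights, peristalsis deformation,
illumination changes, interlacing, compression artifacts.  Results on these
fixtures bound the geometry/bookkeeping of the pipeline, not detector or
tracker performance on clinical footage.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence, Tuple

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .annotation_model import AnnotationSet, BoxAnnotation, ClassRange
from .freeze_detection import FreezeSegment
from .video_io import FRAME_NAME_FMT, VideoMeta

__all__ = [
    "BlobSpec",
    "FixtureSpec",
    "generate_fixture",
    "write_fixture",
    "sample_freeze_spec",
]


@dataclass
class BlobSpec:
    """One moving elliptical lesion and its ground-truth trajectory."""

    start_frame: int
    end_frame: int
    initial_box: Tuple[int, int, int, int]  # x, y, w, h
    velocity: Tuple[float, float] = (0.0, 0.0)  # px/frame (vx, vy)
    contrast: float = 60.0  # brightness of the lesion tone over the mucosa base
    label: str = "polyp"


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic video."""

    n_frames: int = 300
    width: int = 384
    height: int = 288
    seed: int = 42
    freeze_segments: list[Tuple[int, int]] = dc_field(default_factory=list)
    blobs: list[BlobSpec] = dc_field(default_factory=list)
    noise_sigma: float = 2.0
    motion_amplitude: float = 3.0  # background drift in px/frame
    freeze_noise_sigma: float = 0.0  # 0 -> frozen frames are exact repeats
    fps: float = 30.0

    def __post_init__(self) -> None:
        for s, e in self.freeze_segments:
            if not 0 <= s <= e < self.n_frames:
                raise ValueError(f"freeze segment ({s},{e}) outside [0,{self.n_frames})")


def _background_texture(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Smooth mucosa-like RGB texture, double-sized for drift cropping."""
    base = np.array([150.0, 85.0, 75.0])  # reddish tissue tone
    field_ = gaussian_filter(rng.normal(0.0, 1.0, (2 * h, 2 * w)), sigma=8.0)
    field_ *= 50.0 / max(field_.std(), 1e-9)
    tex = base[None, None, :] + field_[:, :, None] * np.array([1.0, 0.8, 0.7])
    return tex


def _blob_box_at(blob: BlobSpec, t: int, w: int, h: int) -> Tuple[int, int, int, int]:
    x0, y0, bw, bh = blob.initial_box
    dt = t - blob.start_frame
    x = x0 + round(blob.velocity[0] * dt)
    y = y0 + round(blob.velocity[1] * dt)
    # clamp trajectory at the frame border, ground truth follows the clamp
    x = max(0, min(x, w - bw))
    y = max(0, min(y, h - bh))
    return int(x), int(y), int(bw), int(bh)


def _render_blob(img: np.ndarray, box: Tuple[int, int, int, int], contrast: float) -> None:
    x, y, w, h = box
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    # ellipse inscribed in the box: opaque core, soft rim over the outer 20%
    r2 = ((xx - cx) / (w / 2.0)) ** 2 + ((yy - cy) / (h / 2.0)) ** 2
    mask = np.clip((1.0 - r2) / 0.2, 0.0, 1.0)
    # surface texture in blob-local coordinates: polyps carry their own
    # vascular pattern, which is what makes them trackable against a
    # drifting background
    speckle = 0.25 * np.sin(2 * np.pi * xx / 7.3) * np.sin(2 * np.pi * yy / 5.1)
    tint = np.array([1.0, 0.75, 0.7])
    base = np.array([150.0, 85.0, 75.0])
    color = (base + contrast * tint)[None, None, :] * (1.0 + speckle)[:, :, None]
    patch = img[y : y + h, x : x + w, :]
    # the lesion occludes the mucosa behind it (opaque, soft-edged)
    patch[:] = patch * (1.0 - mask[:, :, None]) + color * mask[:, :, None]


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[list[np.ndarray], AnnotationSet, list[FreezeSegment]]:
    """Render a fixture video.

    Returns (frames, ground_truth, freeze_segments): uint8 RGB frames, the
    ground-truth annotation set (one expert box per blob per visible frame,
    plus freeze frames and one class range per blob), and the inserted
    freeze segments.  Frames inside a freeze repeat the segment's first
    frame exactly (plus ``freeze_noise_sigma`` noise if configured), and the
    ground-truth trajectory holds still with them; when the feed resumes the
    live trajectory has moved on.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    texture = _background_texture(rng, h, w)

    freeze_of: dict[int, int] = {}  # frame -> freeze start
    for s, e in spec.freeze_segments:
        for t in range(s, e + 1):
            freeze_of[t] = s

    # pre-draw drift offsets and per-frame noise so frozen frames do not
    # consume randomness (keeps streams aligned across freeze configurations)
    steps = rng.integers(-1, 2, size=(spec.n_frames, 2)).astype(float)
    offsets = np.cumsum(steps * spec.motion_amplitude, axis=0).round().astype(int)
    # center the drift walk in the double-sized texture and clip, so the
    # visible crop slides continuously instead of wrapping around an edge
    offsets[:, 0] = np.clip(offsets[:, 0] + h // 2, 0, h)
    offsets[:, 1] = np.clip(offsets[:, 1] + w // 2, 0, w)

    frames: list[np.ndarray] = []
    boxes: list[BoxAnnotation] = []
    rendered: dict[int, np.ndarray] = {}

    def render_live(t: int) -> tuple[np.ndarray, list[tuple[BlobSpec, tuple]]]:
        dy, dx = offsets[t, 0], offsets[t, 1]
        img = texture[dy : dy + h, dx : dx + w, :].copy()
        placed = []
        for blob in spec.blobs:
            if blob.start_frame <= t <= blob.end_frame:
                box = _blob_box_at(blob, t, w, h)
                _render_blob(img, box, blob.contrast)
                placed.append((blob, box))
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma, img.shape)
        return img, placed

    for t in range(spec.n_frames):
        src = freeze_of.get(t, t)
        if src == t:
            img, placed = render_live(t)
            img = np.clip(img, 0, 255).astype(np.uint8)
            rendered[t] = img
            for blob, box in placed:
                boxes.append(
                    BoxAnnotation(
                        frame=t, x=box[0], y=box[1], w=box[2], h=box[3],
                        label=blob.label, provenance="expert",
                    )
                )
            frames.append(img)
        else:
            img = rendered[src].astype(np.float64)
            if spec.freeze_noise_sigma > 0:
                img += rng.normal(0.0, spec.freeze_noise_sigma, img.shape)
            img = np.clip(img, 0, 255).astype(np.uint8)
            frames.append(img)
            for b in [b for b in boxes if b.frame == src]:
                boxes.append(b.model_copy(update={"frame": t}))

    freeze_frames = [s for s, _ in spec.freeze_segments]
    class_ranges = []
    if freeze_frames:
        for blob in spec.blobs:
            parent = min(freeze_frames, key=lambda f: abs(f - blob.start_frame))
            class_ranges.append(
                ClassRange(
                    class_label=blob.label,
                    start_frame=blob.start_frame,
                    end_frame=min(blob.end_frame, spec.n_frames - 1),
                    parent_freeze=parent,
                )
            )

    gt = AnnotationSet(
        stage="final",
        video=VideoMeta(
            path="<synthetic>", fps=spec.fps, frame_count=spec.n_frames,
            width=w, height=h,
        ),
        freeze_frames=freeze_frames,
        class_ranges=class_ranges,
        boxes=boxes,
    )
    segments = [FreezeSegment(s, e) for s, e in sorted(spec.freeze_segments)]
    return frames, gt, segments


def write_fixture(
    spec: FixtureSpec, out_dir: "str | Path"
) -> tuple[VideoMeta, AnnotationSet, list[FreezeSegment]]:
    """Render a fixture and write frames + ground truth to ``out_dir``.

    Produces ``frames/<index>.png``, ``ground_truth.json`` and
    ``freezes.json``; returns the frame-cache VideoMeta alongside the ground
    truth.
    """
    from .annotation_model import write_annotations

    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    frames, gt, segments = generate_fixture(spec)
    for i, img in enumerate(frames):
        iio.imwrite(frames_dir / FRAME_NAME_FMT.format(i), img)
    meta = (
        gt.video.model_copy(update={"frames_dir": str(frames_dir)})
        if gt.video
        else None
    )
    gt = gt.model_copy(update={"video": meta})
    write_annotations(gt, out_dir / "ground_truth.json")
    (out_dir / "freezes.json").write_text(
        __import__("json").dumps(
            [{"start_frame": s.start_frame, "end_frame": s.end_frame} for s in segments],
            indent=2,
        )
        + "\n"
    )
    return meta, gt, segments


def sample_freeze_spec(
    seed: int,
    n_frames: int = 300,
    width: int = 384,
    height: int = 288,
) -> FixtureSpec:
    """Draw a fixture spec with 1-3 randomly placed exact-repeat freezes.

    Freeze lengths span 15-40 frames with at least 40 motion frames between
    segments, mimicking the cadence of photo captures during withdrawal.
    Deterministic in ``seed``.
    """
    rng = np.random.default_rng([seed, 1905])
    n_freezes = int(rng.integers(1, 4))
    segments: list[Tuple[int, int]] = []
    cursor = int(rng.integers(20, 60))
    for _ in range(n_freezes):
        length = int(rng.integers(15, 41))
        if cursor + length >= n_frames - 20:
            break
        segments.append((cursor, cursor + length - 1))
        cursor += length + int(rng.integers(40, 80))
    return FixtureSpec(
        n_frames=n_frames, width=width, height=height, seed=seed,
        freeze_segments=segments,
    )
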