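"""Detector contract for semi-automated prelabeling.

A detector is anything that maps a frame index to scored bounding boxes.
Three implementations of the contract live here:

* :class:`HTTPDetector` — client for the online mode, where a detection
  model runs behind a web server (typically inside a container) and is
  queried over HTTP, so the model stays loaded between predictions;
* offline batch files — a JSON list of per-frame predictions produced by an
  external machine and merged in later;
* :class:`MockDetector` — a fixture-backed stand-in for tests, answering
  with ground truth degraded by configurable miss rate, localization jitter
  and false positives, deterministic under a seed.

Merging predictions never touches manual annotations: only boxes with
provenance ``ai`` are ever added, and re-merging the same source is
idempotent (duplicates are detected by frame, label and near-exact overlap).

Wire protocol (clean-room, any model container can implement it):

    POST /predict           body {"frame": <int>}
    GET  /predict?frame=<int>
    response 200            {"frame": <int>, "boxes": [{x, y, w, h, score, label}, ...]}
"""

from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import List, Protocol, Sequence
from urllib.parse import parse_qs, urlparse
from urllib.request import Request, urlopen

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from .annotation_model import AnnotationSet, AnnotationSchemaError, BoxAnnotation
from .evaluation import box_overlap

__all__ = [
    "PredBox",
    "DetectorPrediction",
    "Detector",
    "MockDetector",
    "HTTPDetector",
    "DetectorServiceError",
    "predict_frames",
    "import_offline_predictions",
    "write_offline_predictions",
    "serve_mock_detector",
]

DEFAULT_SCORE_THRESHOLD = 0.5
# ai boxes this close to an already-merged ai box are duplicates, not news
DEDUP_IOU = 0.95


class DetectorServiceError(RuntimeError):
    """Detector endpoint unreachable or returned a malformed response."""


class PredBox(BaseModel):
    x: int
    y: int
    w: int = Field(gt=0)
    h: int = Field(gt=0)
    score: float = Field(ge=0.0, le=1.0)
    label: str = "polyp"


class DetectorPrediction(BaseModel):
    """All predicted boxes for one frame."""

    frame: int = Field(ge=0)
    boxes: List[PredBox] = Field(default_factory=list)


class Detector(Protocol):
    def predict(self, frame: int) -> DetectorPrediction: ...


class MockDetector:
    """Ground-truth-backed detector with controllable degradation.

    Answers from a fixture's ground-truth boxes, dropping each with
    probability ``miss_rate``, perturbing corners by uniform integer jitter
    in [-jitter_px, jitter_px], and adding a false positive per frame with
    probability ``fp_rate``.  Per-frame randomness is derived from
    (seed, frame), so responses are deterministic and independent of query
    order.
    """

    def __init__(
        self,
        ground_truth: AnnotationSet,
        miss_rate: float = 0.0,
        jitter_px: int = 0,
        fp_rate: float = 0.0,
        seed: int = 0,
        score: float = 0.9,
    ) -> None:
        if not 0.0 <= miss_rate <= 1.0 or not 0.0 <= fp_rate <= 1.0:
            raise ValueError("miss_rate and fp_rate must lie in [0, 1]")
        self._by_frame: dict[int, list[BoxAnnotation]] = {}
        for b in ground_truth.boxes:
            self._by_frame.setdefault(b.frame, []).append(b)
        self.frame_size = (
            (ground_truth.video.width, ground_truth.video.height)
            if ground_truth.video else (384, 288)
        )
        self.miss_rate = miss_rate
        self.jitter_px = jitter_px
        self.fp_rate = fp_rate
        self.seed = seed
        self.score = score

    def predict(self, frame: int) -> DetectorPrediction:
        rng = np.random.default_rng([self.seed, frame])
        boxes: list[PredBox] = []
        for gt in self._by_frame.get(frame, []):
            if rng.random() < self.miss_rate:
                continue
            j = self.jitter_px
            dx, dy, dw, dh = (
                rng.integers(-j, j + 1, size=4) if j > 0 else (0, 0, 0, 0)
            )
            boxes.append(
                PredBox(
                    x=gt.x + int(dx), y=gt.y + int(dy),
                    w=max(1, gt.w + int(dw)), h=max(1, gt.h + int(dh)),
                    score=self.score, label=gt.label,
                )
            )
        if rng.random() < self.fp_rate:
            W, H = self.frame_size
            w = int(rng.integers(10, max(11, W // 4)))
            h = int(rng.integers(10, max(11, H // 4)))
            boxes.append(
                PredBox(
                    x=int(rng.integers(0, max(1, W - w))),
                    y=int(rng.integers(0, max(1, H - h))),
                    w=w, h=h, score=self.score, label="polyp",
                )
            )
        return DetectorPrediction(frame=frame, boxes=boxes)


class HTTPDetector:
    """Client for a detector served over HTTP at ``base_url``."""

    def __init__(self, base_url: str, timeout: float = 10.0) -> None:
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout

    def predict(self, frame: int) -> DetectorPrediction:
        req = Request(
            f"{self.base_url}/predict",
            data=json.dumps({"frame": frame}).encode(),
            headers={"Content-Type": "application/json"},
            method="POST",
        )
        try:
            with urlopen(req, timeout=self.timeout) as resp:
                payload = resp.read()
        except OSError as exc:
            raise DetectorServiceError(
                f"detector at {self.base_url} unreachable: {exc}"
            ) from exc
        try:
            return DetectorPrediction.model_validate_json(payload)
        except ValidationError as exc:
            raise DetectorServiceError(
                f"malformed detector response: {exc}"
            ) from exc


class _MockHandler(BaseHTTPRequestHandler):
    detector: MockDetector  # set on the subclass by serve_mock_detector

    def _respond(self, frame: int | None) -> None:
        if frame is None or frame < 0 or frame not in self.detector._by_frame:
            if frame is None or frame < 0:
                self.send_response(400)
                self.end_headers()
                self.wfile.write(b'{"error": "missing or invalid frame"}')
                return
            # unknown frame: empty prediction plus a warning header
            body = DetectorPrediction(frame=frame).model_dump_json().encode()
            self.send_response(200)
            self.send_header("Warning", "199 - unknown frame, no ground truth")
            self.send_header("Content-Type", "application/json")
            self.end_headers()
            self.wfile.write(body)
            return
        body = self.detector.predict(frame).model_dump_json().encode()
        self.send_response(200)
        self.send_header("Content-Type", "application/json")
        self.end_headers()
        self.wfile.write(body)

    def do_POST(self) -> None:  # noqa: N802 (http.server API)
        if urlparse(self.path).path != "/predict":
            self.send_response(404)
            self.end_headers()
            return
        length = int(self.headers.get("Content-Length", 0))
        try:
            payload = json.loads(self.rfile.read(length) or b"{}")
            frame = payload.get("frame")
            frame = int(frame) if frame is not None else None
        except (json.JSONDecodeError, TypeError, ValueError):
            frame = None
        self._respond(frame)

    def do_GET(self) -> None:  # noqa: N802
        parsed = urlparse(self.path)
        if parsed.path != "/predict":
            self.send_response(404)
            self.end_headers()
            return
        qs = parse_qs(parsed.query)
        try:
            frame = int(qs["frame"][0])
        except (KeyError, ValueError):
            frame = None
        self._respond(frame)

    def log_message(self, *args) -> None:  # silence request logging
        pass


class MockDetectorServer:
    """A running HTTP endpoint wrapping a :class:`MockDetector`."""

    def __init__(self, detector: MockDetector, host: str = "127.0.0.1", port: int = 0):
        handler = type("BoundMockHandler", (_MockHandler,), {"detector": detector})
        self._server = ThreadingHTTPServer((host, port), handler)
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()
        self.url = f"http://{host}:{self._server.server_address[1]}"

    def close(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        self._thread.join(timeout=5)

    def __enter__(self) -> "MockDetectorServer":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def serve_mock_detector(
    ground_truth: AnnotationSet,
    miss_rate: float = 0.0,
    jitter_px: int = 0,
    fp_rate: float = 0.0,
    seed: int = 0,
) -> MockDetectorServer:
    """Start an HTTP mock-detector endpoint on an ephemeral localhost port."""
    det = MockDetector(
        ground_truth, miss_rate=miss_rate, jitter_px=jitter_px,
        fp_rate=fp_rate, seed=seed,
    )
    return MockDetectorServer(det)


def _is_duplicate(cand: BoxAnnotation, existing: Sequence[BoxAnnotation]) -> bool:
    # a suggestion sitting on top of ANY existing same-label box (manual or
    # ai) adds no information, only a spurious double annotation
    for b in existing:
        if b.label == cand.label and box_overlap(b, cand) > DEDUP_IOU:
            return True
    return False


def _merge(
    aset: AnnotationSet,
    predictions: Sequence[DetectorPrediction],
    score_threshold: float,
) -> AnnotationSet:
    new_boxes = list(aset.boxes)
    for pred in predictions:
        frame_existing = [b for b in new_boxes if b.frame == pred.frame]
        for pb in pred.boxes:
            if pb.score < score_threshold:
                continue
            cand = BoxAnnotation(
                frame=pred.frame, x=pb.x, y=pb.y, w=pb.w, h=pb.h,
                label=pb.label, provenance="ai", score=pb.score,
            )
            if not _is_duplicate(cand, frame_existing):
                new_boxes.append(cand)
                frame_existing.append(cand)
    return aset.model_copy(update={"boxes": new_boxes})


def predict_frames(
    detector: "Detector | str",
    frames: Sequence[int],
    aset: AnnotationSet,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> AnnotationSet:
    """Query a detector for the given frames and merge accepted predictions.

    ``detector`` is either an object satisfying the detector contract or an
    HTTP base URL.  Predictions scoring below ``score_threshold`` are
    discarded; accepted ones are added with provenance ``ai``.  Existing
    manual boxes are never modified.  On a service error the input set is
    returned untouched semantics-wise: the exception propagates before any
    merge happens.
    """
    if isinstance(detector, str):
        detector = HTTPDetector(detector)
    predictions = [detector.predict(f) for f in frames]  # all-or-nothing
    return _merge(aset, predictions, score_threshold)


def write_offline_predictions(
    predictions: Sequence[DetectorPrediction], path: "str | Path"
) -> None:
    """Write a prediction batch file (JSON list of per-frame predictions)."""
    Path(path).write_text(
        json.dumps([p.model_dump() for p in predictions], indent=2) + "\n",
        encoding="utf-8",
    )


def import_offline_predictions(
    aset: AnnotationSet,
    predictions_path: "str | Path",
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> AnnotationSet:
    """Merge an offline prediction batch file, same semantics as predict_frames.

    Re-importing the same file is a no-op: duplicates are recognized by
    frame, label and near-exact geometry.
    """
    try:
        raw = json.loads(Path(predictions_path).read_text(encoding="utf-8"))
        predictions = [DetectorPrediction.model_validate(p) for p in raw]
    except (json.JSONDecodeError, ValidationError, TypeError) as exc:
        raise AnnotationSchemaError(
            f"{predictions_path}: invalid prediction batch: {exc}"
        ) from exc
    return _merge(aset, predictions, score_threshold)
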