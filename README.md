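# fastcat

A headless toolkit for **semi-automated annotation of endoscopy video**,
built for teams producing bounding-box training data for polyp detection
models without burning scarce gastroenterologist time.

The workflow it supports splits annotation in two tiers:

1. **Expert pass** — a gastroenterologist reviews only the relevant moments
   of a colonoscopy, marks frame-level classes over frame ranges (e.g.
   "polyp visible", Paris type) and draws one exemplary box per lesion.
2. **Non-expert pass** — assisted by AI box suggestions, box duplication and
   object tracking, a non-expert completes the boxes on every in-between
   frame.

Relevant moments are found automatically: when the examiner captures a still
photo of suspicious tissue, the mechanically stabilized feed repeats
(near-)identical frames — a *freeze frame*. Detecting those runs lets the
expert jump straight to the pathology instead of reviewing the whole video.

## What is inside

- **Freeze-frame detection.** Consecutive frames are differenced in RGB, the
  absolute difference image is converted to HSV, and the mean Euclidean norm
  of the saturation and value channels (0–255 scale) is taken. A trailing
  moving average over a batch of 10 comparisons is thresholded with
  hysteresis: a freeze starts when the average falls below the start
  threshold and ends when it exceeds the (higher) end threshold.
- **Timestamp/frame navigation and preload scheduling.** `f = t[ms]·FPS/1000`
  maps timestamps to frames and back; the frame viewer's preload queue is
  paced by `ms = 50·(1−capacity)^2.75`, so a full queue waits 0 ms and an
  empty one 50 ms.
- **Annotation model with provenance.** Every box carries its origin —
  `expert`, `non_expert`, `ai`, `tracker` or `duplicated` — through JSON
  serialization and every conversion, so automatic labels stay
  distinguishable from manual ones.
- **Pluggable AI prelabeling.** A detector is anything answering
  `POST /predict` over HTTP (online mode) or a batch JSON file (offline
  mode); a deterministic fixture-backed mock detector with configurable
  miss rate, jitter and false positives serves tests.
- **Tracking.** Box duplication, a normalized-cross-correlation reference
  tracker, and the two reinitialization policies (every frame / on user
  resize) behind a contract any third-party tracker can implement.
- **Evaluation.** Per-frame one-to-one greedy matching with a true positive
  requiring ≥ 70 % overlap (IoU by default), precision / recall /
  `F1 = 2·TP/(2·TP+FP+FN)`, seconds-per-frame annotation speed, and
  segment-level freeze-detection quality.
- **Format interchange.** Configurable DSV export/import (delimiter, column
  order, absolute or YOLO-normalized coordinates), plus YOLO txt, Pascal-VOC
  XML and COCO JSON exporters.
- **Synthetic fixtures.** Deterministic colonoscopy-like videos — drifting
  mucosa texture, moving textured "polyp" blobs with exact ground-truth
  boxes, inserted exact-repeat freezes — so everything above is testable
  without clinical data.

## Worked example

Run the full pipeline on a synthetic 120-frame video with one freeze
(frames 30–55), one moving polyp (frames 20–100), and a mock detector that
misses 30 % of boxes (the tracker fills the gaps):

```
fastcat run demo.json --workdir demo_out
```

with `demo.json`:

```json
{
  "seed": 0,
  "fixture": {
    "n_frames": 120, "width": 384, "height": 288, "seed": 42,
    "freeze_segments": [[30, 55]],
    "blobs": [{"start_frame": 20, "end_frame": 100,
               "initial_box": [60, 60, 50, 40], "velocity": [1.5, 0.5]}]
  },
  "prelabel": {"mode": "mock", "miss_rate": 0.3, "seed": 7}
}
```

The summary it prints ends with:

```json
  "report": {
    "precision": 1.0,
    "recall": 1.0,
    "f1": 1.0,
    "tp": 81,
    "fp": 0,
    "fn": 0,
    "freeze_precision": 1.0,
    "freeze_recall": 1.0
  }
```

81 true positives are the 81 frames of the polyp's visibility range
(20–100), each ending up with exactly one box within the 0.7-IoU criterion
— the expert's exemplar, an accepted AI suggestion, or a tracker fill-in —
and no false positives or misses. `freeze_precision/recall = 1.0` says the
single inserted freeze was recovered (detected as frames 39–55: the trailing
10-comparison average needs a full batch of zero differences before it
triggers, hence the documented start-boundary lag of up to one window).
Scoring the final annotations directly gives the same numbers:

```
$ fastcat evaluate --pred demo_out/final.json --gt demo_out/ground_truth.json --iou 0.7
precision=1.0000 recall=1.0000 f1=1.0000 (tp=81 fp=0 fn=0)
```

and the flat export (`demo_out/boxes.dsv`) keeps provenance per box:

```
frame,label,x,y,w,h,provenance,score
20,polyp,60,60,50,40,expert,
22,polyp,63,61,50,40,ai,0.9
23,polyp,64,62,50,40,ai,0.9
```

Other subcommands: `extract`, `freeze-detect`, `make-fixture`, `prelabel`,
`track`, `evaluate`, `convert`, `validate` — see `fastcat --help`.

## Documentation

Model, parameters, numerical choices and limitations: `docs/methods.md`.
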