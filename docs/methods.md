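# Methods

This note documents the models and procedures implemented in `fastcat`, the
parameters that matter, what the synthetic fixtures do and do not emulate,
and the design choices made where the design was genuinely open.

## Freeze-frame detection

During colonoscopy, pressing the capture button mechanically stabilizes the
endoscope and the recorded feed repeats (near-)identical frames for a short
run. These runs index the clinically relevant moments.

For each pair of consecutive frames the detector computes a difference
norm: the per-pixel absolute RGB difference image is converted to HSV and
the Euclidean norm of the (saturation, value) pair, both scaled to 0–255,
is averaged over pixels. Hue is excluded: the hue of a near-black
difference image is numerically meaningless noise. The implementation
computes S and V directly (`V = max(R,G,B)`, `S = (max−min)/max`), which is
algebraically identical to a full HSV conversion restricted to those two
channels; the test suite cross-checks it against `skimage.color.rgb2hsv`.

A note on the measure's behavior: saturation of a difference image is
near-maximal for *any* chromatically unbalanced difference, however small,
so the norm is large (often > 100) for ordinary sensor noise and drops to
~0 essentially only for exact or gray-balanced near-exact repeats. This is
what makes the detector robust — frozen feeds are display repeats — and it
is why the default thresholds sit far below typical motion values.

A trailing moving average over `window = 10` comparisons is thresholded
with hysteresis:

| parameter | default | meaning |
|---|---|---|
| `window` | 10 comparisons | trailing moving-average batch |
| `start_threshold` | 3.0 (0–255 norm scale) | average below ⇒ freeze starts |
| `end_threshold` | 6.0 | average above ⇒ freeze ends (≥ start, prevents boundary flicker) |
| `min_length` | 5 frames | shorter segments are discarded |

The state machine evaluates the average only once a full window of
comparisons exists, and reports the segment start at the comparison index
that triggered. Consequently a detected start lags the true freeze start by
up to `window − 1` frames; segment boundaries are therefore specified, and
evaluated, with a tolerance of one window. A freeze still open at the last
frame is closed there.

`detect_freezes_from_diffs` exposes the state machine over precomputed
norms so thresholds can be explored without recomputing the expensive part.

## Navigation and preload scheduling

Timestamp to frame: `f = ⌊t[ms]·FPS/1000⌋` — flooring selects the frame
currently displayed at time `t`. An epsilon of 1e-6 is added before
flooring so that the exact inverse `t = f·1000/FPS` round-trips under
floating-point error at fractional frame rates (23.976, 29.97, …); the
round-trip identity is property-tested over those grids. Frame indices are
0-based everywhere, including the JSON schema.

The frame viewer's preload queue is paced by the capacity-dependent
polynomial `ms = 50·(1−capacity)^2.75` with `capacity ∈ [0, 1]` the filled
fraction of the queue: 0 ms at a full queue, 50 ms at an empty one,
continuous and monotonically non-increasing in between.

## Annotation model

Two stages share one container (`AnnotationSet`): the expert's intermediate
output (freeze frames, class ranges, exemplary boxes) and the non-expert's
final output (boxes on every relevant frame). Frame-level classes are
stored as inclusive frame ranges parented to a freeze frame — the expert
assigns a class by marking its start and end frame; the per-frame entry
style is the degenerate length-1 range. Box annotations are stored
independently of class assignments (a box does not imply a class).

Boxes are top-left `x, y, w, h` in integer pixels, half-open interval
`[x, x+w)`. Every box carries a `provenance` tag
(`expert | non_expert | ai | tracker | duplicated`); serialization refuses
records without one, so automatic annotations remain distinguishable
end-to-end. The JSON schema is versioned (`schema_version: 1`) and
validated on read with errors naming the offending field.

## Prelabeling

The detector contract is one operation: frame index in, scored boxes out.
Online mode speaks HTTP (`POST /predict`, JSON body `{"frame": i}`,
response `{"frame": i, "boxes": [{x,y,w,h,score,label}]}`) — the protocol a
model server in a container would expose so the model stays loaded between
predictions. Offline mode merges a JSON batch file produced elsewhere.

Merge semantics: predictions with `score ≥ 0.5` (configurable) are added
with provenance `ai`; manual boxes are never modified or deleted; a
suggestion with IoU > 0.95 against any existing same-label box on the frame
is a duplicate and is skipped, which makes merging idempotent and keeps an
AI suggestion from doubling a box the user already drew.

The mock detector answers from fixture ground truth degraded by a miss
rate, integer corner jitter, and a per-frame false-positive rate. Its
randomness is derived from `(seed, frame_index)`, so responses are
deterministic and independent of query order.

## Tracking

The reference tracker is normalized cross-correlation (NCC) template
matching at fixed box size over a search window of the previous box dilated
by `search_radius = 32 px`. It is deterministic and sufficient to exercise
the propagation machinery; production trackers plug in through the same
`init(frame, box)/update(frame)` contract and are deliberately not
reimplemented here.

Two reinitialization policies address template staleness, the dominant
failure mode on endoscopy-like content:

- `reinit_every_frame` — the template is rebuilt from every frame's
  (possibly user-corrected) box, so the tracker always holds the latest
  appearance of the lesion;
- `reinit_on_resize` — rebuilt only when a user correction changed box
  width or height by ≥ 1 px; pure translation does not retrigger.

User corrections override the tracker's output on their frame and feed
reinitialization. A match score below `lost_score_floor = 0.3` flags the
frame `lost`; tracking continues from the last confident box rather than
compounding a bad match. Both cut-offs are engineering choices documented
here, not derived quantities.

`fill_gaps_with_tracker` composes this with the annotation model: frames in
a class range that already carry a box (expert, non-expert or AI) act as
anchors; only anchor-less frames gain tracker boxes.

## Evaluation

Quality follows the standard detection protocol: within each frame,
predictions are matched one-to-one to ground truth greedily by descending
overlap; a pair is a true positive when overlap ≥ 0.7. "Overlap" is IoU by
default; a one-sided ground-truth-coverage mode is available since a bare
percentage criterion admits either reading. `F1 = 2·TP/(2·TP+FP+FN)`
(equal, algebraically, to the harmonic mean of precision and recall — the
suite asserts the identity on random count triples). Greedy matching can in
principle differ from the optimal assignment on adversarial instances; the
suite compares it against an exhaustive `linear_sum_assignment` oracle on
random frames and requires discrepancies below 1 % (none are observed at
the tested seeds).

Annotation speed is seconds per frame: active annotation time, minus
explicit pause intervals, divided by distinct annotated frames.

Freeze detection is scored at segment level: a predicted segment is a true
positive when it overlaps a ground-truth segment with both boundaries
within the tolerance (default 10 frames = one window).

## Synthetic fixtures

The generator renders what the toolkit needs to be tested against, as a
pure function of its spec (two runs are byte-identical):

- a smooth reddish mucosa-like texture (Gaussian field, σ = 8 px, ±50
  intensity) drifting as an integer random walk of `motion_amplitude = 3`
  px/frame — unsteady camera; the walk is centered in a double-sized
  texture so the visible crop never wraps discontinuously;
- per-pixel Gaussian sensor noise, `noise_sigma = 2`;
- elliptical polyp blobs: opaque core with a soft rim, fixed surface
  speckle in blob-local coordinates (lesions carry their own vascular
  pattern, which is what makes them trackable), constant-velocity
  trajectories clamped at frame borders, exact per-frame ground-truth
  boxes;
- freeze segments: exact repeats of the segment's first frame (ground
  truth holds still with the display; the live trajectory resumes after),
  with an optional `freeze_noise_sigma` to stress hysteresis.

The default geometry is 300 frames at 384×288, seed 42. The fixtures do
**not** emulate specular highlights, peristaltic deformation, illumination
changes, interlacing or compression artifacts; green results on them
validate the pipeline's geometry, bookkeeping and determinism — not
detector or tracker performance on clinical footage.

Because a difference image of pure sensor noise already scores far above
`end_threshold` (see the saturation note above), any nonzero noise or drift
makes non-frozen frames unambiguous to the detector; the discriminating
case is exact repeats, which is what real frozen feeds produce.

## Problem sizes used in the checks

The behavioral guarantees are exercised at desk scale, chosen to probe each
property without redundancy: 20 seeded 300-frame fixtures for freeze
recovery; 500 random frames with ≤ 6 boxes for the matching oracle; 10⁴
random count triples for the F1 identity; one 300-frame pipeline run each
for the identity-detector and 30 %-miss tracker-fill-in checks; 100-box
sets for format round-trips; frame indices 0–10⁴ across five frame rates
for the timestamp identity.

## Known limitations

- Variable-frame-rate video is handled only at its nominal FPS.
- The NCC reference tracker assumes fixed box size and translation-only
  motion between consecutive frames; scale changes arrive only through
  user corrections.
- Multi-object tracking has no identity management; objects are tracked
  per class range.
- The greedy matcher is the standard protocol, not a guaranteed-optimal
  assignment (see above).
- Medical semantics (Paris classes etc.) are opaque strings by design.
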