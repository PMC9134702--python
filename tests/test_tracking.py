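import numpy as np
import pytest

from fastcat import (
    AnnotationSet,
    BlobSpec,
    BoxAnnotation,
    FixtureSpec,
    NCCTracker,
    TrackerPolicy,
    box_overlap,
    duplicate_box,
    fill_gaps_with_tracker,
    generate_fixture,
    reference_tracker,
    track,
)


def box(frame, x, y, w=10, h=10, provenance="non_expert", label="polyp"):
    return BoxAnnotation(frame=frame, x=x, y=y, w=w, h=h, label=label,
                         provenance=provenance)


class TestDuplicateBox:
    def test_copies_geometry_with_duplicated_provenance(self):
        s = AnnotationSet(boxes=[box(10, 5, 6)])
        out = duplicate_box(s, 10, 11)
        dup = out.boxes_on(11)
        assert len(dup) == 1
        assert (dup[0].x, dup[0].y, dup[0].w, dup[0].h) == (5, 6, 10, 10)
        assert dup[0].provenance == "duplicated"

    def test_existing_target_boxes_kept(self):
        s = AnnotationSet(boxes=[box(10, 5, 6), box(11, 20, 20)])
        out = duplicate_box(s, 10, 11)
        assert len(out.boxes_on(11)) == 2

    def test_chain_duplication_preserves_geometry(self):
        s = AnnotationSet(boxes=[box(10, 5, 6)])
        s = duplicate_box(s, 10, 11)
        s = duplicate_box(s, 11, 12)
        b = s.boxes_on(12)[0]
        assert (b.x, b.y, b.w, b.h) == (5, 6, 10, 10)

    def test_no_source_warns_noop(self):
        s = AnnotationSet(boxes=[box(10, 5, 6)])
        with pytest.warns(UserWarning, match="no boxes"):
            assert duplicate_box(s, 3, 4) == s


class TestReferenceTracker:
    def test_self_match_scores_one_at_source(self, rng):
        frame = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        tmpl = frame[20:30, 12:24]
        found, score = reference_tracker(tmpl, frame, (12, 20, 12, 10))
        assert found == (12, 20, 12, 10)
        assert score == pytest.approx(1.0)

    def test_shifted_copy_displaces_box_exactly(self, rng):
        frame = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        tmpl = frame[20:30, 12:24]
        shifted = np.roll(np.roll(frame, 1, axis=0), 3, axis=1)
        found, score = reference_tracker(tmpl, shifted, (12, 20, 12, 10))
        assert found == (12 + 3, 20 + 1, 12, 10)
        assert score == pytest.approx(1.0)

    def test_uncorrelated_noise_scores_near_zero(self, rng):
        tmpl = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        noise = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        _, score = reference_tracker(tmpl, noise, (26, 26, 12, 12))
        # expectation of NCC between independent noise patches is 0; the max
        # over ~4k offsets stays well under a confident-match level
        assert score < 0.6

    def test_template_larger_than_frame_rejected(self, rng):
        tmpl = rng.integers(0, 256, (70, 70, 3)).astype(np.uint8)
        frame = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        with pytest.raises(ValueError, match="template"):
            reference_tracker(tmpl, frame, (0, 0, 70, 70))


@pytest.fixture(scope="module")
def static_case():
    spec = FixtureSpec(
        n_frames=30, width=256, height=192, seed=21,
        blobs=[BlobSpec(start_frame=0, end_frame=29, initial_box=(100, 90, 40, 36))],
    )
    frames, gt, _ = generate_fixture(spec)
    return frames, gt


@pytest.fixture(scope="module")
def moving_case():
    spec = FixtureSpec(
        n_frames=60, width=384, height=288, seed=22,
        blobs=[BlobSpec(start_frame=0, end_frame=59,
                        initial_box=(60, 60, 50, 40), velocity=(2.0, 0.0))],
    )
    frames, gt, _ = generate_fixture(spec)
    return frames, gt


class TestTrack:
    def test_stationary_blob_stays_put(self, static_case):
        frames, gt = static_case
        out = track(frames, gt.boxes_on(0)[0], TrackerPolicy("none"))
        assert len(out) == len(frames)
        for b in out:
            assert abs(b.x - 100) <= 1 and abs(b.y - 90) <= 1
            assert b.provenance == "tracker"

    def test_constant_velocity_reinit_every_frame_iou(self, moving_case):
        frames, gt = moving_case
        out = track(frames, gt.boxes_on(0)[0], TrackerPolicy("reinit_every_frame"))
        ious = [box_overlap(b, gt.boxes_on(b.frame)[0]) for b in out]
        assert min(ious) >= 0.7

    def test_one_box_per_frame(self, moving_case):
        frames, gt = moving_case
        out = track(frames, gt.boxes_on(0)[0], TrackerPolicy("reinit_every_frame"))
        assert [b.frame for b in out] == list(range(len(frames)))

    def test_reinit_on_resize_triggers_once(self, static_case):
        frames, gt = static_case
        init = gt.boxes_on(0)[0]
        resized = init.model_copy(update={"frame": 15, "w": init.w + 6})
        trk = NCCTracker()
        track(
            frames, init, TrackerPolicy("reinit_on_resize"),
            corrections={15: resized}, tracker=trk,
        )
        assert trk.init_count == 2  # initial + the resize event

    def test_translation_correction_does_not_reinit(self, static_case):
        frames, gt = static_case
        init = gt.boxes_on(0)[0]
        moved = init.model_copy(update={"frame": 15, "x": init.x + 4})
        trk = NCCTracker()
        track(
            frames, init, TrackerPolicy("reinit_on_resize"),
            corrections={15: moved}, tracker=trk,
        )
        assert trk.init_count == 1

    def test_perfect_corrections_reproduced_exactly(self, moving_case):
        frames, gt = moving_case
        corrections = {b.frame: b for b in gt.boxes}
        out = track(
            frames, gt.boxes_on(0)[0], TrackerPolicy("reinit_every_frame"),
            corrections=corrections,
        )
        for b in out:
            g = gt.boxes_on(b.frame)[0]
            assert (b.x, b.y, b.w, b.h) == (g.x, g.y, g.w, g.h)

    def test_lost_flag_on_vanishing_target(self, rng):
        # target visible only on frame 0; later frames are fresh noise
        frames = [rng.integers(0, 256, (96, 96, 3)).astype(np.uint8)
                  for _ in range(5)]
        init = box(0, 30, 30, 16, 16, provenance="expert")
        out = track(frames, init, TrackerPolicy("none"))
        assert any(b.note == "lost" for b in out[1:])


class TestFillGaps:
    def test_fills_only_unannotated_frames(self, moving_blob_fixture):
        spec, frames, gt, _ = moving_blob_fixture
        blob = spec.blobs[0]
        anchors = [b for b in gt.boxes if b.frame % 5 == 0]
        sparse = gt.model_copy(update={"boxes": anchors})
        out = fill_gaps_with_tracker(
            sparse, frames[blob.start_frame : blob.end_frame + 1],
            "polyp", blob.start_frame, blob.end_frame,
        )
        assert set(b.frame for b in out.boxes) == set(
            range(blob.start_frame, blob.end_frame + 1)
        )
        added = [b for b in out.boxes if b not in anchors]
        assert all(b.provenance == "tracker" for b in added)

    def test_no_anchor_warns_noop(self, moving_blob_fixture):
        _, frames, gt, _ = moving_blob_fixture
        empty = gt.model_copy(update={"boxes": []})
        with pytest.warns(UserWarning, match="nothing to track"):
            out = fill_gaps_with_tracker(empty, frames[:10], "polyp", 0, 9)
        assert out == empty
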