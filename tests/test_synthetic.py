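from collections import defaultdict

import numpy as np
import pytest

from rovannot import synthetic as syn
from rovannot.box_consensus import consensus_regions
from rovannot.clip_consensus import aggregate_clip
from rovannot.errors import ValidationError
from rovannot.observations import aggregate_detections


def _group_by_subject(annotations):
    out = defaultdict(list)
    for a in annotations:
        out[a.subject_id].append(a)
    return out


class TestSceneGeneration:
    def test_tracks_stay_on_canvas_and_consecutive(self, small_scene):
        for t in small_scene.tracks:
            frames = sorted(t.boxes)
            assert frames == list(range(frames[0], frames[-1] + 1))
            for b in t.boxes.values():
                assert 0 <= b.x and b.x2 <= small_scene.canvas_w
                assert 0 <= b.y and b.y2 <= small_scene.canvas_h

    def test_same_seed_same_scene(self):
        a = syn.make_scene("m", seed=3)
        b = syn.make_scene("m", seed=3)
        assert a == b


class TestClipAnnotations:
    def test_noiseless_annotations_equal_truth(self, small_scene, perfect_profiles):
        anns = syn.simulate_clip_annotations(small_scene, perfect_profiles, seed=1)
        truths = {t.subject_id: t for t in syn.clip_truths(small_scene)}
        for a in anns:
            t = truths[a.subject_id]
            if t.present:
                assert a.choice_id == syn.TAXON_CHOICE
                assert a.first_seen_s == pytest.approx(t.first_seen_s)
                assert a.individual_count == t.count
            else:
                assert a.choice_id == syn.NOTHING_CHOICE

    def test_same_seed_identical_tables(self, small_scene):
        profiles = syn.default_profiles(8)
        a = syn.simulate_clip_annotations(small_scene, profiles, seed=7)
        b = syn.simulate_clip_annotations(small_scene, profiles, seed=7)
        assert a == b

    def test_empirical_hit_rate_near_sensitivity(self):
        # one long scene with one full-length track: every clip is a present-clip
        from rovannot.boxes import BBox
        from rovannot.synthetic import Track, TrueScene

        n_clips = 500
        track = Track("o", {f: BBox(10, 10, 50, 50) for f in range(n_clips * 250)})
        scene = TrueScene("m", 25.0, n_clips * 10.0, 480, 270, (track,))
        profiles = syn.default_profiles(8, sensitivity=0.9, specificity=0.9)
        anns = syn.simulate_clip_annotations(scene, profiles, seed=7)
        hits = defaultdict(int)
        per_ann = defaultdict(int)
        for a in anns:
            per_ann[a.annotator_id] += 1
            if a.choice_id == syn.TAXON_CHOICE:
                hits[a.annotator_id] += 1
        for ann_id, n in per_ann.items():
            assert n == n_clips
            assert abs(hits[ann_id] / n - 0.9) < 0.03

    def test_empty_profiles_rejected(self, small_scene):
        with pytest.raises(ValidationError):
            syn.simulate_clip_annotations(small_scene, [], seed=0)


class TestFrameAnnotations:
    def test_noiseless_closure_with_box_consensus(self, small_scene, perfect_profiles):
        anns = syn.simulate_frame_annotations(small_scene, perfect_profiles, seed=2)
        for subject, group in _group_by_subject(anns).items():
            frame_no = int(subject.rsplit("_f", 1)[1])
            true_boxes = sorted(
                small_scene.boxes_at(frame_no), key=lambda b: (b.y, b.x)
            )
            result = consensus_regions(group, threshold=0.8)
            got = sorted((c.bbox for c in result), key=lambda b: (b.y, b.x))
            if len(true_boxes) == 1:  # overlapping truths can merge components
                assert len(got) == 1
                for g, t in zip(got, true_boxes):
                    assert g.x == pytest.approx(t.x, abs=1e-9)
                    assert g.y == pytest.approx(t.y, abs=1e-9)
                    assert g.w == pytest.approx(t.w, abs=1e-9)
                    assert g.h == pytest.approx(t.h, abs=1e-9)

    def test_miss_prob_one_yields_empty_consensus(self, small_scene):
        profiles = syn.default_profiles(5, box_miss_prob=1.0)
        anns = syn.simulate_frame_annotations(small_scene, profiles, seed=3)
        assert all(a.boxes == () for a in anns)
        for group in _group_by_subject(anns).values():
            assert consensus_regions(group, 0.8) == []

    def test_jittered_consensus_center_near_truth(self):
        # single static object so the consensus never merges components
        from rovannot.boxes import BBox
        from rovannot.synthetic import Track, TrueScene

        track = Track("o", {f: BBox(200.0, 100.0, 60, 50) for f in range(2500)})
        scene = TrueScene("m", 25.0, 1000.0, 480, 270, (track,))
        profiles = syn.default_profiles(5, box_jitter_sd=2.0, box_miss_prob=0.0)
        frame_nos = list(range(0, 2500, 25))[:100]
        anns = syn.simulate_frame_annotations(scene, profiles, seed=3,
                                              frame_nos=frame_nos)
        good = 0
        for group in _group_by_subject(anns).values():
            result = consensus_regions(group, threshold=0.8)
            if len(result) == 1:
                cx, cy = result[0].bbox.center
                if abs(cx - 230.0) <= 2 and abs(cy - 125.0) <= 2:
                    good += 1
        assert good >= 95


class TestDetections:
    def test_noiseless_stream_closure_with_aggregation(self):
        from rovannot.boxes import BBox
        from rovannot.synthetic import Track, TrueScene

        track = Track("o", {f: BBox(10, 10, 50, 50) for f in range(100, 150)})
        scene = TrueScene("m", 25.0, 10.0, 480, 270, (track,))
        dets = syn.simulate_detections(scene, conf_mean_present=0.9, conf_sd=0.0,
                                       false_pos_rate=0.0, seed=1)
        (p,) = aggregate_detections(dets, conf_threshold=0.5)
        assert (p.frame_no_start, p.frame_no_end) == (100, 149)
        assert p.max_conf == pytest.approx(0.9)

    def test_low_confidence_yields_no_periods(self, small_scene):
        dets = syn.simulate_detections(small_scene, 0.6, 0.0, 0.0, seed=1)
        assert aggregate_detections(dets, conf_threshold=0.9) == []

    def test_same_seed_identical_stream(self, small_scene):
        a = syn.simulate_detections(small_scene, 0.8, 0.1, 0.05, seed=5)
        b = syn.simulate_detections(small_scene, 0.8, 0.1, 0.05, seed=5)
        assert a == b
        assert all(0.01 <= d.confidence <= 0.99 for d in a)


class TestRenderFrames:
    def test_same_seeds_identical_pixels(self, small_scene):
        a = syn.render_frames(small_scene, texture_seed=1, frame_nos=[0, 5])
        b = syn.render_frames(small_scene, texture_seed=1, frame_nos=[0, 5])
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_canvas_minimum(self):
        from rovannot.synthetic import TrueScene

        tiny = TrueScene("m", 25.0, 1.0, 32, 32, ())
        with pytest.raises(ValidationError):
            syn.render_frames(tiny)
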