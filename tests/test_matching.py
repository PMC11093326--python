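"""Two-stage matcher: motion prediction, gating, stranding, identities."""

import math

import pytest

from herdtrack.datamodel import Detection, FrameTable, TrackerConfig
from herdtrack.matching import (
    Track,
    TrackStatus,
    Tracker,
    advance_stranding,
    greedy_match,
    predict_motion,
    run_tracker,
)


def make_track(tid, center, size=(10.0, 10.0), velocity=(0.0, 0.0),
               health=0, status=TrackStatus.ACTIVE, history=None):
    return Track(id=tid, status=status, last_center=center, last_size=size,
                 velocity=velocity, health=health, last_frame=1,
                 history=history or [(1, Detection(1, center, size, 1.0))])


class TestPredictMotion:
    def test_single_observation_is_zero(self):
        assert predict_motion(make_track(1, (5, 5)), alpha=0.5) == (0, 0)

    def test_constant_displacement_is_fixed_point(self):
        hist = [(f, Detection(f, (2.0 * f, 0.0), (4, 4), 1.0))
                for f in range(1, 5)]
        for alpha in (0.1, 0.5, 1.0):
            vx, vy = predict_motion(make_track(1, (8, 0), history=hist), alpha)
            assert (vx, vy) == pytest.approx((2.0, 0.0))

    def test_ema_blend_from_rest(self):
        # EMA state (0,0) after two static observations; a displacement of
        # (4,0) at alpha 0.5 blends to (2,0)
        hist = [(1, Detection(1, (0.0, 0.0), (4, 4), 1.0)),
                (2, Detection(2, (0.0, 0.0), (4, 4), 1.0)),
                (3, Detection(3, (4.0, 0.0), (4, 4), 1.0))]
        vx, vy = predict_motion(make_track(1, (4, 0), history=hist), alpha=0.5)
        assert (vx, vy) == pytest.approx((2.0, 0.0))

    def test_empty_history_errors(self):
        t = make_track(1, (0, 0))
        t.history = []
        with pytest.raises(ValueError):
            predict_motion(t, 0.5)


class TestGreedyMatch:
    def test_inside_gate_matches(self):
        det = Detection(1, (10, 10), (4, 4), 0.9)
        res = greedy_match([det], [(make_track(1, (11, 10)), (11, 10), 5.0)])
        assert len(res.pairs) == 1

    def test_outside_gate_unmatched(self):
        det = Detection(1, (100, 100), (4, 4), 0.9)
        res = greedy_match([det], [(make_track(1, (0, 0)), (0, 0), 5.0)])
        assert not res.pairs
        assert len(res.unmatched_detections) == 1
        assert len(res.unmatched_tracks) == 1

    def test_confidence_order_decides_contention(self):
        # d1 (higher score) takes the nearest candidate c1; d2 falls to c2.
        d1 = Detection(1, (0.0, 0.0), (4, 4), 0.9)
        d2 = Detection(1, (1.0, 0.0), (4, 4), 0.8)
        c1 = (make_track(1, (0.4, 0.0)), (0.4, 0.0), 5.0)
        c2 = (make_track(2, (3.0, 0.0)), (3.0, 0.0), 5.0)
        res = greedy_match([d1, d2], [c1, c2])
        got = {(d.center[0], t.id) for d, t in res.pairs}
        assert got == {(0.0, 1), (1.0, 2)}

    def test_each_side_used_at_most_once(self, rng):
        dets = [Detection(1, tuple(rng.uniform(0, 50, 2)), (4, 4),
                          float(rng.uniform(0.2, 1.0))) for _ in range(8)]
        cands = [(make_track(i + 1, tuple(rng.uniform(0, 50, 2))),
                  tuple(rng.uniform(0, 50, 2)), 20.0) for i in range(5)]
        res = greedy_match(dets, cands)
        matched_dets = [id(d) for d, _ in res.pairs]
        matched_tracks = [t.id for _, t in res.pairs]
        assert len(set(matched_dets)) == len(matched_dets)
        assert len(set(matched_tracks)) == len(matched_tracks)
        for d, t in res.pairs:
            # pair distance within the candidate's gate
            pred = next(p for tt, p, _ in cands if tt.id == t.id)
            assert math.dist(d.center, pred) <= 20.0


class TestStranding:
    def test_empty_area(self):
        assert advance_stranding([]) == []

    def test_drift_and_decrement(self):
        t = make_track(1, (10.0, 10.0), velocity=(2.0, 0.0), health=3,
                       status=TrackStatus.STRANDED)
        (out,) = advance_stranding([t])
        assert out.last_center == (12.0, 10.0)
        assert out.health == 2

    def test_expiry_terminates(self):
        t = make_track(1, (0, 0), health=1, status=TrackStatus.STRANDED)
        assert advance_stranding([t]) == []
        assert t.status is TrackStatus.TERMINATED


def _run_gap_scenario(gap, config=None, speed=3.0):
    """One target moving right, missing for `gap` frames in the middle."""
    recs = []
    for f in range(1, 41):
        if 11 <= f <= 10 + gap:
            continue
        recs.append(Detection(f, (10.0 + speed * f, 20.0), (8, 8), 0.9))
    return run_tracker(FrameTable(recs), config)


class TestTwoStageUpdate:
    def test_first_frame_assigns_sequential_ids(self):
        dets = [Detection(1, (10.0 * i, 10.0), (5, 5), 0.9) for i in range(1, 4)]
        tracker = Tracker()
        out = tracker.step(1, dets)
        assert sorted(d.id for d in out) == [1, 2, 3]

    def test_mixed_frames_rejected(self):
        tracker = Tracker()
        with pytest.raises(ValueError, match="mixed"):
            tracker.step(1, [Detection(1, (0, 0), (4, 4), 0.9),
                             Detection(2, (0, 0), (4, 4), 0.9)])

    def test_score_threshold_filters(self):
        tracker = Tracker(TrackerConfig(score_threshold=0.5))
        out = tracker.step(1, [Detection(1, (0, 0), (4, 4), 0.2)])
        assert out == []

    def test_short_gap_keeps_identity(self):
        out = _run_gap_scenario(gap=5)
        ids = {d.id for d in out}
        assert ids == {1}

    def test_gap_longer_than_lifespan_spawns_new_identity(self):
        out = _run_gap_scenario(gap=25)
        by_frame = {d.frame: d.id for d in out}
        assert by_frame[10] == 1
        assert by_frame[36] == 2
        assert {d.id for d in out} == {1, 2}

    def test_gap_at_lifespan_boundary(self):
        # health L0=20 decrements once per missing frame; the track survives
        # gaps up to 19 frames and dies on the 20th.
        assert {d.id for d in _run_gap_scenario(gap=19)} == {1}
        assert {d.id for d in _run_gap_scenario(gap=20)} == {1, 2}

    def test_stage2_disabled_always_spawns_new_id(self):
        out = _run_gap_scenario(gap=5, config=TrackerConfig(stage2_enabled=False))
        assert {d.id for d in out} == {1, 2}

    def test_identity_uniqueness_and_conservation(self, rng):
        tracker = Tracker(TrackerConfig(score_threshold=0.3))
        for f in range(1, 30):
            n = int(rng.integers(0, 6))
            dets = [Detection(f, tuple(rng.uniform(0, 100, 2)), (8, 8),
                              float(rng.uniform(0, 1))) for _ in range(n)]
            out = tracker.step(f, dets)
            ids = [d.id for d in out]
            assert len(set(ids)) == len(ids)
            kept = sum(1 for d in dets if d.score >= 0.3)
            assert len(out) == kept  # every retained detection gets an id

    def test_ids_strictly_increase_and_never_return(self, rng):
        tracker = Tracker()
        seen_max = 0
        dead = set()
        for f in range(1, 60):
            dets = [Detection(f, tuple(rng.uniform(0, 100, 2)), (6, 6), 0.9)
                    for _ in range(int(rng.integers(0, 4)))]
            out = tracker.step(f, dets)
            for d in out:
                assert d.id not in dead
            new_ids = {d.id for d in out if d.id > seen_max}
            if new_ids:
                seen_max = max(new_ids)
            dead |= {t.id for t in tracker.terminated}
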