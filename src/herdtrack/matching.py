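"""Two-stage distance-based greedy association with a stranding area.

Occluded animals vanish from the detector for a handful of frames and, with
a plain greedy matcher, come back as new identities.  The two-stage scheme
keeps a track that failed stage-1 matching alive in a *stranding area*: its
position keeps drifting by its last motion vector, its health counts down
from an initial lifespan (default 20 frames), and a detection that reappears
within the stage-2 gate reclaims the original identity.  A track whose
health reaches zero is deleted for good; its id is never reused.

The motion vector is an exponential moving average of observed per-frame
center displacements, frozen on entry to the stranding area.  The backward
motion vector is its negation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .datamodel import Detection, FrameTable, TrackerConfig


class TrackStatus(Enum):
    ACTIVE = "active"
    STRANDED = "stranded"
    TERMINATED = "terminated"


@dataclass
class Track:
    id: int
    status: TrackStatus
    last_center: tuple[float, float]
    last_size: tuple[float, float]
    velocity: tuple[float, float] = (0.0, 0.0)
    health: int = 0
    last_frame: int = 0
    history: list[tuple[int, Detection]] = field(default_factory=list)

    def observe(self, frame: int, det: Detection, alpha: float) -> None:
        """Fold a matched detection into the track state (EMA velocity)."""
        if self.status is TrackStatus.TERMINATED:
            raise ValueError(f"track {self.id} is terminated")
        if self.history:
            gap = frame - self.last_frame
            prev = self.history[-1][1].center
            step = ((det.center[0] - prev[0]) / gap,
                    (det.center[1] - prev[1]) / gap)
            if len(self.history) == 1:
                # seed the EMA with the first observed displacement
                self.velocity = step
            else:
                self.velocity = (
                    (1 - alpha) * self.velocity[0] + alpha * step[0],
                    (1 - alpha) * self.velocity[1] + alpha * step[1],
                )
        self.last_center = det.center
        self.last_size = det.size
        self.last_frame = frame
        self.history.append((frame, det))


def predict_motion(track: Track, alpha: float) -> tuple[float, float]:
    """EMA of per-frame center displacements over the track history.

    The EMA is seeded with the first observed displacement, so a constant
    displacement sequence is a fixed point for any alpha.  Returns (0, 0)
    for a single-observation track; the backward motion vector is the
    negation of the returned forward vector.
    """
    if not track.history:
        raise ValueError("track has no history")
    vel = (0.0, 0.0)
    prev_frame, prev_det = track.history[0]
    for i, (frame, det) in enumerate(track.history[1:]):
        gap = frame - prev_frame
        step = ((det.center[0] - prev_det.center[0]) / gap,
                (det.center[1] - prev_det.center[1]) / gap)
        if i == 0:
            vel = step  # EMA seeded with the first displacement
        else:
            vel = ((1 - alpha) * vel[0] + alpha * step[0],
                   (1 - alpha) * vel[1] + alpha * step[1])
        prev_frame, prev_det = frame, det
    return vel


@dataclass
class MatchResult:
    pairs: list[tuple[Detection, Track]]
    unmatched_detections: list[Detection]
    unmatched_tracks: list[Track]


def greedy_match(
    detections: Sequence[Detection],
    candidates: Sequence[tuple[Track, tuple[float, float], float]],
) -> MatchResult:
    """Confidence-ordered greedy nearest-neighbor matching with gating.

    Detections are processed in descending score (ties keep input order);
    each takes the nearest still-unmatched candidate whose Euclidean center
    distance is within that candidate's gate radius.  Exact distance ties go
    to the lower track id.
    """
    for _, _, gate in candidates:
        if gate <= 0:
            raise ValueError("gate radius must be positive")
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, i))
    taken = [False] * len(candidates)
    pairs: list[tuple[Detection, Track]] = []
    unmatched_dets: list[Detection] = []
    for i in order:
        det = detections[i]
        best: Optional[int] = None
        best_key: Optional[tuple[float, int]] = None
        for j, (track, pred, gate) in enumerate(candidates):
            if taken[j]:
                continue
            dist = math.hypot(det.center[0] - pred[0], det.center[1] - pred[1])
            if dist > gate:
                continue
            key = (dist, track.id)
            if best_key is None or key < best_key:
                best, best_key = j, key
        if best is None:
            unmatched_dets.append(det)
        else:
            taken[best] = True
            pairs.append((det, candidates[best][0]))
    unmatched_tracks = [c[0] for j, c in enumerate(candidates) if not taken[j]]
    return MatchResult(pairs, unmatched_dets, unmatched_tracks)


def advance_stranding(stranded: list[Track]) -> list[Track]:
    """One tick of the stranding area: drift, decrement health, expire.

    Each stranded track's center shifts by its frozen velocity and its
    health drops by one; tracks reaching zero are terminated and dropped.
    """
    survivors: list[Track] = []
    for t in stranded:
        t.last_center = (t.last_center[0] + t.velocity[0],
                         t.last_center[1] + t.velocity[1])
        t.health -= 1
        if t.health <= 0:
            t.status = TrackStatus.TERMINATED
        else:
            survivors.append(t)
    return survivors


class Tracker:
    """Stateful two-stage tracker consuming per-frame detection batches."""

    def __init__(self, config: Optional[TrackerConfig] = None) -> None:
        self.config = config or TrackerConfig()
        self.config.validate()
        self.active: list[Track] = []
        self.stranded: list[Track] = []
        self.terminated: list[Track] = []
        self._next_id = 1

    def _new_track(self, frame: int, det: Detection) -> Track:
        t = Track(id=self._next_id, status=TrackStatus.ACTIVE,
                  last_center=det.center, last_size=det.size,
                  last_frame=frame, history=[(frame, det)])
        self._next_id += 1
        return t

    def _gate(self, track: Track, factor: float) -> float:
        w, h = track.last_size
        return factor * math.sqrt(w * h)

    def step(self, frame: int, detections: Sequence[Detection]) -> list[Detection]:
        """Associate one frame of detections; returns id-bearing output boxes."""
        cfg = self.config
        if any(d.frame != frame for d in detections):
            raise ValueError("detections from mixed frames")
        dets = [d for d in detections if d.score >= cfg.score_threshold]

        # Stage 1: active tracks at their predicted positions.
        cands1 = [
            (t,
             (t.last_center[0] + t.velocity[0] * (frame - t.last_frame),
              t.last_center[1] + t.velocity[1] * (frame - t.last_frame)),
             self._gate(t, cfg.gate_factor))
            for t in self.active
        ]
        res1 = greedy_match(dets, cands1)
        for det, track in res1.pairs:
            track.observe(frame, det, cfg.ema_alpha)

        # Tracks that lost their detection enter the stranding area (or die
        # immediately when stage 2 is disabled: the pure-greedy baseline).
        for t in res1.unmatched_tracks:
            if cfg.stage2_enabled:
                t.status = TrackStatus.STRANDED
                t.health = cfg.lifespan
                if cfg.stage2_backward:
                    t.velocity = (-t.velocity[0], -t.velocity[1])
                self.stranded.append(t)
            else:
                t.status = TrackStatus.TERMINATED
                self.terminated.append(t)
        self.active = [t for _, t in res1.pairs]

        # Stage 2: leftover detections vs stranded tracks at drifted
        # positions, with the wider gate.
        new_dets = res1.unmatched_detections
        if cfg.stage2_enabled and self.stranded:
            cands2 = [(t, t.last_center, self._gate(t, cfg.gate_factor_s2))
                      for t in self.stranded]
            res2 = greedy_match(new_dets, cands2)
            for det, track in res2.pairs:
                track.status = TrackStatus.ACTIVE
                track.health = 0
                track.observe(frame, det, cfg.ema_alpha)
                self.active.append(track)
            self.stranded = res2.unmatched_tracks
            new_dets = res2.unmatched_detections

        for det in new_dets:
            self.active.append(self._new_track(frame, det))

        self.stranded = advance_stranding(self.stranded)
        self.terminated.extend(
            t for t in self.stranded if t.status is TrackStatus.TERMINATED
        )

        return [
            Detection(frame, d.center, d.size, d.score, id=t.id)
            for t in self.active
            if t.last_frame == frame
            for d in [t.history[-1][1]]
        ]


def run_tracker(
    detections: FrameTable,
    config: Optional[TrackerConfig] = None,
) -> FrameTable:
    """Track a whole detection table frame by frame.

    Every frame index in the table's range is stepped, including empty ones,
    so stranded tracks age during detection gaps.
    """
    tracker = Tracker(config)
    out: list[Detection] = []
    rng = detections.frame_range
    if rng is None:
        return FrameTable()
    for frame in range(rng[0], rng[1] + 1):
        out.extend(tracker.step(frame, detections.in_frame(frame)))
    return FrameTable(out)
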