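"""Core record types shared across the toolkit.

Conventions
-----------
Image coordinates: origin at the top-left corner, x rightward, y downward;
boxes are half-open ``[left, left+w) x [top, top+h)`` and stored in memory
as center + size.

Ground frame L: north-east-down (NED). X points north, Y east, Z down; the
ground plane sits at ``Z = 0`` so a UAV hovering at 10 m AGL has ``Z = -10``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence


@dataclass(frozen=True)
class Detection:
    """One observed bounding box in one frame.

    ``id`` is None for raw detector output and a positive integer in ground
    truth and tracker output.
    """

    frame: int
    center: tuple[float, float]
    size: tuple[float, float]
    score: float = 1.0
    id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame must be >= 1, got {self.frame}")
        w, h = self.size
        if not (w > 0 and h > 0):
            raise ValueError(f"box size must be positive, got {self.size}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")

    @property
    def left(self) -> float:
        return self.center[0] - self.size[0] / 2.0

    @property
    def top(self) -> float:
        return self.center[1] - self.size[1] / 2.0

    @classmethod
    def from_ltwh(
        cls,
        frame: int,
        left: float,
        top: float,
        w: float,
        h: float,
        score: float = 1.0,
        id: Optional[int] = None,
    ) -> "Detection":
        return cls(frame, (left + w / 2.0, top + h / 2.0), (w, h), score, id)


class FrameTable:
    """Ordered collection of detections grouped by frame.

    Records are kept sorted by (frame, id, left); within one frame no two
    id-bearing records may share an id.
    """

    def __init__(self, records: Sequence[Detection] = ()) -> None:
        recs = sorted(
            records,
            key=lambda d: (d.frame, d.id if d.id is not None else -1, d.left),
        )
        seen: set[tuple[int, int]] = set()
        for d in recs:
            if d.id is not None:
                key = (d.frame, d.id)
                if key in seen:
                    raise ValueError(f"duplicate id {d.id} in frame {d.frame}")
                seen.add(key)
        self._records: list[Detection] = recs

    @property
    def records(self) -> list[Detection]:
        return list(self._records)

    @property
    def frame_range(self) -> Optional[tuple[int, int]]:
        if not self._records:
            return None
        return self._records[0].frame, self._records[-1].frame

    def frames(self) -> list[int]:
        return sorted({d.frame for d in self._records})

    def in_frame(self, frame: int) -> list[Detection]:
        return [d for d in self._records if d.frame == frame]

    def by_id(self) -> dict[int, list[Detection]]:
        out: dict[int, list[Detection]] = {}
        for d in self._records:
            if d.id is not None:
                out.setdefault(d.id, []).append(d)
        return out

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[Detection]:
        return iter(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameTable):
            return NotImplemented
        return self._records == other._records


@dataclass(frozen=True)
class UAVPose:
    """UAV pose at one frame, in the NED ground frame L.

    position : (X north, Y east, Z down) meters; Z is negative above ground.
    attitude : (roll, pitch, yaw) radians, intrinsic Z-Y-X (yaw-pitch-roll).
    gimbal   : (pan, tilt) radians; pan about body z, then tilt about the
               panned y axis.  tilt = -pi/2 points the camera straight down.
    """

    frame: int
    position: tuple[float, float, float]
    attitude: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gimbal: tuple[float, float] = (0.0, -math.pi / 2.0)

    def __post_init__(self) -> None:
        for v in (*self.position, *self.attitude, *self.gimbal):
            if not math.isfinite(v):
                raise ValueError("pose values must be finite")
        yaw = self.attitude[2]
        if not (-math.pi < yaw <= math.pi + 1e-12):
            raise ValueError(f"yaw must lie in (-pi, pi], got {yaw}")

    @property
    def altitude(self) -> float:
        """Height above the Z = 0 ground plane (positive when airborne)."""
        return -self.position[2]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera: focal length and principal point in pixels."""

    f: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("focal length must be positive")
        u0, v0 = self.principal_point
        W, H = self.image_size
        if not (0 < u0 < W and 0 < v0 < H):
            raise ValueError("principal point must lie inside the image")


@dataclass
class TrackerConfig:
    """Two-stage matcher parameters.

    gate_factor      : stage-1 gate radius = gate_factor * sqrt(w*h) of the
                       candidate track's last box.
    gate_factor_s2   : stage-2 gate factor (drifted positions are less
                       certain, so the default is 1.5x the stage-1 factor).
    score_threshold  : detections below this confidence are discarded.
    ema_alpha        : EMA weight for the motion-vector estimate.
    lifespan         : initial health of a track entering the stranding area.
    stage2_enabled   : disable for the pure-greedy baseline.
    stage2_backward  : drift stranded tracks by the negated (backward) motion
                       vector instead of the forward one.
    """

    gate_factor: float = 1.0
    gate_factor_s2: float = 1.5
    score_threshold: float = 0.3
    ema_alpha: float = 0.5
    lifespan: int = 20
    stage2_enabled: bool = True
    stage2_backward: bool = False

    def validate(self) -> None:
        errs = []
        if self.lifespan < 1:
            errs.append(f"lifespan must be >= 1, got {self.lifespan}")
        if not (0.0 < self.ema_alpha <= 1.0):
            errs.append(f"ema_alpha must be in (0, 1], got {self.ema_alpha}")
        if self.gate_factor <= 0 or self.gate_factor_s2 <= 0:
            errs.append("gate factors must be positive")
        if not (0.0 <= self.score_threshold <= 1.0):
            errs.append("score_threshold must be in [0, 1]")
        if errs:
            raise ValueError("; ".join(errs))


@dataclass
class FilterConfig:
    """IMM particle-filter parameters.

    models            : model names from the registry ("cv", "ct+", "ct-",
                        "ca").
    n_particles       : particles per model.
    transition        : Markov model-transition matrix (rows sum to 1); None
                        means 0.9 self-transition, remainder uniform.
    dt                : time step (s) between observations.
    sigma_process     : process-noise scale (m/s^2 acceleration std).
    sigma_obs         : observation-noise std (m) on ground-plane position.
    turn_rate         : nominal turn rate omega0 (rad/s) of the turn models.
    init_pos_spread   : std (m) of the initial particle cloud around the
                        first observation.
    init_vel_spread   : std (m/s) of initial particle velocities about 0.
    seed              : filter random seed.
    """

    models: tuple[str, ...] = ("cv", "ct+", "ct-")
    n_particles: int = 500
    transition: Optional[list[list[float]]] = None
    dt: float = 0.1
    sigma_process: float = 0.5
    sigma_obs: float = 0.5
    turn_rate: float = 0.6
    init_pos_spread: float = 1.0
    init_vel_spread: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.n_particles < 1:
            errs.append(f"n_particles must be >= 1, got {self.n_particles}")
        if not self.models:
            errs.append("model set must be non-empty")
        if self.dt <= 0:
            errs.append("dt must be positive")
        if self.transition is not None:
            import numpy as np

            P = np.asarray(self.transition, dtype=float)
            if P.shape != (len(self.models), len(self.models)):
                errs.append(
                    f"transition matrix must be {len(self.models)}x"
                    f"{len(self.models)}, got {P.shape}"
                )
            elif not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                errs.append("transition matrix rows must sum to 1")
            elif (P < 0).any():
                errs.append("transition matrix entries must be >= 0")
        if errs:
            raise ValueError("; ".join(errs))


@dataclass
class Config:
    """Top-level configuration: tracker + filter + scenario sections."""

    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    scenario: Optional[object] = None  # simulate.ScenarioConfig when present
    paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.tracker.validate()
        self.filter.validate()
        if self.scenario is not None:
            self.scenario.validate()
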