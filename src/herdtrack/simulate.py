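"""Synthetic aerial-herd scenarios: trajectories, poses, boxes, corruption.

The generator emulates the statistical structure the tracker and filter
assume: ground-plane animal trajectories switching between straight and
coordinated-turn motion modes under a first-order Markov chain, a pinhole
camera on a hovering (or slowly translating) UAV with per-frame GPS
position jitter and INS attitude jitter, and detector-like corruption of
the rendered ground-truth boxes — center/size noise, independent missed
detections, deterministic mutual-occlusion dropouts, and Poisson false
positives with their own confidence distribution.

Three presets ship with the package:

* ``separated``  — well-spaced targets, corruption off; a tracker should
  reproduce the ground truth exactly.
* ``crossing``   — two targets converge and one is occluded (dropped) for a
  scripted, exactly-controlled number of frames around closest approach;
  the stress case for stranding-area identity recovery.
* ``maneuvering``— a single mode-switching target; the stress case for the
  multi-model filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import CameraIntrinsics, Detection, FrameTable, UAVPose
from .io import default_intrinsics

MODE_NAMES = ("straight", "turn-left", "turn-right")
_MODE_OMEGA = {0: 0.0, 1: 1.0, 2: -1.0}  # sign of turn rate per mode index


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic scenario (units in comments)."""

    n_targets: int = 6
    n_frames: int = 200
    frame_rate: float = 10.0  # Hz
    arena_size: float = 16.0  # m, square side, centered under the UAV
    footprint: tuple[float, float] = (2.4, 0.9)  # m, adult-cow scale
    speed_range: tuple[float, float] = (0.5, 2.0)  # m/s
    turn_rate: float = 0.6  # rad/s of the turn modes
    mode_switch_prob: float = 0.05  # per frame
    altitude: float = 10.0  # m AGL
    uav_velocity: tuple[float, float] = (0.0, 0.0)  # m/s north/east drift
    pos_jitter_std: float = 0.5  # m, GPS-like position error
    att_jitter_std: float = 0.01  # rad, INS-like attitude error
    center_noise_px: float = 2.0  # detector center noise
    size_noise: float = 0.05  # lognormal sigma on box size
    p_miss: float = 0.05  # independent missed-detection probability
    fp_rate: float = 0.2  # Poisson false positives per frame
    occlusion_iou: float = 0.3  # tau_occ for mutual occlusion dropout
    # Beta confidence parameters; None means a noise-free score of 1.0
    score_true: Optional[tuple[float, float]] = (8.0, 2.0)
    score_false: tuple[float, float] = (2.0, 5.0)
    scripted: Optional[str] = None  # None or "crossing"
    occlusion_gap: int = 5  # frames, scripted crossing dropout length
    seed: int = 0
    intrinsics: Optional[CameraIntrinsics] = None

    def validate(self) -> None:
        errs = []
        for name in ("mode_switch_prob", "p_miss", "occlusion_iou"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errs.append(f"{name} must be in [0, 1], got {v}")
        if self.altitude <= 0:
            errs.append("altitude must be positive")
        if self.n_frames < 1 or self.n_targets < 1:
            errs.append("n_frames and n_targets must be >= 1")
        if self.speed_range[0] < 0 or self.speed_range[1] < self.speed_range[0]:
            errs.append("speed_range must satisfy 0 <= lo <= hi")
        # targets must stay well inside the camera footprint
        intr = self.intrinsics or default_intrinsics()
        half_view = self.altitude * intr.principal_point[0] / intr.f
        if self.arena_size / 2 > 0.9 * half_view:
            errs.append(
                f"arena half-size {self.arena_size / 2:.1f} m exceeds 90% of "
                f"the half field of view {half_view:.1f} m at this altitude"
            )
        if errs:
            raise ValueError("; ".join(errs))

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def camera(self) -> CameraIntrinsics:
        return self.intrinsics or default_intrinsics()


@dataclass
class TrajectorySet:
    """Ground-truth kinematics: arrays indexed (target, frame)."""

    positions: np.ndarray  # (T, F, 2) m, north/east
    velocities: np.ndarray  # (T, F, 2) m/s
    headings: np.ndarray  # (T, F) rad
    modes: np.ndarray  # (T, F) int, index into MODE_NAMES

    @property
    def n_targets(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


@dataclass
class Scenario:
    """One fully generated scenario bundle.

    ``poses`` are the *measured* UAV poses (true pose plus GPS/INS error),
    the only pose stream a consumer of real flight data would have;
    ``poses_true`` are the exact poses the boxes were rendered with.
    """

    config: ScenarioConfig
    trajectories: TrajectorySet
    poses: list[UAVPose]
    poses_true: list[UAVPose]
    gt: FrameTable
    detections: FrameTable
    forced_drops: set = field(default_factory=set)  # {(target_id, frame)}


def simulate_targets(config: ScenarioConfig, seed: Optional[int] = None) -> TrajectorySet:
    """Markov-switched straight/turn trajectories inside the arena.

    Each target carries one motion mode per frame; modes switch with the
    configured per-frame probability.  Near the arena edge a target heading
    outward is steered back by forcing the turn mode that rotates it toward
    the center — a continuous coordinated turn, so the boundary behavior
    stays within the motion-model family.  A hard reflective clamp remains
    as a last resort for targets that reach the wall mid-turn.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T, F, dt = config.n_targets, config.n_frames, config.dt
    half = config.arena_size / 2.0
    pos = np.empty((T, F, 2))
    vel = np.empty((T, F, 2))
    hdg = np.empty((T, F))
    modes = np.empty((T, F), dtype=int)
    speeds = rng.uniform(*config.speed_range, size=T)
    pos_now = rng.uniform(-0.7 * half, 0.7 * half, size=(T, 2))
    theta = rng.uniform(-math.pi, math.pi, size=T)
    mode = rng.integers(0, 3, size=T)
    # steer away from the wall within one turn radius (plus slack)
    margins = np.minimum(speeds / max(config.turn_rate, 1e-6) + 0.5,
                         0.45 * half)
    for f in range(F):
        for t in range(T):
            if f > 0:
                if rng.uniform() < config.mode_switch_prob:
                    others = [m for m in range(3) if m != mode[t]]
                    mode[t] = others[rng.integers(0, 2)]
                x0, y0 = pos_now[t]
                near = (abs(x0) > half - margins[t]
                        or abs(y0) > half - margins[t])
                if near:
                    vx, vy = math.cos(theta[t]), math.sin(theta[t])
                    if x0 * vx + y0 * vy > 0:  # heading outward
                        cross = x0 * vy - y0 * vx
                        # rotate heading toward the center: turn-right when
                        # the center bears right of travel, else turn-left
                        mode[t] = 1 if cross > 0 else 2
                theta[t] += _MODE_OMEGA[int(mode[t])] * config.turn_rate * dt
                step = speeds[t] * dt
                x = x0 + step * math.cos(theta[t])
                y = y0 + step * math.sin(theta[t])
                if abs(x) > half:
                    theta[t] = math.pi - theta[t]
                    x = math.copysign(half, x)
                if abs(y) > half:
                    theta[t] = -theta[t]
                    y = math.copysign(half, y)
                pos_now[t] = (x, y)
            pos[t, f] = pos_now[t]
            hdg[t, f] = theta[t]
            modes[t, f] = mode[t]
            vel[t, f] = (speeds[t] * math.cos(theta[t]),
                         speeds[t] * math.sin(theta[t]))
    return TrajectorySet(pos, vel, hdg, modes)


def scripted_crossing(config: ScenarioConfig) -> tuple[TrajectorySet, set]:
    """Two targets on converging straight paths; one scripted dropout.

    Target 2 is forcibly dropped for exactly ``config.occlusion_gap``
    frames starting right after the closest approach of the two paths,
    emulating a mutual occlusion of controlled length.
    """
    F, dt = config.n_frames, config.dt
    speed = 1.5
    lateral = 0.6
    x0 = min(6.0, 0.45 * config.arena_size)
    pos = np.empty((2, F, 2))
    vel = np.empty((2, F, 2))
    hdg = np.zeros((2, F))
    hdg[1, :] = math.pi
    for f in range(F):
        t = f * dt
        pos[0, f] = (-x0 + speed * t, lateral)
        pos[1, f] = (x0 - speed * t, -lateral)
        vel[0, f] = (speed, 0.0)
        vel[1, f] = (-speed, 0.0)
    modes = np.zeros((2, F), dtype=int)
    cross_frame = int(round((x0 / speed) / dt))
    drops = {(2, cross_frame + 1 + k) for k in range(config.occlusion_gap)
             if cross_frame + 1 + k < F}
    return TrajectorySet(pos, vel, hdg, modes), drops


def simulate_uav(
    config: ScenarioConfig, seed: Optional[int] = None
) -> tuple[list[UAVPose], list[UAVPose]]:
    """Hovering/drifting UAV with GPS/INS measurement error.

    Returns ``(true_poses, measured_poses)``.  The true pose follows the
    nominal hover or drift path exactly; the measured pose adds per-frame
    Gaussian error on position (GPS) and attitude (INS).  Images form at
    the true pose but localization only ever sees the measured one — that
    mismatch is the error source the positioning filter must absorb.
    """
    config.validate()
    rng = np.random.default_rng(
        (config.seed + 1) if seed is None else seed
    )
    true_poses, meas_poses = [], []
    for f in range(config.n_frames):
        t = f * config.dt
        base = np.array([config.uav_velocity[0] * t,
                         config.uav_velocity[1] * t,
                         -config.altitude])
        jit = rng.normal(0.0, config.pos_jitter_std, size=3)
        att = rng.normal(0.0, config.att_jitter_std, size=3)
        true_poses.append(UAVPose(
            frame=f + 1, position=tuple(base),
            attitude=(0.0, 0.0, 0.0), gimbal=(0.0, -math.pi / 2.0),
        ))
        meas_poses.append(UAVPose(
            frame=f + 1, position=tuple(base + jit),
            attitude=(att[0], att[1], att[2]),
            gimbal=(0.0, -math.pi / 2.0),
        ))
    return true_poses, meas_poses


def _project_point(
    point: np.ndarray, pose: UAVPose, intr: CameraIntrinsics
) -> Optional[tuple[float, float]]:
    from .geolocation import rotation_camera_to_geographic

    v_l = point - np.asarray(pose.position)
    v_c = rotation_camera_to_geographic(pose).T @ v_l
    if v_c[2] <= 1e-9:
        return None
    u0, v0 = intr.principal_point
    return (intr.f * v_c[0] / v_c[2] + u0, intr.f * v_c[1] / v_c[2] + v0)


def render_boxes(
    traj: TrajectorySet,
    poses: list[UAVPose],
    intrinsics: CameraIntrinsics,
    footprint: tuple[float, float] = (2.4, 0.9),
) -> FrameTable:
    """Project target footprints into the image; returns id-bearing gt.

    The box center is the projection of the target's ground-center point
    (so localization round trips are exact); the box size is the extent of
    the projected footprint corners.  Targets projecting outside the image
    or behind the camera are omitted for that frame.
    """
    L, Wd = footprint
    half = np.array([[L / 2, Wd / 2], [L / 2, -Wd / 2],
                     [-L / 2, Wd / 2], [-L / 2, -Wd / 2]])
    W, H = intrinsics.image_size
    records = []
    for f in range(traj.n_frames):
        pose = poses[f]
        for t in range(traj.n_targets):
            cx, cy = traj.positions[t, f]
            th = traj.headings[t, f]
            rot = np.array([[math.cos(th), -math.sin(th)],
                            [math.sin(th), math.cos(th)]])
            corners = (half @ rot.T) + (cx, cy)
            ctr_px = _project_point(np.array([cx, cy, 0.0]), pose, intrinsics)
            if ctr_px is None or not (0 <= ctr_px[0] < W and 0 <= ctr_px[1] < H):
                continue
            pts = [_project_point(np.array([x, y, 0.0]), pose, intrinsics)
                   for x, y in corners]
            if any(p is None for p in pts):
                continue
            xs = [p[0] for p in pts]
            ys = [p[1] for p in pts]
            w = max(xs) - min(xs)
            h = max(ys) - min(ys)
            if w <= 0 or h <= 0:
                continue
            records.append(Detection(frame=f + 1, center=ctr_px,
                                     size=(w, h), score=1.0, id=t + 1))
    return FrameTable(records)


def degrade(
    gt: FrameTable,
    config: ScenarioConfig,
    seed: Optional[int] = None,
    forced_drops: Optional[set] = None,
) -> FrameTable:
    """Corrupt ground-truth boxes into detector-like, id-free detections.

    Per box: scripted forced drops, the deterministic mutual-occlusion rule
    (when two gt boxes overlap above tau_occ the higher id is dropped),
    independent misses, Gaussian center noise, lognormal size noise.
    Poisson(fp_rate) uniform false boxes are added per frame; confidences
    come from the configured Beta distributions.
    """
    from .metrics import iou as box_iou

    config.validate()
    rng = np.random.default_rng(
        (config.seed + 2) if seed is None else seed
    )
    drops = forced_drops or set()
    intr = config.camera()
    W, H = intr.image_size
    out = []
    for f in gt.frames():
        boxes = gt.in_frame(f)
        occluded = set()
        for i, a in enumerate(boxes):
            for bx in boxes[i + 1:]:
                if box_iou(a, bx) > config.occlusion_iou:
                    occluded.add(max(a.id, bx.id))
        for d in boxes:
            dropped = (
                (d.id, f) in drops
                or d.id in occluded
                or rng.uniform() < config.p_miss
            )
            if dropped:
                continue
            cx = d.center[0] + rng.normal(0.0, config.center_noise_px)
            cy = d.center[1] + rng.normal(0.0, config.center_noise_px)
            cx = min(max(cx, 0.0), W - 1e-6)
            cy = min(max(cy, 0.0), H - 1e-6)
            w = d.size[0] * rng.lognormal(0.0, config.size_noise)
            h = d.size[1] * rng.lognormal(0.0, config.size_noise)
            score = (1.0 if config.score_true is None
                     else rng.beta(*config.score_true))
            out.append(Detection(f, (cx, cy), (w, h), score, id=None))
        sizes = [b.size for b in boxes]
        mean_w = float(np.mean([s[0] for s in sizes])) if sizes else 40.0
        mean_h = float(np.mean([s[1] for s in sizes])) if sizes else 40.0
        for _ in range(rng.poisson(config.fp_rate)):
            fw = mean_w * rng.uniform(0.5, 1.5)
            fh = mean_h * rng.uniform(0.5, 1.5)
            out.append(Detection(
                f,
                (rng.uniform(0, W), rng.uniform(0, H)),
                (fw, fh),
                rng.beta(*config.score_false),
                id=None,
            ))
    return FrameTable(out)


def generate(config: ScenarioConfig) -> Scenario:
    """Run the full generator pipeline from one master seed."""
    config.validate()
    rngs = np.random.SeedSequence(config.seed).spawn(3)
    s_targets, s_uav, s_degrade = (int(r.generate_state(1)[0] % (2**31))
                                   for r in rngs)
    if config.scripted == "crossing":
        traj, drops = scripted_crossing(config)
    elif config.scripted is None:
        traj = simulate_targets(config, seed=s_targets)
        drops = set()
    else:
        raise ValueError(f"unknown scripted scenario '{config.scripted}'")
    poses_true, poses_meas = simulate_uav(config, seed=s_uav)
    gt = render_boxes(traj, poses_true, config.camera(), config.footprint)
    dets = degrade(gt, config, seed=s_degrade, forced_drops=drops)
    return Scenario(config, traj, poses_meas, poses_true, gt, dets, drops)


def truth_geo_frame(traj: TrajectorySet):
    """Ground-truth ground-plane positions as a DataFrame."""
    import pandas as pd

    rows = []
    for t in range(traj.n_targets):
        for f in range(traj.n_frames):
            rows.append(dict(
                frame=f + 1, id=t + 1,
                X=traj.positions[t, f, 0], Y=traj.positions[t, f, 1],
                Vx=traj.velocities[t, f, 0], Vy=traj.velocities[t, f, 1],
                mode=MODE_NAMES[int(traj.modes[t, f])],
            ))
    return pd.DataFrame(rows)


def preset(name: str, **overrides) -> ScenarioConfig:
    """Named scenario presets; keyword overrides are applied on top."""
    if name == "separated":
        cfg = ScenarioConfig(
            n_targets=4, n_frames=100, arena_size=14.0,
            speed_range=(0.3, 0.8), mode_switch_prob=0.02,
            pos_jitter_std=0.0, att_jitter_std=0.0,
            center_noise_px=0.0, size_noise=0.0,
            p_miss=0.0, fp_rate=0.0, occlusion_iou=1.0,
            score_true=None,
        )
    elif name == "crossing":
        cfg = ScenarioConfig(
            n_targets=2, n_frames=100, arena_size=14.0,
            scripted="crossing", occlusion_gap=5,
            pos_jitter_std=0.0, att_jitter_std=0.0,
            center_noise_px=0.0, size_noise=0.0,
            p_miss=0.0, fp_rate=0.0, occlusion_iou=1.0,
            score_true=None,
        )
    elif name == "maneuvering":
        cfg = ScenarioConfig(
            n_targets=1, n_frames=200, arena_size=14.0,
            speed_range=(0.8, 1.2), turn_rate=0.6,
            mode_switch_prob=0.04,
        )
    else:
        raise KeyError(f"unknown preset '{name}' "
                       "(available: separated, crossing, maneuvering)")
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"no scenario field '{k}'")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg
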