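"""Pixel -> line-of-sight -> ground-plane localization.

The chain back-projects a detection's box center through the pinhole model,
rotates the ray from the camera frame C through the body/IMU frame I into
the local geographic frame L (north-east-down), reads off the line-of-sight
angles (rho, epsilon), and intersects the ray with the flat ground plane at
the UAV's known altitude above ground.

Frame conventions (documented in docs/methods.md with worked matrices):

* C: z along the optical axis, x image-right, y image-down.
* I: x forward, y right, z down.  At zero gimbal angles the camera looks
  forward (optical axis = body x); pan rotates about body z, tilt about the
  panned y axis; tilt = -pi/2 is nadir.
* L: X north, Y east, Z down, ground plane at Z = 0.

rho is the angle between the ray and the +Z (down) axis, so rho = 0 means
straight down and rho >= pi/2 means the ray never reaches the ground.
epsilon is the azimuth of the ray's horizontal projection, measured from
north, positive toward east.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import CameraIntrinsics, FilterConfig, FrameTable, UAVPose
from .immpf import IMMParticleFilter

# Axis relabeling C -> I at zero gimbal: camera z -> body x (forward),
# camera x -> body y (right), camera y -> body z (down).
_CAM_TO_BODY = np.array([[0.0, 0.0, 1.0],
                         [1.0, 0.0, 0.0],
                         [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class LOSAngles:
    """Line-of-sight height angle rho and azimuth epsilon, radians."""

    rho: float
    epsilon: float


@dataclass(frozen=True)
class GroundPoint:
    x: float  # north, m
    y: float  # east, m
    valid: bool = True


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def pixel_to_los_camera(
    pixel: tuple[float, float], intrinsics: CameraIntrinsics
) -> np.ndarray:
    """Back-project a pixel to a unit line-of-sight vector in frame C."""
    xp, yp = pixel
    W, H = intrinsics.image_size
    if not (0 <= xp <= W and 0 <= yp <= H):
        raise ValueError(f"pixel {pixel} outside {W}x{H} image")
    u0, v0 = intrinsics.principal_point
    v = np.array([(xp - u0) / intrinsics.f, (yp - v0) / intrinsics.f, 1.0])
    return v / np.linalg.norm(v)


def rotation_camera_to_geographic(pose: UAVPose) -> np.ndarray:
    """Composed rotation matrix taking frame-C vectors into frame L."""
    pan, tilt = pose.gimbal
    roll, pitch, yaw = pose.attitude
    r_ci = _rot_z(pan) @ _rot_y(tilt) @ _CAM_TO_BODY
    r_il = _rot_z(yaw) @ _rot_y(pitch) @ _rot_x(roll)
    return r_il @ r_ci


def camera_to_geographic(vec: np.ndarray, pose: UAVPose) -> np.ndarray:
    """Rotate a camera-frame direction into the NED geographic frame L."""
    return rotation_camera_to_geographic(pose) @ np.asarray(vec, dtype=float)


def los_angles(vec: np.ndarray) -> LOSAngles:
    """Line-of-sight angles of a unit direction in frame L.

    rho = arccos(v_Z); epsilon = atan2(v_Y, v_X), 0 at a nadir ray by
    convention (the azimuth is then undefined).
    """
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    v = v / n
    rho = math.acos(max(-1.0, min(1.0, v[2])))
    if abs(v[0]) < 1e-15 and abs(v[1]) < 1e-15:
        return LOSAngles(rho=rho, epsilon=0.0)
    return LOSAngles(rho=rho, epsilon=math.atan2(v[1], v[0]))


def ray_ground_intersect(
    pose: UAVPose, vec: np.ndarray, ground_z: float = 0.0
) -> GroundPoint:
    """Intersect a frame-L ray from the UAV with the flat ground plane.

    Returns an invalid point (flag False, not an exception) when the ray
    does not descend (rho >= pi/2).
    """
    h = ground_z - pose.position[2]
    if h <= 0:
        raise ValueError("UAV must be above the ground plane")
    v = np.asarray(vec, dtype=float)
    if v[2] <= 0:
        return GroundPoint(math.nan, math.nan, valid=False)
    t = h / v[2]
    return GroundPoint(pose.position[0] + t * v[0],
                       pose.position[1] + t * v[1], valid=True)


def pixel_to_ground(
    pixel: tuple[float, float],
    pose: UAVPose,
    intrinsics: CameraIntrinsics,
) -> GroundPoint:
    """Full chain for one pixel: back-project, rotate, intersect."""
    v_c = pixel_to_los_camera(pixel, intrinsics)
    v_l = camera_to_geographic(v_c, pose)
    return ray_ground_intersect(pose, v_l)


def localize_track(
    tracks: FrameTable,
    poses: list[UAVPose],
    intrinsics: CameraIntrinsics,
    filter_config: Optional[FilterConfig] = None,
    use_filter: bool = True,
):
    """Geolocate every identity in a tracker-output table.

    Each box center is mapped to a raw ground observation; per identity an
    IMM particle filter consumes the observation sequence in frame order
    and emits fused estimates.  Frames whose ray misses the ground produce
    no observation and the filter coasts.  With ``use_filter=False`` the raw
    per-frame intersections are returned unfiltered.

    Returns a pandas DataFrame with columns
    frame, id, X, Y, Vx, Vy, valid [, mu_<model>...].
    """
    import pandas as pd

    pose_by_frame = {p.frame: p for p in poses}
    cfg = filter_config or FilterConfig()
    rows = []
    for tid, dets in sorted(tracks.by_id().items()):
        pf = IMMParticleFilter(
            FilterConfig(**{**cfg.__dict__, "seed": cfg.seed + tid})
        ) if use_filter else None
        prev_frame = None
        for det in dets:
            if det.frame not in pose_by_frame:
                raise ValueError(f"no UAV pose for frame {det.frame}")
            pose = pose_by_frame[det.frame]
            gp = pixel_to_ground(det.center, pose, intrinsics)
            if not use_filter:
                rows.append(dict(frame=det.frame, id=tid, X=gp.x, Y=gp.y,
                                 Vx=math.nan, Vy=math.nan, valid=gp.valid))
                continue
            # Coast through skipped frames (gaps or invalid intersections).
            if prev_frame is not None:
                for _ in range(det.frame - prev_frame - 1):
                    pf.predict()
            if gp.valid:
                est = pf.step(np.array([gp.x, gp.y]))
            else:
                est = pf.predict()
            prev_frame = det.frame
            if est is None:
                continue
            row = dict(frame=det.frame, id=tid,
                       X=float(est.fused[0]), Y=float(est.fused[1]),
                       Vx=float(est.fused[2]), Vy=float(est.fused[3]),
                       valid=gp.valid)
            for name, mu in zip(cfg.models, est.model_probs):
                row[f"mu_{name}"] = float(mu)
            rows.append(row)
    return pd.DataFrame(rows)
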