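"""Motion-model registry for the IMM particle filter.

State is ground-plane position and velocity ``(X, Y, Vx, Vy)`` in meters /
meters-per-second (frame L, north-east axes).  Each model carries a linear
state transition F, a noise-input matrix G driven by white acceleration, a
(linear by default) observation map H onto ground-plane position, and
Gaussian process / observation noise densities.

Registered names: ``cv`` (nearly-constant velocity), ``ct+`` / ``ct-``
(coordinated turns at +/- omega0), ``ca`` (constant-acceleration surrogate:
CV with inflated process noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class MotionModel:
    """One dynamic hypothesis: x' = F x + G u,  z = H x + v."""

    name: str
    F: np.ndarray
    G: np.ndarray
    H: np.ndarray
    sigma_process: float
    sigma_obs: float

    @property
    def state_dim(self) -> int:
        return self.F.shape[0]

    @property
    def obs_dim(self) -> int:
        return self.H.shape[0]

    def sample_process_noise(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n samples of the white-acceleration input u, shape (n, u_dim)."""
        return rng.normal(0.0, self.sigma_process, size=(n, self.G.shape[1]))

    def observe(self, states: np.ndarray) -> np.ndarray:
        """Map states (n, dim) to predicted observations (n, obs_dim)."""
        return states @ self.H.T

    def obs_logpdf(self, residuals: np.ndarray) -> np.ndarray:
        """Log density of the observation noise at each residual row."""
        s2 = self.sigma_obs**2
        d = residuals.shape[1]
        return (-0.5 * np.sum(residuals**2, axis=1) / s2
                - 0.5 * d * np.log(2.0 * np.pi * s2))


def _cv_matrices(dt: float) -> tuple[np.ndarray, np.ndarray]:
    F = np.array([[1, 0, dt, 0],
                  [0, 1, 0, dt],
                  [0, 0, 1, 0],
                  [0, 0, 0, 1]], dtype=float)
    G = np.array([[dt**2 / 2, 0],
                  [0, dt**2 / 2],
                  [dt, 0],
                  [0, dt]], dtype=float)
    return F, G


def _ct_matrices(dt: float, omega: float) -> tuple[np.ndarray, np.ndarray]:
    # Exact coordinated-turn transition for turn rate omega.
    s, c = np.sin(omega * dt), np.cos(omega * dt)
    F = np.array([[1, 0, s / omega, -(1 - c) / omega],
                  [0, 1, (1 - c) / omega, s / omega],
                  [0, 0, c, -s],
                  [0, 0, s, c]], dtype=float)
    _, G = _cv_matrices(dt)
    return F, G


_H_POS = np.array([[1.0, 0.0, 0.0, 0.0],
                   [0.0, 1.0, 0.0, 0.0]])


def make_model(
    name: str,
    dt: float,
    sigma_process: float,
    sigma_obs: float,
    turn_rate: float = 0.4,
) -> MotionModel:
    """Build a registered motion model by name."""
    if name == "cv":
        F, G = _cv_matrices(dt)
        return MotionModel("cv", F, G, _H_POS, sigma_process, sigma_obs)
    if name == "ca":
        F, G = _cv_matrices(dt)
        return MotionModel("ca", F, G, _H_POS, 3.0 * sigma_process, sigma_obs)
    if name in ("ct+", "ct-"):
        omega = turn_rate if name == "ct+" else -turn_rate
        if abs(omega) < 1e-12:
            raise ValueError("turn model requires a nonzero turn rate")
        F, G = _ct_matrices(dt, omega)
        return MotionModel(name, F, G, _H_POS, sigma_process, sigma_obs)
    raise KeyError(f"unknown motion model '{name}' "
                   "(registered: cv, ca, ct+, ct-)")
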