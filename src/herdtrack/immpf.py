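"""Interacting-multiple-model particle filter (IMM-PF).

One particle set per motion model; each recursion step runs

1. *interact* — per-particle mixing of model-conditioned states with the
   Markov mixing weights mu(i|j) = p[i,j] mu[i] / b[j],
   b[j] = sum_i p[i,j] mu[i];
2. *propagate and weight* — particles pushed through each model's dynamics
   with sampled process noise, weighted by the observation-noise density of
   the residual, weights normalized per model;
3. *resample* — systematic resampling per model back to uniform 1/N
   weights; the per-model estimate is the resampled-particle mean;
4. *model-probability update* — pooled residual covariance S per model,
   model likelihood = mean Gaussian density N(r; 0, S) over particles,
   mu[j] <- Lambda[j] b[j] / B with B the normalizer;
5. *fuse* — overall estimate = sum_j mu[j] * estimate[j].

Randomness: one seeded generator per filter with independent sub-streams
per model (and one for resampling), so adding a model never perturbs the
draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import FilterConfig
from .models import MotionModel, make_model


@dataclass
class ModelUpdateReport:
    """Diagnostics of one recursion step."""

    b: np.ndarray  # interaction normalization factors, per model
    likelihoods: np.ndarray  # Lambda per model
    B: float  # overall normalizer sum(Lambda * b)
    mean_predicted_obs: np.ndarray  # z-bar per model, (M, obs_dim)
    residual_cov: np.ndarray  # S per model, (M, obs_dim, obs_dim)
    weight_collapse: list[str] = field(default_factory=list)
    likelihood_collapse: bool = False


@dataclass
class StateEstimate:
    fused: np.ndarray  # (state_dim,)
    per_model: np.ndarray  # (M, state_dim)
    model_probs: np.ndarray  # (M,)


class IMMState:
    """Particle sets, weights and model probabilities at one time index."""

    def __init__(
        self,
        models: Sequence[MotionModel],
        transition: np.ndarray,
        particles: np.ndarray,
        weights: np.ndarray,
        model_probs: np.ndarray,
        k: int = 0,
    ) -> None:
        self.models = list(models)
        self.transition = np.asarray(transition, dtype=float)
        self.particles = np.asarray(particles, dtype=float)  # (M, N, dim)
        self.weights = np.asarray(weights, dtype=float)  # (M, N)
        self.model_probs = np.asarray(model_probs, dtype=float)  # (M,)
        self.k = k
        self.check()

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_particles(self) -> int:
        return self.particles.shape[1]

    def check(self, atol: float = 1e-9) -> None:
        M = self.n_models
        if self.transition.shape != (M, M):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=atol):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=atol):
            raise ValueError("per-model particle weights must sum to 1")
        if not np.isclose(self.model_probs.sum(), 1.0, atol=atol):
            raise ValueError("model probabilities must sum to 1")


class DegenerateProbabilityError(RuntimeError):
    pass


def interact(state: IMMState) -> tuple[IMMState, np.ndarray]:
    """Mix per-model particle states with the Markov mixing weights.

    Returns the mixed state and the normalization factors b (one per
    target model).  A single-model state passes through unchanged.
    """
    M = state.n_models
    P, mu = state.transition, state.model_probs
    b = P.T @ mu  # b[j] = sum_i P[i, j] mu[i]
    reachable = P.max(axis=0) > 0
    if np.any((b <= 0) & reachable & (mu.sum() > 0)) and M > 1:
        bad = [state.models[j].name for j in range(M) if b[j] <= 0]
        if bad:
            raise DegenerateProbabilityError(
                f"zero interaction probability for models {bad}"
            )
    if M == 1:
        return state, np.ones(1)
    mixing = (P * mu[:, None]) / np.where(b > 0, b, 1.0)[None, :]  # (i, j)
    # mixed particle l of model j = sum_i x^l(i) * mixing[i, j]
    mixed = np.einsum("ind,ij->jnd", state.particles, mixing)
    out = IMMState(state.models, P, mixed, state.weights.copy(), mu, state.k)
    return out, b


def propagate_and_weight(
    state: IMMState,
    observation: np.ndarray,
    rng_per_model: Sequence[np.random.Generator],
) -> tuple[IMMState, list[str]]:
    """Push particles through each model's dynamics and reweight.

    Raw weights are the observation-noise density at the residual
    z - H(x); they are normalized per model.  A model whose raw weights
    all vanish (or go non-finite) is reset to uniform and flagged.
    """
    z = np.asarray(observation, dtype=float)
    collapsed: list[str] = []
    parts = np.empty_like(state.particles)
    weights = np.empty_like(state.weights)
    for m, model in enumerate(state.models):
        x = state.particles[m]
        u = model.sample_process_noise(x.shape[0], rng_per_model[m])
        xk = x @ model.F.T + u @ model.G.T
        logw = model.obs_logpdf(z[None, :] - model.observe(xk))
        top = np.max(logw)
        # raw (unshifted) densities all underflow to zero, or go non-finite:
        # the weight-collapse condition -> uniform reset, flagged
        if not np.isfinite(top) or top < -700.0:
            collapsed.append(model.name)
            w = np.full(x.shape[0], 1.0 / x.shape[0])
        else:
            w = np.exp(logw - top)  # shift for numerical stability
            w = w / w.sum()
        parts[m] = xk
        weights[m] = w
    out = IMMState(state.models, state.transition, parts, weights,
                   state.model_probs, state.k)
    return out, collapsed


def systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Systematic resampling: indices drawn at (l + u)/N on the weight CDF."""
    n = weights.shape[0]
    positions = (np.arange(n) + rng.uniform()) / n
    cumsum = np.cumsum(weights)
    cumsum[-1] = 1.0  # guard against roundoff
    return np.searchsorted(cumsum, positions)


def resample(state: IMMState, rng: np.random.Generator) -> tuple[IMMState, np.ndarray]:
    """Per-model systematic resampling back to uniform weights.

    Returns the resampled state and the per-model estimates (means of the
    resampled particle sets).
    """
    M, N, dim = state.particles.shape
    parts = np.empty_like(state.particles)
    for m in range(M):
        idx = systematic_resample(state.weights[m], rng)
        parts[m] = state.particles[m][idx]
    weights = np.full((M, N), 1.0 / N)
    estimates = parts.mean(axis=1)
    out = IMMState(state.models, state.transition, parts, weights,
                   state.model_probs, state.k)
    return out, estimates


def update_model_probs(
    state: IMMState,
    observation: np.ndarray,
    b: np.ndarray,
    eps_scale: float = 1e-9,
) -> tuple[IMMState, ModelUpdateReport]:
    """Update model probabilities from pooled residual statistics.

    Per model: residuals r^l = z - H(x^l) over the resampled particles;
    S is the empirical covariance of the predicted observations about
    their mean *plus* the observation-noise covariance R (the residual
    contains the measurement noise, so its covariance must include R —
    without it the Gaussian likelihood underflows as soon as the particle
    cloud is tighter than the sensor noise), regularized by eps*I when
    near-singular.  Likelihood = mean Gaussian density N(r^l; 0, S); then
    mu[j] = Lambda[j] b[j] / B.  If B = 0 the probabilities are left
    unchanged and the report is flagged.
    """
    z = np.asarray(observation, dtype=float)
    M = state.n_models
    d = state.models[0].obs_dim
    lam = np.empty(M)
    zbars = np.empty((M, d))
    covs = np.empty((M, d, d))
    for m, model in enumerate(state.models):
        zpred = model.observe(state.particles[m])  # (N, d)
        zbar = zpred.mean(axis=0)
        dev = zpred - zbar
        S = dev.T @ dev / zpred.shape[0] + model.sigma_obs**2 * np.eye(d)
        # Eq for the likelihood needs S invertible; add a trace-scaled ridge.
        ridge = eps_scale * max(np.trace(S), 1.0) / d
        if np.linalg.matrix_rank(S) < d or np.linalg.cond(S) > 1e12:
            S = S + ridge * np.eye(d)
        r = z[None, :] - zpred
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            S = S + max(ridge, 1e-12) * np.eye(d)
            sign, logdet = np.linalg.slogdet(S)
        Sinv = np.linalg.inv(S)
        quad = np.einsum("ni,ij,nj->n", r, Sinv, r)
        dens = np.exp(-0.5 * quad) / np.sqrt((2 * np.pi) ** d * np.exp(logdet))
        lam[m] = dens.mean()
        zbars[m] = zbar
        covs[m] = S
    B = float(np.sum(lam * b))
    report = ModelUpdateReport(b=np.asarray(b, dtype=float), likelihoods=lam,
                               B=B, mean_predicted_obs=zbars,
                               residual_cov=covs)
    if not np.isfinite(B) or B <= 0:
        report.likelihood_collapse = True
        mu = state.model_probs.copy()
    else:
        mu = lam * b / B
    out = IMMState(state.models, state.transition, state.particles,
                   state.weights, mu, state.k)
    return out, report


class IMMParticleFilter:
    """Sequential estimator over a bank of motion models.

    Feed ground-plane observations with :meth:`step`; ``predict`` coasts
    through frames with no observation (e.g. an invalid ground
    intersection).  Deterministic for a fixed config seed.
    """

    def __init__(self, config: Optional[FilterConfig] = None) -> None:
        self.config = config or FilterConfig()
        self.config.validate()
        cfg = self.config
        self.models = [
            make_model(name, cfg.dt, cfg.sigma_process, cfg.sigma_obs,
                       cfg.turn_rate)
            for name in cfg.models
        ]
        M = len(self.models)
        if cfg.transition is not None:
            self.transition = np.asarray(cfg.transition, dtype=float)
        elif M == 1:
            self.transition = np.ones((1, 1))
        else:
            self.transition = np.full((M, M), 0.1 / (M - 1))
            np.fill_diagonal(self.transition, 0.9)
        ss = np.random.SeedSequence(cfg.seed)
        children = ss.spawn(M + 1)
        self._rng_models = [np.random.default_rng(c) for c in children[:M]]
        self._rng_resample = np.random.default_rng(children[M])
        self.state: Optional[IMMState] = None
        self.last_report: Optional[ModelUpdateReport] = None

    def initialize(self, observation: np.ndarray) -> StateEstimate:
        """Seed particle clouds around the first position observation."""
        cfg = self.config
        z = np.asarray(observation, dtype=float)
        M, N = len(self.models), cfg.n_particles
        parts = np.empty((M, N, 4))
        for m in range(M):
            rng = self._rng_models[m]
            parts[m, :, 0] = z[0] + rng.normal(0, cfg.init_pos_spread, N)
            parts[m, :, 1] = z[1] + rng.normal(0, cfg.init_pos_spread, N)
            parts[m, :, 2] = rng.normal(0, cfg.init_vel_spread, N)
            parts[m, :, 3] = rng.normal(0, cfg.init_vel_spread, N)
        weights = np.full((M, N), 1.0 / N)
        mu = np.full(M, 1.0 / M)
        self.state = IMMState(self.models, self.transition, parts, weights, mu)
        est = parts.mean(axis=1)
        return StateEstimate(fused=(mu @ est), per_model=est, model_probs=mu)

    def step(self, observation: np.ndarray) -> StateEstimate:
        """One full recursion; initializes on the first observation."""
        if self.state is None:
            return self.initialize(observation)
        st = self.state
        st.k += 1
        mixed, b = interact(st)
        prop, collapsed = propagate_and_weight(
            mixed, observation, self._rng_models
        )
        res, estimates = resample(prop, self._rng_resample)
        updated, report = update_model_probs(res, observation, b)
        report.weight_collapse = collapsed
        self.state = updated
        self.last_report = report
        mu = updated.model_probs
        return StateEstimate(fused=(mu @ estimates), per_model=estimates,
                             model_probs=mu)

    def predict(self) -> Optional[StateEstimate]:
        """Coast one step without an observation (no reweighting)."""
        if self.state is None:
            return None
        st = self.state
        st.k += 1
        mixed, _ = interact(st)
        parts = np.empty_like(mixed.particles)
        for m, model in enumerate(self.models):
            x = mixed.particles[m]
            u = model.sample_process_noise(x.shape[0], self._rng_models[m])
            parts[m] = x @ model.F.T + u @ model.G.T
        self.state = IMMState(st.models, st.transition, parts,
                              mixed.weights, st.model_probs, st.k)
        estimates = parts.mean(axis=1)
        mu = st.model_probs
        return StateEstimate(fused=(mu @ estimates), per_model=estimates,
                             model_probs=mu)

    @property
    def map_model(self) -> str:
        """Name of the currently most probable motion model."""
        if self.state is None:
            raise RuntimeError("filter not initialized")
        return self.models[int(np.argmax(self.state.model_probs))].name
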