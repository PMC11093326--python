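# Methods

This note documents the models and procedures implemented in `herdtrack`,
the parameter defaults and why they were chosen, the numerical choices
that matter, and what the synthetic validation scenarios do and do not
establish about real aerial footage.

## Coordinate conventions

* **Image**: origin top-left, x rightward, y downward; boxes are half-open
  `[left, left+w) × [top, top+h)`, stored in memory as center + size and on
  disk as MOTChallenge `(left, top, w, h)` rows.
* **Ground frame L** (north-east-down): X north, Y east, Z down; the ground
  plane is `Z = 0`, so a UAV at 10 m AGL has `Z = −10`.
* **Body/IMU frame I**: x forward, y right, z down. **Camera frame C**:
  z along the optical axis, x image-right, y image-down. At zero gimbal
  angles the camera looks forward; pan rotates about body z, tilt about the
  panned y axis, so tilt = −π/2 is nadir.
* Composed direction transform: `v_L = Rz(yaw)·Ry(pitch)·Rx(roll) ·
  Rz(pan)·Ry(tilt)·M · v_C`, with `M` the fixed axis relabeling
  (camera z → body x, camera x → body y, camera y → body z). At nadir with
  zero yaw, image-right maps to east and image-up to north.
* Line-of-sight angles: ρ = arccos(v_Z) (0 = straight down; the ray misses
  the ground when ρ ≥ π/2) and ε = atan2(v_Y, v_X), the azimuth from north.
  A nadir ray has undefined azimuth; ε = 0 is returned by convention.

Lever arms between the camera, IMU and GPS origins are neglected
(centimeter offsets against a 10 m altitude); a config hook can add them
later. Terrain is flat at a known altitude above ground — a pasture
assumption; no DEM support.

## Two-stage association

Tracking-by-detection with greedy nearest-neighbor association:

1. Detections below the score threshold (default 0.3) are discarded.
2. **Stage 1**: remaining detections, highest confidence first, each take
   the nearest active track predicted at `last_center + velocity·Δframes`,
   within a gate of radius `κ·√(w·h)` of the track's last box (κ = 1).
3. Unmatched tracks enter the **stranding area** with health = L0 = 20.
   The lifespan default follows the observation that most occlusions in
   overhead herd footage resolve within about 20 frames. Health decrements
   by 1 per frame with no replenishment (the simplest monotone decay);
   expired tracks are terminated and their ids never reused.
4. **Stage 2**: leftover detections are matched against stranded tracks at
   their drifted positions with the wider gate `1.5κ·√(w·h)` (drifted
   positions are less certain). A match restores the track, and its
   original identity, to the active set.
5. Leftover detections found new tracks with fresh, strictly increasing
   ids. Finally every stranded track drifts by its frozen motion vector
   and ages by one frame.

The motion vector is an exponential moving average (α = 0.5) of observed
per-frame center displacements, **seeded with the first displacement** so a
constant displacement sequence is a fixed point for any α, and frozen when
the track strands. The backward vector is its negation; stage-2 drift uses
the forward vector by default (`stage2_backward` switches it, since either
reading is defensible). Exact distance ties resolve to the lower track id
for determinism. Tracks are emitted from their first frame — no n-hit
confirmation. With stage 2 disabled (`--disable-stage2`), unmatched tracks
terminate immediately: the pure-greedy baseline used for comparisons.

Per-frame conservation holds by construction: every retained detection is
a stage-1 match, a stage-2 match, or a new track.

## IMM particle filter

State x = (X, Y, Vx, Vy) in ground meters; observation z = (X, Y), making
H linear for all registered models (an angle-observation H can be plugged
into the registry). Model registry:

| name | dynamics | notes |
|------|----------|-------|
| `cv` | nearly-constant velocity | F the standard CV matrix |
| `ct+`, `ct-` | coordinated turn at ±ω₀ | exact CT transition, ω₀ default 0.6 rad/s |
| `ca` | CV with 3× process noise | cheap constant-acceleration surrogate |

Defaults: N = 500 particles per model; Markov transition matrix 0.9
self-transition, remainder uniform; process noise σ_u = 0.5 m/s² white
acceleration through `G = [dt²/2, dt]`; observation noise σ_v = 0.5 m
(matching GPS-dominated localization error at 10 m altitude); initial
particles Gaussian around the first observation (σ_pos = 1 m) with
velocities ~ N(0, 2 m/s) — wide enough to cover walking-to-trotting animal
speeds; μ₀ uniform.

One recursion step: per-particle mixing with weights
μ(i|j) = p(i,j)·μ(i)/b(j), b(j) = Σᵢ p(i,j)·μ(i) (the mixing sum includes
the self term — the only reading consistent with the normalization);
propagation and likelihood weighting; **systematic** resampling per model,
unconditionally every step, back to uniform 1/N weights;
model-probability update; fused output
x̂ = Σ_m x̂(m)·μ(m) with x̂(m) the resampled-particle mean.

Numerical choices:

* Likelihood weights are computed in log space and shifted by their
  maximum before exponentiation. If the *unshifted* maximum log-density is
  non-finite or below −700 (i.e. every raw density underflows to zero),
  the model's weights reset to uniform and the step is flagged — the
  weight-collapse condition.
* The residual covariance used in the model-probability update is
  S = (empirical covariance of predicted observations about their mean)
  **+ R**, R = σ_v²·I. The residual z − H(x) contains the measurement
  noise, so its covariance must include R; omitting it makes every model
  likelihood underflow as soon as the resampled cloud is tighter than the
  sensor noise, and the model probabilities then flip chaotically. S is
  additionally ridge-regularized by 1e-9·trace(S)/dim when near-singular.
* S is pooled over particles (one covariance per model), not per-particle.
* If the total normalizer B = Σ Λ(m)b(m) is zero, model probabilities are
  left unchanged and the report flags the collapse.
* Randomness: one `SeedSequence` per filter, spawned into independent
  per-model streams plus one resampling stream, so changing the model set
  never perturbs the other models' draws. Identical config + seed gives
  bit-identical estimates.

Frames with no usable observation (occluded target, ray above the
horizon) are coasted: mixing + propagation without reweighting.

## Geolocation chain

box center → unit ray in C (pinhole back-projection, normalized) → rotate
to L → intersect `Z = 0`: t = h/v_Z, point = (X + t·v_X, Y + t·v_Y). Rays
with ρ ≥ π/2 yield an invalid point (a flag, not an exception) and the
filter coasts. With exact poses the chain inverts the simulator's
projection to machine precision (the round-trip tests assert < 1e-6 m;
observed ~1e-15 m). Each identity gets its own filter instance with a
per-id derived seed.

## Synthetic scenarios

The generator emulates the statistical structure the tracker and filter
assume, not appearance: no pixels are rendered, boxes are projected
footprint rectangles (default 2.4 m × 0.9 m, adult-cow scale, giving
~50–80 px boxes at the default 10 m altitude and 90° field of view).

* **Trajectories**: per-target first-order Markov chain over
  {straight, turn-left, turn-right}; speed fixed per target, drawn from
  0.5–2.0 m/s (grazing-to-walking); switch probability 0.05/frame at
  10 Hz. Near the arena edge an outward-heading target is steered back by
  forcing the turn mode that rotates it toward the center: a continuous
  coordinated turn that stays inside the motion-model family (animals veer
  from fences, they do not bounce). A hard reflective clamp remains as a
  last resort; instantaneous reversals are unrepresentable by any model in
  the registry and would dominate filter error.
* **UAV**: nominal hover (or linear drift) at 10 m; the *measured* pose
  adds Gaussian GPS error (σ = 0.5 m) and INS attitude error
  (σ = 0.01 rad) to the true pose. Boxes form at the true pose;
  localization only sees the measured pose — rendering and inverting
  through the same pose would cancel the error exactly.
* **Ground truth**: the box center is the projection of the target's
  ground center (so localization round trips are exact); the box size is
  the projected-footprint-corner extent. The two differ by sub-pixel
  perspective terms only.
* **Corruption**: independent misses (p = 0.05); deterministic mutual
  occlusion — when two gt boxes overlap above IoU 0.3 the higher id is
  dropped (a nadir camera gives no depth ordering between ground animals,
  and determinism aids testing); Gaussian center noise (2 px); lognormal
  size noise (σ = 0.05); Poisson false positives (0.2/frame) sized like
  real boxes; confidences Beta(8,2) for true and Beta(2,5) for false
  boxes (arbitrary but configurable; `None` gives noise-free scores).

Presets: `separated` (4 well-spaced targets, corruption off — a correct
tracker must reproduce the ground truth exactly), `crossing` (two
converging targets, one force-dropped for exactly `occlusion_gap` frames
at closest approach — the identity-recovery stress case; a scripted drop
is used because making the geometric IoU rule last an exact number of
frames is brittle), `maneuvering` (one mode-switching target at
0.8–1.2 m/s with 0.6 rad/s turns — the multi-model stress case).

What passing these scenarios does **not** show: robustness to detector
appearance failures (the score model is an abstraction), camera motion
beyond slow drift, non-flat terrain, herd-density regimes where occlusion
is the norm rather than an event, or any claim about a specific real
dataset.

## Evaluation protocol

CLEAR-MOT at IoU gate 0.5: per frame, correspondences persisting from the
previous frame are kept while their IoU clears the gate; the remainder is
assigned by maximizing total IoU (Hungarian); unmatched gt → FN, unmatched
hypotheses → FP; an id switch is counted when a gt's matched hypothesis id
differs from its *last* matched id, including across fully-unmatched gaps.
MOTP is reported on the IoU scale in [0,1] (printed as a percentage).
IDF1 comes from one global gt-id/hypothesis-id assignment maximizing the
per-frame agreement count. MT ≥ 0.8 tracked fraction, ML < 0.2. FM counts
*interruptions*: maximal unmatched gaps strictly inside a gt trajectory
with matched frames on both sides (definitions vary across papers; this
one is stated explicitly). The whole suite is verified count-for-count
against a brute-force exhaustive-assignment oracle on random small scenes.

## Problem sizes

The shipped validation runs use 100–200-frame scenarios with 1–8 targets,
20-seed replications for stochastic comparisons, N = 500–2000 particles,
and a 50-step linear-Gaussian sequence for the Kalman-limit check —
sizes at which every reported comparison is stable across seeds while the
whole suite stays fast enough to run routinely.

## Known limitations

* The original association design this follows used a learned
  bi-directional displacement head; the EMA motion vector preserves the
  interface but is weaker for erratic motion, and there is no appearance
  or re-identification cue — two animals that swap positions inside one
  occlusion gap will swap identities.
* Health decays linearly; no replenishment on near misses.
* The filter's observation is the ground-plane position, so observation
  noise is treated as isotropic even though attitude error grows with the
  off-nadir angle.
* Boundary steering means arena edges mildly bias long trajectories
  toward turning modes.
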