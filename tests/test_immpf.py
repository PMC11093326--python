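"""IMM particle filter: mixing arithmetic, resampling, normalization,
Kalman limit and mode identification."""

import numpy as np
import pytest

from herdtrack.datamodel import FilterConfig
from herdtrack.immpf import (
    IMMParticleFilter,
    IMMState,
    interact,
    propagate_and_weight,
    resample,
    systematic_resample,
    update_model_probs,
)
from herdtrack.models import make_model

from .oracles import kalman_filter


def two_model_state(n=4, seed=0):
    rng = np.random.default_rng(seed)
    models = [make_model("cv", 0.1, 0.5, 0.5),
              make_model("ct+", 0.1, 0.5, 0.5, turn_rate=0.6)]
    parts = rng.normal(0, 1, size=(2, n, 4))
    weights = np.full((2, n), 1.0 / n)
    P = np.array([[0.9, 0.1], [0.1, 0.9]])
    return IMMState(models, P, parts, weights, np.array([0.5, 0.5]))


class TestInteract:
    def test_identity_transition_is_noop(self):
        st = two_model_state()
        st.transition = np.eye(2)
        mixed, b = interact(st)
        np.testing.assert_allclose(mixed.particles, st.particles)
        np.testing.assert_allclose(b, [0.5, 0.5])

    def test_single_model_passthrough(self):
        m = [make_model("cv", 0.1, 0.5, 0.5)]
        st = IMMState(m, np.ones((1, 1)), np.zeros((1, 3, 4)),
                      np.full((1, 3), 1 / 3), np.ones(1))
        mixed, b = interact(st)
        assert mixed is st
        np.testing.assert_allclose(b, [1.0])

    def test_symmetric_mixing_arithmetic(self):
        # p = [[.9,.1],[.1,.9]], mu = (.5,.5): b = (.5,.5) and the mixing
        # weight columns are (.9,.1) and (.1,.9).
        st = two_model_state()
        mixed, b = interact(st)
        np.testing.assert_allclose(b, [0.5, 0.5])
        expected0 = 0.9 * st.particles[0] + 0.1 * st.particles[1]
        np.testing.assert_allclose(mixed.particles[0], expected0)


class TestPropagateAndWeight:
    def test_zero_noise_is_pure_linear_push(self):
        models = [make_model("cv", 0.1, 0.0, 0.5)]
        parts = np.arange(8, dtype=float).reshape(1, 2, 4)
        st = IMMState(models, np.ones((1, 1)), parts,
                      np.full((1, 2), 0.5), np.ones(1))
        rng = [np.random.default_rng(0)]
        out, collapsed = propagate_and_weight(st, np.zeros(2), rng)
        np.testing.assert_allclose(out.particles[0],
                                   parts[0] @ models[0].F.T)
        assert not collapsed

    def test_zero_residual_particle_gets_max_weight(self):
        models = [make_model("cv", 0.1, 0.0, 0.5)]
        parts = np.array([[[0.0, 0, 0, 0], [5.0, 5, 0, 0]]])
        st = IMMState(models, np.ones((1, 1)), parts,
                      np.full((1, 2), 0.5), np.ones(1))
        out, _ = propagate_and_weight(st, np.zeros(2),
                                      [np.random.default_rng(0)])
        assert out.weights[0, 0] > out.weights[0, 1]

    def test_weights_normalized_per_model(self):
        st = two_model_state(n=50)
        out, _ = propagate_and_weight(
            st, np.array([0.3, -0.2]),
            [np.random.default_rng(i) for i in range(2)])
        np.testing.assert_allclose(out.weights.sum(axis=1), [1.0, 1.0],
                                   rtol=1e-12)

    def test_weight_collapse_resets_uniform_and_flags(self):
        # an observation absurdly far from every particle underflows
        models = [make_model("cv", 0.1, 0.0, 1e-6)]
        parts = np.zeros((1, 4, 4))
        st = IMMState(models, np.ones((1, 1)), parts,
                      np.full((1, 4), 0.25), np.ones(1))
        out, collapsed = propagate_and_weight(
            st, np.array([1e9, 1e9]), [np.random.default_rng(0)])
        assert collapsed == ["cv"]
        np.testing.assert_allclose(out.weights[0], 0.25)


class TestResample:
    def test_uniform_weights_preserve_multiset(self):
        w = np.full(8, 1 / 8)
        idx = systematic_resample(w, np.random.default_rng(3))
        assert sorted(idx) == list(range(8))

    def test_degenerate_weight_copies_winner(self):
        w = np.zeros(6)
        w[2] = 1.0
        idx = systematic_resample(w, np.random.default_rng(0))
        assert (idx == 2).all()

    def test_post_weights_uniform_and_estimate_is_mean(self):
        st = two_model_state(n=32)
        st.weights = np.tile(np.random.default_rng(1).dirichlet(np.ones(32)),
                             (2, 1))
        out, est = resample(st, np.random.default_rng(0))
        np.testing.assert_allclose(out.weights, 1 / 32)
        np.testing.assert_allclose(est, out.particles.mean(axis=1))


class TestModelProbUpdate:
    def test_equal_likelihood_equal_b_leaves_mu(self):
        st = two_model_state(n=64, seed=1)
        st.particles[1] = st.particles[0]  # identical clouds -> equal Lambda
        out, rep = update_model_probs(st, np.zeros(2), np.array([0.5, 0.5]))
        np.testing.assert_allclose(out.model_probs, [0.5, 0.5])
        assert rep.B == pytest.approx(float(np.sum(rep.likelihoods * rep.b)))

    def test_zero_likelihood_model_gets_zero_mu(self):
        st = two_model_state(n=64, seed=2)
        st.particles[1, :, :2] += 1e6  # model 2 predicts absurd positions
        out, _ = update_model_probs(st, np.zeros(2), np.array([0.5, 0.5]))
        assert out.model_probs[0] == pytest.approx(1.0)
        assert out.model_probs[1] == pytest.approx(0.0, abs=1e-12)

    def test_mu_sums_to_one(self):
        st = two_model_state(n=64, seed=3)
        out, _ = update_model_probs(st, np.array([1.0, -2.0]),
                                    np.array([0.4, 0.6]))
        assert out.model_probs.sum() == pytest.approx(1.0, rel=1e-12)


class TestFilter:
    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        zs = rng.normal(0, 1, size=(30, 2)).cumsum(axis=0)
        runs = []
        for _ in range(2):
            f = IMMParticleFilter(FilterConfig(seed=11))
            runs.append(np.array([f.step(z).fused for z in zs]))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_single_model_fusion_is_that_model(self):
        f = IMMParticleFilter(FilterConfig(models=("cv",), n_particles=100,
                                           seed=0))
        f.step(np.zeros(2))
        est = f.step(np.array([0.1, 0.1]))
        np.testing.assert_allclose(est.fused, est.per_model[0])
        assert est.model_probs == pytest.approx([1.0])

    def test_normalization_through_long_run(self):
        """Weights and model probabilities stay normalized for 500 steps."""
        f = IMMParticleFilter(FilterConfig(n_particles=60, seed=5))
        rng = np.random.default_rng(9)
        z = np.zeros(2)
        for _ in range(500):
            z = z + rng.normal(0, 0.2, 2)
            f.step(z)
            np.testing.assert_allclose(f.state.weights.sum(axis=1), 1.0,
                                       rtol=1e-12)
            assert f.state.model_probs.sum() == pytest.approx(1.0, rel=1e-12)

    def test_kalman_limit_gap_shrinks_with_particles(self):
        """Single-model linear-Gaussian: the PF-to-Kalman RMSE gap shrinks
        (in seed average) as the particle count grows."""
        dt, sp, so = 0.1, 0.5, 0.5
        m = make_model("cv", dt, sp, so)
        gaps = {100: [], 500: [], 2000: []}
        for seed in range(5):
            rng = np.random.default_rng(21 + seed)
            x = np.array([0.0, 0.0, 1.0, 0.5])
            xs, zs = [], []
            for _ in range(50):
                x = m.F @ x + m.G @ rng.normal(0, sp, 2)
                xs.append(x.copy())
                zs.append(m.H @ x + rng.normal(0, so, 2))
            xs = np.array(xs)
            kf = kalman_filter(m.F, m.H, m.G @ m.G.T * sp**2,
                               np.eye(2) * so**2,
                               [zs[0][0], zs[0][1], 0, 0], np.eye(4), zs)
            kf_rmse = np.sqrt(np.mean(np.sum((kf[5:, :2] - xs[5:, :2])**2, 1)))
            for n in gaps:
                f = IMMParticleFilter(FilterConfig(
                    models=("cv",), n_particles=n, seed=seed,
                    sigma_process=sp, sigma_obs=so,
                    init_pos_spread=1.0, init_vel_spread=1.0))
                pf = np.array([f.step(z).fused for z in zs])
                pf_rmse = np.sqrt(
                    np.mean(np.sum((pf[5:, :2] - xs[5:, :2])**2, 1)))
                gaps[n].append(abs(pf_rmse - kf_rmse) / kf_rmse)
        assert np.mean(gaps[2000]) < 0.15
        assert np.mean(gaps[2000]) <= np.mean(gaps[100])

    def test_map_model_tracks_true_mode(self):
        """Two-mode switching trajectory: MAP model right > 60% of steps."""
        dt, tr, v = 0.1, 1.0, 1.2
        modes = np.repeat([0, 1, 0, 1, 0, 1], 40)
        th = np.cumsum(np.where(modes == 1, tr * dt, 0.0))
        pos = np.cumsum(np.stack([v * np.cos(th), v * np.sin(th)], 1) * dt, 0)
        rng = np.random.default_rng(4)
        zs = pos + rng.normal(0, 0.3, pos.shape)
        f = IMMParticleFilter(FilterConfig(
            models=("cv", "ct+"), n_particles=500, seed=4,
            sigma_obs=0.3, turn_rate=tr))
        hits = n = 0
        for k, z in enumerate(zs):
            f.step(z)
            if k >= 20:
                hits += {"cv": 0, "ct+": 1}[f.map_model] == modes[k]
                n += 1
        assert hits / n > 0.6
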