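"""Integrator correctness, latent projections, dimensionality, fixed points."""

import numpy as np
import pytest
from scipy.optimize import brentq

from sparserank.connectivity import (
    WeightMatrix,
    build_gaussian,
    build_rank_one,
    draw_connectivity_vectors,
    draw_mask,
    sparsify,
)
from sparserank.dynamics import (
    NetworkModel,
    SimulationConfig,
    SimulationDivergence,
    Trajectory,
    draw_input_vector,
    find_fixed_point,
    latent_projections,
    participation_ratio,
    pca_alignment,
    simulate,
)


def _zero_model(N=50, tau=100.0):
    return NetworkModel(W=np.zeros((N, N)), tau=tau)


class TestSimulate:
    def test_uncoupled_autonomous_dynamics_decay_exponentially(self, rng):
        model = _zero_model()
        x0 = rng.standard_normal(50)
        traj = simulate(model, SimulationConfig(T=10 * model.tau, x0=x0))
        assert np.abs(traj.x[-1]).max() < 1e-3
        # terminal state matches the Euler-discretised exponential exactly
        dt = traj.times[1] - traj.times[0]
        n = len(traj.times) - 1
        np.testing.assert_allclose(traj.x[-1], x0 * (1 - dt / model.tau) ** n, rtol=1e-10)

    def test_subunit_spectrum_decays_to_zero(self):
        # sparse rank-one with outlier and bulk both below one: activity dies
        rng = np.random.default_rng(5)
        v = draw_connectivity_vectors(500, sigma2=0.02, sigma_mn=0.002, rng=rng)
        W = sparsify(
            build_rank_one(v, rescaled=True),
            draw_mask(500, rng, scheme="fixed_in_degree", C=100),
        )
        # lambda_1 = 0.2, R = 0.02 sqrt(100*400/500) = 0.18
        model = NetworkModel(W=W, tau=100.0)
        traj = simulate(
            model, SimulationConfig(T=30 * model.tau, x0="random", x0_scale=0.5, seed=1)
        )
        assert np.abs(traj.x[-1]).max() < 1e-3

    def test_bistable_network_reaches_opposite_fixed_points(self):
        rng = np.random.default_rng(2)
        v = draw_connectivity_vectors(1000, sigma2=2.0, sigma_mn=1.5, rng=rng)
        model = NetworkModel(W=build_rank_one(v), tau=100.0)
        up, kr_up = find_fixed_point(model, v.m, sign=+1)
        down, kr_down = find_fixed_point(model, v.m, sign=-1)
        assert kr_up > 0.1 and kr_down < -0.1
        assert kr_up == pytest.approx(-kr_down, rel=0.05)

    def test_first_order_convergence_in_dt(self):
        rng = np.random.default_rng(9)
        v = draw_connectivity_vectors(100, 2.0, 1.5, rng)
        model = NetworkModel(W=build_rank_one(v), tau=100.0)
        x0 = 0.1 * rng.standard_normal(100)

        def terminal(dt):
            cfg = SimulationConfig(T=200.0, dt=dt, x0=x0)
            return simulate(model, cfg).x[-1]

        ref = terminal(1.25)
        e_coarse = np.linalg.norm(terminal(10.0) - ref)
        e_fine = np.linalg.norm(terminal(5.0) - ref)
        assert 1.5 < e_coarse / e_fine < 3.0

    def test_dt_above_cap_rejected(self):
        with pytest.raises(ValueError):
            simulate(_zero_model(tau=100.0), SimulationConfig(T=100.0, dt=20.0))

    def test_non_finite_input_raises_divergence_error(self):
        model = NetworkModel(W=np.zeros((10, 10)), I=np.ones(10), tau=100.0)
        cfg = SimulationConfig(T=100.0, input_signal=lambda t: np.inf)
        with pytest.raises(SimulationDivergence, match="step"):
            simulate(model, cfg)

    def test_noise_is_reproducible_by_seed(self):
        model = _zero_model(N=20)
        cfg = SimulationConfig(T=200.0, noise_std=0.5, seed=4, x0="random", x0_scale=1.0)
        a = simulate(model, cfg).x
        b = simulate(model, cfg).x
        np.testing.assert_array_equal(a, b)


class TestLatentProjections:
    def test_projection_identity_along_m(self, small_vectors, rng):
        m = small_vectors.m
        I = rng.standard_normal(len(m))
        c = np.array([0.5, -1.0, 2.0])
        traj = Trajectory(times=np.arange(3.0), x=np.outer(c, m))
        lat = latent_projections(traj, m, I, small_vectors.n)
        np.testing.assert_allclose(lat.kappa_r, c, rtol=1e-12)
        np.testing.assert_allclose(lat.kappa_I, c * (I @ m) / (I @ I), rtol=1e-10)

    def test_zero_state_gives_zero_latents(self, small_vectors):
        traj = Trajectory(times=np.arange(2.0), x=np.zeros((2, 300)))
        lat = latent_projections(traj, small_vectors.m, small_vectors.n, small_vectors.n)
        assert not lat.kappa_r.any() and not lat.kappa_I.any() and not lat.kappa_rec.any()

    def test_kappa_r_equals_kappa_rec_at_equilibrium(self):
        rng = np.random.default_rng(8)
        v = draw_connectivity_vectors(2000, 2.0, 1.5, rng)
        model = NetworkModel(W=build_rank_one(v), tau=100.0)
        x_star, kr = find_fixed_point(model, v.m, sign=+1)
        traj = Trajectory(times=np.array([0.0]), x=x_star[None, :])
        lat = latent_projections(traj, v.m, None, v.n)
        assert lat.kappa_r[0] == pytest.approx(lat.kappa_rec[0], rel=1e-3)

    def test_zero_norm_vectors_rejected(self, small_vectors):
        traj = Trajectory(times=np.arange(2.0), x=np.ones((2, 300)))
        with pytest.raises(ValueError):
            latent_projections(traj, np.zeros(300), small_vectors.n, small_vectors.n)
        with pytest.raises(ValueError):
            latent_projections(traj, small_vectors.m, np.zeros(300), small_vectors.n)


class TestDimensionality:
    def test_one_dimensional_trajectory_has_unit_participation_ratio(self, rng):
        direction = rng.standard_normal(100)
        amp = rng.standard_normal(200)
        traj = Trajectory(times=np.arange(200.0), x=np.outer(amp, direction))
        assert participation_ratio(traj) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_trajectory_has_dimension_d(self, rng):
        d = 5
        x = rng.standard_normal((20_000, d))
        traj = Trajectory(times=np.arange(20_000.0), x=x)
        assert participation_ratio(traj) == pytest.approx(d, rel=0.05)

    def test_zero_variance_trajectory_rejected(self):
        traj = Trajectory(times=np.arange(3.0), x=np.ones((3, 10)))
        with pytest.raises(ValueError):
            participation_ratio(traj)

    def test_trajectory_along_m_aligns_first_component(self, small_vectors, rng):
        amp = rng.standard_normal(50)
        traj = Trajectory(times=np.arange(50.0), x=np.outer(amp, small_vectors.m))
        rep = pca_alignment(traj, small_vectors.m, k=3)
        assert rep.alignment_m[0] > 0.999
        assert rep.pca_variance_fractions[0] > 0.999

    def test_orthogonal_input_propagates_only_along_I(self):
        # sigma_nI = 0 in a dense rank-one network: the input is not picked
        # up by the recurrence; activity stays on the I axis, kappa_r ~ 0
        rng = np.random.default_rng(3)
        v = draw_connectivity_vectors(1000, 0.043, 0.0, rng)
        I = draw_input_vector(v.n, 0.0, rng, 0.043)
        model = NetworkModel(W=build_rank_one(v), I=I, tau=100.0)
        traj = simulate(
            model, SimulationConfig(T=800.0, input_signal=lambda t: 1.0)
        )
        lat = latent_projections(traj, v.m, I, v.n)
        rep = pca_alignment(traj, v.m, I, k=3)
        assert rep.alignment_I[0] > 0.95
        # terminal state has essentially no component off the I axis
        resid = traj.x[-1] - lat.kappa_I[-1] * I
        assert np.linalg.norm(resid) < 0.01 * np.linalg.norm(traj.x[-1])

    def test_dense_rank_one_input_driven_plane(self):
        # with sigma_nI = 0.2 the trajectory spans the m-I plane
        rng = np.random.default_rng(4)
        v = draw_connectivity_vectors(1000, 0.043, 0.0, rng)
        model_I = draw_input_vector(v.n, 0.2, rng, 0.043)
        model = NetworkModel(W=build_rank_one(v), I=model_I, tau=100.0)
        traj = simulate(model, SimulationConfig(T=800.0, input_signal=lambda t: 1.0))
        rep = pca_alignment(traj, v.m, model_I, k=3)
        assert rep.pca_variance_fractions[:2].sum() > 0.95
        assert rep.alignment_I[0] > 0.9

    def test_reconstruction_from_two_latents(self):
        # x(t) ~= kappa_r m + kappa_I I for dense rank-one input-driven runs
        # cross-talk between the non-orthogonal m and I projections scales
        # as ~1/sqrt(N); N = 4000 keeps it well below the 5% bound
        rng = np.random.default_rng(6)
        v = draw_connectivity_vectors(4000, 1.0, 0.0, rng)
        I = draw_input_vector(v.n, 0.3, rng, 1.0)
        model = NetworkModel(W=build_rank_one(v), I=I, tau=100.0)
        traj = simulate(model, SimulationConfig(T=1000.0, input_signal=lambda t: 1.0))
        lat = latent_projections(traj, v.m, I, v.n)
        sel = traj.times > 300.0  # post-transient
        x = traj.x[sel]
        recon = np.outer(lat.kappa_r[sel], v.m) + np.outer(lat.kappa_I[sel], I)
        err = np.linalg.norm(x - recon, axis=1) / np.linalg.norm(x, axis=1)
        assert err.max() < 0.05


class TestFixedPoint:
    def test_subcritical_network_has_only_trivial_equilibrium(self):
        rng = np.random.default_rng(1)
        v = draw_connectivity_vectors(500, 1.0, 0.5, rng)  # outlier 0.5 < 1
        model = NetworkModel(W=build_rank_one(v), tau=100.0)
        # residual state scale is tol * tau / (1 - lambda_1) ~ 2e-4
        x_star, kr = find_fixed_point(model, v.m, sign=+1)
        assert np.abs(x_star).max() < 1e-3
        assert abs(kr) < 1e-3

    def test_bistable_kappa_matches_scalar_self_consistency_root(self):
        # independent oracle: 1-D root of kappa = (1/N) sum n_j tanh(kappa m_j)
        rng = np.random.default_rng(7)
        v = draw_connectivity_vectors(1000, 2.0, 1.5, rng)
        model = NetworkModel(W=build_rank_one(v), tau=100.0)

        def F(kappa):
            return kappa - np.tanh(kappa * v.m) @ v.n / v.N

        kappa_star = brentq(F, 1e-3, 50.0)
        _, kr = find_fixed_point(model, v.m, sign=+1)
        assert kr == pytest.approx(kappa_star, rel=1e-3)

    def test_zero_direction_rejected(self):
        model = _zero_model()
        with pytest.raises(ValueError):
            find_fixed_point(model, np.zeros(50))


class TestInputVector:
    def test_overlap_and_variance_of_drawn_input(self, rng):
        N, sigma2, snI = 100_000, 0.5, 0.3
        n = draw_connectivity_vectors(N, sigma2, 0.0, rng).n
        I = draw_input_vector(n, snI, rng, sigma2)
        assert I.var() == pytest.approx(1.0, abs=0.02)
        assert n @ I / N == pytest.approx(snI, abs=3 * np.sqrt(sigma2 / N))

    def test_excessive_overlap_rejected(self, rng):
        n = rng.standard_normal(100)
        with pytest.raises(ValueError):
            draw_input_vector(n, 2.0, rng, 1.0)
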