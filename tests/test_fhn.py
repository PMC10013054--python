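import numpy as np
import pytest
from scipy.integrate import solve_ivp

from musicbrain.cochlea import InputSignal
from musicbrain.connectome import generate_synthetic_connectome
from musicbrain.fhn import (
    FHNNetwork,
    FHNParameters,
    RescaledInput,
    coupling_matrix,
    fhn_rhs,
    initial_conditions,
    natural_frequency,
    single_fhn_rhs,
)
from musicbrain.synchrony import geometric_phase, kuramoto_order


def triple_loop_rhs(state, network, params, B, input_value):
    """Naive per-node, per-neighbour evaluation of the network equations."""
    N = network.n_nodes
    u, v = state[:N], state[N:]
    A = network.adjacency
    hemi = network.hemisphere_mask
    C = network.input_mask
    du = np.empty(N)
    dv = np.empty(N)
    for k in range(N):
        su = sv = 0.0
        for j in range(N):
            w = A[k, j]
            if w == 0:
                continue
            strength = params.sigma if hemi[j] == hemi[k] else params.varsigma
            su += strength * w * (B[0, 0] * (u[j] - u[k]) + B[0, 1] * (v[j] - v[k]))
            sv += strength * w * (B[1, 0] * (u[j] - u[k]) + B[1, 1] * (v[j] - v[k]))
        du[k] = (u[k] - u[k] ** 3 / 3 - v[k] + su + C[k] * input_value) / params.epsilon
        dv[k] = u[k] + params.a + sv
    return np.concatenate([du, dv])


class TestCouplingMatrix:
    def test_zero_phase_is_identity(self):
        assert np.allclose(coupling_matrix(0.0), np.eye(2))

    def test_quarter_turn_is_pure_cross_coupling(self):
        B = coupling_matrix(np.pi / 2)
        assert np.allclose(B, [[0, 1], [-1, 0]], atol=1e-15)

    def test_default_phase_component(self):
        B = coupling_matrix(np.pi / 2 - 0.1)
        assert B[0, 0] == pytest.approx(np.sin(0.1))

    def test_rotation_properties(self):
        B = coupling_matrix(1.234)
        assert np.linalg.det(B) == pytest.approx(1.0)
        assert np.allclose(B @ B.T, np.eye(2), atol=1e-15)


class TestRHS:
    def test_matches_triple_loop_oracle(self, connectome, rng):
        params = FHNParameters()
        B = coupling_matrix(params.phi)
        for _ in range(5):
            state = rng.uniform(-2, 2, 180)
            I_val = rng.uniform(0, 1)
            fast = fhn_rhs(0.0, state, connectome, params, B, I_val)
            slow = triple_loop_rhs(state, connectome, params, B, I_val)
            np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_numba_core_matches_reference(self, connectome, rng):
        from musicbrain._integrate import fhn_rhs_flat

        params = FHNParameters()
        model = FHNNetwork(connectome, params)
        state = rng.uniform(-2, 2, 180)
        ref = fhn_rhs(0.0, state, connectome, params, input_value=0.0)
        got = fhn_rhs_flat(
            0.0, state.copy(), model.W, model.rowsum,
            model.Buu, model.Buv, model.Bvu, model.Bvv,
            params.epsilon, params.a, model.C,
            np.empty(0), 1.0, 0.0,
        )
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_decoupled_limit_is_isolated_field(self, connectome, rng):
        params = FHNParameters(sigma=0.0, varsigma=0.0)
        state = rng.uniform(-2, 2, 180)
        out = fhn_rhs(0.0, state, connectome, params)
        u, v = state[:90], state[90:]
        np.testing.assert_allclose(
            out[:90], (u - u**3 / 3 - v) / params.epsilon, atol=1e-13
        )
        np.testing.assert_allclose(out[90:], u + params.a, atol=1e-13)

    def test_coupling_vanishes_on_synchronization_manifold(self, connectome):
        params = FHNParameters()
        state = np.concatenate([np.full(90, 0.7), np.full(90, -0.3)])
        out = fhn_rhs(0.0, state, connectome, params)
        u0, v0 = 0.7, -0.3
        expected_du = (u0 - u0**3 / 3 - v0) / params.epsilon
        np.testing.assert_allclose(out[:90], expected_du, atol=1e-12)
        np.testing.assert_allclose(out[90:], u0 + params.a, atol=1e-12)

    def test_nonfinite_state_rejected(self, connectome):
        state = np.zeros(180)
        state[5] = np.nan
        with pytest.raises(FloatingPointError):
            fhn_rhs(0.0, state, connectome, FHNParameters())


class TestNaturalFrequency:
    def test_measured_values_match_independent_integrators(self, natural):
        # frozen oracle values from Radau/LSODA integration at rtol 1e-10
        omega, T = natural
        assert T == pytest.approx(2.66585, rel=2e-4)
        assert omega == pytest.approx(2.35692, rel=2e-4)
        assert omega * T == pytest.approx(2 * np.pi, rel=1e-9)

    def test_excitable_regime_rejected(self):
        with pytest.warns(UserWarning):
            params = FHNParameters(a=1.5)
        with pytest.raises(ValueError, match="excitable"):
            natural_frequency(params)

    def test_stable_across_tolerances(self):
        vals = []
        for rtol, atol in [(1e-6, 1e-8), (1e-9, 1e-11)]:
            omega, _ = natural_frequency(FHNParameters(rtol=rtol, atol=atol))
            vals.append(omega)
        assert abs(vals[0] - vals[1]) / vals[1] < 0.005


class TestRescaledInput:
    def make_signal(self, duration=1.0, rate=1000.0):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, int(duration * rate))
        vals /= vals.max()
        return InputSignal(vals, rate)

    def test_one_second_spans_T_times_nb_units(self, natural):
        _, T = natural
        sig = self.make_signal()
        drive = RescaledInput(sig, 30.0, T)
        assert drive.duration_sim == pytest.approx(30.0 * T)

    def test_zero_outside_support(self, natural):
        _, T = natural
        drive = RescaledInput(self.make_signal(), 30.0, T)
        assert drive(-1.0) == 0.0
        assert drive(drive.duration_sim + 1.0) == 0.0

    def test_max_normalized_after_decimation(self, natural):
        _, T = natural
        drive = RescaledInput(self.make_signal(), 10.0, T)
        assert drive.values.max() == pytest.approx(1.0)
        assert np.all(drive.values >= 0)

    def test_invalid_nb(self, natural):
        with pytest.raises(ValueError):
            RescaledInput(self.make_signal(), 0.0, natural[1])


class TestSimulate:
    def test_deterministic_under_seed(self, connectome, natural):
        model = FHNNetwork(connectome)
        kw = dict(n_b=30.0, seeds=3, t_transient=10.0, duration=20.0, period=natural[1])
        a = model.simulate(**kw)
        b = model.simulate(**kw)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)

    def test_trajectory_bounded(self, connectome, natural):
        model = FHNNetwork(connectome)
        traj = model.simulate(
            None, seeds=0, t_transient=50.0, duration=100.0, period=natural[1]
        )
        assert np.abs(traj.u).max() < 5 and np.abs(traj.v).max() < 5

    def test_initial_conditions_on_radius_two_circle(self):
        ic = initial_conditions(7, 90)
        r = np.hypot(ic[:90], ic[90:])
        np.testing.assert_allclose(r, 2.0, atol=1e-12)

    def test_uncoupled_nodes_run_at_natural_frequency(self, connectome, natural):
        from musicbrain.synchrony import mean_phase_velocity

        omega, T = natural
        model = FHNNetwork(connectome, FHNParameters(sigma=0.0, varsigma=0.0))
        traj = model.simulate(
            None, seeds=1, t_transient=100.0, duration=200.0, period=T
        )
        omega_k = mean_phase_velocity(traj)
        np.testing.assert_allclose(omega_k, omega, rtol=0.02)

    def test_synchronization_manifold_preserved(self, connectome, natural):
        # identical initial states for all nodes, no input: diffusive coupling
        # keeps the nodes identical up to round-off
        model = FHNNetwork(connectome)
        y0 = np.concatenate([np.full(90, 1.3), np.full(90, 0.2)])
        t_eval = np.linspace(0, 50, 200)
        out, _ = model.integrate(y0, 0.0, 50.0, t_eval, None)
        u = out[:, :90]
        v = out[:, 90:]
        assert np.abs(u - u[:, :1]).max() < 1e-6
        assert np.abs(v - v[:, :1]).max() < 1e-6

    def test_core_tracks_scipy_reference(self, connectome, natural):
        # same tolerances, same RK45 pair: trajectories must agree closely
        # over a short window
        params = FHNParameters()
        model = FHNNetwork(connectome, params)
        y0 = initial_conditions(11, 90)
        t_eval = np.linspace(0.0, 5.0, 51)
        ours, _ = model.integrate(y0, 0.0, 5.0, t_eval, None)
        B = coupling_matrix(params.phi)
        ref = solve_ivp(
            lambda t, y: fhn_rhs(t, y, connectome, params, B, 0.0),
            (0.0, 5.0),
            y0,
            method="RK45",
            rtol=params.rtol,
            atol=params.atol,
            t_eval=t_eval,
        )
        assert np.abs(ours - ref.y.T).max() < 1e-3

    def test_coupling_increases_coherence(self, natural, phase_map):
        # paired runs from identical initial conditions on a well-connected
        # surrogate: the coupled network is more coherent than the uncoupled
        # one (whose R stays frozen at the initial phase spread)
        _, T = natural
        net = generate_synthetic_connectome(
            seed=2, intra_density=0.6, inter_density=0.15, weight_sigma=0.7
        )
        uncoupled = FHNNetwork(net, FHNParameters(sigma=0.0, varsigma=0.0))
        coupled = FHNNetwork(net)
        R = {}
        for name, model in [("off", uncoupled), ("on", coupled)]:
            traj = model.simulate(
                None, seeds=5, t_transient=100.0, duration=300.0, period=T
            )
            theta = phase_map(geometric_phase(traj.u, traj.v))
            R[name] = kuramoto_order(theta).mean()
        assert R["on"] > R["off"]

    def test_duration_required_without_input(self, connectome):
        model = FHNNetwork(connectome)
        with pytest.raises(ValueError):
            model.simulate(None, seeds=0)
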