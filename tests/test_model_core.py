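"""Pendulum model: geometry, switching law, integration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm, solve_continuous_lyapunov

from swayabc import (
    ControlParams,
    PendulumPlant,
    active_control_on,
    c_on_to_slope,
    derive_com_height,
    simulate_sway,
    slope_to_c_on,
    torque_components,
)


class TestComHeight:
    @pytest.mark.parametrize("h_sub, expected", [(1.0, 0.465), (1.70, 0.850)])
    def test_anthropometric_rule(self, h_sub, expected):
        assert derive_com_height(h_sub) == pytest.approx(expected)

    def test_rejects_implausible_height(self):
        with pytest.raises(ValueError):
            derive_com_height(0.1545)  # would give non-positive COM height
        with pytest.raises(ValueError):
            derive_com_height(3.0)


class TestControlLevel:
    def test_printed_default_slope(self):
        # the default sector slope -0.4 corresponds to 62% control
        assert round(slope_to_c_on(-0.4), 2) == 0.62

    @pytest.mark.parametrize("c_on, a_s", [(0.5, 0.0), (0.75, -1.0)])
    def test_known_slopes(self, c_on, a_s):
        assert c_on_to_slope(c_on) == pytest.approx(a_s, abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, c_on):
        assert slope_to_c_on(c_on_to_slope(c_on)) == pytest.approx(c_on, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            c_on_to_slope(bad)


class TestSwitchingLaw:
    @pytest.mark.parametrize("theta_d, omega_d, expected", [
        (0.0, 0.0, False),          # both strict inequalities fail at origin
        (0.01, 0.01, True),         # sector and radius both satisfied
        (1e-3, 1e-3, False),        # inside the quiet zone (radius^2 = 2e-6)
    ])
    def test_hand_cases(self, theta_d, omega_d, expected):
        assert active_control_on(theta_d, omega_d, -0.4, 0.004) is expected

    def test_on_fraction_matches_c_on(self, rng):
        # far outside the quiet zone, the ON region is a double sector
        # occupying exactly c_on of the plane
        c_on = 0.62
        a_s = c_on_to_slope(c_on)
        ang = rng.uniform(0, 2 * np.pi, 200_000)
        R = 1.0
        hits = np.mean([active_control_on(R * math.cos(t), R * math.sin(t), a_s, 0.004)
                        for t in ang])
        assert hits == pytest.approx(c_on, abs=0.01)


class TestPlantAndParams:
    def test_inertia_and_default_stiffness(self):
        p = PendulumPlant(m=60.0, h=1.0)
        assert p.I == pytest.approx(60.0)
        assert p.K == pytest.approx(0.8 * 60.0 * 9.81 * 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            PendulumPlant(m=-1.0, h=1.0)
        with pytest.raises(ValueError):
            ControlParams(P=-5, D=10, delta=0.2, sigma=0.2, c_on=0.62)
        with pytest.raises(ValueError):
            ControlParams(P=147, D=10, delta=0.2, sigma=0.2, c_on=1.2)


class TestSimulation:
    def test_deterministic_given_seed(self, default_plant, default_params):
        a = simulate_sway(default_plant, default_params, duration=10, seed=5)[0]
        b = simulate_sway(default_plant, default_params, duration=10, seed=5)[0]
        assert np.array_equal(a.samples, b.samples)

    def test_zero_noise_zero_init_is_fixed_point(self, default_plant):
        params = ControlParams(P=147, D=10, delta=0.2, sigma=0.0, c_on=0.62)
        tr = simulate_sway(default_plant, params, duration=10, seed=0, eta=0.0)[0]
        assert np.all(tr.samples == 0.0)

    def test_overstiff_passive_decay_matches_matrix_exponential(self):
        # with K > mgh, sigma = 0 and active control forced OFF the system
        # is linear and stable; Euler at fine dt must track expm(A t) x0
        m, h = 60.0, 1.0
        plant = PendulumPlant(m=m, h=h, K=1.2 * m * 9.81 * h)
        params = ControlParams(P=147, D=10, delta=0.2, sigma=0.0, c_on=0.62)
        dt = 1e-3
        tr = simulate_sway(plant, params, duration=5.0, dt=dt, seed=0,
                           eta=0.005, force_active=-1)[0]
        state = tr.state
        A = np.array([[0.0, 1.0], [state.a, state.b]])
        t_grid = np.arange(0, 5.0, 1.0)
        for t in t_grid[1:]:
            exact = (expm(A * t) @ np.array([0.005, 0.0]))[0]
            n = int(round(t / dt))
            assert state.theta[n] == pytest.approx(exact, rel=0.02, abs=1e-6)
        assert abs(state.theta[-1]) < 0.005  # decays

    def test_default_passive_alone_falls(self, default_plant):
        # K = 0.8 mgh leaves one positive eigenvalue without active help
        params = ControlParams(P=147, D=10, delta=0.2, sigma=0.0, c_on=0.62)
        tr = simulate_sway(default_plant, params, duration=30.0, seed=0,
                           eta=0.005, force_active=-1)[0]
        assert tr.fell

    def test_fall_flag_on_large_noise(self, default_plant):
        params = ControlParams(P=147, D=10, delta=0.2, sigma=50.0, c_on=0.62)
        trials = simulate_sway(default_plant, params, duration=60, seed=1,
                               n_trials=3)
        assert any(t.fell for t in trials)
        for t in trials:  # flagged paths stay finite, never truncated
            assert len(t.samples) == 3000
            assert np.all(np.isfinite(t.samples))

    def test_invalid_duration(self, default_plant, default_params):
        with pytest.raises(ValueError):
            simulate_sway(default_plant, default_params, duration=-1)

    def test_linear_limit_stationary_covariance(self, default_plant):
        # active permanently ON with zero delay: a 2-D linear SDE whose
        # stationary covariance solves the continuous Lyapunov equation
        params = ControlParams(P=147, D=10, delta=0.0, sigma=0.2, c_on=0.62)
        dt = 0.005
        n_trials = 12
        trials = simulate_sway(default_plant, params, duration=150.0, dt=dt,
                               seed=9, n_trials=n_trials, force_active=1)
        st0 = trials[0].state
        A = np.array([[0.0, 1.0], [st0.a + st0.c, st0.b + st0.d]])
        Q = np.array([[0.0, 0.0], [0.0, st0.e ** 2]])
        S = solve_continuous_lyapunov(A, -Q)
        burn = int(30.0 / dt)
        var_theta = np.array([t.state.theta[burn:].var() for t in trials])
        var_omega = np.array([t.state.omega[burn:].var() for t in trials])
        for est, truth in ((var_theta, S[0, 0]), (var_omega, S[1, 1])):
            se = est.std(ddof=1) / np.sqrt(n_trials)
            assert abs(est.mean() - truth) < 3 * se + 0.05 * truth

    def test_dt_refinement_stable_moments(self, default_plant, default_params):
        # halving the step leaves COM mean and SD within 10%
        def pooled(dt):
            trials = simulate_sway(default_plant, default_params, duration=300,
                                   dt=dt, seed=77, n_trials=6)
            x = np.concatenate([t.samples for t in trials])
            return x.std()

        coarse, fine = pooled(0.02), pooled(0.01)
        assert abs(fine - coarse) / coarse < 0.10


class TestTorqueComponents:
    def test_off_steps_zero_and_on_steps_proportional(self, default_plant,
                                                      default_params):
        tr = simulate_sway(default_plant, default_params, duration=60, seed=3)[0]
        tq = torque_components(tr.state, default_params, default_plant)
        on = tq["active_mask"]
        assert np.all(tq["f_P"][~on] == 0.0)
        assert np.all(tq["f_D"][~on] == 0.0)
        # on an ON step, f_P equals P times the delayed angle
        k = tr.state.k
        idx = np.flatnonzero(on)
        idx = idx[idx >= k][0]
        assert tq["f_P"][idx] == pytest.approx(
            default_params.P * tr.state.theta[idx - k], rel=1e-12)

    def test_step_wise_torque_balance(self, default_plant, default_params):
        # the recorded path must satisfy the discretized torque balance:
        # I*(Omega_{n+1}-Omega_n)/dt = gravity - passive - active + noise
        tr = simulate_sway(default_plant, default_params, duration=20, seed=8)[0]
        s = tr.state
        tq = torque_components(s, default_params, default_plant)
        I = default_plant.I
        n = len(s.theta) - 1
        lhs = I * (s.omega[1:] - s.omega[:-1]) / s.dt
        rhs = (tq["gravity"][:-1] - tq["passive"][:-1]
               - tq["f_P"][:-1] - tq["f_D"][:-1]
               + default_params.sigma * s.xi[:n] / np.sqrt(s.dt))
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_damping_torque_linear_in_d_on_fixed_path(self, default_plant,
                                                      default_params):
        from dataclasses import replace
        tr = simulate_sway(default_plant, default_params, duration=60, seed=3)[0]
        tq1 = torque_components(tr.state, default_params, default_plant)
        tq2 = torque_components(tr.state, replace(default_params, D=100.0),
                                default_plant)
        on = tq1["active_mask"]
        r1 = np.mean(np.abs(tq1["f_P"][on])) / np.mean(np.abs(tq1["f_D"][on]))
        r2 = np.mean(np.abs(tq2["f_P"][on])) / np.mean(np.abs(tq2["f_D"][on]))
        assert r2 == pytest.approx(r1 / 10.0, rel=1e-12)
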