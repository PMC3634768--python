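import numpy as np
import pytest

from tremorloop import (
    ClosedLoopTrajectory,
    ControllerGains,
    InfeasibleGainsError,
    ParamSchedule,
    TremorModelParams,
    adaptation_rhs,
    control_law,
    lyapunov_value,
    simulate_closed_loop,
    steady_state_time,
)
from tremorloop.fixtures import recovery_bounds

GAINS = ControllerGains(k=10.0, s=1e-4, gamma=100.0)


class TestControlLaw:
    def test_zero_output_passes_estimate_through(self):
        assert control_law(GAINS, 0.0, 3.0) == 3.0

    def test_matches_formula_at_random_points(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            y, u_hat = rng.normal(), rng.uniform(0, 5)
            assert control_law(GAINS, y, u_hat) == pytest.approx(u_hat - GAINS.k * y)

    def test_finite_over_wide_output_range(self):
        for y in (-1e3, -1.0, 0.0, 1.0, 1e3):
            assert np.isfinite(control_law(GAINS, y, 2.0))


class TestAdaptationLaw:
    def test_fixed_point_at_zero_output(self):
        assert adaptation_rhs(GAINS, 0.0, 1.7) == 0.0

    def test_scales_linearly_with_gamma(self):
        g2 = ControllerGains(k=10.0, s=1e-4, gamma=200.0)
        assert adaptation_rhs(g2, 0.3, 1.0) == pytest.approx(2 * adaptation_rhs(GAINS, 0.3, 1.0))

    def test_cancels_input_cross_term_in_lyapunov_derivative(self):
        """The adaptation contribution (u_hat - A_n) * du_hat / gamma must
        cancel the x1 * (u_hat - A_n) input term of dV/dt exactly."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            y, u_hat, A_n = rng.normal(), rng.uniform(0, 5), rng.uniform(0, 5)
            ut = u_hat - A_n
            residual = ut * adaptation_rhs(GAINS, y, u_hat) / GAINS.gamma + y * ut
            assert residual == pytest.approx(0.0, abs=1e-12)


class TestLyapunovValue:
    def test_zero_only_at_equilibrium(self):
        assert lyapunov_value(GAINS, (0.0, 0.0), 3.0, 3.0, C=10.0) == 0.0

    def test_positive_definite_sampling(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(1000, 3))
        pts = pts[np.abs(pts).sum(axis=1) > 1e-9]
        V = lyapunov_value(GAINS, (pts[:, 0], pts[:, 1]), 3.0 + pts[:, 2], 3.0,
                           C=np.full(len(pts), 10.0))
        assert np.all(V > 0.0)

    def test_nonpositive_C_rejected(self):
        with pytest.raises(ValueError):
            lyapunov_value(GAINS, (1.0, 0.0), 0.0, 1.0, C=0.0)


@pytest.fixture(scope="module")
def raw_run():
    """One randomized raw-mode recovery run shared by the closed-loop tests."""
    from tremorloop import make_recovery_suite, run_scenario, synthesize_gains

    gains = synthesize_gains(recovery_bounds())
    scenario = make_recovery_suite(seed=42, n=1)[0]
    traj = run_scenario(scenario, gains=gains)
    return gains, scenario, traj


class TestClosedLoop:
    def test_estimate_converges_to_nominal_amplitude(self, raw_run):
        _, scenario, traj = raw_run
        A_n = scenario.model.A_n
        assert abs(traj.u_hat[-1] - A_n) / A_n < 0.05

    def test_lyapunov_nonincreasing_in_raw_mode(self, raw_run):
        _, scenario, traj = raw_run
        V = traj.V[traj.t >= scenario.t_on]
        assert np.all(np.diff(V) <= 1e-6 * V[0])

    def test_conditioned_signals_respect_actuator_contracts(self, raw_run):
        gains, scenario, _ = raw_run
        cond = scenario.conditioning
        traj = simulate_closed_loop(
            scenario.model, gains, cond, t_on=scenario.t_on,
            t_span=(0.0, 10.0), mode="conditioned", bounds=scenario.bounds,
        )
        active = traj.t >= scenario.t_on
        assert np.all(traj.u_sat[active] >= cond.u_min - 1e-12)
        assert np.all(traj.u_sat[active] <= cond.u_max + 1e-12)
        dt = np.diff(traj.t)
        slew = np.abs(np.diff(traj.u_rl)) / dt
        assert slew.max() <= cond.R * (1 + 1e-3)

    def test_infeasible_gains_refused_unless_overridden(self, raw_run):
        _, scenario, _ = raw_run
        bad = ControllerGains(k=1e-6, s=1e-4, gamma=100.0)
        with pytest.raises(InfeasibleGainsError):
            simulate_closed_loop(scenario.model, bad, t_on=1.0, t_span=(0.0, 2.0),
                                 bounds=scenario.bounds)
        traj = simulate_closed_loop(scenario.model, bad, t_on=1.0, t_span=(0.0, 2.0),
                                    bounds=scenario.bounds, allow_infeasible=True)
        assert len(traj.t) > 0

    def test_invalid_controller_start_time_rejected(self, raw_run):
        gains, scenario, _ = raw_run
        with pytest.raises(ValueError):
            simulate_closed_loop(scenario.model, gains, t_on=30.0, t_span=(0.0, 10.0))

    def test_noise_and_filter_paths_run_and_are_deterministic(self, raw_run):
        gains, scenario, _ = raw_run
        kw = dict(t_on=1.0, t_span=(0.0, 4.0), mode="raw", noise_std=0.02,
                  filter_band=(3.0, 12.0), seed=9, bounds=scenario.bounds)
        t1 = simulate_closed_loop(scenario.model, gains, **kw)
        t2 = simulate_closed_loop(scenario.model, gains, **kw)
        assert np.array_equal(t1.u_hat, t2.u_hat)
        assert np.all(np.isfinite(t1.u_hat))


def synthetic_traj(t, y, u_hat):
    z = np.zeros_like(t)
    return ClosedLoopTrajectory(t=t, x1=y, x2=z, y=y, u_raw=z, u_sat=z, u_rl=z,
                                u_hat=u_hat, V=z, t_on=0.0, A_n=1.0)


class TestSteadyStateTime:
    def test_quiet_trajectory_settles_immediately(self):
        t = np.linspace(0.0, 10.0, 1001)
        traj = synthetic_traj(t, np.zeros_like(t), np.full_like(t, 2.0))
        assert steady_state_time(traj, eps=1e-2, window=1.0) == 0.0

    def test_persistent_oscillation_never_settles(self):
        t = np.linspace(0.0, 10.0, 1001)
        traj = synthetic_traj(t, np.sin(2 * np.pi * 5 * t), np.full_like(t, 2.0))
        assert steady_state_time(traj, eps=1e-2, window=1.0) is None

    def test_detects_decay_onset(self):
        t = np.linspace(0.0, 10.0, 1001)
        y = np.where(t < 4.0, 1.0, 0.0)
        traj = synthetic_traj(t, y, np.full_like(t, 2.0))
        assert steady_state_time(traj, eps=1e-2, window=1.0) == pytest.approx(4.0, abs=0.02)

    def test_window_longer_than_span_rejected(self):
        t = np.linspace(0.0, 2.0, 201)
        traj = synthetic_traj(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(ValueError):
            steady_state_time(traj, window=5.0)
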