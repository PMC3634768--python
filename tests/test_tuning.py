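import numpy as np
import pytest

from tremorloop import (
    ConditioningConfig,
    TrialTiming,
    dichotomy_factory,
    mean_amplitude,
    run_grid_search,
    run_trial,
    select_optimal,
    tremor_power,
)
from tremorloop.fixtures import CASE1_FREQ_HZ, CASE2_FREQ_HZ, PULSE_WIDTH_US, _case_model


def periods(f=5.0, n=10, fs=1000.0):
    t = np.arange(0.0, n / f, 1.0 / fs)  # integer number of periods, endpoint excluded
    return t


class TestMeanAmplitude:
    def test_constant_signal(self):
        t = np.linspace(0, 10, 1001)
        assert mean_amplitude(t, np.full_like(t, 2.9), (0, 10)) == pytest.approx(2.9)

    def test_sinusoid_over_integer_periods(self):
        t = periods()
        u = 3.0 + 0.1 * np.sin(2 * np.pi * 5.0 * t)
        assert mean_amplitude(t, u, (t[0], t[-1] + 1e-9)) == pytest.approx(3.0, abs=1e-12)

    def test_agrees_with_bruteforce_accumulation(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 5, 501)
        u = rng.uniform(0, 5, len(t))
        lo, hi = 1.0, 4.0
        total, count = 0.0, 0
        for ti, ui in zip(t, u):
            if lo <= ti <= hi:
                total += ui
                count += 1
        assert mean_amplitude(t, u, (lo, hi)) == pytest.approx(total / count)

    def test_empty_window_rejected(self):
        t = np.linspace(0, 1, 11)
        with pytest.raises(ValueError):
            mean_amplitude(t, t, (5.0, 6.0))


class TestTremorPower:
    def test_zero_signal(self):
        t = np.linspace(0, 1, 101)
        assert tremor_power(t, np.zeros_like(t), (0, 1)) == 0.0

    def test_sinusoid_rms_is_amplitude_over_sqrt2(self):
        t = periods()
        for A0 in (0.5, 1.0, 2.7):
            y = A0 * np.sin(2 * np.pi * 5.0 * t)
            assert tremor_power(t, y, (t[0], t[-1] + 1e-9)) == pytest.approx(
                A0 / np.sqrt(2), rel=1e-6)

    def test_constant_signal_rms_is_magnitude(self):
        t = np.linspace(0, 1, 101)
        assert tremor_power(t, np.full_like(t, -0.4), (0, 1)) == pytest.approx(0.4)


class TestSelectOptimal:
    def test_singleton(self):
        assert select_optimal(np.array([[3.0]])) == (0, 0)

    def test_row_major_tie_break(self):
        assert select_optimal(np.array([[2.0, 1.0], [1.0, 1.0]])) == (0, 1)

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            grid = rng.uniform(0, 1, size=(rng.integers(1, 6), rng.integers(1, 6)))
            i, j = select_optimal(grid)
            best = min(((grid[a, b], a, b) for a in range(grid.shape[0])
                        for b in range(grid.shape[1])), key=lambda x: (x[0], x[1], x[2]))
            assert (i, j) == (best[1], best[2])

    def test_nan_identifies_cell(self):
        grid = np.array([[1.0, np.nan], [0.5, 2.0]])
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            select_optimal(grid)


TIMING = TrialTiming(t_on=5.0, tf=40.0, T_s=30.0, T_e=40.0)


class TestTrials:
    def test_case2_trial_converges_and_estimates_amplitude(self, case_gains):
        res, traj = run_trial(dichotomy_factory, case_gains, ConditioningConfig(),
                              CASE2_FREQ_HZ, PULSE_WIDTH_US, TIMING)
        pre = traj.pre_controller_rms()
        assert res.converged
        assert res.P < 0.05 * pre
        assert abs(res.A_hat - 3.0) < 0.05 * 3.0

    def test_case1_trial_flags_nonconvergence(self, case_gains):
        res, traj = run_trial(dichotomy_factory, case_gains, ConditioningConfig(),
                              CASE1_FREQ_HZ, PULSE_WIDTH_US, TIMING,
                              project_u_hat=True)
        assert not res.converged
        assert res.P > 0.1 * traj.pre_controller_rms()

    def test_longer_averaging_horizon_shrinks_estimation_error(self, case_gains):
        errors = []
        for T_e in (16.0, 26.0, 40.0):
            timing = TrialTiming(t_on=5.0, tf=40.0, T_s=12.0, T_e=T_e)
            res, _ = run_trial(dichotomy_factory, case_gains, ConditioningConfig(),
                               CASE2_FREQ_HZ, PULSE_WIDTH_US, timing)
            errors.append(abs(res.A_hat - 3.0))
        assert errors[1] <= errors[0] + 1e-6
        assert errors[2] <= errors[1] + 1e-6


class TestGridSearch:
    def test_two_cell_grid_selects_the_valid_amplitude_cell(self, case_gains):
        report = run_grid_search([CASE1_FREQ_HZ, CASE2_FREQ_HZ], [PULSE_WIDTH_US],
                                dichotomy_factory, case_gains, timing=TIMING,
                                project_u_hat=True)
        assert (report.i_opt, report.j_opt) == (1, 0)
        assert report.optimal.F == CASE2_FREQ_HZ
        assert abs(report.optimal.A - 3.0) < 0.15

    def test_identical_cells_tie_break_to_first(self, case_gains):
        factory = lambda F, mu: _case_model(A_n=3.0)  # noqa: E731
        timing = TrialTiming(t_on=2.0, tf=12.0, T_s=8.0, T_e=12.0)
        report = run_grid_search([110.0, 140.0], [60.0, 90.0], factory, case_gains,
                                timing=timing)
        assert (report.i_opt, report.j_opt) == (0, 0)

    def test_planted_unique_best_cell_is_found(self, case_gains):
        """3x3 grid: only one setting admits an in-range nominal amplitude."""

        def factory(F, mu):
            if (F, mu) == (140.0, 90.0):
                return _case_model(A_n=3.0)
            # off-cells: nominal amplitude unreachable, spread so powers differ
            return _case_model(A_n=6.0 + 0.1 * F / 100.0 + 0.001 * mu)

        timing = TrialTiming(t_on=2.0, tf=12.0, T_s=8.0, T_e=12.0)
        report = run_grid_search([110.0, 140.0, 170.0], [60.0, 90.0, 120.0],
                                factory, case_gains, timing=timing,
                                project_u_hat=True)
        assert (report.i_opt, report.j_opt) == (1, 1)

    def test_empty_grid_rejected(self, case_gains):
        with pytest.raises(ValueError):
            run_grid_search([], [90.0], dichotomy_factory, case_gains)
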