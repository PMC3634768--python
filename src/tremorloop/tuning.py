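"""Stimulation-parameter selection by multi-trial adaptive estimation.

For each candidate pair of stimulation frequency F_i (Hz) and pulse-width
mu_j (us), one closed-loop trial is run in conditioned mode; the delivered
amplitude signal is averaged over a post-settling window [T_s, T_e] to give
the amplitude estimate A_hat_ij, and the root-mean-square of the tremor over
the same window gives the tremor power P_ij.  The grid cell with minimum
tremor power wins (ties broken row-major: lowest i, then lowest j), and the
selected triple (A_hat, F, mu) is the recommended DBS setting.  Because
A_hat is an average of a continuously adapted signal, the amplitude is
chosen from the whole continuum [u_min, u_max] rather than from a preset
list.

How (F, mu) change the plant is not modelled biophysically: the caller
supplies a ``model_factory(F, mu) -> TremorModelParams`` encoding, for each
setting, which nominal amplitude (if any inside the actuator range) quiets
the tremor.  The packaged fixtures ship a two-cell factory reproducing the
"no valid amplitude exists" / "valid amplitude exists" dichotomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .conditioning import ConditioningConfig
from .control import ClosedLoopTrajectory, simulate_closed_loop, steady_state_time
from .models import TremorModelParams, open_loop_equilibrium
from .synthesis import ControllerGains, ParameterBounds

__all__ = [
    "StimulusParams",
    "TrialTiming",
    "TrialResult",
    "TuningReport",
    "mean_amplitude",
    "tremor_power",
    "run_trial",
    "select_optimal",
    "run_grid_search",
]


@dataclass(frozen=True)
class StimulusParams:
    """One DBS setting: amplitude A (V), frequency F (Hz), pulse-width mu (us)."""

    A: float
    F: float
    mu: float

    def __post_init__(self) -> None:
        if self.F <= 0.0 or self.mu <= 0.0:
            raise ValueError("F and mu must be positive")


@dataclass(frozen=True)
class TrialTiming:
    """Timing of one estimation trial (all seconds, trial-relative).

    T_s is the settling time after which the adapted amplitude is treated as
    constant; None means: detect it from the trajectory, falling back to 50%
    of the trial length.  The averaging window is [T_s, T_e]; T_e defaults
    to the trial end.
    """

    t_on: float = 2.0
    tf: float = 20.0
    T_s: float | None = None
    T_e: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_on < self.tf:
            raise ValueError("need 0 <= t_on < tf")
        te = self.tf if self.T_e is None else self.T_e
        if self.T_s is not None and not self.t_on <= self.T_s < te <= self.tf:
            raise ValueError("need t_on <= T_s < T_e <= tf")


@dataclass
class TrialResult:
    """Outcome of one grid cell."""

    i: int
    j: int
    F: float
    mu: float
    A_hat: float
    P: float
    T_s: float
    T_e: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "i": self.i, "j": self.j, "F": self.F, "mu": self.mu,
            "A_hat": self.A_hat, "P": self.P, "T_s": self.T_s, "T_e": self.T_e,
            "converged": self.converged,
        }


@dataclass
class TuningReport:
    """All trial results plus the selected optimum."""

    freqs: list[float]
    pulse_widths: list[float]
    results: list[list[TrialResult]]
    i_opt: int
    j_opt: int
    optimal: StimulusParams

    @property
    def power_grid(self) -> np.ndarray:
        return np.array([[r.P for r in row] for row in self.results])

    def to_dict(self) -> dict:
        return {
            "freqs": self.freqs,
            "pulse_widths": self.pulse_widths,
            "results": [[r.to_dict() for r in row] for row in self.results],
            "i_opt": self.i_opt,
            "j_opt": self.j_opt,
            "optimal": {"A": self.optimal.A, "F": self.optimal.F, "mu": self.optimal.mu},
        }


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    ta, tb = float(window[0]), float(window[1])
    if not ta < tb:
        raise ValueError("window must satisfy ta < tb")
    mask = (t >= ta) & (t <= tb)
    if not mask.any():
        raise ValueError("window contains no samples")
    return mask


def mean_amplitude(t: np.ndarray, u_f: np.ndarray, window: tuple[float, float]) -> float:
    """Arithmetic mean of the conditioned control signal over [ta, tb]."""
    mask = _window_mask(np.asarray(t), window)
    return float(np.mean(np.asarray(u_f, dtype=float)[mask]))


def tremor_power(t: np.ndarray, y: np.ndarray, window: tuple[float, float]) -> float:
    """Root-mean-square of the tremor signal over [ta, tb]."""
    mask = _window_mask(np.asarray(t), window)
    return float(np.sqrt(np.mean(np.asarray(y, dtype=float)[mask] ** 2)))


# ---------------------------------------------------------------------------
# trials and selection
# ---------------------------------------------------------------------------

def run_trial(
    model_factory: Callable[[float, float], TremorModelParams],
    gains: ControllerGains,
    conditioning: ConditioningConfig,
    F: float,
    mu: float,
    timing: TrialTiming,
    i: int = 0,
    j: int = 0,
    bounds: ParameterBounds | None = None,
    amplitude_signal: str = "u_rl",
    ss_eps: float = 1e-2,
    ss_window: float = 1.0,
    **sim_kwargs,
) -> tuple[TrialResult, ClosedLoopTrajectory]:
    """Run one conditioned closed-loop trial for the setting (F, mu).

    ``amplitude_signal`` selects which conditioned signal the averaging
    uses: the rate-limited output ``u_rl`` (default, the delivered amplitude)
    or the saturated command ``u_sat``.  Non-convergence is flagged, not an
    error.
    """
    if amplitude_signal not in ("u_rl", "u_sat"):
        raise ValueError("amplitude_signal must be 'u_rl' or 'u_sat'")
    model = model_factory(F, mu)
    if "init" not in sim_kwargs:
        # start on the unstimulated attractor with a unit tremor deflection
        baseline = float(sim_kwargs.get("baseline_u", 0.0))
        x1_eq, x2_eq = open_loop_equilibrium(model, baseline)
        sim_kwargs["init"] = (x1_eq + 1.0, x2_eq)
    traj = simulate_closed_loop(
        model, gains, conditioning,
        t_on=timing.t_on, t_span=(0.0, timing.tf),
        mode="conditioned", bounds=bounds, **sim_kwargs,
    )
    t_ss = steady_state_time(traj, eps=ss_eps, window=ss_window)
    converged = t_ss is not None
    T_s = timing.T_s
    if T_s is None:
        T_s = t_ss if (t_ss is not None and t_ss < timing.tf) else 0.5 * timing.tf
        T_s = max(T_s, timing.t_on)
    T_e = timing.tf if timing.T_e is None else timing.T_e
    if not T_s < T_e:
        T_s = 0.5 * (timing.t_on + T_e)
    u_f = getattr(traj, amplitude_signal)
    A_hat = mean_amplitude(traj.t, u_f, (T_s, T_e))
    P = tremor_power(traj.t, traj.y, (T_s, T_e))
    return TrialResult(i=i, j=j, F=F, mu=mu, A_hat=A_hat, P=P,
                       T_s=float(T_s), T_e=float(T_e), converged=converged), traj


def select_optimal(power_grid: np.ndarray) -> tuple[int, int]:
    """Row-major argmin of the tremor-power grid; NaN is an error."""
    P = np.asarray(power_grid, dtype=float)
    if P.size == 0:
        raise ValueError("empty power grid")
    if np.isnan(P).any():
        i, j = np.argwhere(np.isnan(P))[0]
        raise ValueError(f"NaN tremor power in grid cell ({i}, {j})")
    flat = int(np.argmin(P))  # argmin returns the first (row-major) minimum
    return np.unravel_index(flat, P.shape)  # type: ignore[return-value]


def run_grid_search(
    freqs,
    pulse_widths,
    model_factory: Callable[[float, float], TremorModelParams],
    gains: ControllerGains,
    conditioning: ConditioningConfig | None = None,
    timing: TrialTiming | None = None,
    bounds: ParameterBounds | None = None,
    **trial_kwargs,
) -> TuningReport:
    """Exhaustive grid search over frequencies x pulse-widths.

    Trials run in deterministic row-major order, each from a fresh plant
    state (no carry-over between trials).  The report contains every trial
    and the selected triple (A_hat_opt, F_opt, mu_opt).
    """
    freqs = [float(f) for f in freqs]
    pulse_widths = [float(m) for m in pulse_widths]
    if not freqs or not pulse_widths:
        raise ValueError("freqs and pulse_widths must be nonempty")
    cond = conditioning or ConditioningConfig()
    timing = timing or TrialTiming()
    results: list[list[TrialResult]] = []
    for i, F in enumerate(freqs):
        row = []
        for j, mu in enumerate(pulse_widths):
            res, _ = run_trial(model_factory, gains, cond, F, mu, timing,
                               i=i, j=j, bounds=bounds, **trial_kwargs)
            row.append(res)
        results.append(row)
    P = np.array([[r.P for r in row] for row in results])
    i_opt, j_opt = select_optimal(P)
    best = results[i_opt][j_opt]
    return TuningReport(
        freqs=freqs, pulse_widths=pulse_widths, results=results,
        i_opt=int(i_opt), j_opt=int(j_opt),
        optimal=StimulusParams(A=best.A_hat, F=freqs[i_opt], mu=pulse_widths[j_opt]),
    )
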