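"""Packaged simulation scenarios and their (de)serialization.

A :class:`Scenario` is fully self-describing: the YAML file alone reproduces
a run (model schedules, parameter bounds, gains or a synthesize flag,
conditioning, timing, seed).  Three scenario families ship with the package:

* **Case I** — the chosen stimulation frequency/pulse-width admits *no*
  nominal amplitude inside the actuator range (A_n above u_max), so the
  adaptive estimate pins at the saturation bound and the tremor persists.
* **Case II** — a different stimulation frequency for which a valid nominal
  amplitude exists; the tremor converges to zero and the estimate converges
  to A_n.
* **Model-validation suite** — seven open-loop runs of the linear model at
  fixed frequency/pulse-width and varying constant stimulation amplitude,
  emulating a kinematic study of patient tremor under different DBS
  amplitudes: tremor RMS grows with the distance |A - A_n|.

All numeric values in these fixtures are the package's own documented
defaults (`paper_exact: false` in every file they serialize to): they are
chosen to be representative of parkinsonian rest tremor (4-6 Hz band) and
clinical DBS hardware (0-5 V amplitude range, 130/180 Hz pulse trains,
90 us pulse width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .conditioning import ConditioningConfig
from .control import ClosedLoopTrajectory, simulate_closed_loop
from .models import TremorModelParams, odd_power, open_loop_equilibrium
from .schedules import ParamSchedule
from .synthesis import ControllerGains, ParameterBounds, synthesize_gains

__all__ = [
    "Scenario",
    "make_case1",
    "make_case2",
    "make_amplitude_sweep",
    "make_recovery_suite",
    "dichotomy_factory",
    "recovery_bounds",
    "case_bounds",
    "run_scenario",
    "CASE1_FREQ_HZ",
    "CASE2_FREQ_HZ",
    "PULSE_WIDTH_US",
]

# DBS settings of the two packaged cases (Hz / us); the pulse width is shared.
CASE1_FREQ_HZ = 130.0
CASE2_FREQ_HZ = 180.0
PULSE_WIDTH_US = 90.0

_TREMOR_HZ = 5.0  # centre of the parkinsonian rest-tremor band


@dataclass(frozen=True)
class Scenario:
    """A fully self-describing closed-loop run."""

    name: str
    model: TremorModelParams
    bounds: ParameterBounds
    conditioning: ConditioningConfig
    gains: ControllerGains | None = None  # None -> synthesize from bounds
    t_on: float = 5.0
    tf: float = 40.0
    T_s: float | None = None
    T_e: float | None = None
    init: tuple[float, float] = (1.0, 0.0)
    u_hat0: float = 0.0
    baseline_u: float = 0.0
    mode: str = "conditioned"
    project_u_hat: bool = False
    stim_freq: float = CASE2_FREQ_HZ
    pulse_width: float = PULSE_WIDTH_US
    sample_rate: float = 1000.0
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "RK45"
    seed: int = 0
    paper_exact: bool = False
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "model": self.model.to_dict(),
            "bounds": self.bounds.to_dict(),
            "conditioning": self.conditioning.to_dict(),
            "gains": self.gains.to_dict() if self.gains is not None else None,
            "t_on": self.t_on, "tf": self.tf, "T_s": self.T_s, "T_e": self.T_e,
            "init": list(self.init), "u_hat0": self.u_hat0,
            "baseline_u": self.baseline_u, "mode": self.mode,
            "project_u_hat": self.project_u_hat,
            "stim_freq": self.stim_freq, "pulse_width": self.pulse_width,
            "sample_rate": self.sample_rate, "rtol": self.rtol, "atol": self.atol,
            "method": self.method, "seed": self.seed,
            "paper_exact": self.paper_exact, "notes": self.notes,
        }

    @staticmethod
    def from_dict(d: dict) -> "Scenario":
        return Scenario(
            name=d["name"],
            model=TremorModelParams.from_dict(d["model"]),
            bounds=ParameterBounds.from_dict(d["bounds"]),
            conditioning=ConditioningConfig.from_dict(d["conditioning"]),
            gains=ControllerGains.from_dict(d["gains"]) if d.get("gains") else None,
            t_on=float(d["t_on"]), tf=float(d["tf"]),
            T_s=None if d.get("T_s") is None else float(d["T_s"]),
            T_e=None if d.get("T_e") is None else float(d["T_e"]),
            init=tuple(float(v) for v in d["init"]),
            u_hat0=float(d["u_hat0"]), baseline_u=float(d["baseline_u"]),
            mode=d["mode"], project_u_hat=bool(d["project_u_hat"]),
            stim_freq=float(d["stim_freq"]), pulse_width=float(d["pulse_width"]),
            sample_rate=float(d["sample_rate"]), rtol=float(d["rtol"]),
            atol=float(d["atol"]), method=d["method"], seed=int(d["seed"]),
            paper_exact=bool(d.get("paper_exact", False)), notes=d.get("notes", ""),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "Scenario":
        with open(path) as fh:
            return Scenario.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# parameter boxes
# ---------------------------------------------------------------------------

def case_bounds() -> ParameterBounds:
    """Parameter box covering the two packaged case-scenario plants."""
    return ParameterBounds(
        C_min=30.0, C_max=80.0,
        omega_min=2.0 * np.pi * 4.0, omega_max=2.0 * np.pi * 6.0,
        Cdot_max=5.0, a_max=1.0, b_min=2.0,
        L=48.0,  # phi(x) = x^3 on |x| <= 4
    )


def recovery_bounds() -> ParameterBounds:
    """Box for the randomized amplitude-recovery scenarios."""
    return ParameterBounds(
        C_min=5.0, C_max=15.0,
        omega_min=2.0 * np.pi * 4.0, omega_max=2.0 * np.pi * 6.0,
        Cdot_max=2.0, a_max=0.05, b_min=1.0,
        L=126.75,  # phi(x) = x^3 on |x| <= 6.5
    )


def _case_model(A_n: float, omega_sched: ParamSchedule | None = None) -> TremorModelParams:
    return TremorModelParams(
        C=ParamSchedule.constant(50.0),
        omega=omega_sched or ParamSchedule.constant(2.0 * np.pi * _TREMOR_HZ),
        a=0.5, b=2.0, A_n=A_n,
        phi=odd_power(3, domain=(-4.0, 4.0)),
    )


# ---------------------------------------------------------------------------
# packaged scenarios
# ---------------------------------------------------------------------------

def _tremor_init(model: TremorModelParams, baseline_u: float = 0.0,
                 perturbation: float = 1.0) -> tuple[float, float]:
    """Initial state on the unstimulated attractor plus a tremor deflection.

    The patient has been running open loop at ``baseline_u``; the state sits
    at that equilibrium and the tremor is an oscillation of unit amplitude
    about it.  Initializing far off the attractor would make the
    pre-controller baseline a model transient rather than tremor.
    """
    x1_eq, x2_eq = open_loop_equilibrium(model, baseline_u, t=0.0)
    return (x1_eq + perturbation, x2_eq)


def make_case1() -> Scenario:
    """No valid nominal amplitude: A_n sits above the 0-5 V actuator range.

    The estimate cannot reach A_n = 7 V, pins at the upper saturation bound
    (the anti-windup projection is enabled for this scenario so the pinning
    is visible in u_hat itself), and the tremor does not vanish: the
    amplitude shortfall leaves a persistent output offset plus the
    re-excitation from the mid-run frequency step (5 Hz -> 4.5 Hz).
    """
    omega = ParamSchedule.step(
        (0.0, 25.0),
        (2.0 * np.pi * 5.0, 2.0 * np.pi * 4.5),
    )
    model = _case_model(A_n=7.0, omega_sched=omega)
    return Scenario(
        name="case1",
        model=model,
        bounds=case_bounds(),
        conditioning=ConditioningConfig(),
        t_on=5.0, tf=40.0, T_s=30.0, T_e=40.0,
        init=_tremor_init(model),
        mode="conditioned", project_u_hat=True,
        stim_freq=CASE1_FREQ_HZ, pulse_width=PULSE_WIDTH_US,
        notes="nominal amplitude outside the saturation range; "
              "frequency steps 5 Hz -> 4.5 Hz at t = 25 s",
    )


def make_case2() -> Scenario:
    """Valid nominal amplitude (A_n = 3 V) after changing the stimulation
    frequency (pulse width unchanged): tremor converges, u_hat -> A_n."""
    model = _case_model(A_n=3.0)
    return Scenario(
        name="case2",
        model=model,
        bounds=case_bounds(),
        conditioning=ConditioningConfig(),
        t_on=5.0, tf=40.0, T_s=None, T_e=None,
        init=_tremor_init(model),
        mode="conditioned",
        stim_freq=CASE2_FREQ_HZ, pulse_width=PULSE_WIDTH_US,
        notes="nominal amplitude inside the actuator range",
    )


def make_amplitude_sweep(
    amplitudes: tuple[float, ...] = (0.0, 1.0, 1.5, 2.5, 3.0, 4.0, 5.0),
    A_n: float = 2.5,
) -> list[Scenario]:
    """Seven open-loop linear-model runs at varying stimulation amplitude.

    Each scenario applies a constant amplitude from rest; the modeled tremor
    RMS is proportional to C |A - A_n| / omega, so RMS is zero at the
    nominal amplitude and grows with the mismatch, emulating the
    amplitude-response pattern seen in kinematic DBS studies.
    """
    scenarios = []
    for idx, A in enumerate(amplitudes):
        model = TremorModelParams(
            C=ParamSchedule.constant(10.0),
            omega=ParamSchedule.constant(2.0 * np.pi * _TREMOR_HZ),
            a=0.0, b=0.0, A_n=A_n,
        )
        scenarios.append(Scenario(
            name=f"amp_sweep_{chr(ord('a') + idx)}",
            model=model,
            bounds=case_bounds(),
            conditioning=ConditioningConfig(),
            t_on=10.0, tf=10.0, init=(0.0, 0.0),  # t_on == tf: open loop throughout
            baseline_u=A, u_hat0=A, mode="conditioned",
            stim_freq=CASE1_FREQ_HZ, pulse_width=PULSE_WIDTH_US,
            notes=f"open-loop amplitude sweep: A = {A} V, nominal {A_n} V",
        ))
    return scenarios


def make_recovery_suite(seed: int = 0, n: int = 20) -> list[Scenario]:
    """Randomized amplitude-recovery scenarios (raw loop, no noise).

    Draws A_n uniform in [0.5, 4.5] V and constant plant parameters inside
    :func:`recovery_bounds`; the adaptive loop should recover A_n to within
    a few percent in every run.
    """
    rng = np.random.default_rng(seed)
    bounds = recovery_bounds()
    scenarios = []
    for i in range(n):
        A_n = float(rng.uniform(0.5, 4.5))
        C = float(rng.uniform(bounds.C_min, bounds.C_max))
        omega = float(rng.uniform(bounds.omega_min, bounds.omega_max))
        a = float(rng.uniform(0.0, bounds.a_max))
        b = float(rng.uniform(bounds.b_min, 2.0))
        model = TremorModelParams(
            C=ParamSchedule.constant(C),
            omega=ParamSchedule.constant(omega),
            a=a, b=b, A_n=A_n,
            phi=odd_power(3, domain=(-6.5, 6.5)),
        )
        scenarios.append(Scenario(
            name=f"recovery_{i:02d}",
            model=model,
            bounds=bounds,
            conditioning=ConditioningConfig(),
            t_on=2.0, tf=22.0, mode="raw",
            stim_freq=CASE2_FREQ_HZ, pulse_width=PULSE_WIDTH_US,
            seed=int(rng.integers(0, 2**31 - 1)),
            notes="randomized nominal-amplitude recovery",
        ))
    return scenarios


# ---------------------------------------------------------------------------
# factories and runners
# ---------------------------------------------------------------------------

def dichotomy_factory(F: float, mu: float) -> TremorModelParams:
    """Two-cell (F, mu) -> plant map reproducing the Case I / II dichotomy.

    The low-frequency setting admits no in-range nominal amplitude
    (A_n = 7 V > u_max); the high-frequency setting does (A_n = 3 V).
    """
    key = (float(F), float(mu))
    table = {
        (CASE1_FREQ_HZ, PULSE_WIDTH_US): 7.0,
        (CASE2_FREQ_HZ, PULSE_WIDTH_US): 3.0,
    }
    if key not in table:
        raise KeyError(f"no plant defined for stimulation setting {key}")
    return _case_model(A_n=table[key])


def scenario_gains(scenario: Scenario) -> ControllerGains:
    """The scenario's gains, synthesizing them from its bounds if absent."""
    if scenario.gains is not None:
        return scenario.gains
    return synthesize_gains(scenario.bounds)


def run_scenario(scenario: Scenario, gains: ControllerGains | None = None) -> ClosedLoopTrajectory:
    """Execute a scenario end-to-end and return its sampled trajectory."""
    g = gains or scenario_gains(scenario)
    return simulate_closed_loop(
        scenario.model, g, scenario.conditioning,
        t_on=scenario.t_on, t_span=(0.0, scenario.tf),
        init=scenario.init, u_hat0=scenario.u_hat0,
        baseline_u=scenario.baseline_u, mode=scenario.mode,
        sample_rate=scenario.sample_rate, rtol=scenario.rtol,
        atol=scenario.atol, method=scenario.method,
        bounds=scenario.bounds, project_u_hat=scenario.project_u_hat,
        seed=scenario.seed,
    )
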