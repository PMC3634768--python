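"""Oscillator-based tremor plant models.

The filtered postural/rest tremor of a patient under deep-brain stimulation
(DBS) is close to a sinusoid, so the input-output behaviour from stimulation
amplitude u (volts) to measured tremor y is represented by a second-order
oscillator with time-varying strength C(t) and angular frequency omega(t):

linear model::

    dx1/dt = x2 + C(t) * (u - A_n)
    dx2/dt = -omega(t)**2 * x1
    y      = y_scale * x1

nonlinear generalization (adds a Lipschitz nonlinearity with coefficient
``a`` and a stabilization/damping term with coefficient ``b``)::

    dx2/dt = -omega(t)**2 * x1 - a * phi(x1) - b * x2

``A_n`` is the nominal stimulation amplitude: for u == A_n the origin is an
equilibrium and the modeled tremor vanishes.  With a == b == 0 the nonlinear
model reduces identically to the linear one; without the b-term the
oscillation is undamped, which is why the linear model cannot be quieted by
any constant (open-loop) stimulation once excited.

The stimulation mismatch C*(u - A_n) enters the x1 channel: this is the
structure under which a strictly output-feedback adaptive law (measuring
only y) admits an exact Lyapunov analysis; see docs/methods.md for the
derivation and for what this choice implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .schedules import ParamSchedule

__all__ = [
    "Nonlinearity",
    "odd_power",
    "cubic_fhn",
    "TremorModelParams",
    "PlantState",
    "Trajectory",
    "drift",
    "simulate_open_loop",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the time at which the solver stopped."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (integration stopped at t={t_fail:.6g} s)")
        self.t_fail = t_fail


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Nonlinearity:
    """A scalar nonlinearity phi with phi(0) = 0, locally Lipschitz on `domain`.

    ``name`` is one of ``odd-power`` (phi(x) = x**n, n odd), ``cubic-fhn``
    (the FitzHugh-Nagumo cubic x**3/3 - x), ``zero`` or ``custom``.
    ``domain`` is the bounded interval on which the local Lipschitz constant
    is certified; trajectories are expected to stay inside it.
    """

    name: str
    params: tuple[float, ...] = ()
    domain: tuple[float, float] = (-3.0, 3.0)
    func: Callable[[float], float] | None = None
    dfunc: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("nonlinearity domain must be a nonempty interval")
        if self.name == "custom" and self.func is None:
            raise ValueError("custom nonlinearity requires func")
        if self.name not in ("odd-power", "cubic-fhn", "zero", "custom"):
            raise ValueError(f"unknown nonlinearity {self.name!r}")
        if self.name == "odd-power":
            n = int(self.params[0]) if self.params else 3
            if n < 1 or n % 2 == 0:
                raise ValueError("odd-power exponent must be a positive odd integer")

    def __call__(self, x):
        if self.name == "zero":
            return np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0
        if self.name == "odd-power":
            n = int(self.params[0]) if self.params else 3
            return np.asarray(x) ** n if np.ndim(x) else float(x) ** n
        if self.name == "cubic-fhn":
            x = np.asarray(x, dtype=float) if np.ndim(x) else float(x)
            return x**3 / 3.0 - x
        return self.func(x)  # type: ignore[misc]

    def derivative(self, x):
        """phi'(x); analytic for the named forms, None-guarded for custom."""
        if self.name == "zero":
            return np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0
        if self.name == "odd-power":
            n = int(self.params[0]) if self.params else 3
            return n * (np.asarray(x) if np.ndim(x) else float(x)) ** (n - 1)
        if self.name == "cubic-fhn":
            x = np.asarray(x, dtype=float) if np.ndim(x) else float(x)
            return x**2 - 1.0
        if self.dfunc is None:
            raise ValueError("custom nonlinearity has no derivative; sample slopes instead")
        return self.dfunc(x)

    @property
    def has_derivative(self) -> bool:
        return self.name in ("zero", "odd-power", "cubic-fhn") or self.dfunc is not None

    def to_dict(self) -> dict:
        if self.name == "custom":
            raise ValueError("custom nonlinearities are not serializable")
        return {"name": self.name, "params": list(self.params), "domain": list(self.domain)}

    @staticmethod
    def from_dict(d: dict) -> "Nonlinearity":
        return Nonlinearity(d["name"], tuple(d.get("params", ())), tuple(d.get("domain", (-3.0, 3.0))))


def odd_power(n: int = 3, domain: tuple[float, float] = (-3.0, 3.0)) -> Nonlinearity:
    return Nonlinearity("odd-power", (float(n),), domain)


def cubic_fhn(domain: tuple[float, float] = (-3.0, 3.0)) -> Nonlinearity:
    return Nonlinearity("cubic-fhn", (), domain)


# ---------------------------------------------------------------------------
# plant
# ---------------------------------------------------------------------------

PlantState = tuple[float, float]  # (x1, x2)


@dataclass(frozen=True)
class TremorModelParams:
    """Parameters of the (non)linear oscillator tremor model.

    C
        Strength of the stimulation-mismatch coupling (schedule, model
        units / (V s)); also sets the open-loop tremor amplitude.
    omega
        Tremor angular frequency schedule (rad/s), strictly positive.
    a, b
        Nonlinearity and stabilization (damping) coefficients; a = b = 0
        recovers the linear model.
    A_n
        Nominal stimulation amplitude (V) at which the tremor vanishes.
    phi
        The model nonlinearity (phi(0) = 0).
    y_scale
        Output map scale: y = y_scale * x1.
    """

    C: ParamSchedule
    omega: ParamSchedule
    a: float = 0.0
    b: float = 0.0
    A_n: float = 0.0
    phi: Nonlinearity = field(default_factory=odd_power)
    y_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.omega.values) <= 0.0:
            raise ValueError("omega(t) must be positive for all t")
        if abs(float(self.phi(0.0))) > 0.0:
            raise ValueError("phi(0) must be 0")
        if self.y_scale == 0.0:
            raise ValueError("y_scale must be nonzero")

    @property
    def is_linear(self) -> bool:
        return self.a == 0.0 and self.b == 0.0

    def output(self, x1):
        return self.y_scale * x1

    def breakpoints(self, t0: float, tf: float) -> list[float]:
        pts = set(self.C.interior_breakpoints(t0, tf))
        pts.update(self.omega.interior_breakpoints(t0, tf))
        return sorted(pts)

    def to_dict(self) -> dict:
        return {
            "C": self.C.to_dict(),
            "omega": self.omega.to_dict(),
            "a": self.a,
            "b": self.b,
            "A_n": self.A_n,
            "phi": self.phi.to_dict(),
            "y_scale": self.y_scale,
        }

    @staticmethod
    def from_dict(d: dict) -> "TremorModelParams":
        return TremorModelParams(
            C=ParamSchedule.from_dict(d["C"]),
            omega=ParamSchedule.from_dict(d["omega"]),
            a=float(d.get("a", 0.0)),
            b=float(d.get("b", 0.0)),
            A_n=float(d.get("A_n", 0.0)),
            phi=Nonlinearity.from_dict(d["phi"]) if "phi" in d else odd_power(),
            y_scale=float(d.get("y_scale", 1.0)),
        )


def drift(model: TremorModelParams, state, u: float, t: float):
    """Right-hand side (dx1/dt, dx2/dt) of the tremor model.

    With u == A_n and state == (0, 0) the drift is (0, 0): the
    tremor-vanishing equilibrium.  a == b == 0 gives the linear model.
    """
    x1, x2 = float(state[0]), float(state[1])
    u = float(u)
    if not (math.isfinite(x1) and math.isfinite(x2) and math.isfinite(u)):
        raise ValueError("drift requires finite state and input")
    c = model.C(t)
    w = model.omega(t)
    dx1 = x2 + c * (u - model.A_n)
    dx2 = -w * w * x1 - model.b * x2
    if model.a != 0.0:
        dx2 -= model.a * float(model.phi(x1))
    return (dx1, dx2)


def open_loop_equilibrium(model: TremorModelParams, u: float, t: float = 0.0) -> PlantState:
    """The rest point of the plant under constant stimulation ``u``.

    Solves 0 = x2 + C (u - A_n) and 0 = -omega^2 x1 - a phi(x1) - b x2 at the
    parameter values in force at time t.  For u = A_n this is the origin; for
    a mismatched amplitude the state sits on a shifted attractor, and the
    tremor is the oscillation about it.
    """
    from scipy.optimize import brentq

    c = model.C(t)
    w2 = model.omega(t) ** 2
    x2 = c * (model.A_n - u)
    rhs = -model.b * x2

    def f(x1):
        return w2 * x1 + model.a * float(model.phi(x1)) - rhs

    x1_lin = rhs / w2
    if model.a == 0.0:
        return (x1_lin, x2)
    # bracket around the linear guess; f is increasing for the default
    # odd-power nonlinearities with a >= 0
    lo, hi = x1_lin - 1.0, x1_lin + 1.0
    while f(lo) > 0.0:
        lo -= 1.0
    while f(hi) < 0.0:
        hi += 1.0
    return (float(brentq(f, lo, hi, xtol=1e-12)), x2)


# ---------------------------------------------------------------------------
# open-loop simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled open-loop trajectory."""

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray
    u: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x1": self.x1, "x2": self.x2, "y": self.y, "u": self.u})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def rms(self, t_lo: float | None = None, t_hi: float | None = None) -> float:
        """Root-mean-square of y over [t_lo, t_hi] (defaults: whole span)."""
        mask = np.ones_like(self.t, dtype=bool)
        if t_lo is not None:
            mask &= self.t >= t_lo
        if t_hi is not None:
            mask &= self.t <= t_hi
        if not mask.any():
            raise ValueError("empty window")
        return float(np.sqrt(np.mean(self.y[mask] ** 2)))


def _segment_edges(t0: float, tf: float, interior: list[float]) -> list[float]:
    return [t0] + sorted(set(interior)) + [tf]


def simulate_open_loop(
    model: TremorModelParams,
    u_signal: Callable[[float], float] | float,
    t_span: tuple[float, float],
    init: PlantState = (1.0, 0.0),
    sample_rate: float = 1000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    extra_breakpoints: list[float] | None = None,
) -> Trajectory:
    """Integrate the open-loop plant under a prescribed stimulation signal.

    ``u_signal`` may be a constant or a callable t -> volts defined on
    t_span.  Integration is split at schedule breakpoints so that parameter
    steps do not degrade the adaptive step-size control.
    """
    t0, tf = float(t_span[0]), float(t_span[1])
    if not tf > t0:
        raise ValueError("t_span must satisfy tf > t0")
    if callable(u_signal):
        u_fun = u_signal
    else:
        u_const = float(u_signal)
        u_fun = lambda t: u_const  # noqa: E731

    def rhs(t, z):
        return drift(model, z, u_fun(t), t)

    interior = model.breakpoints(t0, tf)
    if extra_breakpoints:
        interior += [t for t in extra_breakpoints if t0 < t < tf]
    edges = _segment_edges(t0, tf, interior)

    n = int(round((tf - t0) * sample_rate)) + 1
    t_eval = np.linspace(t0, tf, n)

    ts, x1s, x2s = [], [], []
    z = np.asarray(init, dtype=float)
    for a, b_edge in zip(edges[:-1], edges[1:]):
        last = b_edge == tf
        seg_mask = (t_eval >= a) & ((t_eval <= b_edge) if last else (t_eval < b_edge))
        seg_eval = t_eval[seg_mask]
        # always evaluate the segment end so the next segment restarts exactly there
        eval_pts = np.union1d(seg_eval, [b_edge])
        sol = solve_ivp(rhs, (a, b_edge), z, method=method, rtol=rtol, atol=atol,
                        t_eval=eval_pts)
        if not sol.success:
            raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else a)
        keep = np.isin(sol.t, seg_eval)
        if keep.any():
            ts.append(sol.t[keep])
            x1s.append(sol.y[0][keep])
            x2s.append(sol.y[1][keep])
        z = sol.y[:, -1]

    t_arr = np.concatenate(ts)
    x1 = np.concatenate(x1s)
    x2 = np.concatenate(x2s)
    u_arr = np.asarray([u_fun(t) for t in t_arr])
    return Trajectory(t=t_arr, x1=x1, x2=x2, y=model.output(x1), u=u_arr)
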