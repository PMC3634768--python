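"""Time-varying parameter schedules for the tremor models.

Tremor strength ``C(t)`` and angular frequency ``omega(t)`` drift on the time
scale of minutes as the underlying neuronal state changes.  A
:class:`ParamSchedule` captures the three shapes needed for scenario design:
a constant, a piecewise-constant step sequence (left-closed / right-open in
time, i.e. the new value applies *from* its breakpoint onward), and a
piecewise-linear ramp.  Evaluation is defined for all t >= 0 with constant
extrapolation beyond the last breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParamSchedule", "eval_schedule"]

_KINDS = ("constant", "piecewise-constant", "piecewise-linear")


@dataclass(frozen=True)
class ParamSchedule:
    """A scalar parameter as a function of time.

    Parameters
    ----------
    kind
        One of ``constant``, ``piecewise-constant``, ``piecewise-linear``.
    breakpoints
        Strictly increasing times (s).  For ``constant`` a single time
        (conventionally 0.0).
    values
        Parameter value at each breakpoint.
    """

    kind: str
    breakpoints: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}; expected one of {_KINDS}")
        object.__setattr__(self, "breakpoints", tuple(float(t) for t in self.breakpoints))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.breakpoints) != len(self.values):
            raise ValueError("breakpoints and values must have equal length")
        if len(self.breakpoints) == 0:
            raise ValueError("schedule needs at least one breakpoint")
        bp = np.asarray(self.breakpoints)
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.kind == "constant" and len(self.values) != 1:
            raise ValueError("constant schedule takes exactly one value")

    # -- constructors -------------------------------------------------------

    @staticmethod
    def constant(value: float) -> "ParamSchedule":
        return ParamSchedule("constant", (0.0,), (float(value),))

    @staticmethod
    def step(breakpoints, values) -> "ParamSchedule":
        return ParamSchedule("piecewise-constant", tuple(breakpoints), tuple(values))

    @staticmethod
    def ramp(breakpoints, values) -> "ParamSchedule":
        return ParamSchedule("piecewise-linear", tuple(breakpoints), tuple(values))

    # -- evaluation ---------------------------------------------------------

    @property
    def is_constant(self) -> bool:
        return self.kind == "constant" or len(set(self.values)) == 1

    def __call__(self, t):
        """Evaluate at time ``t`` (scalar or array), t >= 0."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0.0):
            raise ValueError("schedules are defined for t >= 0 only")
        if self.kind == "constant":
            out = np.full_like(t_arr, self.values[0])
        elif self.kind == "piecewise-constant":
            bp = np.asarray(self.breakpoints)
            # left-closed intervals: value j applies on [t_j, t_{j+1})
            idx = np.clip(np.searchsorted(bp, t_arr, side="right") - 1, 0, len(bp) - 1)
            out = np.asarray(self.values)[idx]
        else:
            out = np.interp(t_arr, self.breakpoints, self.values)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def scalar_fn(self):
        """A fast scalar-time evaluator for use inside ODE right-hand sides."""
        if self.kind == "constant" or len(self.values) == 1:
            v = self.values[0]
            return lambda t: v
        if self.kind == "piecewise-constant":
            from bisect import bisect_right

            bp, vals = self.breakpoints, self.values
            return lambda t: vals[max(bisect_right(bp, t) - 1, 0)]
        bp = np.asarray(self.breakpoints)
        vals = np.asarray(self.values)
        return lambda t: float(np.interp(t, bp, vals))

    def interior_breakpoints(self, t0: float, tf: float) -> list[float]:
        """Breakpoints strictly inside (t0, tf): integration segment edges."""
        if self.is_constant:
            return []
        return [t for t in self.breakpoints if t0 < t < tf]

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "breakpoints": list(self.breakpoints),
            "values": list(self.values),
        }

    @staticmethod
    def from_dict(d: dict) -> "ParamSchedule":
        return ParamSchedule(d["kind"], tuple(d["breakpoints"]), tuple(d["values"]))


def eval_schedule(schedule: ParamSchedule, t) -> float:
    """Functional alias for ``schedule(t)``."""
    return schedule(t)
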