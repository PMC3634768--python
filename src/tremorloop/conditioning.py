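"""Actuator-side signal conditioning for the stimulation amplitude.

Safety requires the commanded stimulation amplitude to stay inside the
device range (typically 0-5 V) and to change slowly: fast amplitude jumps
are undesirable in DBS.  Two stages implement this:

* a static saturation clamping the raw control signal to [u_min, u_max];
* a dynamic rate limiter, a first-order tracking law with a hard slew clamp,

      ds/dt = clip(rl_gain * (u_in - s), -R, +R),

  whose state s is the delivered amplitude.  |ds/dt| <= R always, and
  ds/dt = 0 exactly at s = u_in, so constant inputs are tracked without
  steady-state error.

A zero-phase Butterworth band-pass is provided for sensor-side isolation of
the tremor band (default 3-12 Hz) from the measured signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["ConditioningConfig", "saturate", "rate_limiter_rhs", "bandpass_filter"]


@dataclass(frozen=True)
class ConditioningConfig:
    """Actuator limits and rate-limiter parameters.

    u_min, u_max : stimulation amplitude range (V), default 0-5 V
    R            : maximum slew rate of the delivered amplitude (V/s)
    rl_gain      : rate-limiter tracking gain (1/s); sets how fast the
                   limiter closes small errors once inside the slew budget
    """

    u_min: float = 0.0
    u_max: float = 5.0
    R: float = 1.0
    rl_gain: float = 50.0
    sat_enabled: bool = True
    rl_enabled: bool = True

    def __post_init__(self) -> None:
        if not self.u_min < self.u_max:
            raise ValueError("need u_min < u_max")
        if self.R <= 0.0 or self.rl_gain <= 0.0:
            raise ValueError("R and rl_gain must be positive")

    def to_dict(self) -> dict:
        return {
            "u_min": self.u_min, "u_max": self.u_max, "R": self.R,
            "rl_gain": self.rl_gain, "sat_enabled": self.sat_enabled,
            "rl_enabled": self.rl_enabled,
        }

    @staticmethod
    def from_dict(d: dict) -> "ConditioningConfig":
        return ConditioningConfig(
            u_min=float(d.get("u_min", 0.0)), u_max=float(d.get("u_max", 5.0)),
            R=float(d.get("R", 1.0)), rl_gain=float(d.get("rl_gain", 50.0)),
            sat_enabled=bool(d.get("sat_enabled", True)),
            rl_enabled=bool(d.get("rl_enabled", True)),
        )


def saturate(u, cfg: ConditioningConfig):
    """Clamp the control signal to [u_min, u_max]; identity inside the range."""
    return np.clip(u, cfg.u_min, cfg.u_max) if np.ndim(u) else float(min(max(u, cfg.u_min), cfg.u_max))


def rate_limiter_rhs(state: float, u_in: float, cfg: ConditioningConfig) -> float:
    """ds/dt of the rate limiter: first-order tracking with slew clamp."""
    d = cfg.rl_gain * (u_in - state)
    if d > cfg.R:
        return cfg.R
    if d < -cfg.R:
        return -cfg.R
    return d


def bandpass_filter(y: np.ndarray, fs: float, band: tuple[float, float] = (3.0, 12.0),
                    order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a sampled signal.

    ``order`` is the order per band edge (scipy convention); the default
    3-12 Hz band brackets the 4-6 Hz parkinsonian tremor band.
    """
    lo, hi = band
    if not 0.0 < lo < hi < fs / 2.0:
        raise ValueError("band must satisfy 0 < lo < hi < fs/2")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(y, dtype=float))
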