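"""Adaptive output-feedback control of tremor and closed-loop simulation.

The controller measures only the filtered tremor output y and maintains one
internal state, the adaptive estimate ``u_hat`` of the nominal stimulation
amplitude A_n:

    control law      u_raw   = u_hat - k * y
    adaptation law   du_hat  = -gamma * y

At y = 0 the control passes the converged estimate through unchanged and the
adaptation freezes, which is what makes the steady-state argument work: if
the tremor settles to zero in finite time, the plant equilibrium forces
u_hat = A_n exactly.

Lyapunov diagnostic.  Along the closed loop the function

    V = x1^2 / (2 C(t)) + s x2^2 / 2 + (u_hat - A_n)^2 / (2 gamma)

is positive definite, and its derivative satisfies dV/dt <= z^T M z with
z = (|x1|, |x2|) whenever the plant parameters stay in the bounds the
certificate M was built from (see :mod:`tremorloop.synthesis`).  The two
uncertain cross terms cancel *exactly*: the 1/(2C) weight removes the
unknown C from the input term, and the adaptation law removes the
x1*(u_hat - A_n) term.  The simulator records V along the trajectory so the
monotone decrease can be checked numerically rather than assumed.

Loop modes: ``raw`` feeds u_raw to the plant (the setting under which the
certificate applies); ``conditioned`` feeds the saturated, rate-limited
signal (the realistic actuator path).  Both signals are recorded either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import solve_ivp

from .conditioning import ConditioningConfig
from .models import IntegrationError, TremorModelParams
from .synthesis import ControllerGains, ParameterBounds, build_certificate

__all__ = [
    "control_law",
    "adaptation_rhs",
    "lyapunov_value",
    "simulate_closed_loop",
    "steady_state_time",
    "ClosedLoopTrajectory",
    "InfeasibleGainsError",
]


class InfeasibleGainsError(RuntimeError):
    """Refused to close the loop with gains whose certificate is not negative definite."""


def control_law(gains: ControllerGains, y: float, u_hat: float) -> float:
    """Raw stimulation-amplitude command u_raw = u_hat - k*y (memoryless)."""
    return float(u_hat) - gains.k * float(y)


def adaptation_rhs(gains: ControllerGains, y: float, u_hat: float) -> float:
    """du_hat/dt = -gamma * y; zero exactly at y = 0."""
    return -gains.gamma * float(y)


def lyapunov_value(gains: ControllerGains, state, u_hat, A_n: float, C) -> float:
    """V(state, u_hat) >= 0, zero only at (x, u_hat - A_n) = 0.

    ``C`` is the instantaneous tremor-strength parameter C(t) > 0 (the x1
    weight is 1/(2C), which is what makes the unknown input coefficient
    cancel from dV/dt).  Accepts scalars or aligned arrays.
    """
    x1 = np.asarray(state[0], dtype=float)
    x2 = np.asarray(state[1], dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(C <= 0.0):
        raise ValueError("C must be positive")
    ut = np.asarray(u_hat, dtype=float) - float(A_n)
    V = x1**2 / (2.0 * C) + gains.s * x2**2 / 2.0 + ut**2 / (2.0 * gains.gamma)
    return float(V) if V.ndim == 0 else V


# ---------------------------------------------------------------------------
# closed-loop trajectory container
# ---------------------------------------------------------------------------

@dataclass
class ClosedLoopTrajectory:
    """Sampled closed-loop run: plant, controller, conditioning and V."""

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray
    u_raw: np.ndarray
    u_sat: np.ndarray
    u_rl: np.ndarray
    u_hat: np.ndarray
    V: np.ndarray
    t_on: float
    A_n: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "x1": self.x1, "x2": self.x2, "y": self.y,
            "u_raw": self.u_raw, "u_sat": self.u_sat, "u_rl": self.u_rl,
            "u_hat": self.u_hat, "V": self.V,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def window_rms(self, t_lo: float, t_hi: float) -> float:
        mask = (self.t >= t_lo) & (self.t <= t_hi)
        if not mask.any():
            raise ValueError("empty window")
        return float(np.sqrt(np.mean(self.y[mask] ** 2)))

    def pre_controller_rms(self) -> float:
        """RMS of y over the open-loop phase [t0, t_on]."""
        return self.window_rms(float(self.t[0]), self.t_on)

    def trailing_rms(self, window: float = 2.0) -> float:
        """RMS of y over the last ``window`` seconds."""
        return self.window_rms(float(self.t[-1]) - window, float(self.t[-1]))


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

def _analog_bandpass_ss(band: tuple[float, float], order: int = 2):
    """Continuous-time Butterworth band-pass in state-space form."""
    lo, hi = band
    if not 0.0 < lo < hi:
        raise ValueError("band must satisfy 0 < lo < hi")
    b, a = sps.butter(order, [2.0 * math.pi * lo, 2.0 * math.pi * hi],
                      btype="bandpass", analog=True)
    A, B, Cm, D = sps.tf2ss(b, a)
    return A, B.ravel(), Cm.ravel(), float(np.asarray(D).ravel()[0])


def simulate_closed_loop(
    model: TremorModelParams,
    gains: ControllerGains,
    conditioning: ConditioningConfig | None = None,
    t_on: float = 0.0,
    t_span: tuple[float, float] = (0.0, 20.0),
    init=(1.0, 0.0),
    u_hat0: float = 0.0,
    baseline_u: float = 0.0,
    mode: str = "conditioned",
    sample_rate: float = 1000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    bounds: ParameterBounds | None = None,
    allow_infeasible: bool = False,
    project_u_hat: bool = False,
    noise_std: float = 0.0,
    noise_hold_dt: float = 0.005,
    filter_band: tuple[float, float] | None = None,
    seed: int | None = None,
) -> ClosedLoopTrajectory:
    """Integrate plant + adaptation + rate limiter as one augmented ODE.

    Before ``t_on`` the plant runs open loop at ``baseline_u`` with the
    adaptation frozen at ``u_hat0``.  ``mode`` selects which signal drives
    the plant after t_on: ``raw`` (u_raw, matching the certificate's
    assumptions) or ``conditioned`` (the rate-limited output).  If ``bounds``
    are supplied the gains' certificate is verified first and infeasible
    gains are refused unless ``allow_infeasible``.

    Optional realism features (all off by default): ``project_u_hat`` clamps
    the adaptation state to the actuator range (anti-windup), ``noise_std``
    adds seeded zero-order-hold Gaussian noise to the measured output, and
    ``filter_band`` inserts a causal continuous-time Butterworth band-pass
    between sensor and controller.
    """
    cond = conditioning or ConditioningConfig()
    t0, tf = float(t_span[0]), float(t_span[1])
    if not (t0 <= t_on <= tf):
        raise ValueError("need t0 <= t_on <= tf")
    if mode not in ("raw", "conditioned"):
        raise ValueError("mode must be 'raw' or 'conditioned'")

    if bounds is not None and not allow_infeasible:
        cert = build_certificate(gains, bounds)
        if not cert.feasible:
            raise InfeasibleGainsError(
                f"certificate max eigenvalue {cert.max_eigenvalue:.3e} is not < -{cert.tol:g}; "
                "pass allow_infeasible=True to override"
            )

    C_fn = model.C.scalar_fn()
    w_fn = model.omega.scalar_fn()
    phi = model.phi
    a_c, b_c, A_n, y_scale = model.a, model.b, model.A_n, model.y_scale
    k, gamma = gains.k, gains.gamma
    u_min, u_max, R, rl_gain = cond.u_min, cond.u_max, cond.R, cond.rl_gain
    sat_on, rl_on = cond.sat_enabled, cond.rl_enabled
    conditioned = mode == "conditioned"

    # optional sensor-side causal band-pass as extra ODE states
    if filter_band is not None:
        Af, Bf, Cf, Df = _analog_bandpass_ss(filter_band)
        nf = Af.shape[0]
    else:
        Af = Bf = Cf = None
        Df = 0.0
        nf = 0

    # optional zero-order-hold measurement noise
    if noise_std > 0.0:
        rng = np.random.default_rng(seed)
        n_hold = int(math.ceil((tf - t0) / noise_hold_dt)) + 1
        noise_seq = rng.normal(0.0, noise_std, n_hold)

        def noise_at(t: float) -> float:
            return float(noise_seq[min(int((t - t0) / noise_hold_dt), n_hold - 1)])
    else:
        def noise_at(t: float) -> float:
            return 0.0

    def measured_output(t: float, z) -> float:
        """Controller-side output: scaled x1 plus noise, then the filter."""
        y_m = y_scale * z[0] + noise_at(t)
        if nf:
            return float(Cf @ z[4:4 + nf]) + Df * y_m
        return y_m

    def rhs(t, z, active):
        x1, x2, u_hat, u_rl = z[0], z[1], z[2], z[3]
        c = C_fn(t)
        w = w_fn(t)
        y_ctrl = measured_output(t, z)
        if active:
            u_raw = u_hat - k * y_ctrl
            u_sat = min(max(u_raw, u_min), u_max) if sat_on else u_raw
            du_hat = -gamma * y_ctrl
            if project_u_hat:
                if (u_hat >= u_max and du_hat > 0.0) or (u_hat <= u_min and du_hat < 0.0):
                    du_hat = 0.0
        else:
            u_sat = baseline_u
            du_hat = 0.0
        d_rl = rl_gain * (u_sat - u_rl)
        d_rl = R if d_rl > R else (-R if d_rl < -R else d_rl)
        if active:
            u_plant = (u_rl if rl_on else u_sat) if conditioned else u_hat - k * y_ctrl
        else:
            u_plant = baseline_u
        dx1 = x2 + c * (u_plant - A_n)
        dx2 = -w * w * x1 - b_c * x2
        if a_c != 0.0:
            dx2 -= a_c * float(phi(x1))
        out = [dx1, dx2, du_hat, d_rl]
        if nf:
            y_m = y_scale * x1 + noise_at(t)
            out.extend(Af @ z[4:4 + nf] + Bf * y_m)
        return out

    # segment edges: t_on plus schedule breakpoints
    interior = sorted(set(model.breakpoints(t0, tf)) | ({t_on} if t0 < t_on < tf else set()))
    edges = [t0] + interior + [tf]

    n = int(round((tf - t0) * sample_rate)) + 1
    t_eval = np.linspace(t0, tf, n)

    z0 = np.zeros(4 + nf)
    z0[0], z0[1] = float(init[0]), float(init[1])
    z0[2] = float(u_hat0)
    z0[3] = float(baseline_u)  # rate limiter starts at the baseline amplitude

    ts, zs = [], []
    z = z0
    for a_edge, b_edge in zip(edges[:-1], edges[1:]):
        active = a_edge >= t_on
        last = b_edge == tf
        seg_mask = (t_eval >= a_edge) & ((t_eval <= b_edge) if last else (t_eval < b_edge))
        seg_eval = t_eval[seg_mask]
        eval_pts = np.union1d(seg_eval, [b_edge])
        sol = solve_ivp(rhs, (a_edge, b_edge), z, args=(active,), method=method,
                        rtol=rtol, atol=atol, t_eval=eval_pts)
        if not sol.success:
            raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else a_edge)
        keep = np.isin(sol.t, seg_eval)
        if keep.any():
            ts.append(sol.t[keep])
            zs.append(sol.y[:, keep])
        z = sol.y[:, -1]

    t_arr = np.concatenate(ts)
    Z = np.concatenate(zs, axis=1)
    x1, x2, u_hat, u_rl_state = Z[0], Z[1], Z[2], Z[3]

    # reconstruct recorded signals at the samples
    y_true = model.output(x1)
    if nf or noise_std > 0.0:
        y_ctrl = np.array([measured_output(t, Z[:, i]) for i, t in enumerate(t_arr)])
    else:
        y_ctrl = y_true
    active_mask = t_arr >= t_on
    u_raw = np.where(active_mask, u_hat - k * y_ctrl, baseline_u)
    u_sat_arr = np.clip(u_raw, u_min, u_max) if sat_on else u_raw.copy()
    u_sat_arr = np.where(active_mask, u_sat_arr, baseline_u)

    C_t = np.asarray(model.C(t_arr), dtype=float)
    V = lyapunov_value(gains, (x1, x2), u_hat, A_n, C_t)

    return ClosedLoopTrajectory(
        t=t_arr, x1=x1, x2=x2, y=y_true,
        u_raw=u_raw, u_sat=u_sat_arr, u_rl=u_rl_state, u_hat=u_hat,
        V=np.asarray(V), t_on=float(t_on), A_n=float(A_n),
    )


# ---------------------------------------------------------------------------
# settling detection
# ---------------------------------------------------------------------------

def steady_state_time(
    traj: ClosedLoopTrajectory,
    eps: float = 1e-2,
    window: float = 1.0,
) -> float | None:
    """Earliest t at which the loop has settled, or None.

    Settled means: over [t, t + window], max |y| < eps and the total
    variation headroom of u_hat (max adjacent-sample |change|) < eps.
    """
    t = traj.t
    if len(t) < 2:
        raise ValueError("trajectory too short")
    dt = float(t[1] - t[0])
    span = float(t[-1] - t[0])
    if not 0.0 < window < span:
        raise ValueError("window must be positive and shorter than the trajectory")
    w = max(int(round(window / dt)), 2)
    if w > len(t):
        return None
    abs_y = np.abs(traj.y)
    du = np.abs(np.diff(traj.u_hat))
    y_max = np.lib.stride_tricks.sliding_window_view(abs_y, w).max(axis=1)
    du_max = np.lib.stride_tricks.sliding_window_view(du, w - 1).max(axis=1)
    m = min(len(y_max), len(du_max))
    ok = (y_max[:m] < eps) & (du_max[:m] < eps)
    idx = np.argmax(ok)
    if not ok.any():
        return None
    return float(t[idx])
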