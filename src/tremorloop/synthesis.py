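"""Gain synthesis and stability certificates for the adaptive tremor controller.

The adaptive output-feedback law (see :mod:`tremorloop.control`)

    u      = u_hat - k * y
    du_hat = -gamma * y

admits the Lyapunov function V = x1^2/(2 C(t)) + s x2^2/2 + (u_hat - A_n)^2/(2 gamma).
Along the closed loop, after the exact cancellation of the unknown-C input
term and of the adaptation term, the derivative is bounded by

    dV/dt <= z^T M z,    z = (|x1|, |x2|),

where the symmetric certificate matrix M is assembled from the scalar gains
(k, s, eps) and the assumed parameter box (bounds on C, omega,
|dC/dt|, |a|, a lower bound on b, and the Lipschitz constant L of phi):

    M11 = -k + Cdot_max / (2 C_min^2) + s a_max L eps / 2
    M12 = theta / 2,    theta = max over the box corners of |1/C - s omega^2|
    M22 = -s b_min + s a_max L / (2 eps)

``eps`` is the Young-inequality slack splitting the nonlinearity cross term
s a x2 phi(x1); gamma cancels out of M entirely.  M < 0 (negative definite)
certifies dV/dt <= 0, hence tremor convergence; the synthesizer searches a
deterministic logarithmic grid over (k, s, eps) for a feasible point and
locally refines the margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import Nonlinearity

__all__ = [
    "ParameterBounds",
    "ControllerGains",
    "Certificate",
    "estimate_lipschitz",
    "check_lipschitz",
    "build_certificate",
    "synthesize_gains",
    "sylvester_negative_definite",
    "SynthesisInfeasibleError",
]

DEFAULT_ND_TOL = 1e-9  # strict-inequality margin for M < 0


class SynthesisInfeasibleError(RuntimeError):
    """No feasible gain set inside the search box; carries a structured report."""

    def __init__(self, report: dict):
        self.report = report
        super().__init__(
            "no feasible controller gains in the search box; "
            f"bounds={report['bounds']}, search={report['search']}"
        )


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds on the tremor-model parameters.

    ``a_max`` bounds |a| from above; ``b_min`` bounds the stabilization
    coefficient b from BELOW (the certificate needs guaranteed damping);
    ``L`` is the Lipschitz constant of phi on its working domain.
    """

    C_min: float
    C_max: float
    omega_min: float
    omega_max: float
    Cdot_max: float = 0.0
    a_max: float = 0.0
    b_min: float = 0.0
    L: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.C_min <= self.C_max:
            raise ValueError("need 0 < C_min <= C_max")
        if not 0.0 < self.omega_min <= self.omega_max:
            raise ValueError("need 0 < omega_min <= omega_max")
        if self.Cdot_max < 0.0 or self.a_max < 0.0 or self.L < 0.0:
            raise ValueError("Cdot_max, a_max and L must be nonnegative")
        if self.b_min < 0.0:
            raise ValueError("b_min must be nonnegative")
        if self.a_max > 0.0 and self.L > 0.0 and self.b_min == 0.0:
            # the nonlinearity term cannot be dominated without damping
            raise ValueError("a_max * L > 0 requires b_min > 0")

    def contains(self, C: float, omega: float, a: float = 0.0, b: float = 0.0) -> bool:
        return (
            self.C_min <= C <= self.C_max
            and self.omega_min <= omega <= self.omega_max
            and abs(a) <= self.a_max + 1e-12
            and b >= self.b_min - 1e-12
        )

    def to_dict(self) -> dict:
        return {
            "C_min": self.C_min, "C_max": self.C_max,
            "omega_min": self.omega_min, "omega_max": self.omega_max,
            "Cdot_max": self.Cdot_max, "a_max": self.a_max,
            "b_min": self.b_min, "L": self.L,
        }

    @staticmethod
    def from_dict(d: dict) -> "ParameterBounds":
        return ParameterBounds(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class ControllerGains:
    """Scalar gains of the adaptive controller.

    k      output-feedback gain (V per output unit), > 0
    s      Lyapunov weight on x2^2, > 0
    gamma  adaptation gain (output units -> V/s), > 0; does not enter M
    eps    Young-inequality slack for the nonlinearity cross term, > 0
    """

    k: float
    s: float
    gamma: float
    eps: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k", "s", "gamma", "eps"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"gain {name} must be positive")

    def to_dict(self) -> dict:
        return {"k": self.k, "s": self.s, "gamma": self.gamma, "eps": self.eps}

    @staticmethod
    def from_dict(d: dict) -> "ControllerGains":
        return ControllerGains(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class Certificate:
    """The certificate matrix M, its top eigenvalue, and the feasibility flag."""

    M: np.ndarray
    max_eigenvalue: float
    feasible: bool
    tol: float = DEFAULT_ND_TOL

    @property
    def margin(self) -> float:
        """How far below zero the top eigenvalue sits (positive if feasible)."""
        return -self.max_eigenvalue


# ---------------------------------------------------------------------------
# Lipschitz machinery
# ---------------------------------------------------------------------------

def _grid(region: tuple[float, float], n_grid: int) -> np.ndarray:
    lo, hi = float(region[0]), float(region[1])
    if not np.isfinite(lo) or not np.isfinite(hi) or not lo < hi:
        raise ValueError("region must be a bounded nonempty interval")
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    return np.linspace(lo, hi, int(n_grid))


def estimate_lipschitz(
    phi: Nonlinearity,
    region: tuple[float, float] | None = None,
    n_grid: int = 2001,
    safety_factor: float = 1.05,
) -> float:
    """Numerically estimate the Lipschitz constant of phi on a bounded region.

    The maximum secant slope over all grid pairs equals the maximum over
    adjacent pairs (every secant is a convex combination of adjacent
    secants), so adjacent pairs suffice.  For differentiable phi the analytic
    |phi'| is also sampled and the larger value is taken.  The result is
    inflated by ``safety_factor`` (>= 1) because grid sampling
    under-estimates suprema.
    """
    if safety_factor < 1.0:
        raise ValueError("safety_factor must be >= 1")
    region = region or phi.domain
    x = _grid(region, n_grid)
    fx = np.asarray(phi(x), dtype=float)
    slopes = np.abs(np.diff(fx) / np.diff(x))
    L = float(slopes.max()) if len(slopes) else 0.0
    if phi.has_derivative:
        L = max(L, float(np.max(np.abs(phi.derivative(x)))))
    return L * safety_factor


def check_lipschitz(
    phi: Nonlinearity,
    L: float,
    region: tuple[float, float] | None = None,
    n_grid: int = 2001,
) -> tuple[bool, tuple[float, float] | None]:
    """Verify |phi(x) - phi(y)| <= L |x - y| on all sampled pairs.

    Returns (passed, worst_pair); worst_pair is the adjacent grid pair with
    the largest secant slope when the check fails, else None.
    """
    if L < 0.0:
        raise ValueError("L must be nonnegative")
    region = region or phi.domain
    x = _grid(region, n_grid)
    fx = np.asarray(phi(x), dtype=float)
    slopes = np.abs(np.diff(fx) / np.diff(x))
    worst = int(np.argmax(slopes))
    if slopes[worst] <= L * (1.0 + 1e-12):
        return True, None
    return False, (float(x[worst]), float(x[worst + 1]))


# ---------------------------------------------------------------------------
# certificate
# ---------------------------------------------------------------------------

def _theta(s: float, bounds: ParameterBounds) -> float:
    """max |1/C - s omega^2| over the parameter box (attained at a corner)."""
    vals = [
        abs(1.0 / C - s * w * w)
        for C in (bounds.C_min, bounds.C_max)
        for w in (bounds.omega_min, bounds.omega_max)
    ]
    return max(vals)


def build_certificate(
    gains: ControllerGains,
    bounds: ParameterBounds,
    tol: float = DEFAULT_ND_TOL,
) -> Certificate:
    """Assemble M from gains and bounds and test negative definiteness."""
    k, s, eps = gains.k, gains.s, gains.eps
    g = s * bounds.a_max * bounds.L
    m11 = -k + bounds.Cdot_max / (2.0 * bounds.C_min**2) + g * eps / 2.0
    m22 = -s * bounds.b_min + g / (2.0 * eps)
    m12 = _theta(s, bounds) / 2.0
    M = np.array([[m11, m12], [m12, m22]], dtype=float)
    lam = float(np.linalg.eigvalsh(M)[-1])
    return Certificate(M=M, max_eigenvalue=lam, feasible=lam < -tol, tol=tol)


def sylvester_negative_definite(M: np.ndarray, tol: float = DEFAULT_ND_TOL) -> bool:
    """Negative definiteness of a symmetric 2x2 via leading principal minors.

    M < 0  iff  M11 < 0 and det(M) > 0 (with the strict-inequality margin).
    Used as an independent cross-check of the eigenvalue test.
    """
    M = np.asarray(M, dtype=float)
    return bool(M[0, 0] < -tol and (M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]) > tol * tol)


# ---------------------------------------------------------------------------
# deterministic gain search
# ---------------------------------------------------------------------------

def default_gamma(bounds: ParameterBounds) -> float:
    """Default adaptation gain: couple at least as stiffly as the plant.

    gamma = omega_max^2 / C_min makes C*gamma comparable to omega^2, which
    puts the slow (estimation) eigenvalue of the linearized loop near the
    plant damping b rather than far below it.
    """
    return bounds.omega_max**2 / bounds.C_min


def synthesize_gains(
    bounds: ParameterBounds,
    margin: float = DEFAULT_ND_TOL,
    points_per_decade: int = 20,
    decades: float = 4.0,
    gamma: float | None = None,
    refine: bool = True,
) -> ControllerGains:
    """Find scalar gains whose certificate is negative definite.

    Deterministic search: a logarithmic grid per scalar (``points_per_decade``
    points per decade over ``decades`` decades, centred on an analytic guess),
    first-feasible-wins in a fixed iteration order (s nearest its optimum
    first, then eps, then k ascending), followed by a greedy multiplicative
    coordinate refinement of the margin.  Raises
    :class:`SynthesisInfeasibleError` with a structured report if the box is
    exhausted.
    """
    gamma = default_gamma(bounds) if gamma is None else float(gamma)

    # analytic centres: s* minimizes theta; eps* balances the nonlinearity split
    s_star = (1.0 / bounds.C_min + 1.0 / bounds.C_max) / (bounds.omega_min**2 + bounds.omega_max**2)
    if bounds.a_max * bounds.L > 0.0:
        eps_star = max(1.0, bounds.a_max * bounds.L / bounds.b_min)
    else:
        eps_star = 1.0
    k_star = 1.0 + bounds.Cdot_max / (2.0 * bounds.C_min**2)

    half = decades / 2.0
    n_pts = int(points_per_decade * decades) + 1

    def loggrid(center: float) -> np.ndarray:
        return center * np.logspace(-half, half, n_pts)

    s_grid = loggrid(s_star)
    s_grid = s_grid[np.argsort(np.abs(np.log(s_grid / s_star)), kind="stable")]
    eps_grid = loggrid(eps_star)
    eps_grid = eps_grid[np.argsort(np.abs(np.log(eps_grid / eps_star)), kind="stable")]
    k_grid = k_star * np.logspace(0.0, decades, n_pts)  # k only needs to grow

    found: ControllerGains | None = None
    for s in s_grid:
        for eps in eps_grid:
            for k in k_grid:
                g = ControllerGains(k=float(k), s=float(s), gamma=gamma, eps=float(eps))
                if build_certificate(g, bounds, tol=margin).feasible:
                    found = g
                    break
            if found:
                break
        if found:
            break

    if found is None:
        raise SynthesisInfeasibleError({
            "bounds": bounds.to_dict(),
            "search": {
                "s_range": [float(s_grid.min()), float(s_grid.max())],
                "eps_range": [float(eps_grid.min()), float(eps_grid.max())],
                "k_range": [float(k_grid.min()), float(k_grid.max())],
                "points_per_decade": points_per_decade,
                "margin": margin,
            },
        })

    if refine:
        found = _refine(found, bounds, margin)
    return found


def _relative_margin(gains: ControllerGains, bounds: ParameterBounds, margin: float) -> float:
    """-lambda_max(M) normalized by ||M||_F: scale-free negativity margin.

    The absolute margin grows without bound with k, which would drive the
    refinement toward uselessly stiff feedback; the normalized margin
    rewards a well-conditioned negative M instead.
    """
    cert = build_certificate(gains, bounds, tol=margin)
    if not cert.feasible:
        return -np.inf
    return cert.margin / float(np.linalg.norm(cert.M))


def _refine(gains: ControllerGains, bounds: ParameterBounds, margin: float,
            rounds: int = 12) -> ControllerGains:
    """Greedy multiplicative coordinate descent on the normalized margin."""
    best = gains
    best_obj = _relative_margin(best, bounds, margin)
    factors = (0.5, 0.8, 1.25, 2.0)
    for _ in range(rounds):
        improved = False
        for name in ("k", "s", "eps"):
            for f in factors:
                d = best.to_dict()
                d[name] = d[name] * f
                cand = ControllerGains.from_dict(d)
                obj = _relative_margin(cand, bounds, margin)
                if obj > best_obj * (1.0 + 1e-9):
                    best, best_obj = cand, obj
                    improved = True
        if not improved:
            break
    return best
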