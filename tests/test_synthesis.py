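import numpy as np
import pytest

from tremorloop import (
    ControllerGains,
    Nonlinearity,
    ParameterBounds,
    SynthesisInfeasibleError,
    build_certificate,
    check_lipschitz,
    estimate_lipschitz,
    odd_power,
    synthesize_gains,
    sylvester_negative_definite,
)
from tremorloop.fixtures import case_bounds, recovery_bounds

identity = Nonlinearity("custom", func=lambda x: np.asarray(x, dtype=float),
                        dfunc=lambda x: np.ones_like(np.asarray(x, dtype=float)),
                        domain=(-5.0, 5.0))


class TestLipschitzEstimation:
    def test_identity_slope_one(self):
        assert estimate_lipschitz(identity, (-5, 5), safety_factor=1.0) == pytest.approx(1.0)

    def test_cubic_on_unit_interval(self):
        L = estimate_lipschitz(odd_power(3), (-1, 1), safety_factor=1.0)
        assert L == pytest.approx(3.0, rel=1e-3)

    def test_zero_function(self):
        zero = Nonlinearity("zero")
        assert estimate_lipschitz(zero, (-1, 1), safety_factor=1.0) == 0.0

    def test_safety_factor_inflates(self):
        L1 = estimate_lipschitz(odd_power(3), (-1, 1), safety_factor=1.0)
        L2 = estimate_lipschitz(odd_power(3), (-1, 1), safety_factor=1.1)
        assert L2 == pytest.approx(1.1 * L1)

    def test_unbounded_region_rejected(self):
        with pytest.raises(ValueError):
            estimate_lipschitz(odd_power(3), (-np.inf, 1))


class TestLipschitzCheck:
    def test_cubic_passes_at_true_constant(self):
        ok, pair = check_lipschitz(odd_power(3), 3.0, (-1, 1))
        assert ok and pair is None

    def test_cubic_fails_at_understated_constant(self):
        ok, pair = check_lipschitz(odd_power(3), 1.0, (-1, 1))
        assert not ok
        # worst pair sits where |phi'| is maximal: the interval boundary
        assert max(abs(pair[0]), abs(pair[1])) > 0.9

    def test_identity_passes_with_equality(self):
        ok, _ = check_lipschitz(identity, 1.0, (-5, 5))
        assert ok

    @pytest.mark.parametrize("phi,region", [
        (odd_power(3), (-2.0, 2.0)),
        (odd_power(5), (-1.5, 1.5)),
        (Nonlinearity("cubic-fhn"), (-3.0, 3.0)),
    ])
    def test_estimator_soundness(self, phi, region):
        """check_lipschitz always passes at the estimator's own output."""
        L = estimate_lipschitz(phi, region, safety_factor=1.05)
        ok, _ = check_lipschitz(phi, L, region)
        assert ok


class TestCertificate:
    def test_diagonal_case_max_eigenvalue(self):
        # C == 1, omega == 1, s == 1 makes theta = 0; b_min = 1 and k = 1
        # give M = diag(-1, -1)
        bounds = ParameterBounds(C_min=1, C_max=1, omega_min=1, omega_max=1, b_min=1)
        gains = ControllerGains(k=1.0, s=1.0, gamma=1.0)
        cert = build_certificate(gains, bounds)
        np.testing.assert_allclose(cert.M, -np.eye(2))
        assert cert.max_eigenvalue == pytest.approx(-1.0)
        assert cert.feasible

    def test_nonnegative_diagonal_infeasible(self):
        # Cdot_max term overwhelms k: M11 >= 0
        bounds = ParameterBounds(C_min=0.1, C_max=1, omega_min=1, omega_max=1,
                                 Cdot_max=10.0, b_min=1)
        gains = ControllerGains(k=1.0, s=1.0, gamma=1.0)
        cert = build_certificate(gains, bounds)
        assert cert.M[0, 0] >= 0.0
        assert not cert.feasible

    def test_eigenvalue_agrees_with_sylvester_minors(self):
        rng = np.random.default_rng(11)
        agree = 0
        for _ in range(100):
            bounds = ParameterBounds(
                C_min=rng.uniform(0.5, 5), C_max=rng.uniform(5, 50),
                omega_min=rng.uniform(1, 10), omega_max=rng.uniform(10, 50),
                Cdot_max=rng.uniform(0, 2), a_max=rng.uniform(0, 1),
                b_min=rng.uniform(0.1, 3), L=rng.uniform(0, 10),
            )
            gains = ControllerGains(
                k=rng.uniform(0.1, 100), s=10.0 ** rng.uniform(-5, 0),
                gamma=1.0, eps=10.0 ** rng.uniform(-1, 3),
            )
            cert = build_certificate(gains, bounds)
            agree += cert.feasible == sylvester_negative_definite(cert.M, tol=cert.tol)
        assert agree == 100


class TestGainSynthesis:
    @pytest.mark.parametrize("bounds", [recovery_bounds(), case_bounds()])
    def test_returns_verified_gains(self, bounds):
        gains = synthesize_gains(bounds)
        cert = build_certificate(gains, bounds)
        assert cert.feasible and cert.max_eigenvalue < -1e-9
        assert sylvester_negative_definite(cert.M)

    def test_huge_lipschitz_constant_is_infeasible(self):
        b = recovery_bounds()
        inflated = ParameterBounds(**{**b.to_dict(), "L": b.L * 1e6})
        with pytest.raises(SynthesisInfeasibleError) as exc:
            synthesize_gains(inflated)
        assert "bounds" in exc.value.report and "search" in exc.value.report

    def test_tighter_bounds_do_not_shrink_margin(self):
        """At fixed gains, shrinking Cdot_max and L (where M is entry-wise
        monotone) can only improve the certificate margin."""
        loose = recovery_bounds()
        gains = synthesize_gains(loose)
        m_loose = build_certificate(gains, loose).margin
        tight = ParameterBounds(**{**loose.to_dict(),
                                   "Cdot_max": loose.Cdot_max / 4.0,
                                   "L": loose.L / 4.0})
        m_tight = build_certificate(gains, tight).margin
        assert m_tight >= m_loose

    def test_deterministic(self):
        g1 = synthesize_gains(case_bounds())
        g2 = synthesize_gains(case_bounds())
        assert g1 == g2


class TestValidation:
    def test_bounds_ordering_enforced(self):
        with pytest.raises(ValueError):
            ParameterBounds(C_min=2, C_max=1, omega_min=1, omega_max=2)

    def test_nonlinearity_without_damping_rejected(self):
        with pytest.raises(ValueError):
            ParameterBounds(C_min=1, C_max=2, omega_min=1, omega_max=2,
                            a_max=1.0, L=1.0, b_min=0.0)

    def test_gain_positivity_enforced(self):
        with pytest.raises(ValueError):
            ControllerGains(k=-1.0, s=1.0, gamma=1.0)
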