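"""Constitutive closures, force balance, time stepping and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteowave import (
    ConfigurationError,
    FieldState,
    FrontNearBoundaryError,
    NumericalInstabilityError,
    default_params,
    differentiation_rate,
    homeostatic_density,
    pressure,
    simulate,
    solve_force_balance,
    step,
    step_preset,
    stiffness_of_phi,
)
from osteowave.fronts import front_trajectory
from osteowave.model import stability_dt


# ---------------------------------------------------------------------------
# Closures
# ---------------------------------------------------------------------------

class TestStiffness:
    def test_endpoints_and_midpoint(self, params):
        assert stiffness_of_phi(0.0, params) == params.E_m
        assert stiffness_of_phi(1.0, params) == params.E_o
        assert stiffness_of_phi(0.5, params) == pytest.approx(
            (params.E_m + params.E_o) / 2
        )

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_bounded(self, a, b):
        p = default_params()
        lo, hi = sorted((a, b))
        assert stiffness_of_phi(lo, p) <= stiffness_of_phi(hi, p)
        assert p.E_m <= stiffness_of_phi(a, p) <= p.E_o

    def test_domain_error(self, params):
        with pytest.raises(ValueError):
            stiffness_of_phi(1.2, params)
        with pytest.raises(ValueError):
            stiffness_of_phi(-0.1, params)


class TestDifferentiationRate:
    def test_baseline_saturation_midpoint(self, params):
        assert differentiation_rate(params.E_m, params) == 0.0
        assert differentiation_rate(params.E_o, params) == pytest.approx(params.beta)
        mid = (params.E_m + params.E_o) / 2
        assert differentiation_rate(mid, params) == pytest.approx(params.beta / 2)

    def test_clamped_outside_range(self, params):
        assert differentiation_rate(10 * params.E_o, params) == params.beta
        assert differentiation_rate(0.0, params) == 0.0

    def test_negative_stiffness_rejected(self, params):
        with pytest.raises(ValueError):
            differentiation_rate(-1.0, params)


class TestPressure:
    def test_homeostatic_states_have_zero_pressure(self, params):
        assert pressure(params.rho0_m, 0.0, params) == 0.0
        assert pressure(params.rho0_o, 1.0, params) == 0.0

    def test_doubled_mesenchyme_density(self, params):
        assert pressure(2 * params.rho0_m, 0.0, params) == pytest.approx(params.E_m)

    def test_increasing_in_density(self, params):
        rhos = np.linspace(0, 3 * params.rho0_o, 50)
        P = pressure(rhos, 0.4, params)
        assert np.all(np.diff(P) > 0)


# ---------------------------------------------------------------------------
# Force balance
# ---------------------------------------------------------------------------

class TestForceBalance:
    def test_constant_pressure_gives_zero_velocity(self, params):
        P = np.full(64, 2.3)
        v = solve_force_balance(P, params, dx=2.0)
        assert np.allclose(v, 0.0)

    def test_frictional_balance_linear_pressure(self):
        # eta = 0: the balance is algebraic, v = -a/xi at interior points
        p = default_params(eta=0.0, xi=0.01)
        a = 0.05
        x = np.arange(32) * 2.0
        v = solve_force_balance(a * x, p, dx=2.0)
        assert np.allclose(v[1:-1], -a / p.xi)

    @pytest.mark.parametrize("n", [8, 16, 32, 64])
    def test_matches_dense_solve(self, n, rng):
        """Banded solver agrees with a dense solve of the same discretization."""
        p = default_params()
        dx = 2.0
        P = rng.normal(size=n)
        xi = p.xi * (1 + 10 * rng.random(n))
        v = solve_force_balance(P, p, dx, xi=xi)
        # dense oracle
        A = np.zeros((n - 2, n - 2))
        for i in range(n - 2):
            A[i, i] = -2 * p.eta / dx**2 - xi[i + 1]
            if i > 0:
                A[i, i - 1] = p.eta / dx**2
            if i < n - 3:
                A[i, i + 1] = p.eta / dx**2
        g = (P[2:] - P[:-2]) / (2 * dx)
        v_dense = np.zeros(n)
        v_dense[1:-1] = np.linalg.solve(A, g)
        assert np.max(np.abs(v - v_dense)) <= 1e-12 * max(1.0, np.max(np.abs(v_dense)))

    def test_lateral_overpressure_drives_medial_flow(self, params):
        # higher pressure at low x (bone side) pushes medially (+x)
        x = np.linspace(0, 200, 101)
        P = np.where(x < 100, 1.0, 0.0)
        v = solve_force_balance(P, params, dx=2.0)
        assert v[40:60].max() > 0

    def test_singular_system_rejected(self):
        p = default_params(eta=0.0, xi=0.01)
        with pytest.raises(ConfigurationError):
            solve_force_balance(np.zeros(16), p, 2.0, xi=np.zeros(16))


# ---------------------------------------------------------------------------
# Stepping: fixed points, conservation, positivity
# ---------------------------------------------------------------------------

def _uniform_state(params, phi, n=64):
    x = np.linspace(0, params.domain_length, n)
    rho = homeostatic_density(phi, params)
    return FieldState(
        x=x,
        rho_m=np.full(n, rho * (1 - phi)),
        rho_o=np.full(n, rho * phi),
        k=np.zeros(n),
        col=np.full(n, float(phi)),
        pg=np.zeros(n),
        v=np.zeros(n),
        t=0.0,
    )


class TestFixedPoints:
    @pytest.mark.parametrize("phi", [0.0, 1.0])
    def test_homogeneous_homeostatic_states_are_stationary(self, params, phi):
        s0 = _uniform_state(params, phi)
        s = s0.copy()
        for _ in range(20):
            s = step(s, params, dt=0.05)
        scale = max(params.rho0_m, params.rho0_o)
        assert np.max(np.abs(s.rho_m - s0.rho_m)) <= 1e-10 * scale
        assert np.max(np.abs(s.rho_o - s0.rho_o)) <= 1e-10 * scale


class TestConservation:
    def test_differentiation_conserves_cells_pointwise(self, params):
        """Pure conversion (no flow, growth or diffusion) moves cells between
        populations without changing their local total, exactly."""
        p = params.replace(D=0.0, alpha=0.0, pi0=0.0)
        n = 64
        x = np.linspace(0, p.domain_length, n)
        col = np.linspace(0, 1, n)
        rho = homeostatic_density(col, p)      # rho0(col): zero elastic pressure
        frac = np.linspace(0.1, 0.9, n)        # composition out of maturity sync
        rho_o = rho * frac
        rho_m = rho - rho_o                    # sum equals rho bit-exactly
        s = FieldState(x, rho_m, rho_o, np.zeros(n), col,
                       np.zeros(n), np.zeros(n), 0.0)
        s1 = step(s, p, dt=0.05)
        # velocity is identically zero, so the only change is the transfer
        # term, which cancels in the sum up to one rounding ulp
        assert np.max(np.abs((s1.rho_m + s1.rho_o) - (s.rho_m + s.rho_o))) <= 1e-15
        assert np.any(s1.rho_o != s.rho_o)     # conversion actually happened

    def test_total_cell_number_conserved_with_growth_off(self, params):
        """Full dynamics (advection, diffusion, conversion) with alpha = 0:
        the domain total changes by < 1e-8 relative over 1000 steps."""
        p = params.replace(alpha=0.0)
        s = step_preset(p)
        total0 = s.rho.sum()
        for _ in range(1000):
            dt = min(p.dt, stability_dt(s, p))
            s = step(s, p, dt)
        assert abs(s.rho.sum() - total0) / total0 <= 1e-8


class TestPositivityAndStability:
    @pytest.mark.parametrize("overrides", [
        {},
        {"beta": 0.48},
        {"pi0": 400.0},
        {"D": 3.0},
        {"xi_ratio": 1.0},
    ])
    def test_densities_stay_non_negative(self, params, overrides):
        p = params.replace(**overrides)
        s = step_preset(p)
        for _ in range(200):
            dt = min(p.dt, stability_dt(s, p))
            s = step(s, p, dt)
        assert s.rho_m.min() >= 0
        assert s.rho_o.min() >= 0

    def test_oversized_step_is_rejected(self, params):
        s = step_preset(params)
        with pytest.raises(NumericalInstabilityError):
            step(s, params, dt=50.0)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_zero_horizon_returns_only_initial_state(self, params):
        states = simulate(params.replace(t_end=0.0))
        assert len(states) == 1
        assert states[0].t == 0.0

    def test_deterministic(self, params):
        p = params.replace(t_end=3.0)
        a = simulate(p, save_every=1.0)
        b = simulate(p, save_every=1.0)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.rho_o, sb.rho_o)
            assert np.array_equal(sa.v, sb.v)

    def test_matured_bone_without_differentiation_only_smooths(self, params):
        """No coupling, fully matured bone: the front moves less than the
        diffusive bound 2*sqrt(D*t) over 6 h (no sustained propagation)."""
        p = params.replace(beta=0.0, t_end=6.0)
        states = simulate(p, "matured-step")
        disp = front_trajectory(states).displacement()
        assert abs(disp) < 2 * np.sqrt(p.D * 6.0)

    def test_front_near_boundary_raises(self, params):
        p = params.replace(domain_length=400.0, n_grid=201, t_end=40.0)
        with pytest.raises(FrontNearBoundaryError):
            simulate(p, x_front0=250.0)

    def test_unknown_preset_rejected(self, params):
        with pytest.raises(ValueError, match="preset"):
            simulate(params, "wedge")
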