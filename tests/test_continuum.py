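"""Continuum Debye profiles: Boltzmann exclusion, pressure balance, Vegard drop."""

import numpy as np
import pytest

from osmosim import (
    MembranePotential,
    R,
    SolutionState,
    SpatialGrid,
    equilibrium_profile,
    fundamental_flux,
    numeric_ode_solution,
    steady_state_profile,
    vegard_drop,
)

T = 300.0
RT = R * T
H = 1e-8  # 10 nm membrane


def plateau(n_rt: float = 30.0, width: float | None = None) -> MembranePotential:
    return MembranePotential.plateau(n_rt * RT, H, width)


def gaussian(n_rt: float = 30.0, width: float | None = None) -> MembranePotential:
    return MembranePotential.gaussian(n_rt * RT, H, width)


class TestPotential:
    def test_vanishes_in_bulk(self):
        for pot in (plateau(), gaussian()):
            assert pot.energy(np.array([-5 * H, 6 * H])) == pytest.approx([0.0, 0.0], abs=1e-30)

    def test_plateau_reaches_u_max_inside(self):
        # logistic edges leave a ~1e-4 relative shortfall at the midpoint
        pot = plateau()
        assert pot.energy(np.array([H / 2]))[0] == pytest.approx(pot.U_max, rel=1e-3)

    def test_force_is_minus_gradient(self):
        xs = np.linspace(-2 * H, 3 * H, 40001)
        for pot in (plateau(), gaussian()):
            dU = np.gradient(pot.energy(xs), xs)
            resid = np.max(np.abs(pot.force(xs) + dU))
            assert resid <= 1e-3 * np.max(np.abs(dU))

    def test_impermeable_threshold(self):
        assert plateau(30.0).is_impermeable(T)
        assert not plateau(29.0).is_impermeable(T)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MembranePotential("square-well", 1.0, H, H / 20)
        with pytest.raises(ValueError):
            MembranePotential.plateau(-1.0, H)
        with pytest.raises(ValueError):
            MembranePotential.plateau(1.0, H, H)  # width > span/4


class TestEquilibrium:
    def test_no_membrane_is_uniform(self):
        # without a barrier the "chambers" share one solution
        prof = equilibrium_profile(plateau(0.0), 100.0, 5e4, T, c_bulk_left=100.0)
        assert np.allclose(prof.c, 100.0, rtol=1e-12)
        assert np.allclose(prof.P, 5e4, rtol=1e-12)
        assert prof.phi_V == 0.0

    def test_van_t_hoff_pressure_difference(self):
        """Chamber-to-chamber dP equals R T c_r to the exclusion error."""
        prof = equilibrium_profile(plateau(), 100.0, 0.0, T)
        assert prof.delta_p_chambers() == pytest.approx(RT * 100.0, rel=1e-12)

    def test_left_chamber_pressure_closed_form(self):
        u = 8.0
        prof = equilibrium_profile(plateau(u), 100.0, 2e5, T)
        expected_left = 2e5 - RT * 100.0 * (1 - np.exp(-u))
        # smoothing leaves U slightly below U_max at the midpoint, hence 1e-4
        assert prof.P[0] == pytest.approx(expected_left, rel=1e-4)

    def test_barrier_shape_cancels(self):
        """Plateau and gaussian barriers of equal height give identical
        chamber pressure differences: only the Boltzmann factor survives."""
        d1 = equilibrium_profile(plateau(), 100.0, 0.0, T).delta_p_chambers()
        d2 = equilibrium_profile(gaussian(), 100.0, 0.0, T).delta_p_chambers()
        assert d1 == pytest.approx(d2, rel=1e-10)

    @pytest.mark.parametrize("n_rt", [30.0, 50.0, 100.0])
    @pytest.mark.parametrize("make", [plateau, gaussian])
    @pytest.mark.parametrize("width_frac", [1 / 30, 1 / 20, 1 / 10])
    def test_f_cancellation_sweep(self, n_rt, make, width_frac):
        prof = equilibrium_profile(make(n_rt, H * width_frac), 250.0, 0.0, T)
        assert prof.delta_p_chambers() == pytest.approx(RT * 250.0, rel=1e-6)

    def test_mechanical_balance_pointwise(self):
        """dP/dx = c F holds at every grid point (discretization residual)."""
        pot = plateau(10.0)
        prof = equilibrium_profile(pot, 100.0, 0.0, T)
        x = prof.grid.x
        dPdx = np.gradient(prof.P, x)
        cF = prof.c * pot.force(x)
        assert np.max(np.abs(dPdx - cF)) <= 2e-3 * np.max(np.abs(cF))

    def test_dilute_limit_monotone(self):
        """dP/(RT c_r) increases monotonically to 1 as the barrier grows."""
        ratios = [
            equilibrium_profile(plateau(u), 100.0, 0.0, T).delta_p_chambers() / (RT * 100.0)
            for u in (1.0, 2.0, 5.0, 10.0, 20.0, 30.0)
        ]
        assert np.all(np.diff(ratios) > 0)
        assert ratios[-1] == pytest.approx(1.0, rel=1e-9)

    def test_coarse_grid_rejected(self):
        pot = plateau()
        coarse = SpatialGrid(np.linspace(-5 * H, 6 * H, 101), H)
        with pytest.raises(ValueError, match="too coarse"):
            equilibrium_profile(pot, 100.0, 0.0, T, coarse)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_profile(plateau(), -1.0, 0.0, T)


class TestSteadyState:
    Lp = 1e-12

    def test_identical_chambers_flat(self):
        s = SolutionState(0.0, 0.0, T)
        prof = steady_state_profile(plateau(), self.Lp, s, s)
        assert prof.phi_V == 0.0
        assert np.allclose(prof.c, 0.0)
        assert np.allclose(prof.P, 0.0, atol=1e-12)

    def test_osmotic_flux_and_intramembrane_drop(self):
        """Pure water left, 100 mol/m^3 right, equal chamber pressures:
        flux +2.4942e-7 m/s toward the solution and a linear intramembrane
        pressure rise of R T c_r from left face to right face."""
        left = SolutionState(0.0, 0.0, T)
        right = SolutionState(100.0, 0.0, T)
        prof = steady_state_profile(plateau(), self.Lp, left, right)
        expected = fundamental_flux(self.Lp, 0.0, 100.0, T).phi_V
        assert prof.phi_V == pytest.approx(2.4942e-7, rel=1e-12)
        assert prof.phi_V == pytest.approx(expected, rel=1e-12)
        # interior slope satisfies phi_V = -h Lp dP/dx
        x = prof.grid.x
        sel = (x > 0.35 * H) & (x < 0.65 * H)
        slope = np.polyfit(x[sel], prof.P[sel], 1)[0]
        assert slope == pytest.approx(-prof.phi_V / (H * self.Lp), rel=1e-6)
        # total intramembrane drop (right face high, left face low)
        assert slope * H == pytest.approx(-RT * 100.0, rel=1e-6)

    def test_vegard_drop_equals_rtc(self):
        left = SolutionState(0.0, 0.0, T)
        right = SolutionState(100.0, 0.0, T)
        prof = steady_state_profile(plateau(), self.Lp, left, right)
        assert vegard_drop(prof) == pytest.approx(RT * 100.0, rel=1e-6)

    def test_vegard_drop_same_at_equilibrium_and_steady_state(self):
        eq = equilibrium_profile(plateau(), 100.0, 0.0, T)
        ss = steady_state_profile(
            plateau(), self.Lp, SolutionState(0.0, 0.0, T), SolutionState(100.0, 0.0, T)
        )
        assert vegard_drop(eq) == pytest.approx(vegard_drop(ss), rel=1e-9)
        assert vegard_drop(eq) == pytest.approx(RT * 100.0, rel=1e-9)

    def test_zero_solute_drop_is_zero(self):
        prof = equilibrium_profile(plateau(), 0.0, 0.0, T)
        assert vegard_drop(prof) == 0.0

    def test_balanced_pressure_recovers_equilibrium(self):
        """Chamber dP = R T dc: no flux, and the equilibrium profile returns."""
        left = SolutionState(0.0, 0.0, T)
        right = SolutionState(100.0, RT * 100.0, T)
        prof = steady_state_profile(plateau(), self.Lp, left, right)
        eq = equilibrium_profile(plateau(), 100.0, RT * 100.0, T)
        assert prof.phi_V == 0.0
        assert np.allclose(prof.c, eq.c, rtol=1e-12, atol=1e-20)
        assert np.allclose(prof.P, eq.P, rtol=1e-12, atol=1e-6)

    def test_flux_linear_in_both_drivers(self):
        """phi_V responds linearly to dP and to RT dc with coefficient -Lp."""
        left = SolutionState(0.0, 0.0, T)
        phis_P, phis_c = [], []
        dps = np.array([-2e5, -1e5, 0.0, 1e5, 2e5])
        for dp in dps:
            prof = steady_state_profile(plateau(), self.Lp, left, SolutionState(0.0, dp, T))
            phis_P.append(prof.phi_V)
        dcs = np.array([50.0, 100.0, 150.0, 200.0])
        for dc in dcs:
            prof = steady_state_profile(plateau(), self.Lp, left, SolutionState(dc, 0.0, T))
            phis_c.append(prof.phi_V)
        coeff_P = np.polyfit(dps, phis_P, 1)[0]
        coeff_c = np.polyfit(RT * dcs, phis_c, 1)[0]
        assert coeff_P == pytest.approx(-self.Lp, rel=1e-8)
        assert coeff_c == pytest.approx(self.Lp, rel=1e-8)

    def test_leaky_membrane_rejected(self):
        with pytest.raises(ValueError, match="impermeable"):
            steady_state_profile(
                plateau(5.0), self.Lp, SolutionState(0.0, 0.0, T), SolutionState(100.0, 0.0, T)
            )

    def test_mismatched_temperatures_rejected(self):
        with pytest.raises(ValueError, match="temperatures"):
            steady_state_profile(
                plateau(), self.Lp, SolutionState(0.0, 0.0, 290.0), SolutionState(1.0, 0.0, 310.0)
            )


class TestNumericOracle:
    def test_free_solution_exact(self):
        num = numeric_ode_solution(plateau(0.0), 100.0, T, c_bulk_left=100.0)
        assert np.allclose(num.c, 100.0, rtol=1e-10)
        assert np.allclose(num.P, 0.0, atol=1e-6)

    @pytest.mark.parametrize("make,n_rt", [(gaussian, 10.0), (plateau, 10.0), (plateau, 30.0), (gaussian, 30.0)])
    def test_matches_closed_form(self, make, n_rt):
        """Direct integration of the zero-flux and mechanical-balance ODEs
        agrees with the Boltzmann/pressure closed form."""
        pot = make(n_rt)
        num = numeric_ode_solution(pot, 100.0, T)
        closed = equilibrium_profile(pot, 100.0, 0.0, T)
        assert np.max(np.abs(num.c - closed.c)) / 100.0 <= 1e-8
        assert np.max(np.abs(num.P - closed.P)) / (RT * 100.0) <= 1e-8

    def test_chamber_dp_converges_with_refinement(self):
        """The numerically integrated chamber dP approaches the Boltzmann
        prediction R T c_r (1 - e^{-U_max/RT}) as the grid is refined."""
        pot = gaussian(10.0)
        expected = RT * 100.0 * (1 - np.exp(-10.0))
        errs = []
        for n in (1001, 4001):
            grid = SpatialGrid.for_membrane(pot, n_points=n)
            num = numeric_ode_solution(pot, 100.0, T, grid, rtol=1e-10)
            errs.append(abs(num.delta_p_chambers() - expected))
        assert errs[-1] <= expected * 1e-8
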