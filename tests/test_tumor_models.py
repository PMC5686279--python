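"""Tumor-growth ODE models: right-hand sides, simulation, derived quantities."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import resistpkpd as rp
from resistpkpd.dosing import daily_regimen
from resistpkpd.errors import InputError, InvalidParameterError
from resistpkpd.pk import solve_pk
from resistpkpd.tumor import (BaseTGIParameters, ResistanceTGIParameters,
                              growth_rate, resistant_fraction, rhs_base,
                              rhs_resistance, simulate, tau)


class TestGrowthRate:
    def test_zero_at_zero(self):
        assert growth_rate(0.0, 0.217, 42.8) == 0.0

    def test_half_linear_rate_at_switch_volume(self):
        # at S = lambda1 / (2 lambda0) the two phases contribute equally
        l0, l1 = 0.217, 42.8
        s = l1 / (2 * l0)
        assert growth_rate(s, l0, l1) == pytest.approx(l1 / 2)

    def test_linear_limit(self):
        assert growth_rate(1e6, 0.217, 42.8) == pytest.approx(42.8, rel=1e-4)

    def test_exponential_limit(self):
        s = 1e-6
        assert growth_rate(s, 0.217, 42.8) == pytest.approx(2 * 0.217 * s,
                                                            rel=1e-6)


class TestTau:
    def test_published_value(self):
        assert tau(1.52) == pytest.approx(1.97, abs=0.005)

    @pytest.mark.parametrize("k1,expected", [(3.0, 1.0), (0.5, 6.0)])
    def test_arithmetic(self, k1, expected):
        assert tau(k1) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            tau(0.0)


def _hand_rhs_base(state, cp, p):
    S, T1, T2, T3 = state
    g = 2 * p.lambda0 * p.lambda1 * S / (2 * p.lambda0 * S + p.lambda1)
    return np.array([g - p.k2 * cp * S,
                     p.k2 * cp * S - p.k1 * T1,
                     p.k1 * (T1 - T2),
                     p.k1 * (T2 - T3)])


class TestRHS:
    def test_unperturbed_growth(self, res_params):
        d = rhs_base(np.array([100.0, 0, 0, 0]), 0.0,
                     BaseTGIParameters(100, 0.217, 42.8, 1.52, 3.15e-4),
                     lambda t: 0.0)
        assert d[0] > 0 and np.all(d[1:] == 0)

    def test_no_inflow_without_sensitive_cells(self):
        p = BaseTGIParameters(100, 0.217, 42.8, 1.52, 3.15e-4)
        d = rhs_base(np.array([0.0, 5.0, 1.0, 0.5]), 0.0, p, lambda t: 1e4)
        assert d[1] == pytest.approx(-p.k1 * 5.0)

    def test_matches_hand_coded_formula(self):
        p = BaseTGIParameters(100, 0.3, 50.0, 1.2, 2e-4)
        state = np.array([80.0, 12.0, 6.0, 2.0])
        got = rhs_base(state, 1.0, p, lambda t: 8000.0)
        np.testing.assert_allclose(got, _hand_rhs_base(state, 8000.0, p),
                                   rtol=1e-12)

    def test_resistance_reduces_to_base(self):
        pr = ResistanceTGIParameters(100, 0.3, 50.0, 1.2, 2e-4, kSR=0.0)
        state5 = np.array([80.0, 12.0, 6.0, 2.0, 0.0])
        got = rhs_resistance(state5, 1.0, pr, lambda t: 8000.0)
        base = _hand_rhs_base(state5[:4], 8000.0, pr)
        np.testing.assert_allclose(got[:4], base, rtol=1e-12)
        assert got[4] == 0.0

    def test_der_off_below_threshold(self):
        pr = ResistanceTGIParameters(100, 0.3, 50.0, 1.2, 2e-4, kSR=1e-3,
                                     beta=0.9, k2R=1e-3, C_th=7152.7,
                                     der_enabled=True)
        state = np.array([50.0, 5.0, 3.0, 1.0, 10.0])
        below = rhs_resistance(state, 0.0, pr, lambda t: 7000.0)
        off = rhs_resistance(state, 0.0, pr.with_(der_enabled=False,
                                                 C_th=float("inf")),
                             lambda t: 7000.0)
        np.testing.assert_allclose(below, off, rtol=1e-12)

    def test_der_mass_action_above_threshold(self):
        pr = ResistanceTGIParameters(100, 0.3, 50.0, 1.2, 2e-4, kSR=1e-3,
                                     beta=0.9, k2R=1e-3, C_th=7152.7,
                                     der_enabled=True)
        state = np.array([50.0, 5.0, 3.0, 1.0, 10.0])
        cp = 9000.0
        on = rhs_resistance(state, 0.0, pr, lambda t: cp)
        off = rhs_resistance(state, 0.0, pr.with_(der_enabled=False,
                                                 C_th=float("inf")),
                             lambda t: cp)
        assert on[4] == pytest.approx(off[4] - pr.k2R * cp * state[4])


class TestSimulate:
    def test_vehicle_matches_scalar_growth_ode(self, res_params, grid30):
        """With no drug the 4-state system collapses to the 1-D growth ODE."""
        traj = simulate(res_params, None, grid30, model="base")
        sol = solve_ivp(lambda t, y: [float(growth_rate(y[0], res_params.lambda0,
                                                        res_params.lambda1))],
                        (0, 30), [res_params.TV0], t_eval=grid30,
                        rtol=1e-11, atol=1e-12)
        np.testing.assert_allclose(traj.TV, sol.y[0], rtol=1e-6)
        assert np.all(np.diff(traj.TV) > 0)

    def test_k2_zero_equals_vehicle(self, erl_pk, grid30, high_dose_regimen):
        prof = solve_pk(erl_pk, high_dose_regimen, grid30)
        p0 = BaseTGIParameters(100, 0.217, 42.8, 1.52, 0.0)
        treated = simulate(p0, prof, grid30, rtol=1e-10, atol=1e-12)
        vehicle = simulate(p0, None, grid30, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(treated.TV, vehicle.TV, rtol=1e-7)

    def test_composition_sums_to_tv(self, res_params, erl_pk, grid30,
                                    high_dose_regimen):
        prof = solve_pk(erl_pk, high_dose_regimen, grid30)
        traj = simulate(res_params, prof, grid30)
        np.testing.assert_allclose(
            traj.TV, traj.S + traj.T1 + traj.T2 + traj.T3 + traj.R, rtol=0,
            atol=1e-12)
        for comp in (traj.S, traj.T1, traj.T2, traj.T3, traj.R):
            assert np.all(comp >= 0)

    def test_reduction_identity_random_draws(self):
        """kSR = 0, DER off: resistance TV equals base TV to < 1e-8 relative."""
        rng = np.random.default_rng(7)
        grid = np.linspace(0, 20, 201)
        for _ in range(50):
            l0 = rng.uniform(0.05, 0.6)
            l1 = rng.uniform(10, 80)
            k1 = rng.uniform(0.5, 4)
            k2 = rng.uniform(5e-5, 6e-4)
            tv0 = rng.uniform(50, 300)
            dose = rng.uniform(5, 100)
            pk = rp.params.ERLOTINIB_PK
            reg = daily_regimen(rng.uniform(0, 3), rng.integers(1, 10), dose)
            prof = solve_pk(pk, reg, grid)
            base = simulate(BaseTGIParameters(tv0, l0, l1, k1, k2), prof, grid,
                            rtol=1e-10, atol=1e-12)
            res = simulate(ResistanceTGIParameters(tv0, l0, l1, k1, k2,
                                                   kSR=0.0, beta=1.0),
                           prof, grid, rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(res.TV, base.TV, rtol=1e-8)

    def test_growth_limits_on_simulated_paths(self):
        l0, l1 = 0.3, 40.0
        p_small = BaseTGIParameters(0.01, l0, l1, 1.0, 0.0)
        grid = np.linspace(0, 5, 501)
        traj = simulate(p_small, None, grid, rtol=1e-10, atol=1e-13)
        slope = np.polyfit(grid, np.log(traj.TV), 1)[0]
        assert slope == pytest.approx(2 * l0, rel=1e-2)
        p_big = BaseTGIParameters(5e5, l0, l1, 1.0, 0.0)
        traj = simulate(p_big, None, grid, rtol=1e-10, atol=1e-13)
        tv_slope = (traj.TV[-1] - traj.TV[0]) / 5.0
        assert tv_slope == pytest.approx(l1, rel=1e-3)

    def test_beta_monotonicity(self, erl_pk, grid30, high_dose_regimen):
        """Larger beta -> pointwise larger resistant compartment."""
        prof = solve_pk(erl_pk, high_dose_regimen, grid30)
        prev = None
        for beta in (0.5, 0.87, 1.3):
            pars = rp.params.resistance_parameters().with_(beta=beta)
            traj = simulate(pars, prof, grid30)
            after = grid30 > 4.0
            if prev is not None:
                assert np.all(traj.R[after] >= prev[after])
            prev = traj.R

    def test_bad_grid_rejected(self, res_params):
        with pytest.raises(InputError):
            simulate(res_params, None, np.array([0.0]))


class TestResistantFraction:
    def test_zero_without_resistance(self, res_params, grid30):
        traj = simulate(res_params.with_(kSR=0.0), None, grid30)
        np.testing.assert_array_equal(resistant_fraction(traj), 0.0)

    def test_all_resistant_state(self, grid30):
        traj = simulate(rp.params.resistance_parameters(), None, grid30)
        traj.S[:] = traj.T1[:] = traj.T2[:] = traj.T3[:] = 0.0
        traj.R[:] = 50.0
        np.testing.assert_array_equal(resistant_fraction(traj), 1.0)

    def test_base_trajectory_rejected(self, grid30):
        base = simulate(BaseTGIParameters(100, 0.2, 40, 1.5, 1e-4), None, grid30)
        with pytest.raises(InputError):
            resistant_fraction(base)

    def test_rises_during_treatment_falls_after(self, erl_pk):
        """20 daily high doses from day 3 then washout."""
        grid = np.linspace(0, 50, 1001)
        reg = daily_regimen(3.0, 20, 100.0, compound="erlotinib")
        prof = solve_pk(erl_pk, reg, grid)
        traj = simulate(rp.params.resistance_parameters(), prof, grid)
        frac = resistant_fraction(traj)
        i_start = np.searchsorted(grid, 4.0)
        i_end = np.searchsorted(grid, 23.0)
        assert frac[i_end] > frac[i_start]
        assert np.all(np.diff(frac[i_start:i_end]) > -1e-9)
        assert frac[-1] < frac[i_end]
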