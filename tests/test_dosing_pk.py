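"""PK layer: effective volume, multi-dose superposition, unit conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resistpkpd.dosing import (DosingRegimen, daily_regimen,
                               regimen_from_config, regimen_to_config)
from resistpkpd.errors import InputError, InvalidParameterError
from resistpkpd.pk import (PKParameters, effective_volume, solve_pk,
                           solve_pk_ode, threshold_concentration)


class TestDosingRegimen:
    def test_vehicle_is_empty(self):
        reg = DosingRegimen((), "vehicle")
        assert len(reg) == 0 and reg.total_dose == 0

    def test_events_sorted_and_validated(self):
        reg = DosingRegimen(((2.0, 10.0), (1.0, 5.0)))
        assert list(reg.times) == [1.0, 2.0]
        with pytest.raises(InputError):
            DosingRegimen(((-1.0, 5.0),))
        with pytest.raises(InputError):
            DosingRegimen(((1.0, -5.0),))

    def test_daily_regimen_schedule(self):
        reg = daily_regimen(3.0, 14, 100.0)
        assert len(reg) == 14
        assert reg.times[0] == 3.0 and reg.times[-1] == 16.0
        assert reg.total_dose == 1400.0

    def test_config_round_trip(self):
        block = {"start_day": 3, "n_doses": 14, "interval_days": 1,
                 "dose_mg_per_kg": 100, "compound": "erlotinib"}
        reg = regimen_from_config(block)
        again = regimen_from_config(regimen_to_config(reg))
        assert reg == again

    def test_config_rejects_unknown_keys(self):
        with pytest.raises(InputError):
            regimen_from_config({"events": [[0, 10]], "typo": 1})


class TestEffectiveVolume:
    def test_identity_when_I_zero(self, erl_pk):
        assert effective_volume(erl_pk, 100.0) == erl_pk.V == 0.127

    def test_dose_dependent_volume(self, gef_pk):
        # 1.40 - 100 * 0.00772
        assert effective_volume(gef_pk, 100.0) == pytest.approx(0.628)

    def test_nonpositive_volume_names_dose(self, gef_pk):
        with pytest.raises(InvalidParameterError, match="200"):
            effective_volume(gef_pk, 200.0)


class TestThresholdConcentration:
    def test_published_conversion(self):
        # 1 uM erlotinib, fu = 0.055 -> ~7152.7 ug/L
        cth = threshold_concentration(1.0, 393.4, 0.055)
        assert cth == pytest.approx(7152.7, abs=0.1)

    def test_no_binding_correction(self):
        assert threshold_concentration(1.0, 393.4, 1.0) == pytest.approx(393.4)

    def test_hand_arithmetic(self):
        assert threshold_concentration(2.0, 100.0, 0.5) == pytest.approx(400.0)

    def test_invalid_fu(self):
        with pytest.raises(InvalidParameterError):
            threshold_concentration(1.0, 393.4, 0.0)


def _bateman(t, amount, veff, ka, ke):
    return (amount * ka / (veff * (ka - ke))) * (np.exp(-ke * t) - np.exp(-ka * t))


class TestSolvePK:
    def test_empty_regimen_zero_everywhere(self, erl_pk, grid30):
        prof = solve_pk(erl_pk, DosingRegimen((), "vehicle"), grid30)
        assert np.all(prof.Cp == 0)

    def test_single_dose_matches_bateman(self, erl_pk):
        grid = np.linspace(0, 5, 401)
        prof = solve_pk(erl_pk, DosingRegimen(((0.0, 100.0),), "erlotinib"), grid)
        expected = _bateman(grid, erl_pk.amount_ug(100.0), erl_pk.V,
                            erl_pk.ka, erl_pk.ke)
        np.testing.assert_allclose(prof.Cp, np.maximum(expected, 0), rtol=1e-12)

    def test_zero_before_first_dose(self, erl_pk):
        grid = np.linspace(0, 10, 101)
        prof = solve_pk(erl_pk, DosingRegimen(((4.0, 50.0),)), grid)
        assert np.all(prof.Cp[grid < 4.0] == 0)
        assert np.all(prof.Cp >= 0)

    def test_terminal_slope_is_ke(self, erl_pk):
        # post-absorption log-linear decay with slope -ke (ka >> ke)
        grid = np.linspace(0, 2, 2001)
        prof = solve_pk(erl_pk, DosingRegimen(((0.0, 100.0),)), grid)
        tail = (grid > 0.5) & (grid < 1.2)
        slope = np.polyfit(grid[tail], np.log(prof.Cp[tail]), 1)[0]
        assert slope == pytest.approx(-erl_pk.ke, rel=1e-3)

    def test_ka_equals_ke_raises(self):
        pk = PKParameters(ka=5.0, ke=5.0, V=1.0)
        with pytest.raises(InvalidParameterError):
            solve_pk(pk, DosingRegimen(((0.0, 10.0),)), np.linspace(0, 5, 10))

    def test_unsorted_grid_rejected(self, erl_pk):
        with pytest.raises(InputError):
            solve_pk(erl_pk, DosingRegimen(((0.0, 10.0),)), np.array([1.0, 0.5, 2.0]))

    def test_grid_must_cover_doses(self, erl_pk):
        with pytest.raises(InputError):
            solve_pk(erl_pk, DosingRegimen(((5.0, 10.0),)), np.linspace(0, 3, 10))

    def test_per_dose_effective_volume(self, gef_pk):
        # each dose is scaled by its own V - D*I
        grid = np.linspace(0, 6, 601)
        prof = solve_pk(gef_pk, DosingRegimen(((0.0, 100.0), (2.0, 5.0)), "gefitinib"),
                        grid)
        d1 = _bateman(grid, gef_pk.amount_ug(100.0),
                      effective_volume(gef_pk, 100.0), gef_pk.ka, gef_pk.ke)
        t2 = np.maximum(grid - 2.0, 0)
        d2 = np.where(grid >= 2.0,
                      _bateman(t2, gef_pk.amount_ug(5.0),
                               effective_volume(gef_pk, 5.0), gef_pk.ka, gef_pk.ke),
                      0.0)
        np.testing.assert_allclose(prof.Cp, np.maximum(d1 + d2, 0), rtol=1e-10,
                                   atol=1e-12)


class TestPKProperties:
    def test_linearity_in_dose_when_I_zero(self, erl_pk, grid30,
                                           high_dose_regimen):
        prof1 = solve_pk(erl_pk, high_dose_regimen, grid30)
        doubled = DosingRegimen(tuple((t, 2 * d) for t, d in
                                      high_dose_regimen.events), "erlotinib")
        prof2 = solve_pk(erl_pk, doubled, grid30)
        np.testing.assert_allclose(prof2.Cp, 2 * prof1.Cp, rtol=1e-12)

    def test_superposition_two_doses(self, erl_pk):
        grid = np.linspace(0, 8, 801)
        both = solve_pk(erl_pk, DosingRegimen(((1.0, 30.0), (3.0, 70.0))), grid)
        a = solve_pk(erl_pk, DosingRegimen(((1.0, 30.0),)), grid)
        b = solve_pk(erl_pk, DosingRegimen(((3.0, 70.0),)), grid)
        np.testing.assert_allclose(both.Cp, a.Cp + b.Cp, rtol=1e-12, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ka=st.floats(1.0, 80.0), ke_frac=st.floats(0.05, 0.8),
           v=st.floats(0.05, 5.0), dose=st.floats(1.0, 200.0))
    def test_analytic_matches_ode(self, ka, ke_frac, v, dose):
        """Closed form and direct numerical integration agree to < 1e-6."""
        pk = PKParameters(ka=ka, ke=ka * ke_frac, V=v)
        grid = np.linspace(0, 4, 101)
        reg = DosingRegimen(((0.0, dose), (1.5, dose / 2)))
        analytic = solve_pk(pk, reg, grid).Cp
        numeric = solve_pk_ode(pk, reg, grid)
        scale = analytic.max()
        np.testing.assert_allclose(numeric / scale, analytic / scale,
                                   rtol=0, atol=1e-6)

    def test_scalar_concentration_matches_vector(self, erl_pk, grid30,
                                                 high_dose_regimen):
        prof = solve_pk(erl_pk, high_dose_regimen, grid30)
        sampled = np.array([prof.concentration_scalar(t) for t in grid30])
        np.testing.assert_allclose(sampled, prof.Cp, rtol=1e-12, atol=1e-12)
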