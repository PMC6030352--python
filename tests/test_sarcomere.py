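"""Myofilament mechanics: force laws, kinetics, calibrations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvsim.errors import CalibrationError, ParameterError
from rvsim.sarcomere import (SarcomereParams, SarcomereState, active_stress,
                             calcium_transient, calibrate_contractility,
                             calibrate_fibrosis, crossbridge_derivatives,
                             fiber_stress_and_rate, isometric_fmax,
                             passive_stress)

PERIOD = 60.0 / 420.0


class TestCalciumTransient:
    def test_starts_at_diastolic_level(self, sarc_params):
        assert calcium_transient(0.0, sarc_params, PERIOD) == sarc_params.Ca_dia

    def test_peaks_at_tau_with_full_amplitude(self, sarc_params):
        peak = calcium_transient(sarc_params.tau_Ca, sarc_params, PERIOD)
        assert peak == pytest.approx(sarc_params.Ca_dia + sarc_params.Ca_amp)
        # analytic maximum of the pulse shape
        grid = np.linspace(0.0, PERIOD, 2000)
        vals = [calcium_transient(t, sarc_params, PERIOD) for t in grid]
        assert max(vals) <= peak + 1e-12

    def test_periodic_and_bounded_below(self, sarc_params):
        for t in (0.01, 0.05, 0.11):
            a = calcium_transient(t, sarc_params, PERIOD)
            b = calcium_transient(t + PERIOD, sarc_params, PERIOD)
            assert a == pytest.approx(b, rel=1e-12)
            assert a >= sarc_params.Ca_dia

    def test_invalid_period_rejected(self, sarc_params):
        with pytest.raises(ParameterError):
            calcium_transient(0.0, sarc_params, 0.0)


class TestCrossbridgeKinetics:
    @given(perm_ca=st.floats(0.2, 20.0), a0=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_steady_attached_fraction_matches_closed_form(self, perm_ca, a0):
        """dA/dt vanishes exactly at A = f*perm/(f*perm + g)."""
        p = SarcomereParams()
        perm = perm_ca ** p.hill_n / (perm_ca ** p.hill_n + p.Ca50 ** p.hill_n)
        a_ss = p.f_attach * perm / (p.f_attach * perm + p.g_detach)
        s = SarcomereState(Ls=p.Ls_ref, A=a_ss, xbar=p.x0)
        da, _ = crossbridge_derivatives(s, perm_ca, 0.0, p)
        assert da == pytest.approx(0.0, abs=1e-9 * p.f_attach)

    def test_zero_calcium_is_pure_detachment(self, sarc_params):
        s = SarcomereState(Ls=2.0, A=0.4, xbar=sarc_params.x0)
        da, _ = crossbridge_derivatives(s, 0.0, 0.0, sarc_params)
        assert da == pytest.approx(-sarc_params.g_detach * 0.4)

    def test_isometric_distortion_fixed_point_is_x0(self, sarc_params):
        """With steady attachment and no shortening, xbar = x0 is stationary."""
        s = SarcomereState(Ls=sarc_params.Ls_ref, A=0.5, xbar=sarc_params.x0)
        _, dxb = crossbridge_derivatives(s, 10.0 * sarc_params.Ca50, 0.0,
                                         sarc_params)
        assert dxb == pytest.approx(0.0, abs=1e-9)

    def test_attached_fraction_stays_in_unit_interval(self, sarc_params):
        """Euler walk of a full twitch never leaves [0, 1]."""
        p = sarc_params
        s = SarcomereState(Ls=p.Ls_ref, A=0.0, xbar=p.x0)
        dt = 1e-5
        for i in range(int(PERIOD / dt)):
            ca = calcium_transient(i * dt, p, PERIOD)
            da, dxb = crossbridge_derivatives(s, ca, 0.0, p)
            s.A += dt * da
            s.xbar += dt * dxb
            assert -1e-9 <= s.A <= 1.0 + 1e-9


class TestActiveStress:
    def test_zero_without_attachment(self, sarc_params):
        s = SarcomereState(Ls=sarc_params.Ls_ref, A=0.0, xbar=0.01)
        assert active_stress(s, sarc_params) == 0.0

    def test_linear_in_stiffness_scale(self, sarc_params):
        from dataclasses import replace
        s = SarcomereState(Ls=2.1, A=0.5, xbar=0.01)
        doubled = replace(sarc_params, k_stiff2=2.0 * sarc_params.k_stiff2)
        assert active_stress(s, doubled) == pytest.approx(
            2.0 * active_stress(s, sarc_params))

    def test_overlap_vanishes_at_tent_edge(self, sarc_params):
        edge = sarc_params.Ls_ref + sarc_params.overlap_width
        s = SarcomereState(Ls=edge, A=0.9, xbar=0.01)
        assert active_stress(s, sarc_params) == 0.0


class TestPassiveStress:
    def test_zero_at_slack(self, sarc_params):
        assert passive_stress(sarc_params.Ls_slack, sarc_params).total == 0.0

    def test_collagen_component_linear_in_multiplier(self, sarc_params):
        from dataclasses import replace
        ls = 2.3
        base = passive_stress(ls, sarc_params)
        doubled = passive_stress(
            ls, replace(sarc_params, con_collagen_mult=2.0))
        assert doubled.collagen == pytest.approx(2.0 * base.collagen)
        assert doubled.titin == pytest.approx(base.titin)

    def test_strictly_increasing_over_working_range(self, sarc_params):
        grid = np.linspace(sarc_params.Ls_slack, sarc_params.Ls_slack + 0.6,
                           200)
        totals = [passive_stress(ls, sarc_params).total for ls in grid]
        assert np.all(np.diff(totals) > 0.0)


class TestSeriesElement:
    def test_isometric_equilibrium_has_no_viscous_term(self, sarc_params):
        p = sarc_params
        s = SarcomereState(Ls=2.1, A=0.3, xbar=p.x0)
        # strain chosen so the series stretch equals its isometric value
        eps = math.log((s.Ls + p.L_SE_iso) / p.Ls_ref)
        sigma, dls = fiber_stress_and_rate(s, eps, p)
        assert dls == pytest.approx(0.0, abs=1e-9)
        expected = active_stress(s, p) + passive_stress(s.Ls, p).total
        assert sigma == pytest.approx(expected, abs=1e-9)

    def test_overstretched_series_element_lengthens_sarcomere(self, sarc_params):
        p = sarc_params
        s = SarcomereState(Ls=2.0, A=0.0, xbar=p.x0)
        eps = math.log((s.Ls + 3.0 * p.L_SE_iso) / p.Ls_ref)
        _, dls = fiber_stress_and_rate(s, eps, p)
        assert dls > 0.0

    def test_no_viscosity_removes_rate_dependence(self):
        p = SarcomereParams(mu_visc=1e-12)
        s = SarcomereState(Ls=2.0, A=0.2, xbar=p.x0)
        s1, _ = fiber_stress_and_rate(s, 0.0, p)
        s2, _ = fiber_stress_and_rate(s, 0.05, p)
        # stress changes only through the (negligible) viscous term
        assert s1 == pytest.approx(s2, abs=1e-6)


class TestIsometricFmax:
    def test_matches_analytic_steady_state(self, sarc_params):
        p = sarc_params
        expected = p.k_stiff2 * p.x0 * p.f_attach / (p.f_attach + p.g_detach)
        assert isometric_fmax(p) == pytest.approx(expected, rel=1e-3)

    def test_linear_in_stiffness_scale(self, sarc_params):
        from dataclasses import replace
        doubled = replace(sarc_params, k_stiff2=2.0 * sarc_params.k_stiff2)
        assert isometric_fmax(doubled) == pytest.approx(
            2.0 * isometric_fmax(sarc_params), rel=1e-6)

    def test_active_stress_decays_without_calcium(self, sarc_params):
        """Clamped at diastolic calcium, force falls below 1% of Fmax
        within ten detachment time constants."""
        p = sarc_params
        s = SarcomereState(Ls=p.Ls_ref, A=p.f_attach / (p.f_attach + p.g_detach),
                           xbar=p.x0)
        dt = 1e-5
        t_end = 10.0 / p.g_detach
        for i in range(int(t_end / dt)):
            da, dxb = crossbridge_derivatives(s, p.Ca_dia, 0.0, p)
            s.A += dt * da
            s.xbar += dt * dxb
        assert active_stress(s, p) < 0.01 * isometric_fmax(p)


class TestContractilityCalibration:
    def test_identity_target_returns_parameters_unchanged(self, sarc_params):
        assert calibrate_contractility(sarc_params, 1.0) is sarc_params

    @pytest.mark.parametrize("ratio", [0.64, 0.78])
    def test_force_ratio_hits_target(self, sarc_params, ratio):
        calibrated = calibrate_contractility(sarc_params, ratio)
        achieved = isometric_fmax(calibrated) / isometric_fmax(sarc_params)
        assert achieved == pytest.approx(ratio, abs=1e-3)

    def test_unphysical_target_rejected(self, sarc_params):
        with pytest.raises(CalibrationError):
            calibrate_contractility(sarc_params, 1.5)


class TestFibrosisCalibration:
    def test_passive_ratio_hits_target_at_operating_length(self, sarc_params):
        calibrated = calibrate_fibrosis(sarc_params, 2.7, Ls_operating=2.2)
        ratio = passive_stress(2.2, calibrated).total \
            / passive_stress(2.2, sarc_params).total
        assert ratio == pytest.approx(2.7, rel=1e-9)

    def test_target_below_titin_floor_rejected(self, sarc_params):
        with pytest.raises(CalibrationError):
            calibrate_fibrosis(sarc_params, 0.01, Ls_operating=2.2)


def test_invalid_parameters_rejected():
    with pytest.raises(ParameterError):
        SarcomereParams(k_stiff2=-1.0)
    with pytest.raises(ParameterError):
        SarcomereParams(Ls_slack=2.5)  # above Ls_ref
    with pytest.raises(ParameterError):
        SarcomereParams(hill_n=0.5)
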