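"""Three-wall geometry: caps, tensions, junction balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvsim.circulation import default_model
from rvsim.errors import ParameterError
from rvsim.sarcomere import SarcomereParams, SarcomereState
from rvsim.triseg import (KPA_TO_MMHG, WallSegment, cap_metrics, fiber_strain,
                          solve_cap_height, solve_heart,
                          wall_tension_components)


class TestCapGeometry:
    def test_flat_membrane(self):
        vm, am, cm = cap_metrics(0.0, 2.0)
        assert vm == 0.0
        assert am == pytest.approx(math.pi * 4.0)
        assert cm == 0.0

    def test_hemisphere(self):
        vm, am, cm = cap_metrics(1.0, 1.0)
        assert vm == pytest.approx(2.0 * math.pi / 3.0)
        assert am == pytest.approx(2.0 * math.pi)
        assert cm == pytest.approx(1.0)

    def test_general_cap(self):
        vm, am, cm = cap_metrics(1.0, 2.0)
        assert vm == pytest.approx(13.0 * math.pi / 6.0)
        assert am == pytest.approx(5.0 * math.pi)
        assert cm == pytest.approx(0.4)

    def test_inverse_recovers_hemisphere(self):
        assert solve_cap_height(2.0 * math.pi / 3.0, 1.0) == pytest.approx(1.0)

    def test_inverse_of_zero_volume_is_flat(self):
        assert solve_cap_height(0.0, 1.5) == pytest.approx(0.0, abs=1e-12)

    @given(x=st.floats(-3.0, 3.0), y=st.floats(0.5, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, x, y):
        vm, _, _ = cap_metrics(x, y)
        assert solve_cap_height(vm, y) == pytest.approx(x, abs=1e-9)

    def test_negative_junction_radius_rejected(self):
        with pytest.raises(ParameterError):
            cap_metrics(1.0, 0.0)


class TestFiberStrain:
    def test_zero_at_reference(self):
        assert fiber_strain(50.0, 50.0) == 0.0

    def test_unit_strain_at_e_squared(self):
        assert fiber_strain(math.e ** 2 * 40.0, 40.0) == pytest.approx(1.0)

    def test_monotone_in_area(self):
        grid = np.linspace(20.0, 120.0, 50)
        strains = [fiber_strain(a, 60.0) for a in grid]
        assert np.all(np.diff(strains) > 0)


class TestWallTension:
    def test_flat_wall_pulls_purely_radially(self):
        tm, tx, ty = wall_tension_components(10.0, 50.0, 0.0, 2.0)
        assert tx == 0.0
        assert ty == pytest.approx(tm)

    def test_hemisphere_pulls_purely_axially(self):
        tm, tx, ty = wall_tension_components(10.0, 50.0, 2.0, 2.0)
        assert tx == pytest.approx(tm)
        assert ty == pytest.approx(0.0, abs=1e-12)

    def test_zero_stress_gives_zero_tension(self):
        tm, tx, ty = wall_tension_components(0.0, 50.0, 1.0, 2.0)
        assert (tm, tx, ty) == (0.0, 0.0, 0.0)

    @given(x=st.floats(-3.0, 3.0), y=st.floats(0.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_direction_cosines_normalised(self, x, y):
        tm, tx, ty = wall_tension_components(7.0, 30.0, x, y)
        if tm != 0.0:
            assert (tx / tm) ** 2 + (ty / tm) ** 2 == pytest.approx(1.0)


def _passive_walls(vw=(70.0, 42.0, 22.0), am=(73.0, 40.0, 89.0),
                   ls=2.0, mu=1e-12):
    """Three stress-light walls (no activation, negligible viscosity)."""
    sarc = SarcomereParams(mu_visc=mu)
    return tuple(
        WallSegment(name, Vw=v, Am_ref=a, sarcomere=sarc,
                    state=SarcomereState(Ls=ls, A=0.0, xbar=sarc.x0))
        for name, v, a in zip(("lv_free_wall", "septum", "rv_free_wall"),
                              vw, am))


def _frozen_active_walls():
    """Default wall set frozen mid-twitch (for solver-state tests)."""
    model = default_model()
    walls = []
    for w in model.walls:
        w.state = SarcomereState(Ls=2.05, A=0.35, xbar=w.sarcomere.x0)
        walls.append(w)
    return tuple(walls)


class TestSolveHeart:
    def test_symmetric_twins_with_slack_septum(self):
        """Identical free walls, a stress-free septum and equal cavity
        volumes give the mirror-symmetric solution: flat septum, equal
        pressures, hemispherical free walls."""
        sarc = SarcomereParams(mu_visc=1e-12)
        slack = sarc.Ls_slack
        walls = tuple(
            WallSegment(n, Vw=30.0, Am_ref=80.0, sarcomere=sarc,
                        state=SarcomereState(Ls=slack, A=0.0, xbar=sarc.x0))
            for n in ("lv_free_wall", "septum", "rv_free_wall"))
        # free walls mildly stretched, septum exactly at slack (zero stress)
        walls[0].state.Ls = 2.1
        walls[2].state.Ls = 2.1
        g = solve_heart(50.0, 50.0, walls)
        assert g.x_S == pytest.approx(0.0, abs=1e-6)
        assert g.P_LV == pytest.approx(g.P_RV, rel=1e-6)
        # each free wall closes onto a hemisphere (|x| = y)
        assert abs(g.x_R) == pytest.approx(g.y, rel=1e-6)
        assert abs(g.x_L) == pytest.approx(g.y, rel=1e-6)

    def test_septal_transmural_pressure_consistency(self):
        """P_LV - P_RV agrees with the septal Laplace pressure 2 Tm Cm."""
        walls = _frozen_active_walls()
        g = solve_heart(55.0, 50.0, walls)
        septal = 2.0 * g.Tm[1] * g.Cm[1] * KPA_TO_MMHG
        assert g.P_LV - g.P_RV == pytest.approx(septal, rel=0.01)

    def test_virtual_work_consistency(self):
        """Cavity pressure equals the fiber-work conjugate
        sum_w sigma_w Vw_w d(eps_w)/dV (independent energetic oracle)."""
        # fixed, appreciably stressed states with negligible viscosity:
        # sigma then depends on Ls only, so the energetic identity
        # P dV = sum_w sigma_w Vw d(eps_w) holds exactly at force balance
        walls = _passive_walls(ls=2.4)
        dv = 0.05
        g0 = solve_heart(55.0 - dv, 50.0, walls)
        g1 = solve_heart(55.0 + dv, 50.0, walls)
        work = sum(
            0.5 * (g0.sigma_f[i] + g1.sigma_f[i]) * walls[i].Vw
            * (g1.epsilon_f[i] - g0.epsilon_f[i]) / (2.0 * dv)
            for i in range(3))
        p_mid = 0.5 * (g0.P_LV + g1.P_LV) / KPA_TO_MMHG
        # cavity pressure work stretches the walls: P dV = sum sigma Vw deps
        assert work == pytest.approx(p_mid, rel=0.02)

    def test_junction_residual_below_tolerance(self):
        g = solve_heart(55.0, 50.0, _frozen_active_walls())
        assert g.residual < 1e-8

    def test_warm_start_agrees_with_cold_start(self):
        walls = _frozen_active_walls()
        cold = solve_heart(55.0, 50.0, walls)
        perturbed = solve_heart(56.0, 50.5, walls, warm_start=cold)
        warm = solve_heart(55.0, 50.0, walls, warm_start=perturbed)
        assert warm.y == pytest.approx(cold.y, abs=1e-6)
        assert warm.Vm_S == pytest.approx(cold.Vm_S, abs=1e-6)
        assert warm.P_LV == pytest.approx(cold.P_LV, abs=1e-6)

    def test_rv_passive_inflation_raises_pressure(self):
        """Quasi-static passive inflation: more blood volume relaxes to a
        larger RV at a higher RV pressure (positive chamber stiffness).

        With the sarcomere length frozen instead, the curvature drop of
        a larger cavity would lower the pressure; the physical inflation
        curve couples stretch and geometry, so the scan equilibrates the
        whole passive system per volume.
        """
        from dataclasses import replace
        from rvsim.simulator import passive_equilibrium
        model = default_model()
        points = []
        for f in (0.95, 1.0, 1.05):
            c = model.circulation
            m = replace(model, circulation=replace(c, V_total=c.V_total * f))
            st = passive_equilibrium(m, settle_time=4.0)
            walls = []
            for wall, ws in zip(m.walls, st.walls):
                wall = WallSegment(wall.name, Vw=wall.Vw, Am_ref=wall.Am_ref,
                                   sarcomere=wall.sarcomere, state=ws)
                walls.append(wall)
            g = solve_heart(st.volumes["LV"], st.volumes["RV"],
                            tuple(walls), warm_start=st.warm)
            points.append((st.volumes["RV"], g.P_RV))
        vols, pressures = zip(*points)
        assert np.all(np.diff(vols) > 0.0)
        assert np.all(np.diff(pressures) > 0.0)

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ParameterError):
            solve_heart(-1.0, 50.0, _passive_walls())
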