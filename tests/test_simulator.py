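"""Beat integration, convergence, homeostasis."""

from dataclasses import replace

import numpy as np
import pytest

from rvsim.circulation import default_model
from rvsim.errors import RvsimError
from rvsim.simulator import (homeostasis_adjust, integrate_beat,
                             passive_equilibrium, primed_state,
                             run_to_convergence)


class TestIntegrateBeat:
    def test_blood_volume_conserved_through_the_beat(self, baseline):
        model, run = baseline
        total = run.trajectory.total_volume
        assert np.max(np.abs(total - total[0])) < 1e-6 * total[0]

    def test_passive_mode_fixed_point(self):
        """From the relaxed passive state, a passive beat returns the
        same state to within the slow residual creep of the nearly
        tension-free equilibrium (fractions of a microlitre per beat)."""
        model = default_model()
        passive = model.passive_variant()
        st = passive_equilibrium(model, settle_time=16.0)
        st2, _ = integrate_beat(st, passive)
        for name in st.volumes:
            assert st2.volumes[name] == pytest.approx(
                st.volumes[name], abs=0.3)

    def test_convergence_in_tolerance(self, baseline):
        """Halving the integration tolerance changes end-of-beat volumes
        by far less than 0.01%."""
        model, run = baseline
        st1, _ = integrate_beat(run.state, model, rtol=1e-7)
        st2, _ = integrate_beat(run.state, model, rtol=5e-8)
        scale = model.circulation.V_total
        for name in st1.volumes:
            assert abs(st2.volumes[name] - st1.volumes[name]) < 1e-4 * scale

    def test_sampling_covers_the_whole_period(self, baseline):
        model, run = baseline
        tr = run.trajectory
        assert tr.t[0] == 0.0
        assert tr.t[-1] == pytest.approx(model.circulation.period)
        assert len(tr.t) >= 500

    def test_valve_flows_never_negative(self, baseline):
        _, run = baseline
        for col in ("q_mv", "q_av", "q_tv", "q_pv"):
            assert np.all(run.trajectory.column(col) >= 0.0)


class TestRunToConvergence:
    def test_stroke_volumes_match_below_one_percent(self, baseline):
        _, run = baseline
        assert run.sv_mismatch < 0.01

    def test_restart_from_converged_state_reconverges_quickly(self, baseline):
        model, run = baseline
        again = run_to_convergence(model, initial_state=run.state,
                                   max_beats=50)
        assert again.beats_used <= 5

    def test_converged_orbit_is_periodic(self, baseline):
        """Successive beats agree in their pressure traces to within
        0.5% of the pulse pressure in the RMS norm.

        The converged orbit carries an intrinsic ~0.2 ul beat-to-beat
        volume wobble, and the steep activation upstroke makes the
        point-wise maximum timing-hypersensitive, so periodicity is
        asserted in the integral norm.
        """
        model, run = baseline
        _, tr2 = integrate_beat(run.state, model)
        for col in ("P_Ao", "P_RV", "P_LV"):
            a = run.trajectory.column(col)
            b = tr2.column(col)
            pulse = a.max() - a.min()
            assert np.sqrt(np.mean((a - b) ** 2)) < 0.005 * pulse

    def test_determinism_bitwise(self):
        """Two independent runs of the same configuration produce
        bitwise-identical trajectories (no stochastic elements)."""
        model = default_model()
        r1 = run_to_convergence(model, max_beats=60)
        r2 = run_to_convergence(model, max_beats=60)
        assert np.array_equal(r1.trajectory.states, r2.trajectory.states)
        assert r1.beats_used == r2.beats_used

    def test_converged_beat_geometry_is_equilibrated(self, baseline):
        """Re-solving the junction balance at every sampled state of the
        converged beat meets the strict residual tolerance."""
        from rvsim import _core
        model, run = baseline
        pp = model.pack()
        worst = 0.0
        for i in range(0, len(run.trajectory.t), 16):
            y = run.trajectory.states[i]
            out = np.empty(27)
            warm = np.array([0.0, -1.0])
            ok = _core.triseg_solve(y[6], y[7], y[8:17], pp, warm, out, 1e-8)
            assert ok
            worst = max(worst, out[4])
        assert worst < 1e-8

    def test_beats_to_convergence_reported(self, baseline):
        _, run = baseline
        assert 1 <= run.beats_used <= 500


class TestHomeostasis:
    def test_in_range_model_returned_unchanged(self, baseline):
        model, run = baseline
        again_model, again_run = homeostasis_adjust(
            model, initial_state=run.state)
        assert again_model is model

    def test_systolic_pressure_monotone_in_blood_volume(self, baseline):
        """Near the operating point, systolic AoP rises with total blood
        volume (the premise of the volume bisection)."""
        model, run = baseline
        pressures = []
        for f in (0.96, 1.0, 1.04):
            c = model.circulation
            m = replace(model, circulation=replace(c, V_total=c.V_total * f))
            from rvsim.simulator import _scale_state
            r = run_to_convergence(m, initial_state=_scale_state(run.state, f))
            pressures.append(r.trajectory.column("P_Ao").max())
        assert pressures[0] < pressures[1] < pressures[2]


class TestTrajectoryOutput:
    def test_csv_round_trip_with_documented_header(self, baseline, tmp_path):
        import pandas as pd
        _, run = baseline
        path = tmp_path / "traj.csv"
        run.trajectory.to_csv(path)
        df = pd.read_csv(path)
        expected = ["time_s", "P_LV", "P_RV", "P_Ao", "P_PA", "P_PV", "P_SV",
                    "P_LA", "P_RA", "V_Ao", "V_SV", "V_PA", "V_PV", "V_LA",
                    "V_RA", "V_LV", "V_RV", "q_mv", "q_av", "q_tv", "q_pv",
                    "q_sys", "q_pul", "q_ven_s", "q_ven_p",
                    "Ls_LW", "Ls_SW", "Ls_RW"]
        assert list(df.columns) == expected
        assert len(df) == len(run.trajectory.t)

    def test_primed_state_respects_total_volume(self):
        model = default_model()
        st = primed_state(model)
        assert st.total_volume == pytest.approx(model.circulation.V_total)


def test_max_beats_exhaustion_raises():
    model = default_model()
    with pytest.raises(RvsimError):
        run_to_convergence(model, max_beats=1)
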