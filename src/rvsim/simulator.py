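"""Beat-wise integration, periodic convergence, and the homeostasis loop.

A simulation starts from a primed near-physiological distribution of
the blood volume with a short contractility ramp (sarcomeres at rest),
integrates whole beats with an adaptive embedded Runge-Kutta pair
(relative tolerance 1e-7, absolute tolerance 1e-9 of the total blood
volume on the compartment volumes), and stops when the right and left
ventricular stroke volumes agree to within one percent *and* both
end-diastolic volumes are stationary to 0.1% beat over beat.  The
stroke-volume criterion is the physiological statement of periodicity
in a closed loop; the added end-diastolic stationarity check guards
against transient coincidences early in the run.

The homeostasis loop reproduces the study protocol that anchors every
simulation to a common operating point: blood volume first, then
systemic vascular resistance, are adjusted by bisection until the
converged systolic aortic pressure lies in a target window
(110-125 mmHg by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _core
from .circulation import ModelParams, SystemState
from .errors import ConvergenceError, HomeostasisError, IntegrationError

__all__ = [
    "Trajectory",
    "ConvergedRun",
    "integrate_beat",
    "run_to_convergence",
    "passive_equilibrium",
    "homeostasis_adjust",
    "DEFAULT_RTOL",
]

DEFAULT_RTOL = 1e-7
DEFAULT_SAMPLES = 512
# step cap as a fraction of the period: guarantees the volume-extreme
# tracking in the convergence loop sees >= 300 points per beat
HMAX_FRAC = 1.0 / 300.0

AUX_COLUMNS = ("P_LV", "P_RV", "P_Ao", "P_PA", "P_PV", "P_SV", "P_LA", "P_RA",
               "q_mv", "q_av", "q_tv", "q_pv", "q_sys", "q_pul",
               "q_ven_s", "q_ven_p")
VOLUME_COLUMNS = ("V_Ao", "V_SV", "V_PA", "V_PV", "V_LA", "V_RA",
                  "V_LV", "V_RV")
LS_COLUMNS = ("Ls_LW", "Ls_SW", "Ls_RW")


@dataclass
class Trajectory:
    """Uniformly sampled single-beat traces.

    ``states`` holds the raw ODE states (n, 17); ``aux`` the derived
    pressures and flows (n, 16) in ``AUX_COLUMNS`` order.
    """

    t: np.ndarray
    states: np.ndarray
    aux: np.ndarray
    period: float
    hr: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0.0):
            raise IntegrationError("trajectory time grid must be increasing")

    def column(self, name: str) -> np.ndarray:
        if name == "time_s":
            return self.t
        if name in AUX_COLUMNS:
            return self.aux[:, AUX_COLUMNS.index(name)]
        if name in VOLUME_COLUMNS:
            return self.states[:, VOLUME_COLUMNS.index(name)]
        if name in LS_COLUMNS:
            return self.states[:, 8 + 3 * LS_COLUMNS.index(name)]
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        cols = ("time_s",) + AUX_COLUMNS[:8] + VOLUME_COLUMNS \
            + AUX_COLUMNS[8:] + LS_COLUMNS
        return pd.DataFrame({c: self.column(c) for c in cols})

    def to_csv(self, path) -> None:
        """Plain CSV, one row per sample, documented column header."""
        self.to_frame().to_csv(path, index=False)

    @property
    def total_volume(self) -> np.ndarray:
        return self.states[:, :8].sum(axis=1)


@dataclass
class ConvergedRun:
    """Result of :func:`run_to_convergence`."""

    trajectory: Trajectory
    state: SystemState
    beats_used: int
    sv_mismatch: float
    edv_change: float
    model: ModelParams


def _atol_vector(model: ModelParams) -> np.ndarray:
    atol = np.empty(_core.NY)
    atol[:8] = 1e-9 * model.circulation.V_total
    for w in range(3):
        atol[8 + 3 * w] = 1e-9      # Ls (um)
        atol[9 + 3 * w] = 1e-12     # A
        atol[10 + 3 * w] = 1e-12    # xbar (um)
    atol[17:] = 1e-9 * model.circulation.V_total  # ejected-volume integrals
    return atol


def _pad(y: np.ndarray) -> np.ndarray:
    """Append the two cumulative ejected-volume slots to a physical state."""
    return np.concatenate([y, [0.0, 0.0]])


def integrate_beat(state: SystemState, model: ModelParams,
                   n_samples: int = DEFAULT_SAMPLES,
                   rtol: float = DEFAULT_RTOL,
                   ) -> tuple[SystemState, Trajectory]:
    """Integrate exactly one period and sample the trajectory.

    Returns the end-of-beat state (with the geometry warm start carried
    over) and a :class:`Trajectory` with ``n_samples + 1`` rows covering
    the closed interval [0, T].
    """
    state.validate()
    pp = model.pack()
    warm = state.warm.copy()
    atol = _atol_vector(model)
    status, tg, ys, aux, y_end = _core.integrate_sampled(
        _pad(state.to_vector()), pp, warm, n_samples, rtol, atol, HMAX_FRAC)
    if status != 0:
        raise IntegrationError(
            f"beat integration failed with status {status} "
            f"(1 = geometry, 2 = step underflow)")
    if np.any(aux[:, 18] == 0.0):
        raise IntegrationError("geometry solve failed at a sample point")
    traj = Trajectory(t=tg, states=ys[:, :17], aux=aux[:, :16],
                      period=model.circulation.period,
                      hr=model.circulation.HR)
    return SystemState.from_vector(y_end[:17], warm=warm), traj


def run_to_convergence(model: ModelParams,
                       initial_state: SystemState | None = None,
                       max_beats: int = 500,
                       sv_tol: float = 0.01,
                       edv_tol: float = 1e-3,
                       rtol: float = DEFAULT_RTOL,
                       n_samples: int = DEFAULT_SAMPLES) -> ConvergedRun:
    """Iterate beats until the periodic steady state is reached.

    Convergence: |SV_RV - SV_LV| / SV_LV < ``sv_tol`` and beat-to-beat
    end-diastolic volume changes < ``edv_tol`` for both ventricles.
    Starting from the passive equilibrium this typically takes on the
    order of a couple hundred beats; restarting from a converged state
    takes a handful.
    """
    if max_beats < 1:
        raise ValueError("max_beats must be >= 1")
    atol = _atol_vector(model)
    if initial_state is None:
        # soft start from a primed near-physiological distribution:
        # contractility ramps up over a few beats so the loop never sees
        # a violent synchronized transient far from any quasi-steady
        # orbit (a uniform-pressure passive equilibrium grossly overfills
        # the thin-walled RV and drives the geometry through collapse)
        initial_state = primed_state(model)
        warm = initial_state.warm.copy()
        y = _pad(initial_state.to_vector())
        for frac in (0.5, 0.75, 1.0):
            ramped = replace(model, act_scale=model.act_scale * frac)
            status, y, _, _, _ = _core.run_beats(
                y, ramped.pack(), warm, 2, 1e-12, 1e-12, rtol, atol,
                HMAX_FRAC)
            if status in (1, 2):
                raise IntegrationError(
                    f"integration failed during the start-up ramp "
                    f"(contractility fraction {frac})")
        initial_state = SystemState.from_vector(y[:17], warm=warm)
    initial_state.validate()
    pp = model.pack()
    warm = initial_state.warm.copy()
    status, y_end, beats, sv_mis, edv_chg = _core.run_beats(
        _pad(initial_state.to_vector()), pp, warm, max_beats, sv_tol,
        edv_tol, rtol, atol, HMAX_FRAC)
    if status in (1, 2):
        raise IntegrationError(
            f"integration failed in beat {beats} (status {status})")
    if status == 3:
        raise ConvergenceError(
            f"no periodic convergence within {max_beats} beats "
            f"(SV mismatch {sv_mis:.3%}, EDV change {edv_chg:.3%})")
    end_state = SystemState.from_vector(y_end[:17], warm=warm)
    final_state, traj = integrate_beat(end_state, model,
                                       n_samples=n_samples, rtol=rtol)
    return ConvergedRun(trajectory=traj, state=final_state, beats_used=beats,
                        sv_mismatch=float(sv_mis), edv_change=float(edv_chg),
                        model=model)


def primed_state(model: ModelParams) -> SystemState:
    """Deterministic near-physiological starting distribution.

    Ventricles and atria get modest end-diastolic-like volumes; the
    remaining stressed blood volume is split over the four vascular
    compartments in proportion to their compliances.  Sarcomeres start
    just below the reference length with no attached cross-bridges.
    The few-beat contractility ramp in :func:`run_to_convergence`
    absorbs the (deterministic) transient this leaves.
    """
    c = model.circulation
    volumes = {"LV": 55.0, "RV": 50.0, "LA": 25.0, "RA": 25.0}
    stressed = c.V_total - sum(volumes.values()) \
        - (c.V0_Ao + c.V0_SV + c.V0_PA + c.V0_PV)
    if stressed <= 0.0:
        raise IntegrationError("total blood volume too small to prime")
    weights = {"Ao": c.C_Ao, "SV": c.C_SV, "PA": c.C_PA, "PV": c.C_PV}
    wsum = sum(weights.values())
    volumes["Ao"] = c.V0_Ao + stressed * weights["Ao"] / wsum
    volumes["SV"] = c.V0_SV + stressed * weights["SV"] / wsum
    volumes["PA"] = c.V0_PA + stressed * weights["PA"] / wsum
    volumes["PV"] = c.V0_PV + stressed * weights["PV"] / wsum
    walls = tuple(_rest_state(w.sarcomere) for w in model.walls)
    return SystemState(volumes=volumes, walls=walls)


def passive_equilibrium(model: ModelParams,
                        settle_time: float = 8.0,
                        rtol: float = DEFAULT_RTOL) -> SystemState:
    """Relaxed no-activation distribution of the total blood volume.

    The passive variant of the model (zero active stress, flat calcium,
    atrial compliance frozen) is integrated from a crude volume
    distribution until flows die out; the result is the deterministic
    initial condition of every simulation.
    """
    passive = model.passive_variant()
    c = model.circulation
    # crude starting split: stressed volume proportional to compliance
    stressed = c.V_total - (c.V0_Ao + c.V0_SV + c.V0_PA + c.V0_PV)
    weights = {
        "Ao": c.C_Ao, "SV": c.C_SV, "PA": c.C_PA, "PV": c.C_PV,
        "LA": model.la.C_max, "RA": model.ra.C_max, "LV": 8.0, "RV": 8.0,
    }
    wsum = sum(weights.values())
    volumes = {k: stressed * w / wsum for k, w in weights.items()}
    volumes["Ao"] += c.V0_Ao
    volumes["SV"] += c.V0_SV
    volumes["PA"] += c.V0_PA
    volumes["PV"] += c.V0_PV
    walls = tuple(
        # start at the series-element rest length for a mildly stretched wall
        _rest_state(w.sarcomere) for w in model.walls)
    state = SystemState(volumes=volumes, walls=walls)

    pp = passive.pack()
    warm = state.warm.copy()
    atol = _atol_vector(model)
    n_beats = max(1, int(round(settle_time / c.period)))
    status, y_end, beats, _, _ = _core.run_beats(
        _pad(state.to_vector()), pp, warm, n_beats, 1e-12, 1e-12, rtol,
        atol, HMAX_FRAC)
    if status in (1, 2):
        raise IntegrationError("passive relaxation failed")
    return SystemState.from_vector(y_end[:17], warm=warm)


def _rest_state(sp) -> "SarcomereState":
    from .sarcomere import SarcomereState
    return SarcomereState(Ls=sp.Ls_ref * 0.95, A=0.0, xbar=sp.x0)


def systolic_aortic_pressure(run: ConvergedRun) -> float:
    return float(run.trajectory.column("P_Ao").max())


def homeostasis_adjust(model: ModelParams,
                       lo: float = 110.0, hi: float = 125.0,
                       volume_bounds: tuple[float, float] = (0.75, 1.4),
                       svr_bounds: tuple[float, float] = (0.5, 2.5),
                       max_iter: int = 14,
                       knobs: tuple[str, ...] = ("volume", "svr"),
                       **run_kwargs) -> tuple[ModelParams, ConvergedRun]:
    """Adjust blood volume, then SVR, until systolic AoP is in range.

    Both adjustments search multiplicatively outward from the current
    value (the systolic-pressure response is monotone near the operating
    point, though not globally, so the search expands in small steps and
    bisects once the target window is bracketed).  Each candidate is run
    to convergence warm-started from the previous converged state; the
    procedure is deterministic.  Returns the adjusted model with its
    converged run, or raises :class:`HomeostasisError` with the best
    achieved pressure.

    ``knobs`` selects which levers may move, in order.  The default is
    the full protocol (blood volume first, then SVR); disease arms that
    inherit the baseline blood volume use ``("svr",)`` so that every arm
    shares the same total volume and only vascular tone responds.
    """
    initial_state = run_kwargs.pop("initial_state", None)
    run = run_to_convergence(model, initial_state=initial_state, **run_kwargs)
    p = systolic_aortic_pressure(run)
    if lo <= p <= hi:
        return model, run
    target = 0.5 * (lo + hi)

    c0 = model.circulation
    v0_sum = c0.V0_Ao + c0.V0_SV + c0.V0_PA + c0.V0_PV
    vol_lo = max(volume_bounds[0], 1.1 * (v0_sum + 150.0) / c0.V_total)

    def with_volume(mult: float) -> ModelParams:
        return replace(model, circulation=replace(
            model.circulation, V_total=model.circulation.V_total * mult))

    def eval_volume(mult: float, state: SystemState) -> tuple[ConvergedRun, float]:
        scale = mult * model.circulation.V_total / state.total_volume
        r = run_to_convergence(with_volume(mult),
                               initial_state=_scale_state(state, scale),
                               **run_kwargs)
        return r, systolic_aortic_pressure(r)

    adj_model, adj_run = model, run
    if "volume" in knobs:
        result = _expand_and_bisect(eval_volume, run, p, lo, hi, target,
                                    vol_lo, volume_bounds[1], max_iter)
        if result is not None:
            adj_model, adj_run, p = result
            if lo <= p <= hi:
                return adj_model, adj_run
        else:
            p = systolic_aortic_pressure(run)

    # --- stage 2: systemic vascular resistance --------------------------
    if "svr" not in knobs:
        raise HomeostasisError(
            f"systolic AoP target [{lo}, {hi}] mmHg unreachable with "
            f"knobs {knobs}; achieved {p:.1f} mmHg")

    def with_svr(mult: float) -> ModelParams:
        return replace(adj_model, circulation=replace(
            adj_model.circulation, SVR=adj_model.circulation.SVR * mult))

    def eval_svr(mult: float, state: SystemState) -> tuple[ConvergedRun, float]:
        r = run_to_convergence(with_svr(mult), initial_state=state,
                               **run_kwargs)
        return r, systolic_aortic_pressure(r)

    result = _expand_and_bisect(eval_svr, adj_run, p, lo, hi, target,
                                svr_bounds[0], svr_bounds[1], max_iter)
    if result is not None:
        final_model, final_run, p = result
        if lo <= p <= hi:
            return final_model, final_run
    raise HomeostasisError(
        f"systolic AoP target [{lo}, {hi}] mmHg unreachable; "
        f"achieved {p:.1f} mmHg")


def _expand_and_bisect(eval_fn, run0: ConvergedRun, p0: float,
                       lo: float, hi: float, target: float,
                       mult_lo: float, mult_hi: float, max_iter: int):
    """Multiplicative outward search followed by bisection.

    ``eval_fn(mult, state)`` must return (run, pressure) with pressure
    increasing in ``mult`` near mult = 1.  Returns (model, run, p) of the
    last evaluation (inside the window when successful) or None if the
    window was never bracketed inside [mult_lo, mult_hi].
    """
    m_prev, p_prev = 1.0, p0
    state = run0.state
    step = 1.08 if p0 < target else 1.0 / 1.08
    m = 1.0
    first = True
    for _ in range(25):
        m = min(max(m * step, mult_lo), mult_hi)
        r, p = eval_fn(m, state)
        state = r.state
        if lo <= p <= hi:
            return r.model, r, p
        if first:
            first = False
            if abs(p - target) > abs(p0 - target) + 0.2:
                # the response is locally wrong-signed (e.g. extra volume
                # dilating a failing ventricle): this knob cannot help
                return None
        if (p - target) * (p_prev - target) < 0.0:
            # bracketed: bisect between m_prev and m
            a, b = (m_prev, m) if p_prev < target else (m, m_prev)
            for _ in range(max_iter):
                mid = 0.5 * (a + b)
                r, p = eval_fn(mid, state)
                state = r.state
                if lo <= p <= hi:
                    return r.model, r, p
                if p < target:
                    a = mid
                else:
                    b = mid
            return r.model, r, p
        if m in (mult_lo, mult_hi):
            return r.model, r, p
        if abs(p - target) > abs(p_prev - target) - 0.1:
            # response has flattened out; this knob is exhausted
            return None
        m_prev, p_prev = m, p
    return None


def _scale_state(state: SystemState, mult: float) -> SystemState:
    """Uniformly scale all compartment volumes (preload change)."""
    volumes = {k: v * mult for k, v in state.volumes.items()}
    return SystemState(volumes=volumes, walls=state.walls, warm=state.warm.copy())
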