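"""Hemodynamic indices from converged beats.

End-diastole and end-systole are read off the valve flows, which are
unambiguous in a simulation with ideal diode valves: end-diastole is
the instant the inflow valve closes (last sample of the filling block
that wraps the beat boundary) and end-systole the instant the outflow
valve closes.  On top of the per-beat metrics the module provides the
load-independent indices used to characterise ventricular-vascular
interaction: effective arterial elastance Ea = Pes/SV, end-systolic
elastance Ees from a multi-preload fit of the end-systolic
pressure-volume relation (ESPVR), their coupling ratio, and diastolic
chamber compliance from the corresponding end-diastolic points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .circulation import ModelParams
from .errors import MetricsError
from .simulator import ConvergedRun, Trajectory, run_to_convergence, _scale_state

__all__ = [
    "VentricleMetrics",
    "BeatMetrics",
    "VentricularIndices",
    "PreloadPoint",
    "beat_metrics",
    "arterial_elastance",
    "fit_pv_line",
    "preload_series",
    "fit_espvr",
    "diastolic_compliance",
    "ventricular_indices",
    "fold_change_report",
    "DEFAULT_PRELOAD_FRACTIONS",
]

DEFAULT_PRELOAD_FRACTIONS = (1.0, 0.95, 0.9, 0.85, 0.8)


@dataclass(frozen=True)
class VentricleMetrics:
    """Per-beat quantities for one ventricle (volumes ul, pressures mmHg)."""

    EDV: float
    ESV: float
    SV: float
    EF: float
    CO: float            # ul/min
    Pmax: float          # peak cavity pressure
    Pes: float           # pressure at outflow-valve closure
    Ped: float           # pressure at inflow-valve closure (end-diastole)
    Pmin: float          # beat minimum pressure (also reported; see Ped)

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        return {prefix + k: getattr(self, k) for k in
                ("EDV", "ESV", "SV", "EF", "CO", "Pmax", "Pes", "Ped", "Pmin")}


@dataclass(frozen=True)
class BeatMetrics:
    """Both ventricles plus arterial summaries for one converged beat."""

    rv: VentricleMetrics
    lv: VentricleMetrics
    sys_aop: float       # systolic aortic pressure (mmHg)
    mean_ppa: float      # mean pulmonary artery pressure (mmHg)
    hr: float

    @property
    def RVSP(self) -> float:
        """Right ventricular systolic pressure (peak P_RV)."""
        return self.rv.Pmax

    def as_dict(self) -> dict[str, float]:
        out = self.rv.as_dict("RV_")
        out.update(self.lv.as_dict("LV_"))
        out["RVSP"] = self.RVSP
        out["sys_AoP"] = self.sys_aop
        out["mean_PPA"] = self.mean_ppa
        out["HR"] = self.hr
        return out


@dataclass(frozen=True)
class VentricularIndices:
    """Derived ventricular/vascular indices for the right ventricle."""

    Ea: float                    # arterial elastance (mmHg/ul)
    Ees: float                   # end-systolic elastance (mmHg/ul)
    Ees_intercept: float         # ESPVR volume-axis related intercept (mmHg)
    Ees_r2: float
    coupling: float              # Ees / Ea
    chamber_compliance: float    # dEDV/dEDP (ul/mmHg)
    compliance_r2: float

    def as_dict(self) -> dict[str, float]:
        return {"Ea": self.Ea, "Ees": self.Ees, "coupling": self.coupling,
                "chamber_compliance": self.chamber_compliance,
                "Ees_r2": self.Ees_r2, "compliance_r2": self.compliance_r2}


def _closure_index(q: np.ndarray) -> int:
    """Last index of the flow block that contains the beat boundary.

    The trajectory covers one beat starting at ventricular activation,
    so a valve that is open across the boundary closes early in the
    sampled window; the closure instant is the last sample of that
    leading open block.  If the valve is already closed at t = 0 the
    boundary sample itself is the event.
    """
    n = len(q)
    i = 0
    while i + 1 < n and q[i + 1] > 0.0:
        i += 1
    return i


def _last_positive(q: np.ndarray) -> int:
    idx = np.nonzero(q > 0.0)[0]
    if len(idx) == 0:
        raise MetricsError("valve never opened during the beat")
    return int(idx[-1])


def _ventricle(tr: Trajectory, q_in: str, q_out: str, v_col: str,
               p_col: str) -> VentricleMetrics:
    qi = tr.column(q_in)
    qo = tr.column(q_out)
    v = tr.column(v_col)
    p = tr.column(p_col)
    if not np.any(qi > 0.0) or not np.any(qo > 0.0):
        raise MetricsError(
            f"no complete fill/eject cycle in trajectory ({q_in}/{q_out})")
    ed = _closure_index(qi) if qi[0] > 0.0 else int(np.argmax(v))
    es = _last_positive(qo)
    edv = float(v[ed])
    esv = float(v[es])
    if edv <= esv:
        raise MetricsError("end-diastolic volume does not exceed end-systolic")
    sv = edv - esv
    return VentricleMetrics(
        EDV=edv, ESV=esv, SV=sv, EF=sv / edv, CO=sv * tr.hr,
        Pmax=float(p.max()), Pes=float(p[es]), Ped=float(p[ed]),
        Pmin=float(p.min()))


def beat_metrics(tr: Trajectory) -> BeatMetrics:
    """Per-beat hemodynamics of both ventricles from one sampled beat."""
    rv = _ventricle(tr, "q_tv", "q_pv", "V_RV", "P_RV")
    lv = _ventricle(tr, "q_mv", "q_av", "V_LV", "P_LV")
    return BeatMetrics(
        rv=rv, lv=lv,
        sys_aop=float(tr.column("P_Ao").max()),
        mean_ppa=float(np.trapezoid(tr.column("P_PA"), tr.t) / tr.period),
        hr=tr.hr)


def arterial_elastance(Pes: float, SV: float) -> float:
    """Effective arterial elastance Ea = Pes / SV (mmHg/ul)."""
    if SV <= 0.0:
        raise MetricsError("stroke volume must be positive")
    return Pes / SV


def fit_pv_line(volumes: Sequence[float],
                pressures: Sequence[float]) -> tuple[float, float, float]:
    """Least-squares line P = slope * V + intercept; returns
    (slope, intercept, R^2)."""
    v = np.asarray(volumes, dtype=float)
    p = np.asarray(pressures, dtype=float)
    if len(v) < 2 or len(v) != len(p):
        raise MetricsError("need at least two matching (V, P) points")
    if np.ptp(v) == 0.0:
        raise MetricsError("degenerate fit: volumes are collinear in V")
    res = stats.linregress(v, p)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


@dataclass(frozen=True)
class PreloadPoint:
    """End-systolic and end-diastolic RV points at one preload level."""

    fraction: float
    ESV: float
    Pes: float
    EDV: float
    Ped: float
    metrics: BeatMetrics


def preload_series(model: ModelParams,
                   preload_fractions: Sequence[float] = DEFAULT_PRELOAD_FRACTIONS,
                   base_run: ConvergedRun | None = None,
                   **run_kwargs) -> list[PreloadPoint]:
    """Converged runs over a series of total-blood-volume fractions.

    The homeostasis loop stays off for the sub-runs: the point of the
    series is to move preload.  Each sub-run is warm-started from the
    reference converged state with all compartment volumes scaled, which
    keeps the series cheap and deterministic.
    """
    fractions = list(preload_fractions)
    if len(fractions) < 3:
        raise MetricsError("need at least three preload fractions")
    for f in fractions:
        if not 0.7 < f <= 1.0:
            raise MetricsError("preload fractions must lie in (0.7, 1.0]")
    if base_run is None:
        base_run = run_to_convergence(model, **run_kwargs)
    points = []
    for f in sorted(set(fractions), reverse=True):
        if f == 1.0:
            run = base_run
        else:
            c = model.circulation
            m = replace(model,
                        circulation=replace(c, V_total=c.V_total * f))
            start = _scale_state(base_run.state, f)
            run = run_to_convergence(m, initial_state=start, **run_kwargs)
        bm = beat_metrics(run.trajectory)
        points.append(PreloadPoint(fraction=f, ESV=bm.rv.ESV, Pes=bm.rv.Pes,
                                   EDV=bm.rv.EDV, Ped=bm.rv.Ped, metrics=bm))
    return points


def fit_espvr(points: Sequence[PreloadPoint] | None = None,
              model: ModelParams | None = None,
              preload_fractions: Sequence[float] = DEFAULT_PRELOAD_FRACTIONS,
              **run_kwargs) -> tuple[float, float, float]:
    """End-systolic elastance from the multi-preload ESPVR fit.

    Pass precomputed ``points`` (from :func:`preload_series`) or a
    ``model`` to simulate them.  Returns (Ees, intercept, R^2); a
    non-positive slope raises :class:`MetricsError`.
    """
    if points is None:
        if model is None:
            raise MetricsError("provide either points or a model")
        points = preload_series(model, preload_fractions, **run_kwargs)
    slope, intercept, r2 = fit_pv_line([p.ESV for p in points],
                                       [p.Pes for p in points])
    if slope <= 0.0:
        raise MetricsError(f"non-positive ESPVR slope {slope:.3g}")
    return slope, intercept, r2


def diastolic_compliance(points: Sequence[PreloadPoint] | None = None,
                         model: ModelParams | None = None,
                         preload_fractions: Sequence[float] = DEFAULT_PRELOAD_FRACTIONS,
                         **run_kwargs) -> tuple[float, float]:
    """RV chamber compliance: slope of EDV against EDP across preloads.

    Returns (compliance ul/mmHg, R^2 of the fit).
    """
    if points is None:
        if model is None:
            raise MetricsError("provide either points or a model")
        points = preload_series(model, preload_fractions, **run_kwargs)
    slope, _, r2 = fit_pv_line([p.Ped for p in points],
                               [p.EDV for p in points])
    if slope <= 0.0:
        raise MetricsError(f"non-positive EDPVR slope {slope:.3g}")
    return slope, r2


def ventricular_indices(model: ModelParams,
                        base_run: ConvergedRun | None = None,
                        preload_fractions: Sequence[float] = DEFAULT_PRELOAD_FRACTIONS,
                        **run_kwargs) -> tuple[VentricularIndices, list[PreloadPoint]]:
    """All derived RV indices from one preload series."""
    points = preload_series(model, preload_fractions, base_run=base_run,
                            **run_kwargs)
    ref = next(p for p in points if p.fraction == 1.0)
    ea = arterial_elastance(ref.Pes, ref.metrics.rv.SV)
    ees, intercept, ees_r2 = fit_espvr(points=points)
    comp, comp_r2 = diastolic_compliance(points=points)
    return VentricularIndices(
        Ea=ea, Ees=ees, Ees_intercept=intercept, Ees_r2=ees_r2,
        coupling=ees / ea, chamber_compliance=comp,
        compliance_r2=comp_r2), points


def fold_change_report(sim: Mapping[str, float],
                       ref: Mapping[str, float]) -> dict[str, dict[str, float]]:
    """Both normalisation conventions for every shared metric.

    Experimental tables mix "ratio" (sim/ref) and "fractional change"
    ((sim-ref)/ref) conventions; the report always emits both, labeled,
    so no convention is silently picked.
    """
    missing = [k for k in sim if k not in ref]
    if missing:
        raise MetricsError(f"reference values missing for: {missing}")
    out: dict[str, dict[str, float]] = {}
    for k, v in sim.items():
        r = ref[k]
        if r == 0.0:
            raise MetricsError(f"reference value for {k} is zero")
        out[k] = {"value": float(v), "reference": float(r),
                  "ratio": float(v / r),
                  "fractional_change": float((v - r) / r)}
    return out
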