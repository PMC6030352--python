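"""Closed-loop lumped-parameter circulation.

Four linear-compliance vascular compartments (aorta, systemic veins,
pulmonary artery, pulmonary veins), two atria with time-varying
compliance, four diode-resistor valves, and the two bed resistances
SVR and PVR.  Atrial pressure is ``P = V / C(t)``; the compliance dips
from its diastolic maximum to a contracted minimum over a half-cosine
window late in the cycle, which provides the atrial kick that tops up
ventricular filling just before activation.

The module also defines :class:`ModelParams`, the full parameter bundle
(three heart walls + circulation + atria) that the simulator consumes,
and the packing of that bundle into the flat kernel vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from . import _core
from .errors import ParameterError
from .sarcomere import SarcomereParams, SarcomereState
from .triseg import WallSegment

__all__ = [
    "AtrialParams",
    "CirculationParams",
    "SystemState",
    "ModelParams",
    "default_model",
    "atrial_compliance",
    "atrial_pressure",
    "valve_flow",
    "system_derivatives",
]


@dataclass(frozen=True)
class AtrialParams:
    """Time-varying atrial compliance waveform parameters."""

    C_max: float       # diastolic compliance (ul/mmHg)
    C_min: float       # contracted compliance (ul/mmHg)
    t_onset: float = 0.75   # contraction onset, fraction of the beat period
    d_a: float = 0.25       # contraction duration, fraction of the period

    def __post_init__(self) -> None:
        if not 0.0 < self.C_min < self.C_max:
            raise ParameterError("need 0 < C_min < C_max")
        if not 0.0 < self.d_a < 1.0:
            raise ParameterError("d_a must lie in (0, 1)")
        if not 0.0 <= self.t_onset < 1.0:
            raise ParameterError("t_onset must lie in [0, 1)")


@dataclass(frozen=True)
class CirculationParams:
    """Compliances (ul/mmHg), resistances (mmHg s/ul), volumes (ul).

    Defaults describe a healthy ~25 g mouse: cardiac output around
    12 ml/min at 420 bpm with systolic aortic pressure near 120 mmHg and
    mean pulmonary artery pressure near 14 mmHg.
    """

    C_Ao: float = 0.7
    C_SV: float = 12.0
    C_PA: float = 2.2
    C_PV: float = 6.0
    PVR: float = 0.05
    SVR: float = 0.45
    R_av: float = 0.003
    R_pval: float = 0.002
    R_mv: float = 0.004
    R_tv: float = 0.003
    R_ven_s: float = 0.01
    R_ven_p: float = 0.008
    V0_Ao: float = 40.0
    V0_SV: float = 880.0
    V0_PA: float = 30.0
    V0_PV: float = 60.0
    V_total: float = 1380.0
    HR: float = 420.0

    def __post_init__(self) -> None:
        for name in ("C_Ao", "C_SV", "C_PA", "C_PV", "PVR", "SVR", "R_av",
                     "R_pval", "R_mv", "R_tv", "R_ven_s", "R_ven_p",
                     "V_total", "HR"):
            if not getattr(self, name) > 0.0:
                raise ParameterError(f"{name} must be strictly positive")
        v0_sum = self.V0_Ao + self.V0_SV + self.V0_PA + self.V0_PV
        if self.V_total <= v0_sum:
            raise ParameterError("V_total must exceed the summed unstressed volumes")

    @property
    def period(self) -> float:
        return 60.0 / self.HR


COMPARTMENTS = ("Ao", "SV", "PA", "PV", "LA", "RA", "LV", "RV")


@dataclass
class SystemState:
    """Full ODE state: compartment volumes plus per-wall sarcomere states."""

    volumes: dict[str, float]
    walls: tuple[SarcomereState, SarcomereState, SarcomereState]
    warm: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0]))

    def to_vector(self) -> np.ndarray:
        y = np.empty(_core.NY_PHYS)
        for i, name in enumerate(COMPARTMENTS):
            y[i] = self.volumes[name]
        for w, st in enumerate(self.walls):
            y[8 + 3 * w] = st.Ls
            y[9 + 3 * w] = st.A
            y[10 + 3 * w] = st.xbar
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray,
                    warm: np.ndarray | None = None) -> "SystemState":
        volumes = {name: float(y[i]) for i, name in enumerate(COMPARTMENTS)}
        walls = tuple(
            SarcomereState(Ls=float(y[8 + 3 * w]), A=float(y[9 + 3 * w]),
                           xbar=float(y[10 + 3 * w]))
            for w in range(3))
        warm = np.array([0.0, -1.0]) if warm is None else warm.copy()
        return cls(volumes=volumes, walls=walls, warm=warm)

    @property
    def total_volume(self) -> float:
        return float(sum(self.volumes.values()))

    def validate(self, V_total: float | None = None,
                 rtol: float = 1e-6) -> None:
        for name, v in self.volumes.items():
            if not v > 0.0:
                raise ParameterError(f"volume of {name} must be positive")
        for st in self.walls:
            st.validate()
        if V_total is not None:
            if abs(self.total_volume - V_total) > rtol * V_total:
                raise ParameterError("compartment volumes do not sum to V_total")


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter bundle for one simulation."""

    walls: tuple[WallSegment, WallSegment, WallSegment]
    circulation: CirculationParams = field(default_factory=CirculationParams)
    la: AtrialParams = field(default_factory=lambda: AtrialParams(5.0, 2.5))
    ra: AtrialParams = field(default_factory=lambda: AtrialParams(4.0, 2.0))
    act_scale: float = 1.0

    def pack(self) -> np.ndarray:
        pp = np.zeros(_core.NP)
        for w, wall in enumerate(self.walls):
            pp[w * _core.NSP:(w + 1) * _core.NSP] = wall.sarcomere.pack()
            pp[_core.P_VW + w] = wall.Vw
            pp[_core.P_AMREF + w] = wall.Am_ref
        c = self.circulation
        pp[_core.P_C_AO] = c.C_Ao
        pp[_core.P_C_SV] = c.C_SV
        pp[_core.P_C_PA] = c.C_PA
        pp[_core.P_C_PV] = c.C_PV
        pp[_core.P_PVR] = c.PVR
        pp[_core.P_SVR] = c.SVR
        pp[_core.P_R_AV] = c.R_av
        pp[_core.P_R_PVAL] = c.R_pval
        pp[_core.P_R_MV] = c.R_mv
        pp[_core.P_R_TV] = c.R_tv
        pp[_core.P_R_VEN_S] = c.R_ven_s
        pp[_core.P_R_VEN_P] = c.R_ven_p
        pp[_core.P_V0_AO] = c.V0_Ao
        pp[_core.P_V0_SV] = c.V0_SV
        pp[_core.P_V0_PA] = c.V0_PA
        pp[_core.P_V0_PV] = c.V0_PV
        pp[_core.P_V_TOTAL] = c.V_total
        pp[_core.P_HR] = c.HR
        for base, ap in ((_core.P_LA, self.la), (_core.P_RA, self.ra)):
            pp[base] = ap.C_max
            pp[base + 1] = ap.C_min
            pp[base + 2] = ap.t_onset
            pp[base + 3] = ap.d_a
        pp[_core.P_ACT_SCALE] = self.act_scale
        return pp

    # convenience accessors -------------------------------------------------
    @property
    def lv_wall(self) -> WallSegment:
        return self.walls[0]

    @property
    def septum(self) -> WallSegment:
        return self.walls[1]

    @property
    def rv_wall(self) -> WallSegment:
        return self.walls[2]

    def replace_rv_sarcomere(self, sp: SarcomereParams) -> "ModelParams":
        rv = replace_wall(self.rv_wall, sarcomere=sp)
        return replace(self, walls=(self.walls[0], self.walls[1], rv))

    def passive_variant(self) -> "ModelParams":
        """A stationary passive model: no active stress, calcium flat,
        atrial compliance frozen at its diastolic value."""
        walls = tuple(
            replace_wall(w, sarcomere=replace(w.sarcomere, Ca_amp=0.0))
            for w in self.walls)
        la = replace(self.la, C_min=self.la.C_max * (1.0 - 1e-12))
        ra = replace(self.ra, C_min=self.ra.C_max * (1.0 - 1e-12))
        # C_min must stay strictly below C_max; a 1e-12 gap is inert.
        return replace(self, walls=walls, la=la, ra=ra, act_scale=0.0)


def replace_wall(wall: WallSegment, **kwargs) -> WallSegment:
    fields = dict(name=wall.name, Vw=wall.Vw, Am_ref=wall.Am_ref,
                  sarcomere=wall.sarcomere, state=wall.state)
    fields.update(kwargs)
    return WallSegment(**fields)


def default_model() -> ModelParams:
    """Baseline healthy-mouse model (the control arm of every study)."""
    sarc = SarcomereParams()
    walls = (
        WallSegment("lv_free_wall", Vw=70.0, Am_ref=73.0, sarcomere=sarc),
        WallSegment("septum", Vw=42.0, Am_ref=40.0, sarcomere=sarc),
        WallSegment("rv_free_wall", Vw=22.0, Am_ref=89.0, sarcomere=sarc),
    )
    return ModelParams(walls=walls)


# ---------------------------------------------------------------------------
# elementary operations

def atrial_compliance(t_in_beat: float, p: AtrialParams, period: float) -> float:
    """Atrial compliance (ul/mmHg) at time ``t_in_beat`` of the cycle.

    C_max outside the contraction window; inside the window a half-cosine
    dip to C_min at the window midpoint and back.  Continuous, periodic,
    with range exactly [C_min, C_max].
    """
    if period <= 0.0:
        raise ParameterError("period must be positive")
    tb = math.fmod(t_in_beat, period)
    if tb < 0.0:
        tb += period
    return float(_core.atrial_compliance_kernel(
        tb, p.C_max, p.C_min, p.t_onset, p.d_a, period))


def atrial_pressure(V_atria: float, C_atria: float) -> float:
    """Atrial pressure (mmHg) = V_atria / C_atria."""
    if C_atria <= 0.0:
        raise ParameterError("atrial compliance must be positive")
    return V_atria / C_atria


def valve_flow(P_up: float, P_down: float, R: float) -> float:
    """Ideal diode-resistor valve: max(P_up - P_down, 0) / R (ul/s)."""
    if R <= 0.0:
        raise ParameterError("valve resistance must be positive")
    return max(P_up - P_down, 0.0) / R


def system_derivatives(s: SystemState, t: float,
                       model: ModelParams) -> np.ndarray:
    """Time derivative of the full state vector at time ``t``.

    Compartment pressures come from their linear compliances, atrial
    pressures from the time-varying compliance, ventricular pressures
    from the three-wall geometry solve; the volume derivatives are the
    signed sums of the valve, bed and venous-return flows, so their sum
    vanishes identically (closed loop).
    """
    s.validate()
    pp = model.pack()
    warm = s.warm.copy() if s.warm is not None else np.array([0.0, -1.0])
    scratch = np.empty(27)
    y = np.concatenate([s.to_vector(), [0.0, 0.0]])
    ok, dy = _core.rhs(t, y, pp, warm, scratch)
    if not ok:
        from .errors import GeometryError
        raise GeometryError(f"geometry solve failed at t={t:.6f} s")
    s.warm = warm
    return dy[:_core.NY_PHYS]


def state_iter(s: SystemState) -> Iterator[tuple[str, float]]:
    """(name, volume) pairs in canonical order — handy for reports."""
    for name in COMPARTMENTS:
        yield name, s.volumes[name]
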