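"""Three-wall-segment biventricular mechanics.

The two ventricles are represented by three spherical-cap walls (LV free
wall, septum, RV free wall) that meet at a circular junction ring of
radius ``y``.  Each wall is a thin shell whose midwall cap is described
by its signed height ``x`` along the left-to-right axis.  Given the two
cavity volumes and the current sarcomere state of each wall, the solver
finds the septal midwall cap volume and the junction radius such that
the axial and radial tension components of the three walls balance at
the ring.  Cavity pressures follow from the free-wall tensions and
curvatures (Laplace-type relation for a fiber-loaded shell).

Sign conventions: the axis points from left to right; the LV free-wall
cap bulges leftward (x_L < 0, Vm_L < 0), the RV free-wall cap rightward,
and the septal cap height may change sign (septal flattening and
leftward shift under right ventricular pressure overload).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _core
from .errors import GeometryError, ParameterError
from .sarcomere import SarcomereParams, SarcomereState

__all__ = [
    "WallSegment",
    "HeartGeometry",
    "KPA_TO_MMHG",
    "cap_metrics",
    "solve_cap_height",
    "fiber_strain",
    "wall_tension_components",
    "solve_heart",
]

KPA_TO_MMHG = _core.KPA_TO_MMHG

WALL_NAMES = ("lv_free_wall", "septum", "rv_free_wall")


@dataclass
class WallSegment:
    """Structural constants plus sarcomere model of one wall."""

    name: str
    Vw: float                       # wall volume (ul)
    Am_ref: float                   # reference midwall area (mm^2)
    sarcomere: SarcomereParams = field(default_factory=SarcomereParams)
    state: SarcomereState = field(default_factory=SarcomereState)

    def __post_init__(self) -> None:
        if self.Vw <= 0.0 or self.Am_ref <= 0.0:
            raise ParameterError("wall volume and reference area must be positive")


@dataclass
class HeartGeometry:
    """Solved three-cap configuration at one instant."""

    x_L: float
    x_S: float
    x_R: float
    y: float
    Vm_S: float
    Am: tuple[float, float, float]
    Cm: tuple[float, float, float]
    Tm: tuple[float, float, float]
    epsilon_f: tuple[float, float, float]
    sigma_f: tuple[float, float, float]
    dLs_dt: tuple[float, float, float]
    P_LV: float
    P_RV: float
    residual: float
    iterations: int

    def warm_array(self) -> np.ndarray:
        return np.array([self.Vm_S, self.y])


def cap_metrics(x: float, y: float) -> tuple[float, float, float]:
    """Midwall volume, area and curvature of a spherical cap.

    Vm = (pi/6) x (x^2 + 3 y^2) (signed with x), Am = pi (x^2 + y^2),
    Cm = 2x / (x^2 + y^2).
    """
    if y <= 0.0:
        raise ParameterError("junction radius y must be positive")
    vm, am, cm = _core.cap_metrics_kernel(x, y)
    return float(vm), float(am), float(cm)


def solve_cap_height(Vm: float, y: float) -> float:
    """Invert the cap-volume cubic: the unique real x with Vm(x, y) = Vm.

    The cubic is strictly increasing in x, so the root always exists and
    is unique; the closed-form (Cardano) root is polished by Newton to a
    residual below 1e-10 * max(1, |Vm|).
    """
    if y <= 0.0:
        raise ParameterError("junction radius y must be positive")
    x = float(_core.cap_height(Vm, y))
    residual = abs((math.pi / 6.0) * x * (x * x + 3.0 * y * y) - Vm)
    if residual > 1e-10 * max(1.0, abs(Vm)):  # pragma: no cover - defensive
        raise GeometryError(f"cap-height inversion residual {residual:g}")
    return x


def fiber_strain(Am: float, Am_ref: float) -> float:
    """Natural fiber strain from midwall area: 0.5 * ln(Am / Am_ref)."""
    if Am <= 0.0 or Am_ref <= 0.0:
        raise ParameterError("areas must be positive")
    return 0.5 * math.log(Am / Am_ref)


def wall_tension_components(sigma_f: float, Vw: float, x: float,
                            y: float) -> tuple[float, float, float]:
    """Midwall tension and its axial/radial components at the junction.

    Tm = sigma_f * Vw / (2 Am); the cap meets the ring at angle alpha
    with sin(alpha) = 2xy/(x^2+y^2) and cos(alpha) = (y^2-x^2)/(x^2+y^2).
    """
    r2 = x * x + y * y
    if r2 <= 0.0:
        raise ParameterError("cap dimensions must not both be zero")
    am = math.pi * r2
    tm = sigma_f * Vw / (2.0 * am)
    sin_a = 2.0 * x * y / r2
    cos_a = (y * y - x * x) / r2
    return tm, tm * sin_a, tm * cos_a


def _pack_walls(walls: tuple[WallSegment, WallSegment, WallSegment],
                base: np.ndarray | None = None) -> np.ndarray:
    """Pack three walls into a kernel parameter vector (walls only)."""
    pp = np.zeros(_core.NP) if base is None else base
    for w, wall in enumerate(walls):
        pp[w * _core.NSP:(w + 1) * _core.NSP] = wall.sarcomere.pack()
        pp[_core.P_VW + w] = wall.Vw
        pp[_core.P_AMREF + w] = wall.Am_ref
    if base is None:
        pp[_core.P_ACT_SCALE] = 1.0
        pp[_core.P_HR] = 420.0
    return pp


def solve_heart(V_LV: float, V_RV: float,
                walls: tuple[WallSegment, WallSegment, WallSegment],
                warm_start: HeartGeometry | np.ndarray | None = None,
                ) -> HeartGeometry:
    """Solve the junction force balance for given cavity volumes.

    Returns the full geometry, tensions, fiber strains and the two
    cavity pressures.  ``warm_start`` (a previous :class:`HeartGeometry`
    or a 2-vector ``[Vm_S, y]``) accelerates the damped Newton solve;
    without it a cold start from a total-volume sphere is used.
    """
    if V_LV <= 0.0 or V_RV <= 0.0:
        raise ParameterError("cavity volumes must be positive")
    if len(walls) != 3:
        raise ParameterError("exactly three wall segments are required")
    for wall in walls:
        wall.state.validate()

    pp = _pack_walls(tuple(walls))
    sarc = np.empty(9)
    for w, wall in enumerate(walls):
        sarc[3 * w] = wall.state.Ls
        sarc[3 * w + 1] = wall.state.A
        sarc[3 * w + 2] = wall.state.xbar

    if warm_start is None:
        warm = np.array([0.0, -1.0])
    elif isinstance(warm_start, HeartGeometry):
        warm = warm_start.warm_array()
    else:
        warm = np.asarray(warm_start, dtype=float).copy()

    out = np.empty(27)
    ok = _core.triseg_solve(V_LV, V_RV, sarc, pp, warm, out)
    if not ok:
        raise GeometryError(
            f"junction balance failed for V_LV={V_LV:.3f} ul, "
            f"V_RV={V_RV:.3f} ul")
    per = out[6:27].reshape(3, 7)
    return HeartGeometry(
        x_L=float(per[0, 0]), x_S=float(per[1, 0]), x_R=float(per[2, 0]),
        y=float(out[1]), Vm_S=float(out[0]),
        Am=tuple(float(v) for v in per[:, 1]),
        Cm=tuple(float(v) for v in per[:, 2]),
        Tm=tuple(float(v) for v in per[:, 4]),
        epsilon_f=tuple(float(v) for v in per[:, 3]),
        sigma_f=tuple(float(v) for v in per[:, 5]),
        dLs_dt=tuple(float(v) for v in per[:, 6]),
        P_LV=float(out[2]), P_RV=float(out[3]),
        residual=float(out[4]), iterations=int(out[5]),
    )
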