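"""Myofilament mechanics.

A reduced cross-bridge distortion model drives active force: a
calcium-permissive attachment/detachment cycle sets the attached
cross-bridge fraction ``A``, a mean elastic distortion ``xbar`` carries
the power-stroke strain, and active fiber stress is

    sigma_act = k_stiff2 * overlap(Ls) * A * xbar .

``k_stiff2`` is the model's handle on maximum calcium-activated force
(Fmax): at saturating calcium and the reference length the isometric
stress has the closed form ``k_stiff2 * x0 * f / (f + g)``, so Fmax is
exactly linear in ``k_stiff2``.

Passive stress is a two-component exponential: intracellular titin
engaging at the slack length and extracellular collagen engaging later
and more steeply.  Scaling the collagen component (``con_collagen_mult``)
models interstitial fibrosis.  A linear viscous stress and a series
element complete the force balance; the series element lets the
sarcomere length relax toward the wall fiber strain with rate constant
``v_max / L_SE_iso``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _core
from .errors import CalibrationError, ConvergenceError, ParameterError

__all__ = [
    "SarcomereParams",
    "SarcomereState",
    "PassiveStress",
    "calcium_transient",
    "crossbridge_derivatives",
    "active_stress",
    "passive_stress",
    "fiber_stress_and_rate",
    "isometric_fmax",
    "calibrate_contractility",
    "calibrate_fibrosis",
]


@dataclass(frozen=True)
class SarcomereParams:
    """Myofilament constants for one wall.

    Lengths in micrometres, stresses in kPa, rates in 1/s, calcium in uM.
    Defaults are package calibration choices for a healthy adult mouse
    myocardium beating at 420 bpm; they are configuration, and every
    disease scenario perturbs them only through the documented handles
    (``k_stiff2`` for Fmax, ``con_collagen_mult`` for fibrosis).
    """

    Ls_ref: float = 2.2          # reference length, peak of the overlap tent
    Ls_slack: float = 1.8        # titin slack length
    k_stiff2: float = 26000.0    # active stiffness scale (kPa/um) = 26 MPa/um
    x0: float = 0.013            # effective power-stroke distortion (um)
    f_attach: float = 600.0      # attachment rate (1/s)
    g_detach: float = 300.0      # detachment rate (1/s)
    Ca_dia: float = 0.05         # diastolic calcium (uM)
    Ca_amp: float = 1.2          # peak calcium increment (uM)
    tau_Ca: float = 0.018        # transient time constant (s)
    Ca50: float = 0.95           # half-activation calcium (uM)
    hill_n: float = 6.0          # activation steepness
    k_titin: float = 0.0016      # titin exponential scale (kPa)
    alpha_titin: float = 13.0    # titin exponential rate (1/um)
    k_collagen: float = 0.1      # collagen exponential scale (kPa)
    alpha_collagen: float = 1.5  # collagen exponential rate (1/um)
    Ls_collagen: float = 2.0     # collagen engagement length (um)
    con_collagen_mult: float = 1.0  # fibrosis multiplier (1 = control)
    mu_visc: float = 0.3         # viscosity (kPa s/um)
    L_SE_iso: float = 0.04       # isometric series-element stretch (um)
    v_max: float = 7.0           # series-element rate scale (um/s)
    overlap_width: float = 0.5   # overlap tent half-width (um)

    def __post_init__(self) -> None:
        positive = (
            "Ls_ref", "Ls_slack", "k_stiff2", "x0", "f_attach", "g_detach",
            "tau_Ca", "Ca50", "k_titin", "alpha_titin", "k_collagen",
            "alpha_collagen", "Ls_collagen", "mu_visc", "L_SE_iso",
            "v_max", "overlap_width",
        )
        for name in positive:
            if not getattr(self, name) > 0.0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.Ca_dia < 0.0 or self.Ca_amp < 0.0:
            raise ParameterError("calcium levels must be non-negative")
        if self.hill_n < 1.0:
            raise ParameterError("hill_n must be >= 1")
        if not self.Ls_slack < self.Ls_ref:
            raise ParameterError("Ls_slack must be below Ls_ref")
        if self.con_collagen_mult < 0.0:
            raise ParameterError("con_collagen_mult must be >= 0")

    def pack(self) -> np.ndarray:
        """Flatten into the kernel parameter block (length _core.NSP)."""
        sp = np.zeros(_core.NSP)
        sp[_core.SP_LS_REF] = self.Ls_ref
        sp[_core.SP_LS_SLACK] = self.Ls_slack
        sp[_core.SP_K2] = self.k_stiff2
        sp[_core.SP_X0] = self.x0
        sp[_core.SP_F] = self.f_attach
        sp[_core.SP_G] = self.g_detach
        sp[_core.SP_CA_DIA] = self.Ca_dia
        sp[_core.SP_CA_AMP] = self.Ca_amp
        sp[_core.SP_TAU] = self.tau_Ca
        sp[_core.SP_CA50] = self.Ca50
        sp[_core.SP_HILL] = self.hill_n
        sp[_core.SP_KT] = self.k_titin
        sp[_core.SP_AT] = self.alpha_titin
        sp[_core.SP_KC] = self.k_collagen
        sp[_core.SP_AC] = self.alpha_collagen
        sp[_core.SP_LSC] = self.Ls_collagen
        sp[_core.SP_CMULT] = self.con_collagen_mult
        sp[_core.SP_MU] = self.mu_visc
        sp[_core.SP_LSE] = self.L_SE_iso
        sp[_core.SP_VMAX] = self.v_max
        sp[_core.SP_WIDTH] = self.overlap_width
        return sp


@dataclass
class SarcomereState:
    """Dynamic state of one wall's half-sarcomere."""

    Ls: float = 2.0     # sarcomere length (um)
    A: float = 0.0      # attached cross-bridge fraction
    xbar: float = 0.007  # mean cross-bridge distortion (um)

    def validate(self) -> None:
        if not self.Ls > 0.0:
            raise ParameterError("Ls must be positive")
        if not -1e-9 <= self.A <= 1.0 + 1e-9:
            raise ParameterError("attached fraction must lie in [0, 1]")


class PassiveStress(NamedTuple):
    titin: float
    collagen: float

    @property
    def total(self) -> float:
        return self.titin + self.collagen


def calcium_transient(t_in_beat: float, p: SarcomereParams,
                      period: float) -> float:
    """Intracellular calcium (uM) at time ``t_in_beat`` of the cycle.

    The transient is the two-parameter pulse
    ``Ca_dia + Ca_amp * (t/tau) * exp(1 - t/tau)``: it starts at the
    diastolic level, peaks at ``Ca_dia + Ca_amp`` at ``t = tau_Ca`` and
    relaxes back.  The drive is periodic with the beat.
    """
    if period <= 0.0:
        raise ParameterError("period must be positive")
    if p.tau_Ca <= 0.0:
        raise ParameterError("tau_Ca must be positive")
    tb = math.fmod(t_in_beat, period)
    if tb < 0.0:
        tb += period
    return float(_core.calcium_transient(tb, p.Ca_dia, p.Ca_amp, p.tau_Ca))


def crossbridge_derivatives(s: SarcomereState, Ca: float, dLs_dt: float,
                            p: SarcomereParams) -> tuple[float, float]:
    """Time derivatives (dA/dt, dxbar/dt) of the cross-bridge state."""
    s.validate()
    if Ca < 0.0:
        raise ParameterError("calcium must be non-negative")
    da, dxb = _core.crossbridge_rates(s.A, s.xbar, Ca, dLs_dt, p.pack())
    return float(da), float(dxb)


def active_stress(s: SarcomereState, p: SarcomereParams) -> float:
    """Active fiber stress (kPa): k_stiff2 * overlap(Ls) * A * xbar."""
    s.validate()
    return float(_core.active_stress_kernel(s.Ls, s.A, s.xbar, p.k_stiff2,
                                            p.Ls_ref, p.overlap_width))


def passive_stress(Ls: float, p: SarcomereParams) -> PassiveStress:
    """Titin and collagen passive stress components (kPa) at length Ls."""
    if Ls <= 0.0:
        raise ParameterError("Ls must be positive")
    tit, col = _core.passive_stress_kernel(
        Ls, p.k_titin, p.alpha_titin, p.Ls_slack, p.k_collagen,
        p.alpha_collagen, p.Ls_collagen, p.con_collagen_mult)
    return PassiveStress(float(tit), float(col))


def fiber_stress_and_rate(s: SarcomereState, epsilon_f: float,
                          p: SarcomereParams) -> tuple[float, float]:
    """Total fiber stress (kPa) and sarcomere shortening rate (um/s).

    The series element compares the total contractile path length
    ``Ls_ref * exp(epsilon_f)`` with the current sarcomere length; its
    stretch relative to the isometric value sets dLs/dt, and the viscous
    stress ``mu_visc * dLs/dt`` adds to the active and passive parts.
    """
    s.validate()
    sig, dls = _core.wall_fiber_stress(s.Ls, s.A, s.xbar, epsilon_f,
                                       p.pack(), 1.0)
    return float(sig), float(dls)


def isometric_fmax(p: SarcomereParams, max_time: float = 5.0) -> float:
    """Maximal calcium-activated isometric stress (kPa).

    Clamps the sarcomere at ``Ls_ref`` under saturating calcium
    (100 x Ca50), integrates the cross-bridge states to steady state
    (relative change < 1e-9 per ms) and returns the active stress.  In
    this reduced model the result equals
    ``k_stiff2 * overlap(Ls_ref) * x0 * f_attach/(f_attach + g_detach)``
    up to the residual non-saturation of the Hill curve.
    """
    sp = p.pack()
    ca = 100.0 * p.Ca50

    def rates(t: float, z: np.ndarray) -> list[float]:
        da, dxb = _core.crossbridge_rates(z[0], z[1], ca, 0.0, sp)
        return [da, dxb]

    z = np.array([0.0, p.x0])
    t_done = 0.0
    chunk = 0.05
    while t_done < max_time:
        sol = solve_ivp(rates, (0.0, chunk), z, rtol=1e-10, atol=1e-12)
        znew = sol.y[:, -1]
        # relative state change per millisecond
        dz = np.max(np.abs(znew - z) / np.maximum(np.abs(znew), 1e-12))
        z = znew
        t_done += chunk
        if dz / (chunk * 1e3) < 1e-9:
            state = SarcomereState(Ls=p.Ls_ref, A=float(z[0]), xbar=float(z[1]))
            return active_stress(state, p)
    raise ConvergenceError(
        f"isometric clamp did not reach steady state within {max_time} s")


def calibrate_contractility(p: SarcomereParams,
                            target_ratio: float,
                            tol: float = 1e-6) -> SarcomereParams:
    """Scale ``k_stiff2`` so Fmax falls to ``target_ratio`` of control.

    The reduced model is exactly linear in ``k_stiff2`` but the
    calibration is performed by root finding on the simulated force
    ratio, so it remains correct for any overlap/kinetics settings.
    """
    if not 0.0 < target_ratio <= 1.0:
        raise CalibrationError("target_ratio must lie in (0, 1]")
    if target_ratio == 1.0:
        return p
    f0 = isometric_fmax(p)
    if f0 <= 0.0:
        raise CalibrationError("control Fmax is not positive")

    def gap(scale: float) -> float:
        return isometric_fmax(replace(p, k_stiff2=scale * p.k_stiff2)) / f0 \
            - target_ratio

    try:
        scale = brentq(gap, 1e-4, 1.0, xtol=tol)
    except ValueError as exc:  # pragma: no cover - defensive
        raise CalibrationError(f"Fmax target {target_ratio} unattainable") from exc
    return replace(p, k_stiff2=float(scale) * p.k_stiff2)


def calibrate_fibrosis(p: SarcomereParams, target_ratio: float,
                       Ls_operating: float = 2.2) -> SarcomereParams:
    """Scale the collagen multiplier so total passive stress at the
    operating sarcomere length reaches ``target_ratio`` of control.

    The collagen component is linear in the multiplier, so the required
    multiplier has a closed form; a guard rejects targets below the
    titin-only floor (which no collagen scaling can reach).
    """
    if target_ratio <= 0.0:
        raise CalibrationError("target_ratio must be positive")
    base = passive_stress(Ls_operating, p)
    if base.collagen <= 0.0:
        if target_ratio == 1.0:
            return p
        raise CalibrationError(
            "collagen carries no load at the operating length; "
            "passive-stress ratio cannot be calibrated")
    target_total = target_ratio * base.total
    if target_total < base.titin:
        raise CalibrationError(
            f"target ratio {target_ratio} lies below the titin-only floor")
    mult = p.con_collagen_mult * (target_total - base.titin) / base.collagen
    return replace(p, con_collagen_mult=float(mult))
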