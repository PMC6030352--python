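"""Compiled numerical kernels for the heart-circulation model.

Everything that runs inside the beat loop lives here as numba-jitted
scalar kernels operating on a packed float64 parameter vector: the
sarcomere force laws, the three-wall spherical-cap geometry solver, the
closed-loop circulation right-hand side, and an adaptive Cash-Karp
Runge-Kutta driver.  The public modules (:mod:`rvsim.sarcomere`,
:mod:`rvsim.triseg`, :mod:`rvsim.circulation`, :mod:`rvsim.simulator`)
wrap these kernels with typed dataclasses and validation; both layers
share the same formulas, so there is a single source of truth for the
model equations.

Unit system: volumes in microlitres (= mm^3), pressures in mmHg at the
circulation level, stresses in kPa inside the walls, lengths in mm
(geometry) and micrometres (sarcomere), time in seconds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KPA_TO_MMHG = 7.50062

# ---------------------------------------------------------------------------
# packed-parameter layout
#
# Per-wall sarcomere block (3 walls: 0 = LV free wall, 1 = septum,
# 2 = RV free wall), NSP slots each:
SP_LS_REF = 0      # reference sarcomere length (um), peak of overlap tent
SP_LS_SLACK = 1    # titin slack length (um)
SP_K2 = 2          # active stiffness scale k_stiff,2 (kPa/um)
SP_X0 = 3          # power-stroke distortion (um)
SP_F = 4           # crossbridge attachment rate (1/s)
SP_G = 5           # crossbridge detachment rate (1/s)
SP_CA_DIA = 6      # diastolic calcium (uM)
SP_CA_AMP = 7      # peak calcium increment (uM)
SP_TAU = 8         # calcium transient time constant (s)
SP_CA50 = 9        # half-activation calcium (uM)
SP_HILL = 10       # Hill steepness (-)
SP_KT = 11         # titin exponential scale (kPa)
SP_AT = 12         # titin exponential rate (1/um)
SP_KC = 13         # collagen exponential scale (kPa)
SP_AC = 14         # collagen exponential rate (1/um)
SP_LSC = 15        # collagen engagement length (um)
SP_CMULT = 16      # collagen multiplier (-, 1 = control)
SP_MU = 17         # viscosity (kPa s/um)
SP_LSE = 18        # isometric series-element stretch (um)
SP_VMAX = 19       # series-element rate scale (um/s)
SP_WIDTH = 20      # overlap tent half-width (um)
NSP = 22

# Wall structure
P_VW = 66          # +0,1,2 wall volumes (ul)
P_AMREF = 69       # +0,1,2 reference midwall areas (mm^2)
# Circulation
P_C_AO = 72
P_C_SV = 73
P_C_PA = 74
P_C_PV = 75
P_PVR = 76
P_SVR = 77
P_R_AV = 78
P_R_PVAL = 79
P_R_MV = 80
P_R_TV = 81
P_R_VEN_S = 82
P_R_VEN_P = 83
P_V0_AO = 84
P_V0_SV = 85
P_V0_PA = 86
P_V0_PV = 87
P_V_TOTAL = 88
P_HR = 89
# Atria: LA then RA, 4 slots each (C_max, C_min, t_onset, d_a)
P_LA = 90
P_RA = 94
P_ACT_SCALE = 98   # global active-stress scale (1 = normal, 0 = passive mode)
NP = 100

# state layout: 8 compartment volumes, 3 x (Ls, A, xbar), then two
# cumulative ejected-volume integrals (aortic and pulmonary valve flow)
# used for the per-beat stroke-volume bookkeeping
IV_AO, IV_SV, IV_PA, IV_PV, IV_LA, IV_RA, IV_LV, IV_RV = range(8)
NY_PHYS = 17
NY = 19
I_SV_LV = 17
I_SV_RV = 18

# Guard on the attached fraction in the mean-distortion equation.  The
# distortion relaxation rate f*perm*(1-A)/max(A, eps) is physical for
# appreciable attachment but diverges as A -> 0; below the guard the
# active stress k2*A*xbar is negligible, so capping the rate changes no
# observable force while keeping the ODE non-stiff at activation onset.
XB_EPS = 0.05

# Residual acceptance (relative to the summed tension scale) for the
# junction solve inside the ODE right-hand side.  At regular states the
# LM iteration reaches ~1e-12; during violent transients the junction
# system can pass through folds where only a least-squares minimum
# exists, and the cavity pressures are insensitive (<0.1%) to residual
# slack at this level; the folds are confined to strong start-up
# transients, and converged orbits solve to ~1e-12.  The public
# solve_heart API stays strict (1e-8).
RHS_GEOM_TOL = 3e-3

# Branch discriminator: free-wall caps with |x| exceeding this multiple
# of the junction radius are "finger" geometries -- valid roots of the
# tension balance with absurd strains -- and are never accepted.
FINGER_RATIO = 2.5


# ---------------------------------------------------------------------------
# sarcomere kernels

@njit(cache=True)
def calcium_transient(tb, ca_dia, ca_amp, tau):
    """Ca(t) = Ca_dia + Ca_amp * (t/tau) * exp(1 - t/tau), peak at t = tau."""
    r = tb / tau
    return ca_dia + ca_amp * r * math.exp(1.0 - r)


@njit(cache=True)
def permissiveness(ca, ca50, hill):
    c = ca ** hill
    return c / (c + ca50 ** hill)


@njit(cache=True)
def overlap_fraction(ls, ls_ref, width):
    ov = 1.0 - abs(ls - ls_ref) / width
    return ov if ov > 0.0 else 0.0


@njit(cache=True)
def active_stress_kernel(ls, a, xbar, k2, ls_ref, width):
    return k2 * overlap_fraction(ls, ls_ref, width) * a * xbar


@njit(cache=True)
def passive_stress_kernel(ls, kt, at, ls_slack, kc, ac, ls_col, cmult):
    tit = kt * (math.exp(at * (ls - ls_slack)) - 1.0) if ls > ls_slack else 0.0
    col = cmult * kc * (math.exp(ac * (ls - ls_col)) - 1.0) if ls > ls_col else 0.0
    return tit, col


@njit(cache=True)
def series_rate(ls, eps_f, ls_ref, lse_iso, vmax):
    """Sarcomere-length rate from the series element.

    The total contractile-path length follows the wall fiber strain,
    L_tot = Ls_ref * exp(eps_f); the series stretch e_SE = L_tot - Ls
    drives Ls toward its isometric value at rate v_max * (e_SE/L_SE_iso - 1).
    """
    e_se = ls_ref * math.exp(eps_f) - ls
    return vmax * (e_se / lse_iso - 1.0)


@njit(cache=True)
def wall_fiber_stress(ls, a, xbar, eps_f, sp, act_scale):
    """Total fiber stress (kPa) and dLs/dt (um/s) for one wall."""
    dls = series_rate(ls, eps_f, sp[SP_LS_REF], sp[SP_LSE], sp[SP_VMAX])
    act = act_scale * active_stress_kernel(ls, a, xbar, sp[SP_K2],
                                           sp[SP_LS_REF], sp[SP_WIDTH])
    tit, col = passive_stress_kernel(ls, sp[SP_KT], sp[SP_AT], sp[SP_LS_SLACK],
                                     sp[SP_KC], sp[SP_AC], sp[SP_LSC],
                                     sp[SP_CMULT])
    return act + tit + col + sp[SP_MU] * dls, dls


@njit(cache=True)
def crossbridge_rates(a, xbar, ca, dls, sp):
    perm = permissiveness(ca, sp[SP_CA50], sp[SP_HILL])
    fp = sp[SP_F] * perm
    da = fp * (1.0 - a) - sp[SP_G] * a
    denom = a if a > XB_EPS else XB_EPS
    dxb = 0.5 * dls + (fp * (1.0 - a) / denom) * (sp[SP_X0] - xbar)
    # empty-population reset: when almost no bridges are attached the
    # mean distortion is ill-defined and would otherwise integrate the
    # filling stretch unboundedly; new bridges attach at x0, so the
    # population mean relaxes there.  The gate makes this term vanish
    # once attachment is appreciable (systole), leaving the
    # force-velocity behaviour untouched.
    dxb += sp[SP_G] * (XB_EPS / (a + XB_EPS)) * (sp[SP_X0] - xbar)
    return da, dxb


# ---------------------------------------------------------------------------
# spherical-cap geometry

@njit(cache=True)
def cap_height(vm, y):
    """Unique real root x of (pi/6) x (x^2 + 3 y^2) = Vm (Cardano + polish)."""
    q = 6.0 * vm / math.pi
    half = 0.5 * q
    disc = math.sqrt(half * half + y ** 6)
    u = half + disc
    v = half - disc
    x = (math.copysign(abs(u) ** (1.0 / 3.0), u)
         + math.copysign(abs(v) ** (1.0 / 3.0), v))
    # Newton polish to ~1e-15 relative residual
    for _ in range(3):
        f = x * (x * x + 3.0 * y * y) - q
        df = 3.0 * (x * x + y * y)
        x -= f / df
    return x


@njit(cache=True)
def cap_metrics_kernel(x, y):
    vm = (math.pi / 6.0) * x * (x * x + 3.0 * y * y)
    r2 = x * x + y * y
    am = math.pi * r2
    cm = 2.0 * x / r2
    return vm, am, cm


# ---------------------------------------------------------------------------
# three-wall junction balance
#
# Unknowns: Vm_S (septal midwall cap volume, ul) and y (junction radius, mm).
# Residuals: sum of axial (Tx) and radial (Ty) tension components over the
# three walls at the junction ring.

@njit(cache=True)
def _triseg_residual(vms, y, vlv, vrv, sarc, pp):
    """Residuals (Tx, Ty) plus per-wall geometry/stress outputs.

    sarc is the 9-vector (Ls, A, xbar) x 3 walls.  Returns a flat tuple:
    tx, ty, then per wall x, am, cm, eps, tm, sig, dls (walls L, S, R).
    """
    vw0 = pp[P_VW]
    vw1 = pp[P_VW + 1]
    vw2 = pp[P_VW + 2]
    vm0 = -vlv - 0.5 * vw0 - 0.5 * vw1 + vms
    vm1 = vms
    vm2 = vrv + 0.5 * vw2 + 0.5 * vw1 + vms

    tx = 0.0
    ty = 0.0
    out = np.empty(21)
    for w in range(3):
        if w == 0:
            vm = vm0
            vw = vw0
        elif w == 1:
            vm = vm1
            vw = vw1
        else:
            vm = vm2
            vw = vw2
        x = cap_height(vm, y)
        r2 = x * x + y * y
        am = math.pi * r2
        cm = 2.0 * x / r2
        eps = 0.5 * math.log(am / pp[P_AMREF + w])
        sp = pp[w * NSP:(w + 1) * NSP]
        sig, dls = wall_fiber_stress(sarc[3 * w], sarc[3 * w + 1],
                                     sarc[3 * w + 2], eps, sp,
                                     pp[P_ACT_SCALE])
        tm = sig * vw / (2.0 * am)
        sin_a = 2.0 * x * y / r2
        cos_a = (y * y - x * x) / r2
        tx += tm * sin_a
        ty += tm * cos_a
        out[7 * w] = x
        out[7 * w + 1] = am
        out[7 * w + 2] = cm
        out[7 * w + 3] = eps
        out[7 * w + 4] = tm
        out[7 * w + 5] = sig
        out[7 * w + 6] = dls
    return tx, ty, out


@njit(cache=True)
def triseg_solve(vlv, vrv, sarc, pp, warm, out, tol_accept=1e-8):
    """Levenberg-Marquardt solve of the 2x2 junction balance.

    warm[0] = Vm_S, warm[1] = y from the previous accepted solution
    (warm[1] <= 0 requests a cold start).  With a small damping factor
    the step reduces to Newton near a regular root (quadratic
    convergence to ~1e-12); at geometric folds, where the two residual
    curves become tangent and an exact root may not exist, the iteration
    converges to the unique least-squares minimum instead.  The solve is
    accepted when the residual norm falls below ``tol_accept`` times the
    tension scale; cavity pressures are insensitive (<0.1%) to the
    remaining slack at that level.

    On success fills ``out`` (length 27) and returns True:
    out[0] = Vm_S, out[1] = y, out[2] = P_LV, out[3] = P_RV,
    out[4] = |Tx| + |Ty| residual, out[5] = iterations,
    out[6:27] = per-wall (x, Am, Cm, eps_f, Tm, sigma_f, dLs) for L, S, R.
    """
    vms = warm[0]
    y = warm[1]
    if y <= 0.0:
        # cold start: a sphere of the total heart volume sets the scale
        vtot = vlv + vrv + pp[P_VW] + pp[P_VW + 1] + pp[P_VW + 2]
        r = (3.0 * vtot / (4.0 * math.pi)) ** (1.0 / 3.0)
        y = 0.9 * r
        vms = 0.4 * vlv

    tx, ty, aux = _triseg_residual(vms, y, vlv, vrv, sarc, pp)
    res = abs(tx) + abs(ty)
    lam = 1e-4
    it = 0
    for it in range(120):
        tscale = abs(aux[4]) + abs(aux[11]) + abs(aux[18])
        tol = 1e-9 * max(1.0, tscale)
        if res < tol:
            break
        h1 = 1e-7 * (1.0 + abs(vms))
        h2 = 1e-7 * (1.0 + y)
        tx1, ty1, _ = _triseg_residual(vms + h1, y, vlv, vrv, sarc, pp)
        tx2, ty2, _ = _triseg_residual(vms, y + h2, vlv, vrv, sarc, pp)
        j11 = (tx1 - tx) / h1
        j12 = (tx2 - tx) / h2
        j21 = (ty1 - ty) / h1
        j22 = (ty2 - ty) / h2
        # normal equations with Levenberg damping
        a11 = j11 * j11 + j21 * j21
        a12 = j11 * j12 + j21 * j22
        a22 = j12 * j12 + j22 * j22
        g1 = j11 * tx + j21 * ty
        g2 = j12 * tx + j22 * ty
        if not (math.isfinite(a11) and math.isfinite(a22)):
            return False
        improved = False
        for _ in range(12):
            d11 = a11 * (1.0 + lam)
            d22 = a22 * (1.0 + lam)
            det = d11 * d22 - a12 * a12
            if det <= 0.0 or not math.isfinite(det):
                lam = max(lam * 10.0, 1e-12)
                continue
            dvms = -(d22 * g1 - a12 * g2) / det
            dy = -(-a12 * g1 + d11 * g2) / det
            y_try = y + dy
            if y_try <= 1e-6:
                lam = max(lam * 10.0, 1e-12)
                continue
            txn, tyn, auxn = _triseg_residual(vms + dvms, y_try,
                                              vlv, vrv, sarc, pp)
            resn = abs(txn) + abs(tyn)
            if math.isfinite(resn) and resn < res:
                vms += dvms
                y = y_try
                tx, ty, aux = txn, tyn, auxn
                res = resn
                lam = max(lam * 0.3, 1e-12)
                improved = True
                break
            lam *= 10.0
        if not improved:
            # stationary point of the squared residual reached
            break

    # out is always filled with the best point found, even when the
    # solve is not accepted, so callers can fall back on the
    # least-squares minimum during transient folds
    tscale = abs(aux[4]) + abs(aux[11]) + abs(aux[18])
    # signed transmural pressures: the LV cap bulges leftward (Cm < 0),
    # the RV cap rightward (Cm > 0); compressive fiber stress then gives
    # negative cavity pressure (diastolic suction) instead of a spurious
    # positive one
    p_lv = -2.0 * aux[4] * aux[2] * KPA_TO_MMHG
    p_rv = 2.0 * aux[18] * aux[16] * KPA_TO_MMHG
    out[0] = vms
    out[1] = y
    out[2] = p_lv
    out[3] = p_rv
    out[4] = res
    out[5] = float(it)
    out[6:27] = aux
    if res >= tol_accept * max(1.0, tscale) or not math.isfinite(res):
        return False
    # reject the non-physical deep-cap branch: free-wall caps with
    # |x| >> y ("finger" geometries) solve the force balance but carry
    # absurd strains; the physical branch keeps |x|/y moderate
    if abs(aux[0]) > FINGER_RATIO * y or abs(aux[14]) > FINGER_RATIO * y:
        return False
    # reject far-field roots with farcical fiber strains (|eps| ~ O(1)
    # means the wall area is off by a factor e^2 or more)
    if abs(aux[3]) > 1.0 or abs(aux[10]) > 1.0 or abs(aux[17]) > 1.0:
        return False
    warm[0] = vms
    warm[1] = y
    return True


@njit(cache=True)
def _is_finger(out):
    return (abs(out[6]) > FINGER_RATIO * out[1]
            or abs(out[20]) > FINGER_RATIO * out[1])


# ---------------------------------------------------------------------------
# circulation

@njit(cache=True)
def atrial_compliance_kernel(tb, c_max, c_min, t_onset, d_a, period):
    """Half-cosine compliance dip from C_max to C_min and back."""
    t0 = t_onset * period
    t1 = (t_onset + d_a) * period
    if tb < t0 or tb > t1:
        return c_max
    phase = (tb - t0) / (d_a * period)
    return c_max - (c_max - c_min) * 0.5 * (1.0 - math.cos(2.0 * math.pi * phase))


@njit(cache=True)
def _solve_geometry(yv, pp, warm, scratch):
    """Junction solve with graceful fold handling for the hot loop.

    Tries the warm start, then a cold start; if neither meets the
    acceptance tolerance (a transient fold), the better non-finger
    least-squares minimum is used anyway -- cavity pressures are
    insensitive to the remaining imbalance, and the sampled output
    carries the residual so callers can verify converged beats.
    Returns False only when every candidate sits on the non-physical
    finger branch or is non-finite.
    """
    ok = triseg_solve(yv[IV_LV], yv[IV_RV], yv[8:17], pp, warm, scratch,
                      RHS_GEOM_TOL)
    if ok:
        return True
    first = scratch.copy()
    warm2 = np.empty(2)
    warm2[0] = 0.0
    warm2[1] = -1.0
    ok = triseg_solve(yv[IV_LV], yv[IV_RV], yv[8:17], pp, warm2, scratch,
                      RHS_GEOM_TOL)
    if ok:
        warm[0] = warm2[0]
        warm[1] = warm2[1]
        return True
    # both attempts above tolerance: fall back on the better
    # least-squares point that is not a finger geometry
    f1 = _is_finger(first) or not math.isfinite(first[4])
    f2 = _is_finger(scratch) or not math.isfinite(scratch[4])
    if f2 and not f1:
        scratch[:] = first
    elif (not f1) and (not f2) and first[4] < scratch[4]:
        scratch[:] = first
    elif f1 and f2:
        return False
    warm[0] = scratch[0]
    warm[1] = scratch[1]
    return True


@njit(cache=True)
def rhs(t, yv, pp, warm, scratch):
    """Full system right-hand side; returns (ok, dy).

    scratch is a length-27 work array for the geometry solve output so the
    kernel is allocation free in the hot loop.
    """
    period = 60.0 / pp[P_HR]
    tb = t % period
    dy = np.zeros(NY)

    ok = _solve_geometry(yv, pp, warm, scratch)
    if not ok:
        return False, dy
    p_lv = scratch[2]
    p_rv = scratch[3]

    # sarcomere state derivatives (eps and dLs from the accepted geometry)
    for w in range(3):
        sp = pp[w * NSP:(w + 1) * NSP]
        ca = calcium_transient(tb, sp[SP_CA_DIA], sp[SP_CA_AMP], sp[SP_TAU])
        dls = scratch[6 + 7 * w + 6]
        a = yv[9 + 3 * w]
        xb = yv[10 + 3 * w]
        da, dxb = crossbridge_rates(a, xb, ca, dls, sp)
        dy[8 + 3 * w] = dls
        dy[9 + 3 * w] = da
        dy[10 + 3 * w] = dxb

    p_ao = (yv[IV_AO] - pp[P_V0_AO]) / pp[P_C_AO]
    p_sv = (yv[IV_SV] - pp[P_V0_SV]) / pp[P_C_SV]
    p_pa = (yv[IV_PA] - pp[P_V0_PA]) / pp[P_C_PA]
    p_pv = (yv[IV_PV] - pp[P_V0_PV]) / pp[P_C_PV]
    c_la = atrial_compliance_kernel(tb, pp[P_LA], pp[P_LA + 1], pp[P_LA + 2],
                                    pp[P_LA + 3], period)
    c_ra = atrial_compliance_kernel(tb, pp[P_RA], pp[P_RA + 1], pp[P_RA + 2],
                                    pp[P_RA + 3], period)
    p_la = yv[IV_LA] / c_la
    p_ra = yv[IV_RA] / c_ra

    q_mv = max(p_la - p_lv, 0.0) / pp[P_R_MV]
    q_av = max(p_lv - p_ao, 0.0) / pp[P_R_AV]
    q_tv = max(p_ra - p_rv, 0.0) / pp[P_R_TV]
    q_pval = max(p_rv - p_pa, 0.0) / pp[P_R_PVAL]
    q_sys = (p_ao - p_sv) / pp[P_SVR]
    q_pul = (p_pa - p_pv) / pp[P_PVR]
    q_ven_s = (p_sv - p_ra) / pp[P_R_VEN_S]
    q_ven_p = (p_pv - p_la) / pp[P_R_VEN_P]

    dy[IV_AO] = q_av - q_sys
    dy[IV_SV] = q_sys - q_ven_s
    dy[IV_PA] = q_pval - q_pul
    dy[IV_PV] = q_pul - q_ven_p
    dy[IV_LA] = q_ven_p - q_mv
    dy[IV_RA] = q_ven_s - q_tv
    dy[IV_LV] = q_mv - q_av
    dy[IV_RV] = q_tv - q_pval
    dy[I_SV_LV] = q_av
    dy[I_SV_RV] = q_pval
    return True, dy


NAUX = 21


@njit(cache=True)
def aux_outputs(t, yv, pp, warm, scratch):
    """Pressures, flows and the geometry unknowns at one state sample.

    Layout: P_LV, P_RV, P_Ao, P_PA, P_PV, P_SV, P_LA, P_RA,
    q_mv, q_av, q_tv, q_pv, q_sys, q_pul, q_ven_s, q_ven_p, Vm_S, y, ok,
    junction residual, junction tension scale.
    """
    period = 60.0 / pp[P_HR]
    tb = t % period
    out = np.empty(NAUX)
    ok = _solve_geometry(yv, pp, warm, scratch)
    out[18] = 1.0 if ok else 0.0
    out[19] = scratch[4]
    out[20] = (abs(scratch[10]) + abs(scratch[17]) + abs(scratch[24]))
    if not ok:
        return out
    p_lv = scratch[2]
    p_rv = scratch[3]
    p_ao = (yv[IV_AO] - pp[P_V0_AO]) / pp[P_C_AO]
    p_sv = (yv[IV_SV] - pp[P_V0_SV]) / pp[P_C_SV]
    p_pa = (yv[IV_PA] - pp[P_V0_PA]) / pp[P_C_PA]
    p_pv = (yv[IV_PV] - pp[P_V0_PV]) / pp[P_C_PV]
    c_la = atrial_compliance_kernel(tb, pp[P_LA], pp[P_LA + 1], pp[P_LA + 2],
                                    pp[P_LA + 3], period)
    c_ra = atrial_compliance_kernel(tb, pp[P_RA], pp[P_RA + 1], pp[P_RA + 2],
                                    pp[P_RA + 3], period)
    p_la = yv[IV_LA] / c_la
    p_ra = yv[IV_RA] / c_ra
    out[0] = p_lv
    out[1] = p_rv
    out[2] = p_ao
    out[3] = p_pa
    out[4] = p_pv
    out[5] = p_sv
    out[6] = p_la
    out[7] = p_ra
    out[8] = max(p_la - p_lv, 0.0) / pp[P_R_MV]
    out[9] = max(p_lv - p_ao, 0.0) / pp[P_R_AV]
    out[10] = max(p_ra - p_rv, 0.0) / pp[P_R_TV]
    out[11] = max(p_rv - p_pa, 0.0) / pp[P_R_PVAL]
    out[12] = (p_ao - p_sv) / pp[P_SVR]
    out[13] = (p_pa - p_pv) / pp[P_PVR]
    out[14] = (p_sv - p_ra) / pp[P_R_VEN_S]
    out[15] = (p_pv - p_la) / pp[P_R_VEN_P]
    out[16] = scratch[0]
    out[17] = scratch[1]
    return out


# ---------------------------------------------------------------------------
# adaptive Cash-Karp RK45 driver
#
# Explicit embedded pair; the fastest internal time constants (series
# element, valve-loaded compartments) are a few milliseconds, so accuracy
# at rtol 1e-7 controls the step well below the stability limit.

@njit(cache=True)
def _rk45_step(t, yv, h, pp, warm, scratch):
    """One Cash-Karp step; returns (ok, y5, err_vec)."""
    ok1, k1 = rhs(t, yv, pp, warm, scratch)
    if not ok1:
        return False, yv, yv
    ok2, k2 = rhs(t + 0.2 * h, yv + h * 0.2 * k1, pp, warm, scratch)
    if not ok2:
        return False, yv, yv
    ok3, k3 = rhs(t + 0.3 * h, yv + h * (0.075 * k1 + 0.225 * k2),
                  pp, warm, scratch)
    if not ok3:
        return False, yv, yv
    ok4, k4 = rhs(t + 0.6 * h, yv + h * (0.3 * k1 - 0.9 * k2 + 1.2 * k3),
                  pp, warm, scratch)
    if not ok4:
        return False, yv, yv
    ok5, k5 = rhs(t + h, yv + h * ((-11.0 / 54.0) * k1 + 2.5 * k2
                                   + (-70.0 / 27.0) * k3 + (35.0 / 27.0) * k4),
                  pp, warm, scratch)
    if not ok5:
        return False, yv, yv
    ok6, k6 = rhs(t + 0.875 * h,
                  yv + h * ((1631.0 / 55296.0) * k1 + (175.0 / 512.0) * k2
                            + (575.0 / 13824.0) * k3
                            + (44275.0 / 110592.0) * k4
                            + (253.0 / 4096.0) * k5),
                  pp, warm, scratch)
    if not ok6:
        return False, yv, yv
    y5 = yv + h * ((37.0 / 378.0) * k1 + (250.0 / 621.0) * k3
                   + (125.0 / 594.0) * k4 + (512.0 / 1771.0) * k6)
    y4 = yv + h * ((2825.0 / 27648.0) * k1 + (18575.0 / 48384.0) * k3
                   + (13525.0 / 55296.0) * k4 + (277.0 / 14336.0) * k5
                   + 0.25 * k6)
    return True, y5, y5 - y4


@njit(cache=True)
def integrate_span(t0, yv, t1, pp, warm, scratch, rtol, atol, h0, hmax):
    """Integrate from t0 to exactly t1.

    Returns (status, y_end, h_next, min_vlv, max_vlv, min_vrv, max_vrv).
    status: 0 ok, 1 geometry failure, 2 step underflow.
    """
    t = t0
    h = min(h0, hmax, t1 - t0)
    y = yv.copy()
    min_vlv = y[IV_LV]
    max_vlv = y[IV_LV]
    min_vrv = y[IV_RV]
    max_vrv = y[IV_RV]
    while t < t1 - 1e-14:
        if h > t1 - t:
            h = t1 - t
        ok, ynew, err = _rk45_step(t, y, h, pp, warm, scratch)
        if not ok:
            # retry with a smaller step before giving up
            h *= 0.25
            if h < 1e-12:
                return 1, y, h, min_vlv, max_vlv, min_vrv, max_vrv
            continue
        # scaled error norm
        enorm = 0.0
        for i in range(NY):
            sc = atol[i] + rtol * max(abs(y[i]), abs(ynew[i]))
            e = err[i] / sc
            enorm += e * e
        enorm = math.sqrt(enorm / NY)
        if not math.isfinite(enorm):
            h *= 0.25
            if h < 1e-12:
                return 2, y, h, min_vlv, max_vlv, min_vrv, max_vrv
            continue
        if enorm <= 1.0:
            t += h
            y = ynew
            if y[IV_LV] < min_vlv:
                min_vlv = y[IV_LV]
            if y[IV_LV] > max_vlv:
                max_vlv = y[IV_LV]
            if y[IV_RV] < min_vrv:
                min_vrv = y[IV_RV]
            if y[IV_RV] > max_vrv:
                max_vrv = y[IV_RV]
            fac = 5.0 if enorm == 0.0 else min(5.0, 0.9 * enorm ** -0.2)
            h = min(h * fac, hmax)
        else:
            h = max(h * max(0.2, 0.9 * enorm ** -0.25), 1e-13)
            if h < 1e-12:
                return 2, y, h, min_vlv, max_vlv, min_vrv, max_vrv
    return 0, y, h, min_vlv, max_vlv, min_vrv, max_vrv


@njit(cache=True)
def run_beats(yv, pp, warm, max_beats, sv_tol, edv_tol, rtol, atol, hmax_frac):
    """Integrate whole beats until periodic convergence.

    Convergence requires both the RV/LV stroke-volume mismatch below
    sv_tol and the beat-to-beat relative change of each ventricle's
    end-diastolic volume below edv_tol.  Stroke volumes are the ejected
    volumes per beat (integrated outflow-valve flow); EDVs are the
    within-beat ventricular volume maxima.

    Returns (status, y_end, beats_used, sv_mismatch, edv_change) where
    status 0 = converged, 3 = max_beats reached, 1/2 = integrator failure.
    """
    period = 60.0 / pp[P_HR]
    hmax = period * hmax_frac
    scratch = np.empty(27)
    y = yv.copy()
    h = 1e-5
    prev_edv_lv = -1.0
    prev_edv_rv = -1.0
    sv_mis = 1e30
    edv_chg = 1e30
    beats = 0
    for b in range(max_beats):
        status, y, h, mn_lv, mx_lv, mn_rv, mx_rv = integrate_span(
            0.0, y, period, pp, warm, scratch, rtol, atol, h, hmax)
        beats = b + 1
        if status != 0:
            return status, y, beats, sv_mis, edv_chg
        sv_lv = y[I_SV_LV]
        sv_rv = y[I_SV_RV]
        y[I_SV_LV] = 0.0
        y[I_SV_RV] = 0.0
        sv_mis = abs(sv_rv - sv_lv) / max(sv_lv, 1e-12)
        if prev_edv_lv > 0.0:
            edv_chg = max(abs(mx_lv - prev_edv_lv) / prev_edv_lv,
                          abs(mx_rv - prev_edv_rv) / prev_edv_rv)
        prev_edv_lv = mx_lv
        prev_edv_rv = mx_rv
        if b > 0 and sv_mis < sv_tol and edv_chg < edv_tol:
            return 0, y, beats, sv_mis, edv_chg
    return 3, y, beats, sv_mis, edv_chg


@njit(cache=True)
def integrate_sampled(yv, pp, warm, n_samples, rtol, atol, hmax_frac):
    """Integrate one beat, sampling state and auxiliary outputs uniformly.

    Returns (status, t_grid, Y, AUX, y_end): t_grid has n_samples + 1
    points covering [0, T]; Y is (n+1, NY); AUX is (n+1, NAUX).
    """
    period = 60.0 / pp[P_HR]
    hmax = period * hmax_frac
    scratch = np.empty(27)
    n = n_samples
    tg = np.empty(n + 1)
    yout = np.empty((n + 1, NY))
    aout = np.empty((n + 1, NAUX))
    y = yv.copy()
    h = 1e-5
    tg[0] = 0.0
    yout[0] = y
    aout[0] = aux_outputs(0.0, y, pp, warm, scratch)
    for i in range(1, n + 1):
        t0 = period * (i - 1) / n
        t1 = period * i / n
        status, y, h, _, _, _, _ = integrate_span(
            t0, y, t1, pp, warm, scratch, rtol, atol, h, hmax)
        if status != 0:
            return status, tg, yout, aout, y
        tg[i] = t1
        yout[i] = y
        aout[i] = aux_outputs(t1, y, pp, warm, scratch)
    return 0, tg, yout, aout, y
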