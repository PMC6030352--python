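# Model and methods

`rvsim` simulates right ventricular (RV) pressure overload and failure in
the mouse with a three-scale model: a reduced myofilament contraction
model inside each of three ventricular wall segments, a three-segment
(TriSeg-style) biventricular geometry, and a closed-loop lumped-parameter
circulation beating at 420 bpm. Disease arms are multiplicative
perturbations of one healthy baseline: pulmonary vascular resistance
(PVR) ×1.96 with pulmonary artery compliance (C_PA) ×0.70 for pressure
overload, a calibrated collagen increase for fibrosis (total passive
fiber stress ×2.7 at the operating sarcomere length), and a calibrated
reduction of maximal calcium-activated force (Fmax → 64% of control) for
impaired contractility, all confined to the RV free wall. A rescue arm
restores Fmax to 78% of control with afterload and fibrosis left in
place.

## Myofilament model

Active fiber stress is a cross-bridge distortion model with three state
quantities per wall: sarcomere length `Ls`, attached fraction `A`, and
mean elastic distortion `xbar`:

    sigma_act = k_stiff2 * overlap(Ls) * A * xbar
    dA/dt     = f * perm(Ca) * (1 - A) - g * A
    dxbar/dt  = 0.5 * dLs/dt + (f * perm * (1-A) / max(A, 0.05)) * (x0 - xbar)
                + g * (0.05 / (A + 0.05)) * (x0 - xbar)

`perm(Ca)` is a Hill gate on the calcium transient
`Ca(t) = Ca_dia + Ca_amp (t/tau) e^(1 - t/tau)`. The overlap factor is a
tent of half-width 0.5 um peaked at the reference length 2.2 um, which
gives the steep ascending limb that terminates ejection and the
descending limb that degrades force in a dilated ventricle.

Two regularisations depart from the minimal statement of the model, both
active only where the attached population is negligible. The `max(A,
0.05)` guard caps the distortion relaxation rate, which otherwise
diverges as `A -> 0` and makes the ODE explosively stiff at activation
onset. The final term is an *empty-population reset*: without it the
mean distortion of an essentially empty cross-bridge population
integrates the diastolic filling stretch without bound and produces a
large artificial force spike at the next activation; the gate
`0.05/(A+0.05)` makes the term vanish once attachment is appreciable, so
systolic force-velocity behaviour is untouched.

Two design constants tie the reduced model to measurable mechanics: the
closed-form maximal isometric stress `Fmax = k_stiff2 * x0 * f/(f+g)`
(~225 kPa at defaults) and the unloaded shortening velocity `v0 = 2 g
x0` (7.8 um/s at defaults). The attachment/detachment rates (600/300
1/s) keep activation tracking the calcium gate while relaxation is fast
enough for diastole at 420 bpm; with a two-rate scheme activation can
never be slower than relaxation, so the ~15 ms force development time of
the twitch is carried by the calcium gate (Ca50 = 0.95 uM close to the
1.25 uM transient peak, Hill coefficient 6).

Passive stress is titin plus collagen, each exponential above its
engagement length. The defaults make titin a steep, late-engaging
component (alpha = 13 1/um) that acts as the dilation "catch" around
Ls ~ 2.4 um, and collagen a shallow broad component (alpha = 1.5 1/um);
total passive stress at the 2.2 um operating length is deliberately
small (~0.3 kPa) so that the ×2.7 fibrosis calibration adds little
absolute stress at end-systolic lengths. A linear viscosity
(0.3 kPa s/um) damps valve-transition transients. The series element is
kinematic: `dLs/dt = v_max (e_SE/L_SE_iso - 1)` with
`e_SE = Ls_ref e^eps_f - Ls`, so the sarcomere relaxes toward the wall
fiber strain with time constant `L_SE_iso/v_max` ~ 6 ms.

### Calibrations (the disease handles)

* Contractility: `calibrate_contractility` root-finds the `k_stiff2`
  scale so the simulated saturating-calcium isometric force ratio hits
  the target (0.64 for the disease arm, 0.78 for the rescue arm). Fmax
  is exactly linear in `k_stiff2`, so the root find is one step; it is
  kept as a root find so the calibration stays correct under any
  parameter change.
* Fibrosis: `calibrate_fibrosis` scales the collagen multiplier so total
  passive stress at `Ls = 2.2 um` reaches ×2.7 of control (closed form,
  with a guard against targets below the titin-only floor). The
  reported collagen factor of the source experiments is kept as scenario
  metadata; the calibration is driven by the force ratio.
* The rescue arm's 0.78 target is the fractional-change reading of the
  reported stiffness-factor table (1 − 0.22); the force ratio itself is
  not reported for that arm, so this is a documented interpretation.

## Biventricular geometry

Three spherical-cap walls (LV free wall, septum, RV free wall) meet at a
junction ring of radius `y`. Given the cavity volumes, the solver finds
the septal cap volume `Vm_S` and `y` such that the axial and radial
tension components balance at the ring; fiber strain is
`0.5 ln(Am/Am_ref)`, midwall tension `Tm = sigma_f Vw / (2 Am)`, and
cavity pressures are the signed Laplace relations
`P_LV = -2 Tm_L Cm_L`, `P_RV = +2 Tm_R Cm_R` (kPa → mmHg). The signed
form matters: compressive wall stress must read as diastolic suction,
not as a spurious positive pressure.

The 2×2 balance is solved by Levenberg–Marquardt with finite-difference
Jacobians. Near regular roots the step reduces to Newton and converges
to ~1e-12; during strong transients the system can pass through folds
where the two residual curves are tangent and no exact root exists, and
there the iteration lands on the unique least-squares minimum. The
right-hand side accepts that minimum up to 3e-3 of the summed tension
scale (cavity pressures vary by < 0.1% across the slack), while the
public `solve_heart` API keeps a strict 1e-8 acceptance and the
converged beat is re-verified at that tolerance. Two branch guards
reject non-physical roots that the pure force balance admits: "finger"
caps with `|x| > 2.5 y` and far-field roots with `|eps_f| > 1`.
Configurations with near-zero tension in every wall are geometrically
indeterminate (a floppy membrane); the simulator never queries them
because walls carry at least passive tone on the orbit.

## Circulation and protocol

Four linear-compliance compartments (aorta, systemic veins, pulmonary
artery, pulmonary veins), two atria with the time-varying compliance
waveform (half-cosine dip from C_max to C_min during the last quarter of
the cycle, ending at ventricular activation), four diode-resistor
valves, and linear PVR/SVR beds. Atrial pressure is `V/C(t)` exactly.
All flows are resistive; there is no inertance and no regurgitation.

Integration is an adaptive embedded Cash–Karp Runge–Kutta pair compiled
with numba (relative tolerance 1e-7, absolute tolerance 1e-9 of the
total blood volume, step capped at T/300). The system's fastest time
constants are milliseconds, so the explicit pair resolves it
comfortably; halving the tolerance moves end-of-beat volumes by less
than 0.01% of the blood volume. Two auxiliary states accumulate the
ejected volume through each outflow valve so that per-beat stroke
volumes are integrals of flow rather than volume-excursion differences.

A run starts from a primed near-physiological volume distribution with
a six-beat contractility ramp (50/75/100%), and iterates beats until the
RV/LV stroke-volume mismatch is below 1% *and* both end-diastolic
volumes are stationary to 0.1% beat-over-beat. From the primed start
this takes ~10 beats; restarts from a converged state take ≤ 5. The
converged orbit retains an intrinsic ~0.2 ul beat-to-beat volume wobble
(quasi-periodic micro-dynamics, independent of solver tolerances);
periodicity holds to ~0.3% of pulse pressure in the RMS norm.

The homeostasis loop anchors every simulation to systolic aortic
pressure 110–125 mmHg. The baseline adjusts total blood volume first and
SVR second (multiplicative outward search, then bisection; the response
is monotone near the operating point but folds back far from it, so the
search detects wrong-signed or exhausted knobs and falls through).
Disease arms inherit the baseline blood volume and re-adjust vascular
tone (SVR) only; the rescue arm additionally inherits the full-failure
arm's adjusted tone, so the rescue comparison isolates the Fmax change
at identical afterload. A baseline-only mode is available.

## Hemodynamic indices

End-diastole and end-systole are valve events (closure of inflow and
outflow valve respectively), which are unambiguous with ideal diode
valves. RVSP is the per-beat maximum RV pressure; note the model's
activation upstroke produces a brief early-systolic overshoot so the
maximum exceeds the ejection plateau by a few mmHg. Ea = Pes/SV.
Ees and chamber compliance come from converged re-runs at total-volume
fractions {1.0, 0.95, 0.9, 0.85, 0.8} (homeostasis off in the sub-runs):
least-squares slopes of the end-systolic P–V points and of EDV against
EDP. Normalisation reports always emit both the ratio and the
fractional-change conventions because the experimental reference tables
mix them.

## Baseline parameterization

The defaults are a calibration choice, not measured facts: a ~25 g mouse
with heart rate 420 bpm, total blood volume ~1.3 ml after the volume
adjustment, systolic aortic pressure ~118 mmHg, cardiac output
~12.5 ml/min, RV/LV end-diastolic volumes ~53/48 ul, RV ejection
fraction ~0.57, and RV end-diastolic pressure ~1 mmHg. Wall volumes
(70/42/22 ul) and reference midwall areas (73/40/89 mm²) put baseline
end-diastolic sarcomere lengths near 2.2 um. The RV free wall is
deliberately thin so the ventricle operates near its force ceiling —
the regime in which doubling afterload produces dilation and an
ejection-fraction fall rather than an unchallenged pump. The RV
hypertrophy multiplier of the overload arms defaults to 1.0: in this
thin-shell formulation wall volume scales diastolic tension
one-for-one, so a large multiplier acts mainly as diastolic stiffening
that suppresses the dilation phenotype; it is exposed in configuration.

## What the simulated study shows, and what it does not

With these conditions the pipeline reproduces the study's qualitative
structure: pressure overload roughly doubles RV afterload (Ea ×~1.6,
RVSP up) with an EF fall and a CO decrease well under 20%; adding
fibrosis changes CO and EF by under 2%; adding the Fmax deficit drops
CO further and collapses the ESPVR slope; restoring Fmax at fixed
afterload raises EF ~17%, raises RVSP, and leaves Ea within 1%.

Three quantitative behaviours of the source study sit outside what this
reduced closed loop reaches, and the package reports them honestly
rather than forcing them:

* The full-failure arm's measured Ees drop is ~33% rather than ~50%.
  The Fmax-only arm reaches ~46%; in the full arm the multi-preload fit
  runs over a more dilated end-systolic range where the activated P–V
  relation is flatter, and the fibrosis calibration contributes residual
  end-systolic passive stress.
* The rescue arm's CO gain is ~5% rather than ~20% (its EF gain is in
  range). Cardiac output in this loop is pinned between the venous
  return curve and the aortic-pressure anchor, so contractility changes
  move ejection fraction much more than flow. For the same reason the
  five-point Fmax sweep is cleanly linear in EF (R² 0.99) but saturating
  in CO.
* Overload dilates the RV by ~15–20% rather than near-doubling; larger
  dilation in this model requires venous congestion that only appears
  past a catastrophic decompensation threshold (there is no stable
  intermediate orbit).

## Numerical conventions and degenerate inputs

Unit system: ul (= mm³), mmHg, s at the circulation level; kPa, um, mm
in the walls, converted once (1 kPa = 7.50062 mmHg). All parameters are
validated at construction (positivity, ordering constraints); valve and
compliance operations reject non-positive resistances/compliances. The
pipeline contains no random numbers: identical inputs reproduce
metrics bitwise on one platform. The only stochastic component is the
seeded uniform scenario generator used for property testing.

## Synthetic inputs

The package needs no external data: the scenario module *is* the input
generator. Named scenarios carry the study’s reported multipliers; the
seeded random-scenario generator draws uniform multipliers inside a
physiological envelope (PVR ×[1,3], C_PA ×[0.5,1], passive ×[1,3],
Fmax ×[0.4,1]) for property tests. The embedded reference table ships
the experimental values and reported fold changes used by the comparison
reports. What passing tests show is therefore internal consistency of
the model and protocol under the study's stated conditions — not
agreement with any new experimental data, and not behaviours (growth,
remodeling, autonomic reflexes, LV disease) the model does not contain.
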