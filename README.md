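# rvsim

Multiscale simulation of right ventricular (RV) pressure overload and
failure in the mouse: a reduced myofilament contraction model drives a
three-wall-segment biventricular heart coupled to a closed-loop
lumped-parameter circulation at 420 bpm. The package is for
cardiovascular modellers who want to ask how *cellular* changes —
maximal calcium-activated force (Fmax), titin/collagen passive stress —
propagate to *organ-level* hemodynamics (RVSP, EF, CO, Ea, Ees,
ventricular–vascular coupling) under pulmonary hypertension-like
afterload.

## The model in brief

Each wall segment carries a cross-bridge distortion model

    sigma_act = k_stiff2 · overlap(Ls) · A · x̄,
    dA/dt = f·perm(Ca)·(1−A) − g·A,

with Fmax = k_stiff2·x0·f/(f+g) exactly linear in the stiffness scale
k_stiff2, plus exponential titin/collagen passive stress, a viscous
term, and a kinematic series element that relaxes the sarcomere length
toward the wall fiber strain. The two ventricles share a septum in a
three-spherical-cap geometry: the solver balances wall tensions at the
junction ring and returns cavity pressures from the free-wall Laplace
relations. The circulation closes the loop with four windkessel
compartments, two time-varying-compliance atria (P = V/C(t)), ideal
diode valves and the PVR/SVR resistances.

Disease arms are multiplicative edits of one healthy baseline, applied
to the pulmonary vasculature and the RV free wall only:

| arm                | PVR   | C_PA  | passive stress | Fmax |
|--------------------|-------|-------|----------------|------|
| pressure_overload  | ×1.96 | ×0.70 | —              | —    |
| po_fibrosis        | ×1.96 | ×0.70 | ×2.7 at 2.2 µm | —    |
| rvf_full           | ×1.96 | ×0.70 | ×2.7           | →64% |
| po_fmax_only       | ×1.96 | ×0.70 | —              | →64% |
| a6_rescue          | ×1.96 | ×0.70 | ×2.7           | →78% |

Every arm is run to periodic convergence (RV/LV stroke-volume mismatch
below 1%) under a homeostasis protocol that holds systolic aortic
pressure in 110–125 mmHg (blood volume and vascular tone for the
baseline; vascular tone only for the disease arms). See
`docs/methods.md` for the full model description, parameter defaults
and known limitations.

## Worked example

```python
from rvsim import default_model, homeostasis_adjust, run_to_convergence
from rvsim import beat_metrics, build_scenario, apply_scenario

model, base = homeostasis_adjust(default_model())
ctrl = beat_metrics(base.trajectory)
print(f"baseline: sys AoP {ctrl.sys_aop:.1f} mmHg, "
      f"RV EDV {ctrl.rv.EDV:.1f} ul, EF {ctrl.rv.EF:.2f}, "
      f"CO {ctrl.rv.CO / 1000:.1f} ml/min")

overload = apply_scenario(model, build_scenario("pressure_overload"))
run = run_to_convergence(overload, initial_state=base.state)
ph = beat_metrics(run.trajectory)
print(f"overload: RVSP {ph.RVSP:.1f} mmHg (was {ctrl.RVSP:.1f}), "
      f"EF {ph.rv.EF:.2f}, CO {ph.rv.CO / 1000:.1f} ml/min, "
      f"Ea {ph.rv.Pes / ph.rv.SV:.2f} mmHg/ul "
      f"(was {ctrl.rv.Pes / ctrl.rv.SV:.2f})")
```

prints

```
baseline: sys AoP 118.1 mmHg, RV EDV 52.6 ul, EF 0.57, CO 12.5 ml/min
overload: RVSP 38.6 mmHg (was 34.8), EF 0.44, CO 11.8 ml/min, Ea 1.13 mmHg/ul (was 0.72)
```

The homeostasis loop lands the healthy mouse at a systolic aortic
pressure of 118 mmHg with a cardiac output of 12.5 ml/min. Doubling
pulmonary vascular resistance and dropping pulmonary artery compliance
raises RV afterload (arterial elastance 0.72 → 1.13 mmHg/µl, RV
systolic pressure up), and the RV responds with a fall in ejection
fraction while cardiac output declines only modestly — the adaptive
pressure-overload phenotype. `run_scenario_suite` runs all arms with
the ventricular indices (Ees from a five-level preload series,
chamber compliance, coupling) and normalises everything to baseline;
`fmax_sweep` maps CO and EF across evenly spaced Fmax levels at
baseline afterload.

A thin CLI wraps the same functions:

```bash
rvsim simulate --scenario baseline --out out/
rvsim suite --out out/                  # all six arms + comparison reports
rvsim sweep --points 5 --out out/
rvsim ees --out out/
```

Each run echoes its fully resolved configuration (YAML) next to the
outputs; experiments are pure parameter edits, so the configuration file
is the experiment (`--override circulation.PVR=0.098` style dotted
paths).

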