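# torquegait

Predictive simulation of pathological sagittal-plane gait with lumped
muscle torque generators, and identification of ankle-foot-orthosis (AFO)
spring stiffnesses by optimal control.

Clinical gait teams tune AFO springs by trial and error on the patient.
This package implements the model-based alternative for a planar
child-sized musculoskeletal model: synthesize walking that minimizes
muscle effort subject to physically consistent contact dynamics, and let
the optimizer choose the orthosis springs.  It is aimed at researchers in
computational biomechanics / neuromechanics who want a small, fully
scriptable, pure-Python implementation of that pipeline.

## The model and the optimization

* **Skeleton** - 8 planar segments (pelvis, lumped torso/head/arms, two
  thighs, shanks, flat feet), a 3-DoF floating pelvis plus 7 rotational
  joints (10 generalized coordinates).  Child anthropometric proportions
  scale segment masses, lengths and inertias from body mass and stature;
  every entry is overridable.
* **Actuation** - 14 muscle torque generators (an extensor/flexor pair per
  actuated joint), each producing
  `tau = tau_max * a * fA(theta) * fV(omega)` with C2 Bezier normalized
  torque-angle and torque-velocity curves, driven by first-order
  excitation-activation dynamics (`tau_act = 11 ms`, `tau_deact = 68 ms`).
  Strength tables for a healthy and a weakened (crouch-gait) child are
  bundled; patient calibration inverts the torque law at the observed peak
  torque assuming 90% activation.
* **Orthosis** - a 5-stage C2 torque-angle spring law at each ankle
  (preload window, dorsi-/plantarflexion springs `K_D`, `K_P`, stiff hard
  stops) plus shell masses added to shank and foot.  `K_D` and `K_P` per
  side are free parameters of the optimization.
* **Walking as an OCP** - a full left-right stride with 8 contact phases
  in fixed order (heel strike / toe down / heel off / toe off events).
  States `(q, qdot, a)`, controls `e`, free phase durations; path
  constraints enforce positive vertical ground reactions, the friction
  cone, swing clearance and periodicity.  Objectives: dynamic
  least-squares tracking of reference kinematics (`LS`), minimal squared
  activation per distance walked (`MAPD`), and a variant rewarding
  walking speed (`MAPD_WS`).  The transcription (trapezoidal collocation
  by default, multiple shooting available) is solved with exact
  complex-step Jacobians through scipy's trust-constr, staged behind a
  Gauss-Newton tracking warm start.

See `docs/methods.md` for the full formulation, defaults and limitations.

## Worked example

```python
import numpy as np
from torquegait import (build_default_model, build_mtg_set,
                        default_strength_table, torso_strength_from_hips,
                        flexion_from_extension, mtg_torque,
                        default_orthosis_params, build_profile)

# patient-scale model: 24.7 kg, 1.25 m
model = build_default_model(24.7, 1.25)
print(f"total mass     {model.total_mass:.2f} kg")

# strength calibration arithmetic for the weakened-child table
table = default_strength_table("pathological")
ext, flex = torso_strength_from_hips(table)
print(f"torso strength {ext:.2f} / {flex:.2f} Nm (ext/flex)")
print(f"ankle flexion  {flexion_from_extension(16.84, 'ankle'):.2f} Nm")

# an MTG at 90% activation at its optimal angle
mtgs = build_mtg_set(table)
hip_ext = next(p for p in mtgs if (p.joint, p.side, p.direction)
               == ("hip", "L", "extension"))
print(f"hip ext torque {abs(mtg_torque(hip_ext, 0.9, 0.0, 0.0)):.3f} Nm")

# orthosis spring law: secant slope in the plantarflexion spring region
profile = build_profile(default_orthosis_params("L"))
th = np.linspace(-0.005, 0.085, 50)
slope = np.polyfit(th, profile.torque(th), 1)[0]
print(f"K_P region slope {slope:.2f} Nm/rad")
```

prints

```
total mass     24.70 kg
torso strength 24.50 / 17.20 Nm (ext/flex)
ankle flexion  5.85 Nm
hip ext torque 27.315 Nm
K_P region slope -5.00 Nm/rad
```

i.e. the torso strengths are the hip averages, flexion strengths follow
the bundled flexion/extension ratios, the torque law reproduces 90% of
the maximum isometric torque at the curve peaks, and the orthosis profile
realizes the requested spring constant.

Gait synthesis and stiffness identification run through one staged call
(minutes per solve at the default 16-interval discretization):

```python
from torquegait import OCPConfig, solve_walking, gait_metrics

cfg = OCPConfig(mode="MAPD", n_shooting=16, maxiter=700)
solution = solve_walking(model, mtgs, None, cfg)   # barefoot synthesis
print(solution.objective, solution.walking_speed)
print(gait_metrics(solution, model))
```

or from the shell:

```bash
torquegait solve-mapd --mass 24.7 --height 1.25 --population pathological \
    --nodes 16 --out out/barefoot
torquegait identify --nodes 16 --out out/identify
```

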