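# Methods

`torquegait` simulates sagittal-plane walking of a child-sized
neuromusculoskeletal model and identifies ankle-foot-orthosis (AFO) spring
stiffnesses by trajectory optimization.  This note records the model, the
numerical formulation, the defaults and their rationale, and the known
limitations.

## Skeletal model

The body is a branched planar chain of 8 rigid segments: pelvis, a lumped
torso/head/arms segment, and per side a thigh, a shank and a flat foot.
The pelvis is a floating base with anterior (X) and vertical (Z)
translations plus a rotation; each of the 7 joints (lumbar, hips, knees,
ankles) adds one rotational degree of freedom, for 10 generalized
coordinates in total.  Rotations are positive counter-clockwise seen from
the model's right; all joint angles are zero in upright standing.
Reports use clinical conventions (hip flexion, knee flexion and ankle
plantarflexion positive, in degrees).

Segment masses, lengths, centers of mass and gyration radii default to a
bundled table of child anthropometric proportions scaled by total body
mass and stature (`model.CHILD_PROPORTIONS`): per-side mass fractions
thigh 0.100, shank 0.045, foot 0.020, pelvis 0.140, with the torso
absorbing the remainder so masses always sum to the input body mass;
length fractions of stature 0.245 (thigh), 0.246 (shank), 0.152 (foot),
0.090 (pelvis), 0.400 (torso); centers of mass at 43.3% of segment length
from the proximal joint for thigh/shank and mid-segment otherwise;
gyration radii 0.302-0.475 of segment length.  These values follow the
child-oriented regression literature at the precision relevant here; the
sources do not publish a patient's individual geometry, so every entry
can be overridden per segment (`build_default_model(overrides=...)`) or
replaced wholesale through a model YAML file.  Gravity (default 9.81
m/s^2) and the heel/toe placement are configuration, not constants: the
ankle sits 0.039 x stature above the sole and 25% of foot length from the
heel; heel and toe contact points lie at sole level with a configurable
heel-to-toe fraction of foot length (default 1.0).

Each foot is rigid and flat with exactly two ground contact points (heel,
toe).  Contact while active is a bilateral equality constraint (points
pinned to the ground); unilaterality (vertical force >= epsilon) and the
friction cone enter the optimal control problem as path inequalities, not
as complementarity conditions, because the contact sequence is fixed.

Dynamics are assembled from per-body point Jacobians into

    M(q) qdd + c(q, qd) - Q_grav = B tau + Jc(q)^T lambda,
    Jc(q) qdd + dJc/dt qd = 0  (active contacts),

solved as one symmetric indefinite KKT system per evaluation; the
multipliers are the physical ground reactions.  A flat foot in full
contact is constrained by heel-x, heel-z and toe-z; anchoring both points
horizontally would be rank deficient.  The implementation is vectorized
over a trailing batch axis and uses only holomorphic numpy operations, so
exact derivatives of every dynamics quantity are available by complex-step
differentiation; this is how all optimization Jacobians are produced
(no finite-difference noise).

A genuinely degenerate geometry worth knowing about: in the exact neutral
pose both feet coincide and each leg's joints are vertically collinear,
which makes four-point flat contact rank deficient; the constrained solve
raises a diagnostic error naming the contact set.  `split_stance_state`
provides a well-posed double-support pose for static analyses.

## Muscle torque generators

Each actuated coordinate carries an agonist-antagonist pair of muscle
torque generators (MTGs), 14 in total (hips, knees, ankles per side, one
torso pair).  An MTG produces

    tau = tau_max * a * fA(theta) * fV(omega)

with activation `a`, normalized active torque-angle curve `fA` (unit peak)
and torque-angular-velocity curve `fV` (`fV(0) = 1`).  Only active torque
components are modeled - no passive musculotendon elasticity, no
biarticular coupling.  "Extension" at the ankle means plantarflexion
(push-off).  Curves are C2 piecewise quintic Bezier fits; the bundled
defaults are a bell-shaped `fA` (width 0.9 rad, i.e. half of maximal
torque ~43 degrees off peak, matching the falloff of experimental joint
torque-angle data; peak at the neutral angle)
and a Hill-hyperbola `fV` (maximum shortening velocity 12 rad/s,
curvature constant 3, eccentric plateau 1.4), both rescaled so the
normalization identities hold exactly.  The published experimental curve
coefficients for adult subjects are not reproduced numerically; the
contracts of the package (normalization, calibration round trips,
optimization smoothness) depend on the curve *properties*, which these
defaults satisfy, and both curves are replaceable from configuration.
`theta_peak` defaults to the neutral angle for every MTG for the same
reason; per-MTG values can be supplied.

Maximum isometric torques default to a bundled strength table for an
age/weight-matched healthy child and for the pathological case study the
package models (hip/knee/ankle extension and flexion per side, torso
single).  Patient-specific calibration follows the published protocol:
the peak extension torque observed in inverse dynamics is assumed to
occur at 90% activation, and the torque law is inverted for `tau_max`
(`calibrate_tau_max`); flexion strengths follow from bundled per-joint
flexion/extension ratios (hip 34.27/48.82, knee 19.26/36.08, ankle
13.71/39.46); torso strengths are the mean of the two hips.  The
calibration operation takes the (angle, velocity, peak torque) triple
explicitly, staying agnostic about whether the peak is taken globally or
per phase.

Activation follows the first-order excitation-activation lag with
activation/deactivation time constants 0.011 s and 0.068 s.  The exact
law switches branches at `e = a` and is only C0 there; the optimal
control path uses a tanh-blended variant with half-width 1e-3 (both
branches share the factor `e - a`, so the blend is smooth and coincides
with the exact law away from the switching manifold).

## Orthosis model

The AFO is a spring-loaded ankle joint between carbon-fiber shells,
rigidly co-moving with shank and foot.  Its torque-angle law has 5
stages over the clinical ankle angle (dorsiflexion negative): a preload
plateau of +/- tau_0 inside a window of half-width theta_W around the
offset theta_0 (the sign opposes deflection; the plateau crosses zero at
theta_0 over a smoothed step), linear springs K_D / K_P between the
window edges and the hard stops theta_DH / theta_PH, and hard-stop
slopes K_DH / K_PH beyond.  Stage corners are blended by quintic Hermite
spans over a half-width of min(0.005 rad, 0.25 theta_W), which preserves
the nominal slopes over well above 90% of each stage and makes the
profile C2 everywhere.  K_D and K_P are the clinically adjustable
springs and the free parameters of the identification problem; they enter
every Bezier control point affinely, so a profile built once evaluates
exactly for any candidate (K_D, K_P) - the identification does not
re-smooth inside the solver loop.  Device masses (0.34 kg shank shell,
0.69 kg foot shell including the shoe) are added to the respective
segments, by default at the segment center of mass (device geometry
unpublished; attachment point configurable, with the parallel-axis
inertia update).

## Walking as a multi-phase optimal control problem

A full left-right stride is divided into 8 contact phases in fixed order,
starting at left toe off: right flat; right toe only (heel off); right
toe + left heel (heel strike); right toe + left flat (toe down); left
flat (right toe off); left toe only; left toe + right heel; left toe +
right flat.  Consecutive phases differ by exactly one heel/toe event and
the sequence closes periodically.  Newly entering contact points are
constrained to ground height with zero velocity at their phase start
(velocity stays continuous; there is no impact map), so transitions only
swap the active constraint set.

States are x = (q, qdot, a) (34), controls are the 14 neural excitations,
parameters are the per-phase durations (free in the synthesis modes,
fixed in tracking) and optionally the 4 orthosis springs (internally
scaled by 1/100 to the magnitude of the other variables).  Path
constraints at every node: vertical contact force >= 1 N per active
point ("strictly positive" is not representable, so an epsilon bound is
used), anterior force within the friction cone (coefficient 0.8; force
rows are expressed in units of body weight so all constraint families
share a scale), swing-point ground clearance >= 0, and box bounds on
coordinates, velocities (|qdot| <= 12 rad/s, the support of the
torque-velocity curve), activations and excitations.  The synthesis
modes add full-state periodicity (pelvis X excepted), control
periodicity, per-phase duration bounds of [0.04, 0.20] s and a minimum
forward displacement r(T) >= 0.2 m.  The duration and displacement
bounds confine the search to the physiological envelope of child walking
(stride times up to 1.6 s, stride lengths above 0.2 m); without them the
distance-normalized effort objective has a strongly attracting
degenerate quasi-standing local optimum (stride time ~1.9 s, stride
~0.4 m, several-fold worse cost) that a local solver falls into from
most warm starts.  Both bounds are ordinary configuration entries.

Objectives:

* `LS` (tracking): weighted squared joint-angle error at the measurement
  times (weights default to identity) plus `delta = 1e-4` times the
  integrated squared excitations; phase times fixed.  The
  self-consistency studies scale the weights to 30 so that the kinematic
  term dominates the constraint-barrier pressure near an exactly
  attainable reference.
* `MAPD`: integral of the squared activation vector divided by the
  distance walked r(T).
* `MAPD_WS`: MAPD minus `lambda * r(T)/T` (default lambda 2), favoring
  faster walking.

Quadratures treat node signals as piecewise linear (exact closed forms),
so the textbook hand-computable examples hold to rounding.

### Transcription

Two transcriptions share one interface.  The default is trapezoidal
direct collocation: defects couple adjacent node states through the node
dynamics only, the discretization is A-stable (the activation dynamics
are stiff, time constant 11 ms), and one batched complex-step evaluation
per node yields the exact sparse constraint Jacobian.  Direct multiple
shooting (`transcription="shooting"`) integrates each interval with
fixed-step RK4 (mechanical substep <= 0.05 s); the stiff activation
subsystem, which is driven by but does not feed back on the mechanical
states within an interval, is integrated first on its own fine grid
(substep <= 4 ms) and sampled at the RK stage times.  Shooting is the
higher-fidelity transcription but its defect landscape is far harder for
the available NLP solvers at desk scale - gait dynamics are open-loop
unstable, so interval endpoints amplify parameter changes - and the
collocation default is what the test suite and the reproduction script
exercise.  Controls are piecewise linear between nodes in both
transcriptions; activations are states, so they are C1 along the
trajectory.

### Solving

Synthesis from a cold start is staged (`solve_walking`):

1. A kinematic walking prototype is built from planned foot placements
   (stationary stance heels, smooth swing with zero touchdown velocity,
   heel-off pitch about the toe during toe-only phases, limited to the
   brace range when an orthosis is mounted) with closed-form two-link leg
   inverse kinematics, node velocities projected onto the active-contact
   null space, and activations seeded from constrained inverse dynamics
   along the prototype.  The alternative stance-pose guess
   (`initial_guess="stance"`) replicates upright standing with seeded
   jitter; it is retained for reference but the synthesis problem does
   not converge from it in practice.
2. A periodic dynamic tracking fit of the prototype (fixed phase
   durations) is solved first as a penalty-form nonlinear least-squares
   problem - tracking error, control regularization, defect and
   smoothed-hinge inequality penalties of increasing weight (1e2, 1e4,
   1e6) - by a bounded trust-region Gauss-Newton method with the exact
   sparse Jacobians, then polished by the exactly-constrained solver.
   When the initial guess is already nearly feasible (as for
   self-consistency re-fits, whose guesses reconstruct defect-consistent
   velocities and bounded-least-squares activation seeds from the
   reference), the penalty stage is skipped: the interior point then
   stays inside the tracking valley.
3. The requested objective is solved by scipy's trust-constr interior
   point with exact gradient, exact sparse constraint Jacobians and the
   exact objective Hessian, warm-restarted up to `restarts` times (each
   restart resets the barrier, which repeatedly pays off on this problem
   class), and finally projected back onto the constraint manifold by a
   proximal Gauss-Newton step (`refine_feasibility`), which drives the
   violation to ~1e-7 while changing the objective only at the violation
   scale.

A solution is flagged successful iff its recomputed constraint violation
is below `feas_tol` (default 2e-6; force rows in body-weight units).
The solver is local and deterministic for identical guesses and
settings; multi-start from seeded jitter is available through the seed.

Stiffness identification (`identify_orthosis_stiffness`) frees the four
spring parameters (bounds [0, 400] Nm/rad, initial guesses from the
device defaults) inside either a tracking or a synthesis OCP.  The
perturbation analysis re-solves with each spring perturbed and held
fixed, warm-started from the base optimum, and reports percent changes of
the cost and gait metrics; non-converged rows are flagged, never filled.

### Problem sizes

The published formulation discretizes the stride into 64 intervals and
reports multi-hour single-core solve times; this package's test suite and
reproduction script run the same pipeline at 16 intervals (2 per phase),
where a full synthesis solve takes minutes on one core.  Halving or
doubling the node count changes the objective by the expected
discretization error; the regression suite tracks feasibility and
directional properties, not discretization-free values.

## Evaluation procedure

Gait metrics: step length is the anterior distance between contralateral
heels at the stepping foot's touchdown (phase-3 and phase-7 starts);
walking speed is pelvis displacement over stride time; the minimum knee
flexion during stance ("crouch severity") is taken per side over the
stance windows implied by the schedule; duty factor is heel-strike to
toe-off time over stride time.  RMS comparisons resample both
trajectories to a common 0-100% stride grid (tracking fits start the
stride at left toe off; figures conventionally start at left heel strike
- the remap is an explicit offset).  The net ankle torque-angle profile
sums both ankle MTG torques and the orthosis torque along the visited
angles - the quantity an inverse dynamics analysis of a braced leg
reports - and a least-squares secant slope over stance summarizes it.
Floating-base inverse dynamics residuals (anterior force, vertical
force, sagittal moment at the pelvis) are reported as mean/min/max per
condition; applied ground forces act at the measured center of pressure.

## Synthetic fixtures

No recorded gait ships with the package.  `synthetic fixtures
<torquegait.fixtures>` generate reference "recordings" by running the
production pipeline at 16 intervals and exporting joint angles at 120 Hz
and ground reactions at 1080 Hz (the rates typical of clinical motion
capture and force plates), optionally with seeded Gaussian measurement
noise.  Recovery fixtures synthesize gait at known spring stiffnesses
and package the observation separately from the blinded truth.  All
randomness derives from the fixture seed; identical specs reproduce
bit-identical files.

What passing against these fixtures does and does not show: the
fixtures exercise the full code path (model build, curve construction,
OCP assembly, solve, export, re-import, identification) under exactly
the modeling assumptions of the package - flat feet, fixed phase order,
active-only MTGs, planar dynamics.  They cannot detect model-form error
against a real child (foot curvature, transverse-plane motion, reflexes,
passive tissue), and the identification tests quantify recoverability of
the spring parameters under the model, not clinical accuracy.

## Known limitations

* The orthosis spring constants are only weakly observable from joint
  kinematics: with an extensor/flexor pair plus a spring acting on the
  same ankle coordinate, any spring change within actuator capacity can
  be compensated by excitations without moving the joints, so
  tracking-based identification resolves the springs only through the
  (weak) control-effort regularizer, and even the effort-based
  identification has a shallow landscape over the spring values -
  different starts reach different spring sets at near-identical cost.
  Identified stiffnesses should be read as effort-equivalent settings,
  not as uniquely recoverable physical parameters.
* Planar, fixed 8-phase contact order; no contact-sequence discovery.
* Flat rigid feet; no rolling contact.  The net ankle torque level is
  sensitive to the toe lever arm.
* Active MTG torques only; no passive elasticity, no biarticular
  muscles, no reflex feedback.
* The solver is local; different seeds/guesses can reach different gaits
  (as expected for this problem class).
* Trapezoidal collocation at 16 intervals is a coarse discretization;
  quantities that depend on sharp transients (heel-strike force peaks)
  are resolved only at the node scale.
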