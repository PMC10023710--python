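# Methods

`shouldersim` is a software-in-the-loop counterpart of a cable-driven
in-vitro glenohumeral simulator: a physics-based *virtual specimen* stands
in for the cadaver, the *controller* reproduces the rig's three-loop
cascade/parallel PID muscle-force control, and the *evaluation* module
reproduces the rig's data analysis (1° resampling, mean deviation, RMSE,
repeatability SD, ICC reliability). This note documents the model, its
assumptions, the tunable parameters, and what the synthetic experiments do
and do not show about a physical rig.

## Coordinate conventions

Scapular frame: X anterior, Y superior, Z medial; origin at the
glenohumeral centre of rotation (COR) for the plant (the kinematics module
supports an arbitrary scapular origin, e.g. the angulus acromialis, through
its calibration offsets). Glenohumeral orientation uses the Cardan XZY
sequence — abduction about X, flexion/extension about Z, internal/external
rotation about Y — which is non-singular at zero elevation, where the
ISB-recommended YXY sequence gimbal-locks at the initiation of abduction.
All stored angles are clinically signed (abduction, flexion, internal
rotation positive). Because the three clinical positive directions do not
form a right-handed triple, the axial angle enters the geometric
composition negated: `R = Rx(abd) · Rz(flex) · Ry(−rot)`. Decomposition is
unique for flexion in (−90°, 90°); the protocols never exceed ±45° in any
secondary DOF.

**Anatomical calibration at rest.** On a physical rig the humeral
anatomical frame is digitised (epicondylar axis) with the arm hanging at
rest, so flexion and axial rotation read zero in that posture even though
the scapula is tilted. The virtual specimen does the same: at specimen
build time the passive pretensioned equilibrium is computed and a constant
alignment rotation is stored so that measured angles read
(resting abduction, 0, 0) at rest. Without this, the 10° scapular forward
inclination makes the hanging arm read ≈ −9° of extension in the scapular
frame, a bias no anatomical digitisation would produce.

## Virtual specimen (the plant)

A single rigid body (humerus + forearm-replacement mass) with three
rotational DOF about the COR:

- **Muscles.** Six straight cables from humeral insertions to fixed
  scapular guide points (MD, AD, PD, SSC, ISP/TM, SSP). Force direction is
  the unit vector from the rotated insertion toward the guide; cables can
  only pull. No wrapping or via-points: this mirrors the rig's single
  line-of-action cables and shares its limitation for broad muscles.
- **Gravity.** Humerus segment (2.0 kg at 140 mm) and forearm replacement
  (3.0 kg at 280 mm, i.e. 3.2 % of a 94 kg donor) below the COR; the 10°
  scapular forward inclination is applied as a constant tilt of the gravity
  vector in the scapular frame.
- **Passive capsule.** Linear per-DOF stiffness (3.0, 2.0, 2.2) N·m/rad
  about a rest posture of 12° abduction, with viscous damping
  (3.0, 2.0, 0.8) N·m·s/rad. A linearization of mid-range capsular
  behaviour; no end-range stiffening is modelled.
- **Translations.** The humeral head centre translation has two parts:
  a *geometric arc* — the anatomical head centre sits (6, 3, 4) mm from
  the kinematic COR in the humeral frame (the "least-moving point" of a
  pivot calibration is never exactly the head centre), so it sweeps an
  orientation-dependent arc — and a *quasi-static elastic* displacement of
  the head along the net joint load in excess of the centering preload,
  with per-axis stiffness (15, 18, 35) N/mm (AP, SI, ML). Translations are
  measured from the pretensioned resting state and, in recorded trials,
  referenced at the 20°-abduction crossing of the loading phase (mean over
  a one-second window after the first measured crossing, so repeats share
  a common zero that is not set by a single noisy sample). A configurable
  dislocation limit (15 mm) and angular-speed limit (200 °/s) abort a
  trial.

Equations of motion are written in the Cardan coordinates q:
`M(q) q̈ = Eᵀ(q) τ_world − K (q − q_rest) − C q̇` with
`M = Eᵀ R I_body Rᵀ E`, E the map from Cardan rates to world angular
velocity. Velocity-product terms are neglected: at the protocol speed of
0.5 °/s they are ~10 orders of magnitude below the applied torques.
Integration is classical fixed-step RK4 at dt = 5 ms with muscle forces
held over the step; halving dt changes trajectory endpoints by < 10⁻³ °.
The kernels are numba-compiled, with identical pure-Python execution when
numba is unavailable.

**Reference geometry.** No cadaver coordinates are published for this kind
of rig, so the reference specimen is a documented invention, fixed by
anatomical plausibility plus calibration to the force and translation
magnitudes a physical rig reports: middle-deltoid moment arm 30–45 mm over
the abduction range so that MD ≈ 160–175 N at 60° abduction; rotation-couple
geometry and capsule stiffness so that SSC ≈ 160 N at 45° internal
rotation; translation parameters so per-protocol head excursions span
roughly 1–12 mm. Everything ships as an editable YAML schema.

**Sensors.** The optical tracker samples at 50 Hz (measurements held
between frames) with additive white Gaussian noise of 0.1° per angle;
load cells 0.5 N; translations 0.1 mm. Noise enters the *measured* process
variables — the controller acts on what the sensors report — so repeated
trials differ genuinely through their noise streams. Defaults are chosen
to be realistic for passive-marker optical tracking and miniature load
cells and are configurable per specimen.

**Specimen generator.** `generate_specimen(seed, variability)` perturbs
every geometric and mechanical quantity of the reference specimen by
(1 + ε), ε ~ N(0, variability) truncated at ±2.5 SD (default 10 %,
emulating inter-specimen variability across a small donor cohort). A draw
must pass physical validity checks, else it is rejected and resampled:

1. passive pretensioned equilibrium with resting abduction in [4°, 16°]
   (the rig's ≈10° resting posture);
2. anatomical moment-arm signs at 30° abduction (MD, SSP
   abduction-positive; AD flexion-positive; PD flexion-negative; SSC
   internal-rotation-positive; ISP/TM negative);
3. static feasibility of all six protocol end poses: a linear program
   checks that a muscle-force balance exists under the controller's
   structure (SSP slaved to MD, held couples ratio-slaved with 5–95 %
   shares, kinetic constraints at 0.9 margin) — without this ~25 % of
   draws cannot execute the coupled extension + internal-rotation motion
   within the kinetic constraints, which is exactly the flexion/extension
   range limitation a physical rig reports;
4. a predicted head translation ≤ 14 mm at the minimum-effort balance of
   each end pose, so specimens do not graze the dislocation limit
   mid-protocol.

## Controller

Three independent per-DOF loops (abduction, F/E, IR/ER). Setpoints are the
target angles, process variables the measured angles, control variables
the muscle-force commands. Each loop owns an **activation** PID; the two
secondary loops also own a **distribution** PID that splits an
agonist–antagonist couple total, clamped to 5–95 % of the total so neither
cable slackens.

The PID is the time-constant form `u = Kc (e + (1/Ti)∫e dt + Td de/dt)`
with Ti and Td in **minutes** (the convention in which the gains were
tuned); the shipped gain table is:

| loop | controller | mode | Kc | Ti (min) | Td (min) |
|---|---|---|---|---|---|
| abduction | activation | profile | 2.600 | 0.023 | 0.000 |
| abduction | activation | constant | 1.400 | 0.006 | 0.001 |
| F/E | distribution | profile | 0.030 | 0.050 | 0.000 |
| F/E | distribution | constant | 0.050 | 0.070 | 0.000 |
| F/E | activation | — | 0.030 | 0.050 | 0.000 |
| IR/ER | distribution | profile | 0.030 | 0.060 | 0.000 |
| IR/ER | distribution | constant | 0.050 | 0.050 | 0.000 |
| IR/ER | activation | — | 0.020 | 0.050 | 0.000 |

"Profile" rows apply while a loop tracks a moving setpoint, "constant"
rows while it holds an angle. An **activation span** converts the
dimensionless PID output into newtons (the physical rig performs this
conversion in its hydraulic hardware): 1 N/unit for abduction (whose gains
are already force-scaled), 200 N/unit for F/E and 450 N/unit for IR/ER,
fixed by closed-loop analysis so the integral force rates of the three
loops are commensurate; distribution outputs are share offsets (span 1).

**Cascade loading (active abduction).** The abduction activation PID
drives MD, clamped to [pretension, 241 N]. SSP is slaved to MD through the
abduction-dependent ratio (0.99 at 10°, 0.52 at 30°, 0.30 at 60°,
piecewise-linear, end-clamped). The couple totals are slaved:
AD+PD = 0.60 × MD, SSC+ISP/TM = 1.00 × MD (floored at twice the 10 N
pretension). The distribution PIDs split each total to hold the secondary
angles (positive flexion error → larger AD share; positive
internal-rotation error → larger SSC share).

**Parallel loading (active F/E, IR/ER, coupled).** Profiled couples get
their total from their own activation PID, with the error signed by the
protocol's motion direction so the total always grows when tracking lags
(extension and external rotation are negative-going). Couples whose DOF is
merely held stay slaved to MD — without that co-contraction the
distribution PID has no force authority to hold the secondary angle. The
abduction loop holds elevation through MD with constant-row gains; SSP
remains slaved (configurable).

**Clamps and safeguards.**
- Kinetic constraints: per-muscle caps = pCSA × 25 N/cm² rounded half-up
  (MD 241, AD 118, PD 136, SSC 390, ISP/TM 308, SSP 132 N), plus a
  254 N AD+PD couple cap (the combined deltoid constraint).
- Never-slack: every muscle ≥ 10 N (the lower end of the 10–20 N centering
  pretension). When a couple total is near its floor, the share window is
  narrowed to keep both the floor and exact split conservation — the 5–95 %
  window and a 10 N floor are jointly infeasible below 200 N totals.
- Directional total cap: a profiled couple's total is additionally capped
  at (agonist kinetic cap + pretension). Past that point extra total can
  only load the antagonist; with the agonist saturated this creates
  positive feedback (more total → more opposing force → larger error) and
  a runaway.
- Anti-windup by conditional integration: an accumulator freezes while its
  output is clamped in the direction of the error.
- Bumpless transfer: at every gain-row or role switch (loading → hold →
  scored segment) the incoming PID's integral is preloaded so its output
  is continuous.
- The control path low-passes the measured angles (first order,
  τ = 0.03 s) — standard conditioning of optical feedback; at 0.5 °/s the
  induced lag is ~0.015°. τ was chosen as the largest value stable across
  generated specimens. Recorded traces keep the raw noisy measurements.

## Motion protocols

Six built-ins at 0.5 °/s, three repeats, each trial re-zeroed to the
resting posture: abduction 20→60° (0° F/E, 0° IR/ER); flexion 0→30° and
extension 0→−30° at 50° abduction; internal rotation 0→45° and external
rotation 0→−45° at 30° abduction; and coupled extension 0→−30° with
internal rotation 0→30° at 40° abduction (equal ranges, so simultaneous
ramps finish together). Each trial has a loading ramp from rest to the
start configuration (at the protocol velocity for abduction — the 10–20°
initial muscle-loading phase — and at 2 °/s pre-positioning otherwise), a
10 s settling hold so the constant-mode loops converge, the scored
segment, and a 2 s tail. Custom protocols load from YAML.

## Evaluation

The scored segment of each trial is resampled by linear interpolation onto
the integer-degree grid of the profiled DOF's setpoint (inclusive of both
ends; descending ramps give descending grids; the coupled motion is
indexed by its F/E angle). Per protocol and DOF:

- **Accuracy** — mean deviation at each grid point is the across-trial
  mean of (achieved − target); the reported number is its maximum
  magnitude over the grid. RMSE pools squared deviations over grid points
  and trials.
- **Repeatability** — sample SD (n−1) across a specimen's repeats at each
  grid point; maximum and grid-average reported, maximized over specimens.
- **Reliability** — ICC(A,1), the single-measurement absolute-agreement
  two-way model, of each muscle force and translation axis: rows are grid
  points (stacked across specimens by default, mirroring reporting of all
  specimens together; per-specimen medians optional), columns are repeats.
  The 95 % CI is the F-based absolute-agreement interval with
  Satterthwaite degrees of freedom; the implementation is verified to
  machine precision against an independent ANOVA oracle and against
  pingouin. Bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9
  excellent. Translations are evaluated for the five planar protocols
  (15 axis-by-protocol instances); muscle forces for all six (36).

## What the synthetic experiments show — and what they do not

Passing the packaged campaign (3 generated specimens × 6 protocols × 3
repeats, ≈65–90 s on one CPU) demonstrates that the control *algorithm* —
the cascade/parallel sequencing, prior loading ratios, kinetic constraints
and distribution clamps — tracks all six motions accurately and
repeatably, and yields reliable muscle-force and translation outputs, on a
plausible mechanical stand-in with realistic sensor noise and
inter-specimen variability. It does not validate cadaver-specific effects:
real capsules are nonlinear and viscoelastic, real muscle paths wrap,
hydraulic actuators have their own dynamics (modelled here as ideal force
sources, consistent with a fast inner force loop), and real specimens
exhibit hysteresis the quasi-static protocol is designed to minimize.
Absolute force and translation magnitudes therefore inherit the reference
geometry's calibration and should be read as physiologically plausible,
not specimen-predictive.

## Numerical choices and degenerate inputs

- RK4 at dt = 5 ms; controller at every plant step; dt must be ≤ 20 ms.
- Gimbal lock raises an error when |sin(flexion)| ≥ 1 − 10⁻⁹.
- Pivot calibration solves the stacked linear system with `lstsq` and
  raises on rank deficiency (pure translation, or single-axis ambiguity),
  requiring ≥ 10 samples.
- ICC on an all-constant matrix returns estimate 1 with a degenerate-CI
  flag; fewer than 5 grid points or 2 repeats is an error.
- Campaign seeding: one root seed; `numpy.random.SeedSequence` spawns one
  child per specimen and one per trial, all below 2³¹.
- A trial aborting on dislocation/instability is recorded in the run
  manifest and excluded from evaluation; remaining repeats are still used.
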