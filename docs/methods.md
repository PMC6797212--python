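# Methods

`reflexgait` generates simulations of human walking *de novo*: no motion
data are tracked. A planar musculoskeletal model is driven by a reflex-based
gait controller, and the controller's free parameters (plus the initial
state) are found by single-shooting optimization of a task-level objective.
This note documents the model, the numerical methods, the design choices
made where the design was genuinely open, and what the shipped synthetic
fixtures can and cannot validate.

## Musculoskeletal model

The model is a sagittal-plane adult (1.8 m, 75.16 kg) with nine mobile
degrees of freedom: a 3-DOF planar joint between pelvis and ground, and per
leg a pin hip, a 1-DOF knee, and a pin ankle. The lumbar joint is locked at
5° of flexion, so pelvis, torso, head and arms are lumped into one trunk
body. Conventions: x forward, y up, ground at y = 0; flexion positive at
hip and knee, dorsiflexion positive at ankle, pelvis tilt positive =
anterior; radians internally, degrees at file boundaries.

Segment masses and inertias are Winter-style anthropometric values scaled
to the model's stature; muscle parameters (maximum isometric force F_max,
optimal fiber length l_opt, tendon slack length) are adapted from the
widely used planar 9-muscle-per-leg lower-limb gait models. Both are
shipped as an editable YAML table (`data/default_model.yaml`) and are
documented approximations, not asserted reference values. The knee is a
pure pin by default; a coupled tibiofemoral translation can be specified as
a polynomial of knee angle in the model file (the dynamics include the
corresponding motion-subspace terms).

Eighteen Hill-type muscle–tendon units (nine per leg: GMAX, HAMS, ILPSO,
RF, VAS, BFSH, GAS, SOL, TA) actuate the model. Muscle paths are affine (or
optionally polynomial) functions of the spanned joint angles with
coefficients in the model file; moment arms are the analytic derivatives,
so the tendon-excursion identity r = −∂L/∂θ holds exactly.

**Deficit transforms.** Weakness scales F_max to 25% / 12.5% / 6.25%
(mild/moderate/severe); contracture scales l_opt to 85% / 70% / 55%.
Transforms are applied bilaterally to SOL, GAS, or both plantarflexors
(PF), always relative to the stored unimpaired value (severity chains do
not compound), yielding 18 deficit cases. Reducing l_opt raises the
normalized fiber length at a given posture, which raises passive fiber
force — the mechanical signature of contracture.

## Muscle–tendon dynamics

Fibers are zero-pennation (paths are straight lines between lumped
attachment effects) in series with an elastic tendon. Curve families are
smooth closed forms with coefficients in `mtu.py`:

- active force–length: Gaussian `exp(−(l̃−1)²/γ)`, γ = 0.08 (negligible
  force below l̃ ≈ 0.5);
- passive force–length: exponential, zero below l̃ = 1, reaching the
  per-muscle scale at 60% strain; HAMS/VAS/RF ship with scale 0.5 to reduce
  their passive forces;
- force–velocity: Hill hyperbola on the shortening side (zero at
  −v_max = −15 l_opt/s, one at zero) and a saturating eccentric branch with
  plateau 1.4 and matched slope at v = 0 — both branches invertible in
  closed form;
- tendon: exponential force–strain normalized to carry exactly F_max at
  the characteristic strain (4.9% for most muscles; 10% for SOL and GAS,
  whose long compliant tendons matter for gait economics).

Activation follows first-order dynamics with τ_act = 10 ms and
τ_deact = 40 ms; the exact exponential update is used over each control
interval, so sub-stepping is consistent to machine precision. Excitations
are floored at 0.01 before the activation dynamics (configurable) to avoid
the singular fully-off state.

**Fiber-state integration.** The elastic-tendon fiber ODE is stiff (the
tendon is orders of magnitude stiffer than the fiber). Rather than forcing
an explicit integrator through that stiffness, the fiber length is advanced
once per control interval by a backward-Euler equilibrium solve: find l_m
such that fiber force — with the force–velocity multiplier evaluated at the
implied velocity (l_m − l_m,prev)/Δt — balances tendon force at the new
MTU length. The solve is reformulated in normalized tendon force using the
log-form tendon inverse, which makes the residual well-conditioned
(safeguarded vectorized Newton, tolerance 1e−9, typically < 10 iterations).
Within the interval the skeleton sees the tendon force implied by the
frozen fiber length and the instantaneous geometry, i.e. the tendon
responds elastically at full rate while the fiber moves at the control
rate. The same solver with Δt → ∞ gives the static equilibrium used to
initialize muscle states (`equilibrate`).

## Metabolic energetics

Per-muscle gross metabolic rate follows the Umberger-family model with the
later modifications: activation + maintenance heat (fiber-type weighted,
scaled by the active force–length multiplier above optimal length),
shortening/lengthening heat, and positive fiber mechanical work; eccentric
work is not credited back, and the total is clamped non-negative. Muscle
mass is estimated from the *unimpaired* F_max (specific tension 0.25 MPa,
density 1059.7 kg/m³), so modelled weakness does not change muscle mass.
Defaults: 50% slow-twitch everywhere, aerobic scale 1.5, and a whole-body
basal rate of 1.2 W/kg added at the model level (the basal constant is not
part of the per-muscle model and is exposed in `mtu.py`).

## Contact, ligaments, and multibody dynamics

Each foot has one heel sphere (r = 5 cm) and two toe spheres (r = 2.5 cm).
Normal force is Hunt–Crossley: Hertz term (4/3)·E*·√R·x^{3/2} times
(1 + 1.5·c·ẋ) floored at zero, with plane-strain modulus
E* = 500,000 N/m², dissipation c = 1.0 s/m (the 1.5 factor is the standard
Hunt–Crossley dissipation coefficient and lives in the model file).
Friction is smoothed Coulomb, μ_static = μ_dynamic = 0.8, viscous 0,
`tanh` transition at 0.1 m/s. This is deliberately soft contact; it speeds
simulation but produces low-frequency GRF oscillation at very slow speeds.

Joint range limits (hip −30…120°, knee 0…140°, ankle −40…20° with
dorsiflexion positive) are enforced by exponential limit springs
("ligaments"): zero inside the range, torque K·(e^{c·excess} − 1) beyond
it (K = 10 N·m, c = 20 rad⁻¹ defaults). These torques feed the injury term
of the objective.

The equations of motion are assembled numerically per evaluation with
planar spatial algebra over the fixed 9-DOF tree: composite-rigid-body for
the mass matrix and recursive Newton–Euler for bias and external forces.
Two algebraically identical implementations exist: a readable numpy
reference and a scalar fast path used in the rollout loop; tests assert
their agreement to 1e−9. The base is modelled as slider-x → slider-y →
revolute through massless bodies, keeping every joint single-DOF.

**Skeleton integration.** Within each 5 ms control interval the skeleton
states are advanced by classical RK4 with fixed substeps. The stiffest
in-stance mode is the smoothed-friction stick dynamics, with eigenvalue
≈ μ·f_n/(m_foot·v_transition); the substep count adapts to the current
normal load so this mode stays inside the RK4 stability region (5 substeps
unloaded, up to 40 under peak load). Energy and momentum audits back this
choice: a passive-pendulum reduction conserves energy to ~1e−8 % over 5 s
(integrated separately with an error-controlled integrator at rtol 1e−8),
and on full rollouts the change in whole-body momentum matches the
integral of gravity plus ground reactions to well under 1% per second.

**Initialization.** Pelvis x starts at 0. Seven joint angles and nine
generalized speeds come from the 16 free initial-state design variables;
pelvis height is then solved (bracketing + Brent) so the static vertical
GRF equals half body weight (≈ 368.6 N for this model). Muscle states are
equilibrated at activations equal to the controller's initial excitations
(one fixed-point pass: equilibrate at a nominal activation, query the
controller, re-equilibrate).

**Fall detection.** Integration stops early when the whole-body COM height
drops below 0.8 × its initial value, recording t_fall; the criterion is
checked at every control step.

## Reflex controller

Five phases per leg — early stance (ES), mid-stance (MS), pre-swing (PS),
swing (S), landing preparation (LP) — advance cyclically. Four transitions
are threshold-gated (foot–pelvis horizontal distance for ES→MS and S→LP,
ipsilateral GRF magnitude for PS→S and LP→ES); MS→PS fires when the
contralateral leg is in ES. The foot–pelvis distance is measured from the
heel-sphere center to the pelvis origin, signed along +x. Initial phases
are inferred from the initial loading and foot placement.

Law kinds: constant (C), positive length (L+), velocity (V+) and force
(F+) feedback onto the same muscle, one negative force feedback SOL→TA
(F−), and pelvis-tilt PD restricted to ILPSO/GMAX/HAMS. Muscle length and
velocity are sensed as normalized fiber length and its rate; force as
tendon force over F_max. Delays are fixed per law by the most proximal
joint the target muscle spans (hip 5 ms, knee 10 ms, ankle 20 ms; 40 ms
for SOL→TA). Active-law contributions are summed and clamped to [0, 1]
(the combination rule is a documented choice; the floor is configurable).
Sensor histories are buffered at the 5 ms control rate with linear
interpolation; before t = 0 the buffer returns the initial values. All
delays in the default topology are integer multiples of the control step.

The law-to-muscle-to-phase wiring is data, not code
(`data/default_controller.yaml`): the default topology follows the
Geyer–Herr tradition (stance leg: trunk PD + VAS/SOL/GAS force feedback +
TA length feedback with SOL→TA suppression; swing: ILPSO/HAMS/BFSH length
and velocity feedback with small constants) instantiated per phase so that
the census is exactly 70 gain/offset parameters plus 4 thresholds. The
shipped values are plausible hand-set starting guesses for optimization,
not a validated walking solution. With the 16 initial-state values the
full design vector has 90 entries.

## Objective

J = w_cot·J_cot + w_spd·J_spd + w_inj·J_inj + w_head·J_head, with
w_cot = 1 kg·m/J, w_spd = 10,000 s⁻¹, w_inj = 0.1 (N·m)⁻²s⁻¹,
w_head = 0.25 s³/m².

- **J_cot**: time integral of gross metabolic rate (basal + muscles) over
  mass × distance travelled (COM forward displacement), J/(kg·m).
- **J_spd**: per-step speed penalty. A step's credit is
  v_pen = max(0, 1 m/s − Ψ(v_s, v_min, v_max)), zeroed entirely if the
  rollout fell; Ψ is the linear out-of-range penalty. Credits are weighted
  by step duration and normalized:
  J_spd = 1 − Σ_s t_s·v_pen/(t_des·1 m/s). This normalization is chosen to
  reproduce the two boundary conditions that define the term — 0 for a
  completed rollout whose in-range steps cover the simulation, 1 for an
  immediate fall — and is isolated behind `objective.j_spd`. Prescribed
  mode uses v_target ± 0.05 m/s; self-selected mode v_min = 0.75 m/s with
  no upper bound.
- **J_inj**: ∫ Σ_j T_j² dt over the ligament torques.
- **J_head**: ∫ [Ψ(a_x)² + Ψ(a_y)²] dt with bounds ±0.25 g (horizontal)
  and ±0.50 g (vertical), g = 9.80665 m/s², at a head point 0.68 m above
  the pelvis on the trunk (configurable; its exact height is a modelling
  choice).

All integrals are trapezoidal on the output grid. Inside the shooting
optimizer the COM displacement is floored at 0.001 m when computing J_cot so
that candidates that stand still or fall in place receive a finite, heavily
penalized cost instead of an exception; `objective.j_cot` itself raises on
non-positive distance.

## Shooting optimization

CMA-ES (rank-one + rank-μ covariance update, cumulative step-size
adaptation, Hansen's default constants) is implemented in
`shooting_optimizer.py`; it operates in coordinates scaled by the
per-parameter initial SDs and handles box constraints by resampling (clip
fallback after 50 draws). λ = 16 and μ = 8 by default. Candidates that
raise during rollout score a failure constant (1e7); a generation in which
every candidate fails aborts the run. Fixed seeds make runs bit-for-bit
reproducible; the restart protocol runs sets of parallel optimizations
from the same seed point, takes the set best, re-seeds the next set, and
stops when the set best improves by less than 5%. Protocol presets mirror
the full study settings (prescribed speed: t_des = 10 s, 20 runs, 3000
generations, speeds 0.50–2.00 m/s at 0.25 m/s steps seeded outward from
1.25 m/s; self-selected: t_des = 30 s, 10 runs, 1500 generations; deficit
chains seeded unimpaired → mild → moderate → severe) plus reduced `desk-*`
presets (λ = 8, ≤ 50 generations, t_des = 5 s) sized for one workstation
CPU.

The search landscape is dominated by a cliff: any rollout that falls has
J_spd = 1 regardless of when it fell, so J ≈ 10,000 for every falling
candidate and the remaining gradient (cost of transport, injury, head
terms) mainly rewards falling later, cheaper and further. Crossing from
"falls eventually" to "walks for the full horizon" is what the full-size
protocol's thousands of generations and parallel restarts pay for; the
desk-scale presets demonstrate the machinery and the early-phase descent,
not converged gait.

A reduced-scale optimized parameter set is packaged as
`data/pretrained_self_selected.json` (loader:
`shooting_optimizer.pretrained_design_vector`). It was produced with the
package's own CMA-ES at workstation scale using a shaped schedule: optimize
at a 1 s horizon first (where the hand-set defaults already complete with a
step), then grow the horizon, with a survival bonus (100 J per simulated
second) added to the *training* objective to give the optimizer a gradient
across the fall plateau. The packaged metadata records its performance
under the real, unshaped objective: it completes a 5 s rollout upright
(travelling ~0.9 m, essentially a stabilized stand after an initial step;
J ≈ 10,081 because standing earns no step credit). It demonstrates that
desk-scale optimization can cross from "falls" to "stays upright", and it
is a useful seed and demo — not converged walking, which remains a
full-protocol (cluster-scale) outcome.

## Gait analysis

Contacts and lifts are detected from per-foot vertical GRF crossing 1% of
body weight with a 3-sample debounce (flips are backdated to the first
crossing sample). Steps run contact-to-contact across feet; cycles
contact-to-contact on the same foot; the first two steps are excluded from
all summaries. Step speed and step length use COM forward displacement
over the step (for steady planar gait this equals the fore–aft distance
between successive contact points on average). Cycle-normalized
trajectories are linearly resampled to 101 points (every 1% of the cycle)
and averaged over included cycles.

Comparison metrics: RMSE in SD units is the root-*mean*-square of
per-sample Z-scores against a normative mean ± SD band (the mean, not the
sum, keeps the metric scale-free in the number of samples); NCC is the
zero-lag Pearson correlation of mean-centered trajectories (cycles are
already aligned, so no lag search); scalar measures are compared as
Z-scores with |Z| strictly greater than 2 flagged (a round-off guard of
1e−9 relative is applied at the boundary). Peak measures are defined on
the mean cycle, not as averaged per-cycle extrema.

**Synthetic normative bands.** Reference pediatric/adult gait datasets are
not redistributable, so `make_normative_fixture` generates smooth,
gait-like mean ± SD bands: sinusoid mixtures with stance/swing phase
structure (toe-off near 62%), strictly positive SD, deterministic per
seed, plus scalar bands (speed 1.25 ± 0.15 m/s, stance 62 ± 3%, cadence
113 ± 9 steps/min, ...). They exercise the metric pipeline end-to-end —
resampling, banding, Z-scoring — and nothing more: passing tests against
them shows the *analysis* is correct, not that simulated gait matches
human data. Users comparing against real data must also handle their
dataset's conventions (e.g. pelvis-orientation offsets in hip-angle
definitions), which the fixture deliberately ignores.

## Problem sizes used by the tests and the acceptance script

Chosen to exercise every pathway at workstation scale: rollouts of 2–5 s at
the 5 ms control rate; the reduced end-to-end optimization uses λ = 8,
μ = 4, 20–30 generations and t_des = 5 s from a uniformly drawn feasible
design vector; property tests use 100–1000 random draws; the CMA-ES
correctness check solves a 10-D sphere with λ = 16, μ = 8 in ≤ 200
generations. Full-protocol runs (days of CPU) are exposed through the
presets and run configs but are not executed by the test suite.

## Known limitations

- Planar: no hip ab/adduction, pelvis list/rotation, or trunk DOFs; foot
  clearance must come from sagittal compensations.
- The default controller values are a starting guess; desk-scale
  optimization demonstrably improves them but does not converge to
  validated walking — converged gait needs the full-size protocol.
- Zero pennation and straight-line paths overestimate fiber length change
  for some muscles; v_max = 15 l_opt/s partially compensates.
- The fiber state advances at the control rate (backward Euler); force
  transients faster than ~5 ms are carried by the tendon elasticity alone.
- Soft contact trades GRF fidelity at very slow speeds for simulation
  speed.
- The Eq-style speed-penalty normalization and the law-wiring of the
  default topology are documented reconstructions where the underlying
  conventions admit more than one reading; both are isolated behind single
  functions/data files.
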