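# reflexgait

Predictive simulation of human walking for studying muscle deficits.

Clinically common deficits of the ankle plantarflexors — weakness (reduced
maximum isometric force) and contracture (reduced optimal fiber length,
hence abnormally high passive stiffness) — co-occur with other impairments
in conditions such as cerebral palsy, stroke and sarcopenia, which makes
their individual contribution to gait pathology hard to isolate
experimentally. `reflexgait` attacks the question *in silico*: it generates
walking **de novo** (no motion tracking), so an isolated deficit can be
introduced into the model and the gait the optimizer discovers is a
prediction of how a walker adapts to that deficit alone.

The framework, for biomechanists and motor-control researchers:

- a **planar musculoskeletal model** — 9 degrees of freedom (3-DOF
  pelvis–ground planar joint, pin hips/ankles, 1-DOF knees, lumbar locked at
  5° flexion) actuated by 18 Hill-type muscle–tendon units (GMAX, HAMS,
  ILPSO, RF, VAS, BFSH, GAS, SOL, TA per leg), compliant Hunt–Crossley
  foot–ground contact and nonlinear joint-limit ligaments;
- a **reflex-based gait controller** — a 5-phase state machine per leg
  (early stance, mid-stance, pre-swing, swing, landing preparation) gating
  delayed proprioceptive laws
  `u_C = K_C`, `u_L+ = max(0, K_L+[l(t−t_D) − l_o])`,
  `u_V+ = max(0, K_V+ v(t−t_D))`, `u_F± = ±K_F± F(t−t_D)`,
  `u_PD = K_p[θ(t−t_D) − θ_o] + K_v θ̇(t−t_D)`,
  with 70 free gains/offsets plus 4 phase-transition thresholds;
- a **single-shooting optimizer** — CMA-ES (λ = 16, μ = 8, rank-μ update,
  in-package implementation) over the 90 design variables (74 controller +
  16 initial-state), minimizing

  `J = w_cot·J_cot + w_spd·J_spd + w_inj·J_inj + w_head·J_head`

  (gross cost of transport; per-step speed-range/fall penalty; squared
  ligament torque integral; out-of-band head acceleration integral), with a
  parallel-restart protocol and solution-seeding chains across speeds and
  deficit severities;
- **deficit transforms** — weakness scales F_max to 25/12.5/6.25%,
  contracture scales l_opt to 85/70/55%, applied bilaterally to SOL, GAS or
  both plantarflexors (18 cases);
- a **gait-analysis layer** — step/cycle segmentation from GRFs,
  spatiotemporal measures, 101-point cycle normalization, RMSE in SD units,
  normalized cross-correlation, and Z-score panels against normative bands
  (synthetic band generator included; real reference datasets are not
  redistributed).

See `docs/methods.md` for the model equations, numerical methods and design
rationale.

## Worked example

Validate the model and inspect a deficit transform:

```sh
$ reflexgait validate
mobile_dof: 9
muscles: 18
contact_spheres: 6
segments: 4
total_mass_kg: 75.16
OK

$ reflexgait controller lint
43 law instances
70 gain/offset parameters
4 transition thresholds
census OK
```

Severe plantarflexor weakness retains 6.25% of the unimpaired maximum
isometric force on both muscles of both legs:

```python
>>> from reflexgait.msk_model import build_default_model, DeficitSpec, apply_deficit
>>> model = build_default_model()
>>> weak = apply_deficit(model, DeficitSpec("PF", "weakness", "severe"))
>>> model.muscles["SOL_l"].f_max_iso_n, weak.muscles["SOL_l"].f_max_iso_n
(3549.0, 221.8125)
>>> model.muscles["GAS_l"].f_max_iso_n, weak.muscles["GAS_l"].f_max_iso_n
(2241.0, 140.0625)
```

Simulate a rollout with the shipped (hand-set, unoptimized) controller
values and score it:

```python
>>> from reflexgait.planar_dynamics import PlanarModel, rollout
>>> from reflexgait.reflex_controller import GaitController, ControllerTopology
>>> from reflexgait import objective as obj, shooting_optimizer as so
>>> pm = PlanarModel(model)
>>> topology = ControllerTopology.from_yaml()
>>> init = so.DesignVector.default(topology).split()[1]  # 16 initial states
>>> traj = rollout(pm, GaitController(topology), init, t_des=2.0)
>>> traj.termination, traj.t_fall
('fell', 1.13)
>>> b = obj.evaluate(traj, obj.SpeedSpec.self_selected(), distance_floor_m=0.001)
>>> round(b.j_total, 1), round(b.j_cot_raw, 3), b.j_spd_raw
(11853.1, 13.497, 1.0)
```

The model takes a step, travels 1.09 m and falls at 1.13 s: any fall zeroes
all step credit, so J_spd = 1 and J is dominated by `w_spd = 10,000`
(here with a large knee-ligament injury term from the hard landing). This is the
landscape the shooting optimization descends — the default values are a
starting guess, and finding converged walking takes the full-size protocol
(`protocol_presets()["self-selected"]`: 30 s rollouts, 10 parallel runs,
1500 generations per restart set), a cluster-scale job. Desk-scale presets
(`desk-*`) run the identical machinery at reduced size.

A desk-scale optimized example solution ships with the package
(`shooting_optimizer.pretrained_design_vector()`); unlike the raw defaults
it completes a 5 s rollout upright:

```python
>>> dv = so.pretrained_design_vector(topology)
>>> from reflexgait.reflex_controller import ControllerParams
>>> ctrl_vals, init_vals = dv.split()
>>> ctrl = GaitController(topology, ControllerParams(topology, ctrl_vals))
>>> traj = rollout(pm, ctrl, init_vals, t_des=5.0)
>>> traj.termination
'completed'
```

It stabilizes into a stand after an initial step (so it earns no step-speed
credit; see `docs/methods.md` for how it was produced and what it does and
does not demonstrate).

Optimize and analyze from the shell:

```sh
reflexgait optimize --preset desk-self-selected --seed 1 --out run/
reflexgait simulate --tdes 2 --out trajectory.sto
reflexgait analyze trajectory.sto
reflexgait fixtures --seed 0 --out normative/
```

Every run directory contains a config snapshot, per-generation CSV log,
best solution and replay seed; `reflexgait reproduce run/` re-executes it
and verifies the best objective value bit-for-bit.

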