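# Default reflex-controller topology and parameter values.
#
# The controller is leg-symmetric: every law is instantiated for both legs
# with shared parameters.  Five law kinds generate muscle excitations:
#   C   constant                        u = K
#   L+  positive length feedback        u = max(0, K*(l(t-tD) - l_o))
#   V+  positive velocity feedback      u = max(0, K*v(t-tD))
#   F+  positive force feedback         u = K*F(t-tD)
#   F-  negative force feedback         u = -K*F(t-tD)   (SOL -> TA only)
#   PD  pelvis-tilt proportional-derivative (ILPSO/GMAX/HAMS only)
#       u = kp*(theta(t-tD) - theta_o) + kv*thetadot(t-tD)
# Muscle length/velocity are sensed as normalized fiber length (l_opt units)
# and its rate (l_opt/s); force as tendon force / F_max; pelvis tilt in rad,
# positive anterior.  Neural delays are set per law from the most proximal
# joint spanned by the target muscle (hip 5 ms, knee 10 ms, ankle 20 ms;
# 40 ms for the SOL->TA force suppression).
#
# Phases: ES early stance, MS mid-stance, PS pre-swing, S swing, LP landing
# preparation.  Parameter census: 70 gains/offsets + 4 thresholds.
#
# Each parameter is [value, lower_bound, upper_bound, cma_initial_sd].
# Values are plausible hand-set defaults in the Geyer-Herr tradition; they
# are a starting guess for optimization, not asserted reference values.

control_dt_s: 0.005
history_capacity_s: 0.2

thresholds:
  es_to_ms_m:  [-0.02, -0.40, 0.30, 0.03]   # foot-pelvis dx falls below
  ps_to_s_n:   [50.0, 10.0, 400.0, 15.0]    # ipsilateral |GRF| falls below
  s_to_lp_m:   [-0.15, -0.30, 0.60, 0.03]     # foot-pelvis dx rises above
  lp_to_es_n:  [60.0, 20.0, 600.0, 15.0]    # ipsilateral |GRF| rises above

laws:
  # --- trunk balance: PD on pelvis tilt via hip muscles, per stance phase
  - {target: GMAX, kind: PD, phases: [ES],
     params: {kp: [5.0, 0.0, 8.0, 0.25], kv: [0.3, 0.0, 2.0, 0.1], theta_o: [0.09, -0.2, 0.3, 0.03]}}
  - {target: GMAX, kind: PD, phases: [MS],
     params: {kp: [5.0, 0.0, 8.0, 0.25], kv: [0.3, 0.0, 2.0, 0.1], theta_o: [0.09, -0.2, 0.3, 0.03]}}
  - {target: GMAX, kind: PD, phases: [PS],
     params: {kp: [5.0, 0.0, 8.0, 0.25], kv: [0.2, 0.0, 2.0, 0.1], theta_o: [0.09, -0.2, 0.3, 0.03]}}
  - {target: HAMS, kind: PD, phases: [ES],
     params: {kp: [3.0, 0.0, 8.0, 0.25], kv: [0.2, 0.0, 2.0, 0.1], theta_o: [0.09, -0.2, 0.3, 0.03]}}
  - {target: HAMS, kind: PD, phases: [MS],
     params: {kp: [3.0, 0.0, 8.0, 0.25], kv: [0.2, 0.0, 2.0, 0.1], theta_o: [0.09, -0.2, 0.3, 0.03]}}
  - {target: HAMS, kind: PD, phases: [PS],
     params: {kp: [3.0, 0.0, 8.0, 0.25], kv: [0.1, 0.0, 2.0, 0.1], theta_o: [0.09, -0.2, 0.3, 0.03]}}
  - {target: ILPSO, kind: PD, phases: [ES],
     params: {kp: [-2.0, -8.0, 0.0, 0.25], kv: [-0.3, -2.0, 0.0, 0.1], theta_o: [0.09, -0.2, 0.3, 0.03]}}
  - {target: ILPSO, kind: PD, phases: [MS],
     params: {kp: [-2.0, -8.0, 0.0, 0.25], kv: [-0.3, -2.0, 0.0, 0.1], theta_o: [0.09, -0.2, 0.3, 0.03]}}
  - {target: ILPSO, kind: PD, phases: [PS],
     params: {kp: [-1.0, -8.0, 0.0, 0.25], kv: [-0.2, -2.0, 0.0, 0.1], theta_o: [0.09, -0.2, 0.3, 0.03]}}

  # --- stance leg support and propulsion
  - {target: VAS, kind: C, phases: [ES], params: {K: [0.09, 0.0, 1.0, 0.05]}}
  - {target: VAS, kind: F+, phases: [ES], params: {K: [1.6, 0.0, 4.0, 0.2]}}
  - {target: VAS, kind: F+, phases: [MS], params: {K: [1.2, 0.0, 4.0, 0.2]}}
  - {target: VAS, kind: F+, phases: [PS], params: {K: [0.6, 0.0, 4.0, 0.2]}}
  - {target: SOL, kind: F+, phases: [ES], params: {K: [2.2, 0.0, 4.0, 0.2]}}
  - {target: SOL, kind: F+, phases: [MS], params: {K: [2.2, 0.0, 4.0, 0.2]}}
  - {target: SOL, kind: F+, phases: [PS], params: {K: [2.0, 0.0, 4.0, 0.2]}}
  - {target: GAS, kind: F+, phases: [ES], params: {K: [1.6, 0.0, 4.0, 0.2]}}
  - {target: GAS, kind: F+, phases: [MS], params: {K: [2.0, 0.0, 4.0, 0.2]}}
  - {target: GAS, kind: F+, phases: [PS], params: {K: [1.1, 0.0, 4.0, 0.2]}}
  - {target: RF, kind: F+, phases: [ES], params: {K: [0.3, 0.0, 4.0, 0.2]}}

  # --- ankle dorsiflexor: length feedback everywhere, stance suppression
  - {target: TA, kind: L+, phases: [ES], params: {K: [1.1, 0.0, 5.0, 0.25], l_o: [0.72, 0.4, 1.4, 0.05]}}
  - {target: TA, kind: L+, phases: [MS], params: {K: [1.1, 0.0, 5.0, 0.25], l_o: [0.72, 0.4, 1.4, 0.05]}}
  - {target: TA, kind: L+, phases: [PS], params: {K: [1.1, 0.0, 5.0, 0.25], l_o: [0.72, 0.4, 1.4, 0.05]}}
  - {target: TA, kind: L+, phases: [S], params: {K: [1.3, 0.0, 5.0, 0.25], l_o: [0.70, 0.4, 1.4, 0.05]}}
  - {target: TA, kind: L+, phases: [LP], params: {K: [1.3, 0.0, 5.0, 0.25], l_o: [0.70, 0.4, 1.4, 0.05]}}
  - {target: TA, kind: F-, source: SOL, phases: [ES], params: {K: [0.35, 0.0, 2.0, 0.1]}}
  - {target: TA, kind: F-, source: SOL, phases: [MS], params: {K: [0.35, 0.0, 2.0, 0.1]}}
  - {target: TA, kind: F-, source: SOL, phases: [PS], params: {K: [0.35, 0.0, 2.0, 0.1]}}

  # --- swing initiation and leg swing
  - {target: ILPSO, kind: C, phases: [PS], params: {K: [0.25, 0.0, 1.0, 0.05]}}
  - {target: BFSH, kind: C, phases: [PS], params: {K: [0.10, 0.0, 1.0, 0.05]}}
  - {target: RF, kind: L+, phases: [S], params: {K: [1.5, 0.0, 5.0, 0.25], l_o: [1.10, 0.4, 1.6, 0.05]}}
  - {target: ILPSO, kind: L+, phases: [S], params: {K: [3.0, 0.0, 5.0, 0.25], l_o: [0.65, 0.4, 1.4, 0.05]}}
  - {target: ILPSO, kind: V+, phases: [S], params: {K: [0.3, 0.0, 2.0, 0.1]}}
  - {target: BFSH, kind: L+, phases: [S], params: {K: [0.65, 0.0, 5.0, 0.25], l_o: [0.90, 0.4, 1.4, 0.05]}}
  - {target: BFSH, kind: V+, phases: [S], params: {K: [0.3, 0.0, 2.0, 0.1]}}
  - {target: GMAX, kind: C, phases: [S], params: {K: [0.05, 0.0, 1.0, 0.05]}}

  # --- landing preparation: decelerate the swing leg, pre-position the foot
  - {target: HAMS, kind: L+, phases: [S], params: {K: [0.65, 0.0, 5.0, 0.25], l_o: [0.85, 0.4, 1.4, 0.05]}}
  - {target: HAMS, kind: L+, phases: [LP], params: {K: [1.5, 0.0, 5.0, 0.25], l_o: [0.85, 0.4, 1.4, 0.05]}}
  - {target: HAMS, kind: V+, phases: [LP], params: {K: [0.3, 0.0, 2.0, 0.1]}}
  - {target: BFSH, kind: V+, phases: [LP], params: {K: [0.8, 0.0, 2.0, 0.1]}}
  - {target: GMAX, kind: C, phases: [LP], params: {K: [0.15, 0.0, 1.0, 0.05]}}
  - {target: VAS, kind: C, phases: [LP], params: {K: [0.20, 0.0, 1.0, 0.05]}}
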