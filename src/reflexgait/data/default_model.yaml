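# Default planar musculoskeletal model: an adult of ~1.8 m, 75.16 kg.
#
# 9 mobile degrees of freedom: a 3-DOF planar joint between pelvis and ground,
# 1-DOF pin hips and ankles, and 1-DOF knees with an optional coupled
# tibiofemoral translation (zero polynomial = pure pin by default).  The lumbar
# joint is locked at 5 deg of flexion, so the pelvis, torso, head and arms are
# lumped into a single trunk body.
#
# Segment inertial values are literature-based approximations (Winter-style
# anthropometry scaled to 75.16 kg / 1.8 m).  Muscle parameters are
# approximations adapted from the standard planar 9-muscle-per-leg lower-limb
# gait models; they are editable data, not asserted reference values.
#
# Units are encoded in field names.  Angles are degrees in this file and
# radians inside the library.

name: planar-adult-9dof
gravity_m_s2: 9.80665
height_m: 1.8

segments:
  trunk:
    mass_kg: 50.9586          # pelvis + torso + head + arms (lumbar locked)
    moment_of_inertia_kgm2: 2.50
    length_m: 0.80
    com_offset_m: 0.35        # above pelvis origin, along trunk axis
  femur:
    mass_kg: 7.5160
    moment_of_inertia_kgm2: 0.1318
    length_m: 0.41
    com_offset_m: 0.1775      # below hip, along femur axis
  tibia:
    mass_kg: 3.4949
    moment_of_inertia_kgm2: 0.0590
    length_m: 0.43
    com_offset_m: 0.1862
  foot:
    mass_kg: 1.0898
    moment_of_inertia_kgm2: 0.0166
    length_m: 0.26
    com_offset_m: 0.06        # forward of ankle, along foot axis
    com_drop_m: 0.04          # below ankle (foot axis is horizontal)

joints:
  ground_pelvis:
    kind: planar-3dof
    parent: ground
    child: trunk
  lumbar:
    kind: locked
    parent: pelvis
    child: torso
    locked_angle_deg: 5.0     # flexion; baked into the lumped trunk geometry
  hip:
    kind: pin-1dof
    parent: trunk
    child: femur
    location_in_parent_m: [0.0, -0.07]
    axis_sign: 1              # flexion positive
    range_limits_deg: [-30.0, 120.0]
  knee:
    kind: coupled-knee-1dof
    parent: femur
    child: tibia
    location_in_parent_m: [0.0, -0.41]
    axis_sign: -1             # flexion positive (shank rotates backward)
    range_limits_deg: [0.0, 140.0]
    # tibiofemoral translation as polynomial of knee angle (rad), meters:
    # [c1, c2, ...] -> x(q) = c1*q + c2*q^2 + ...   default: pure pin
    coupling_poly_x: []
    coupling_poly_y: []
  ankle:
    kind: pin-1dof
    parent: tibia
    child: foot
    location_in_parent_m: [0.0, -0.43]
    axis_sign: 1              # dorsiflexion positive
    range_limits_deg: [-40.0, 20.0]

head_point:
  segment: trunk
  location_m: [0.0, 0.68]     # near the center of the head, above pelvis origin

# MTU path model: L(q) = l_opt + l_tendon_slack + ref_length_offset_m
#                        + sum_j poly_j(theta_j)
# where poly_j(theta) = c1*theta + c2*theta^2 + ... (theta in rad) and the
# moment arm about joint j is -d(poly_j)/d(theta_j) (tendon-excursion
# identity).  Linear coefficients therefore equal minus the (constant)
# moment arm in the flexion/dorsiflexion-positive convention.
muscles:
  GMAX:
    f_max_iso_n: 1944.0
    l_opt_m: 0.157
    l_tendon_slack_m: 0.070
    tendon_strain_at_fmax: 0.049
    v_max_lopt_per_s: 15.0
    tau_act_s: 0.010
    tau_deact_s: 0.040
    passive_curve_scale: 1.0
    path:
      ref_length_offset_m: 0.0
      joints:
        hip: [0.062]          # extensor: moment arm -0.062 m
  HAMS:
    f_max_iso_n: 2594.0
    l_opt_m: 0.109
    l_tendon_slack_m: 0.310
    tendon_strain_at_fmax: 0.049
    v_max_lopt_per_s: 15.0
    tau_act_s: 0.010
    tau_deact_s: 0.040
    passive_curve_scale: 0.5  # reduced passive force-length curve
    path:
      ref_length_offset_m: 0.0
      joints:
        hip: [0.060]          # extensor
        knee: [-0.030]        # flexor: moment arm +0.030 m
  ILPSO:
    f_max_iso_n: 2342.0
    l_opt_m: 0.100
    l_tendon_slack_m: 0.160
    tendon_strain_at_fmax: 0.049
    v_max_lopt_per_s: 15.0
    tau_act_s: 0.010
    tau_deact_s: 0.040
    passive_curve_scale: 1.0
    path:
      ref_length_offset_m: 0.0
      joints:
        hip: [-0.050]         # flexor
  RF:
    f_max_iso_n: 1169.0
    l_opt_m: 0.075
    l_tendon_slack_m: 0.346
    tendon_strain_at_fmax: 0.049
    v_max_lopt_per_s: 15.0
    tau_act_s: 0.010
    tau_deact_s: 0.040
    passive_curve_scale: 0.5
    path:
      ref_length_offset_m: 0.0
      joints:
        hip: [-0.040]         # flexor
        knee: [0.042]         # extensor
  VAS:
    f_max_iso_n: 4530.0
    l_opt_m: 0.080
    l_tendon_slack_m: 0.157
    tendon_strain_at_fmax: 0.049
    v_max_lopt_per_s: 15.0
    tau_act_s: 0.010
    tau_deact_s: 0.040
    passive_curve_scale: 0.5
    path:
      ref_length_offset_m: 0.0
      joints:
        knee: [0.042]         # extensor
  BFSH:
    f_max_iso_n: 804.0
    l_opt_m: 0.173
    l_tendon_slack_m: 0.089
    tendon_strain_at_fmax: 0.049
    v_max_lopt_per_s: 15.0
    tau_act_s: 0.010
    tau_deact_s: 0.040
    passive_curve_scale: 1.0
    path:
      ref_length_offset_m: 0.0
      joints:
        knee: [-0.030]        # flexor
  GAS:
    f_max_iso_n: 2241.0
    l_opt_m: 0.090
    l_tendon_slack_m: 0.360
    tendon_strain_at_fmax: 0.10   # plantarflexor tendon: 10% strain at F_max
    v_max_lopt_per_s: 15.0
    tau_act_s: 0.010
    tau_deact_s: 0.040
    passive_curve_scale: 1.0
    path:
      ref_length_offset_m: 0.0
      joints:
        knee: [-0.020]        # flexor
        ankle: [0.050]        # plantarflexor: moment arm -0.050 m
  SOL:
    f_max_iso_n: 3549.0
    l_opt_m: 0.050
    l_tendon_slack_m: 0.250
    tendon_strain_at_fmax: 0.10
    v_max_lopt_per_s: 15.0
    tau_act_s: 0.010
    tau_deact_s: 0.040
    passive_curve_scale: 1.0
    path:
      ref_length_offset_m: 0.0
      joints:
        ankle: [0.050]        # plantarflexor
  TA:
    f_max_iso_n: 1579.0
    l_opt_m: 0.098
    l_tendon_slack_m: 0.223
    tendon_strain_at_fmax: 0.049
    v_max_lopt_per_s: 15.0
    tau_act_s: 0.010
    tau_deact_s: 0.040
    passive_curve_scale: 1.0
    path:
      ref_length_offset_m: 0.0
      joints:
        ankle: [-0.040]       # dorsiflexor

# Compliant sphere-plane contact, per foot (positions in the foot frame).
contact:
  plane_strain_modulus_n_m2: 500000.0
  dissipation_s_m: 1.0
  mu_static: 0.8
  mu_dynamic: 0.8
  mu_viscous: 0.0
  transition_velocity_m_s: 0.1
  hc_dissipation_factor: 1.5    # normal force = f_hertz * (1 + factor*c*xdot)
  spheres:
    heel: {radius_m: 0.050, location_m: [-0.050, -0.020]}
    toe_med: {radius_m: 0.025, location_m: [0.150, -0.045]}
    toe_lat: {radius_m: 0.025, location_m: [0.190, -0.045]}

# Nonlinear rotational limit springs, engaged beyond the joint range limits.
ligaments:
  torque_scale_nm: 10.0
  exp_rate_per_rad: 20.0
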