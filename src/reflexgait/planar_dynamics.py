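"""Planar multibody dynamics, muscle geometry, contact, and rollout.

The nine mobile degrees of freedom are ordered

    [pelvis_x, pelvis_y, pelvis_tilt, hip_l, hip_r, knee_l, knee_r,
     ankle_l, ankle_r]

with x forward, y up, angles in radians.  Sign conventions: flexion positive
at hip and knee, dorsiflexion positive at ankle, pelvis tilt positive =
anterior.  Ground plane is y = 0.

The equations of motion are assembled numerically with planar
composite-rigid-body (mass matrix) and recursive Newton-Euler (bias force)
algorithms over the fixed 9-DOF tree.  Foot-ground contact is a compliant
Hunt-Crossley sphere-plane model with smoothed Coulomb friction; joint range
limits are enforced by nonlinear exponential limit springs (the "ligaments").

Time integration during a rollout is a split scheme: the skeleton is advanced
by fixed-substep RK4 within each controller interval while muscle activations
use the exact exponential update and fiber lengths an implicit (backward
Euler) equilibrium update, which removes the stiffness of the elastic-tendon
fiber dynamics.  Rollouts terminate early when the whole-body center of mass
drops below 0.8 of its initial height (a fall).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from reflexgait import mtu
from reflexgait._spatial import (
    REVOLUTE,
    SLIDER_X,
    SLIDER_Y,
    JointModel,
    PlanarTree,
    compile_tree,
    fast_dynamics,
    fast_fk,
    rot,
    spatial_inertia,
)
from reflexgait.msk_model import (
    MOBILE_DOF_NAMES,
    MUSCLE_ORDER,
    ContactSphereSpec,
    LigamentConfig,
    ModelSpec,
)

JOINT_DOF_NAMES = MOBILE_DOF_NAMES[3:]  # hip_l .. ankle_r
GRAVITY_DEFAULT = 9.80665


class InitializationError(RuntimeError):
    """Raised when the initial pelvis height cannot satisfy the GRF condition."""


class SimulationError(RuntimeError):
    """Raised when the integrator fails; carries the last valid state."""

    def __init__(self, message: str, t: float, state: "SkeletalState"):
        super().__init__(message)
        self.t = t
        self.state = state


@dataclass
class SkeletalState:
    q: np.ndarray      # (9,)
    qdot: np.ndarray   # (9,)

    def copy(self) -> "SkeletalState":
        return SkeletalState(self.q.copy(), self.qdot.copy())


@dataclass
class Sensors:
    """Instantaneous sensor values handed to the gait controller."""

    time: float
    lm_norm: np.ndarray        # (18,) normalized fiber lengths
    vm_norm: np.ndarray        # (18,) normalized fiber velocities, lopt/s
    force_norm: np.ndarray     # (18,) tendon force / F_max
    pelvis_tilt: float         # rad, positive anterior
    pelvis_tilt_rate: float    # rad/s
    grf_mag: np.ndarray        # (2,) |GRF| per foot [l, r], N
    foot_pelvis_dx: np.ndarray  # (2,) heel-sphere-center x - pelvis x, m


@dataclass
class Trajectory:
    """Uniformly sampled simulation output."""

    t: np.ndarray                  # (n,)
    q: np.ndarray                  # (n, 9)
    qdot: np.ndarray               # (n, 9)
    excitations: np.ndarray        # (n, 18)
    activations: np.ndarray        # (n, 18)
    norm_fiber_lengths: np.ndarray  # (n, 18)
    muscle_forces: np.ndarray      # (n, 18)  tendon force, N
    grf: np.ndarray                # (n, 4)  [fx_l, fy_l, fx_r, fy_r], N
    joint_moments: np.ndarray      # (n, 6)  muscle+ligament moments, N*m
    ligament_torques: np.ndarray   # (n, 6)  N*m
    head_acc: np.ndarray           # (n, 2)  m/s^2
    metabolic_rate_w: np.ndarray   # (n,)  gross rate incl. basal, W
    com: np.ndarray                # (n, 2)
    phases: np.ndarray             # (n, 2)  controller phase codes per leg
    termination: str               # "completed" | "fell"
    t_fall: float | None
    t_des: float
    total_mass_kg: float
    dof_names: tuple[str, ...] = MOBILE_DOF_NAMES
    muscle_names: tuple[str, ...] = MUSCLE_ORDER

    @property
    def fell(self) -> bool:
        return self.termination == "fell"

    def grf_vertical(self, side: str) -> np.ndarray:
        return self.grf[:, 1] if side == "l" else self.grf[:, 3]

    def channel_frame(self):
        """All channels as a flat pandas DataFrame (for motion-table I/O)."""
        import pandas as pd

        cols: dict[str, np.ndarray] = {"time": self.t}
        for i, nm in enumerate(self.dof_names):
            cols[f"{nm}_rad" if i > 1 else f"{nm}_m"] = self.q[:, i]
        for i, nm in enumerate(self.dof_names):
            cols[f"{nm}_rate"] = self.qdot[:, i]
        for i, nm in enumerate(self.muscle_names):
            cols[f"exc_{nm}"] = self.excitations[:, i]
        for i, nm in enumerate(self.muscle_names):
            cols[f"act_{nm}"] = self.activations[:, i]
        for i, nm in enumerate(self.muscle_names):
            cols[f"force_{nm}_n"] = self.muscle_forces[:, i]
        for i, nm in enumerate(("grf_l_x_n", "grf_l_y_n", "grf_r_x_n", "grf_r_y_n")):
            cols[nm] = self.grf[:, i]
        for i, nm in enumerate(JOINT_DOF_NAMES):
            cols[f"moment_{nm}_nm"] = self.joint_moments[:, i]
        for i, nm in enumerate(JOINT_DOF_NAMES):
            cols[f"lig_{nm}_nm"] = self.ligament_torques[:, i]
        cols["head_acc_x_m_s2"] = self.head_acc[:, 0]
        cols["head_acc_y_m_s2"] = self.head_acc[:, 1]
        cols["metabolic_rate_w"] = self.metabolic_rate_w
        cols["com_x_m"] = self.com[:, 0]
        cols["com_y_m"] = self.com[:, 1]
        cols["phase_l"] = self.phases[:, 0].astype(float)
        cols["phase_r"] = self.phases[:, 1].astype(float)
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# standalone contact / ligament operations


def contact_force(depth: float, depth_rate: float, tangential_velocity: float,
                  sphere: ContactSphereSpec) -> tuple[float, float]:
    """Hunt-Crossley normal force with smoothed Coulomb friction.

    ``depth`` is sphere-plane penetration (m, positive into the ground) and
    ``depth_rate`` its time derivative.  Returns (tangential, normal) force in
    ground coordinates, zero when not penetrating.
    """
    if depth <= 0.0:
        return (0.0, 0.0)
    f_hertz = (4.0 / 3.0) * sphere.plane_strain_modulus_n_m2 \
        * math.sqrt(sphere.radius_m) * depth**1.5
    fn = f_hertz * (1.0 + sphere.hc_dissipation_factor
                    * sphere.dissipation_s_m * depth_rate)
    fn = max(fn, 0.0)
    ft = -fn * (sphere.mu_dynamic
                * math.tanh(tangential_velocity / sphere.transition_velocity_m_s)) \
        - sphere.mu_viscous * tangential_velocity * fn
    return (ft, fn)


def ligament_torque(angle_rad: float, limits_rad: tuple[float, float],
                    config: LigamentConfig | None = None) -> float:
    """Nonlinear rotational limit-spring torque; zero strictly inside limits."""
    cfg = config or LigamentConfig()
    lo, hi = limits_rad
    if angle_rad < lo:
        return cfg.torque_scale_nm * math.expm1(cfg.exp_rate_per_rad * (lo - angle_rad))
    if angle_rad > hi:
        return -cfg.torque_scale_nm * math.expm1(cfg.exp_rate_per_rad * (angle_rad - hi))
    return 0.0


# ---------------------------------------------------------------------------
# compiled model


class PlanarModel:
    """Numeric realization of a :class:`~reflexgait.msk_model.ModelSpec`.

    Compiles the segment tree, muscle-path coefficients, contact-sphere and
    ligament tables into flat arrays, and provides mass-matrix/bias dynamics,
    muscle geometry, state initialization and the rollout integrator.
    """

    #: body ordering of the internal tree (base chain + both legs)
    BODY_DOF = (0, 1, 2, 3, 5, 7, 4, 6, 8)   # dof index of each body
    DOF_BODY = (0, 1, 2, 3, 6, 4, 7, 5, 8)   # body index of each dof

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.g = spec.gravity_m_s2
        seg = spec.segments
        trunk, femur, tibia, foot = seg["trunk"], seg["femur"], seg["tibia"], seg["foot"]
        hip_loc = tuple(spec.joints["hip"].location_in_parent_m)
        knee_loc = tuple(spec.joints["knee"].location_in_parent_m)
        ankle_loc = tuple(spec.joints["ankle"].location_in_parent_m)
        knee = spec.joints["knee"]

        zero_I = np.zeros((3, 3))
        I_trunk = spatial_inertia(trunk.mass_kg, trunk.moment_of_inertia_kgm2,
                                  (0.0, trunk.com_offset_m))
        I_femur = spatial_inertia(femur.mass_kg, femur.moment_of_inertia_kgm2,
                                  (0.0, -femur.com_offset_m))
        I_tibia = spatial_inertia(tibia.mass_kg, tibia.moment_of_inertia_kgm2,
                                  (0.0, -tibia.com_offset_m))
        I_foot = spatial_inertia(foot.mass_kg, foot.moment_of_inertia_kgm2,
                                 (foot.com_offset_m, -foot.com_drop_m))

        def leg_joints():
            return [
                JointModel(REVOLUTE, hip_loc, spec.joints["hip"].axis_sign),
                JointModel(REVOLUTE, knee_loc, knee.axis_sign,
                           knee.coupling_poly_x, knee.coupling_poly_y),
                JointModel(REVOLUTE, ankle_loc, spec.joints["ankle"].axis_sign),
            ]

        joints = [
            JointModel(SLIDER_X), JointModel(SLIDER_Y),
            JointModel(REVOLUTE, (0.0, 0.0), -1.0),  # tilt positive = anterior
            *leg_joints(), *leg_joints(),
        ]
        parents = [-1, 0, 1, 2, 3, 4, 2, 6, 7]
        inertias = [zero_I, zero_I, I_trunk,
                    I_femur, I_tibia, I_foot, I_femur, I_tibia, I_foot]
        self.tree = PlanarTree(parents=parents, joints=joints,
                               inertias=inertias, gravity=self.g)
        self._comp = compile_tree(self.tree)
        self._fast = self._comp["simple"]
        self._body_dof = np.array(self.BODY_DOF)
        self._dof_body = np.array(self.DOF_BODY)
        self._body_mass = np.array([I[1, 1] for I in inertias])
        self._body_com = np.array(
            [[0, 0], [0, 0], [0.0, trunk.com_offset_m],
             [0.0, -femur.com_offset_m], [0.0, -tibia.com_offset_m],
             [foot.com_offset_m, -foot.com_drop_m],
             [0.0, -femur.com_offset_m], [0.0, -tibia.com_offset_m],
             [foot.com_offset_m, -foot.com_drop_m]])
        self.total_mass = float(self._body_mass.sum())

        # --- muscles -------------------------------------------------------
        self.muscle_names = MUSCLE_ORDER
        ms = [spec.muscles[nm] for nm in self.muscle_names]
        self.mus_params = ms
        self.f_max = np.array([m.f_max_iso_n for m in ms])
        self.l_opt = np.array([m.l_opt_m for m in ms])
        self.l_slack = np.array([m.l_tendon_slack_m for m in ms])
        self.eps0 = np.array([m.tendon_strain_at_fmax for m in ms])
        self.v_max = np.array([m.v_max_lopt_per_s for m in ms])
        self.tau_act = np.array([m.tau_act_s for m in ms])
        self.tau_deact = np.array([m.tau_deact_s for m in ms])
        self.pas_scale = np.array([m.passive_curve_scale for m in ms])
        self.mus_mass = np.array([mtu.muscle_mass_kg(m) for m in ms])
        self._dof_index = {nm: i for i, nm in enumerate(MOBILE_DOF_NAMES)}
        # linear path fast path: L = L0 + C @ q[3:9]
        self._path_linear = all(
            all(len(c) <= 1 for c in m.path.joint_coeffs.values()) for m in ms)
        self.L0 = np.array([m.path.ref_length_m for m in ms])
        C = np.zeros((18, 6))
        for i, m in enumerate(ms):
            for jname, coeffs in m.path.joint_coeffs.items():
                if coeffs:
                    C[i, self._dof_index[jname] - 3] = coeffs[0]
        self._C = C

        # --- contact -------------------------------------------------------
        spheres = list(spec.contact.values())
        self.spheres = spheres
        self._sph_body = np.array(
            [5 if s.segment.endswith("_l") else 8 for s in spheres])
        self._sph_loc = np.array([s.location_m for s in spheres])
        self._sph_r = np.array([s.radius_m for s in spheres])
        self._sph_E = np.array([s.plane_strain_modulus_n_m2 for s in spheres])
        self._sph_c = np.array([s.dissipation_s_m for s in spheres])
        self._sph_kd = np.array([s.hc_dissipation_factor for s in spheres])
        self._sph_mud = np.array([s.mu_dynamic for s in spheres])
        self._sph_muv = np.array([s.mu_viscous for s in spheres])
        self._sph_vt = np.array([s.transition_velocity_m_s for s in spheres])
        self._sph_left = np.array([s.segment.endswith("_l") for s in spheres])
        self._heel_idx = {
            "l": next(i for i, s in enumerate(spheres)
                      if s.name.startswith("heel") and s.segment.endswith("_l")),
            "r": next(i for i, s in enumerate(spheres)
                      if s.name.startswith("heel") and s.segment.endswith("_r")),
        }

        # --- ligaments -----------------------------------------------------
        lims = []
        for jname in ("hip", "knee", "ankle"):
            lims.append(spec.joints[jname].range_limits_rad)
        # dof order hip_l, hip_r, knee_l, knee_r, ankle_l, ankle_r
        self._lig_lo = np.array([lims[0][0], lims[0][0], lims[1][0],
                                 lims[1][0], lims[2][0], lims[2][0]])
        self._lig_hi = np.array([lims[0][1], lims[0][1], lims[1][1],
                                 lims[1][1], lims[2][1], lims[2][1]])
        self.lig_cfg = spec.ligaments

        hp_seg, hp_loc = spec.head_point
        self._head_loc = np.array(hp_loc)

        # stiffest dynamics during stance: smoothed Coulomb stick, eigenvalue
        # ~ mu * f_n / (m_foot * v_transition); used for adaptive substepping
        self._foot_mass = float(foot.mass_kg)
        self._fric_mu = float(max(s.mu_dynamic for s in spheres))
        self._fric_vt = float(min(s.transition_velocity_m_s for s in spheres))

    # -- kinematic helpers --------------------------------------------------

    def _qb(self, q: np.ndarray) -> np.ndarray:
        return q[self._body_dof]

    def muscle_geometry(self, q: np.ndarray):
        """MTU lengths (18,) and moment arms (18, 6) at configuration q.

        Moment arm columns follow ``JOINT_DOF_NAMES``; the tendon-excursion
        identity ``r = -dL/dtheta`` holds analytically.
        """
        th = q[3:9]
        if self._path_linear:
            L = self.L0 + self._C @ th
            R = -self._C
            return L, R
        L = np.empty(18)
        R = np.zeros((18, 6))
        angles = {nm: q[self._dof_index[nm]] for nm in MOBILE_DOF_NAMES[3:]}
        for i, m in enumerate(self.mus_params):
            L[i] = m.path.length(angles)
            for jname in m.path.joint_coeffs:
                R[i, self._dof_index[jname] - 3] = m.path.moment_arm(
                    jname, angles[jname])
        return L, R

    def ligament_torques(self, q: np.ndarray) -> np.ndarray:
        """(6,) limit-spring torques at the leg joints."""
        th = q[3:9]
        cfg = self.lig_cfg
        below = np.clip(self._lig_lo - th, 0.0, None)
        above = np.clip(th - self._lig_hi, 0.0, None)
        return cfg.torque_scale_nm * (np.expm1(cfg.exp_rate_per_rad * below)
                                      - np.expm1(cfg.exp_rate_per_rad * above))

    def _contact(self, q: np.ndarray, qdot: np.ndarray):
        """Contact forces: per-sphere world forces + application points.

        Returns (forces (m,2), points (m,2), f_ext list for the tree, grf (4,)).
        """
        if self._fast:
            qb, qdb = q[self._body_dof], qdot[self._body_dof]
            fk = fast_fk(self._comp, qb, qdb)
            f_ext, grf, forces, points = self._contact_from_fk(fk)
            f_ext_arr = [None if f is None else np.array(f) for f in f_ext]
            return forces, points, f_ext_arr, grf
        return self._contact_reference(q, qdot)

    def _contact_from_fk(self, fk):
        """Scalar-path contact evaluation from a fast_fk result."""
        ang, px, py, w, vwx, vwy, _ = fk
        nsph = len(self.spheres)
        forces = np.zeros((nsph, 2))
        points = np.zeros((nsph, 2))
        f_ext: list = [None] * self.tree.n
        grf = np.zeros(4)
        for k in range(nsph):
            b = self._sph_body[k]
            c, s = math.cos(ang[b]), math.sin(ang[b])
            lx, ly = self._sph_loc[k]
            lwx = c * lx - s * ly
            lwy = s * lx + c * ly
            cy = py[b] + lwy
            depth = self._sph_r[k] - cy
            if depth <= 0.0:
                continue
            cx = px[b] + lwx
            wb = w[b]
            vcx = vwx[b] - wb * lwy
            vcy = vwy[b] + wb * lwx
            f_h = (4.0 / 3.0) * self._sph_E[k] * math.sqrt(self._sph_r[k]) * depth**1.5
            fn = f_h * (1.0 - self._sph_kd[k] * self._sph_c[k] * vcy)
            if fn < 0.0:
                fn = 0.0
            vt = vcx + wb * self._sph_r[k]
            ft = -fn * (self._sph_mud[k] * math.tanh(vt / self._sph_vt[k])
                        + self._sph_muv[k] * vt)
            forces[k, 0], forces[k, 1] = ft, fn
            points[k, 0] = cx
            relx = cx - px[b]
            rely = -py[b]
            tau = relx * fn - rely * ft
            fbx = c * ft + s * fn
            fby = -s * ft + c * fn
            if f_ext[b] is None:
                f_ext[b] = [tau, fbx, fby]
            else:
                f_ext[b][0] += tau
                f_ext[b][1] += fbx
                f_ext[b][2] += fby
            if self._sph_left[k]:
                grf[0] += ft
                grf[1] += fn
            else:
                grf[2] += ft
                grf[3] += fn
        return f_ext, grf, forces, points

    def _contact_reference(self, q: np.ndarray, qdot: np.ndarray):
        qb, qdb = self._qb(q), qdot[self._body_dof]
        Es, rs, ang, pos = self.tree.kinematics(qb)
        vs = self.tree.body_velocities(qb, qdb, Es, rs)
        forces = np.zeros((len(self.spheres), 2))
        points = np.zeros((len(self.spheres), 2))
        f_ext = [None] * self.tree.n
        grf = np.zeros(4)
        for k in range(len(self.spheres)):
            b = self._sph_body[k]
            Rb = rot(ang[b])
            loc_w = Rb @ self._sph_loc[k]
            c = pos[b] + loc_w
            depth = self._sph_r[k] - c[1]
            if depth <= 0.0:
                continue
            w = vs[b][0]
            v_origin = Rb @ vs[b][1:]
            v_c = v_origin + w * np.array([-loc_w[1], loc_w[0]])
            depth_rate = -v_c[1]
            f_h = (4.0 / 3.0) * self._sph_E[k] * math.sqrt(self._sph_r[k]) * depth**1.5
            fn = f_h * (1.0 + self._sph_kd[k] * self._sph_c[k] * depth_rate)
            if fn < 0.0:
                fn = 0.0
            vt = v_c[0] + w * self._sph_r[k]   # material point at the ground
            ft = -fn * (self._sph_mud[k] * math.tanh(vt / self._sph_vt[k])
                        + self._sph_muv[k] * vt)
            Fw = np.array([ft, fn])
            pw = np.array([c[0], 0.0])
            forces[k] = Fw
            points[k] = pw
            rel = pw - pos[b]
            tau = rel[0] * Fw[1] - rel[1] * Fw[0]
            fb = np.array([tau, *(Rb.T @ Fw)])
            f_ext[b] = fb if f_ext[b] is None else f_ext[b] + fb
            if self._sph_left[k]:
                grf[0:2] += Fw
            else:
                grf[2:4] += Fw
        return forces, points, f_ext, grf

    # -- dynamics -----------------------------------------------------------

    def mass_matrix(self, q: np.ndarray) -> np.ndarray:
        Mb = self.tree.crba(self._qb(q))
        return Mb[np.ix_(self._dof_body, self._dof_body)]

    def bias_forces(self, q: np.ndarray, qdot: np.ndarray, f_ext=None) -> np.ndarray:
        """h(q, qdot) - J^T f_ext in DOF order (RNEA at qdd = 0)."""
        taub = self.tree.rnea(self._qb(q), qdot[self._body_dof],
                              np.zeros(9), f_ext)
        return taub[self._dof_body]

    def forward_dynamics(self, q: np.ndarray, qdot: np.ndarray,
                         tau: np.ndarray | None = None,
                         contact: bool = True, ligaments: bool = True,
                         locked: tuple[int, ...] = ()):
        """Generalized accelerations, optionally with locked DOFs.

        ``tau`` is an additional generalized force (9,), e.g. muscle moments.
        Returns (qdd (9,), grf (4,)).
        """
        tau9 = np.zeros(9) if tau is None else np.asarray(tau, dtype=float)
        if ligaments:
            tl = self.ligament_torques(q)
            tau9 = tau9.copy()
            tau9[3:9] += tl
        if self._fast and not locked:
            qb, qdb = q[self._body_dof], qdot[self._body_dof]
            if contact:
                fk = fast_fk(self._comp, qb, qdb)
                f_ext, grf, _, _ = self._contact_from_fk(fk)
            else:
                f_ext, grf = None, np.zeros(4)
            qdd_b, _, _ = fast_dynamics(self._comp, qb, qdb, f_ext,
                                        tau9[self._body_dof])
            return qdd_b[self._dof_body], grf
        if contact:
            _, _, f_ext, grf = self._contact(q, qdot)
        else:
            f_ext, grf = None, np.zeros(4)
        bias = self.bias_forces(q, qdot, f_ext)
        M = self.mass_matrix(q)
        rhs = tau9 - bias
        qdd = np.zeros(9)
        if locked:
            free = [i for i in range(9) if i not in locked]
            qdd[free] = np.linalg.solve(M[np.ix_(free, free)], rhs[free])
        else:
            qdd = np.linalg.solve(M, rhs)
        return qdd, grf

    # -- observers ----------------------------------------------------------

    def com(self, q: np.ndarray) -> np.ndarray:
        qb = self._qb(q)
        _, _, ang, pos = self.tree.kinematics(qb)
        tot = np.zeros(2)
        for b in range(self.tree.n):
            if self._body_mass[b] == 0:
                continue
            tot += self._body_mass[b] * (pos[b] + rot(ang[b]) @ self._body_com[b])
        return tot / self.total_mass

    def momentum(self, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
        """Whole-body linear momentum (2,)."""
        qb, qdb = self._qb(q), qdot[self._body_dof]
        Es, rs, ang, pos = self.tree.kinematics(qb)
        vs = self.tree.body_velocities(qb, qdb, Es, rs)
        p = np.zeros(2)
        for b in range(self.tree.n):
            m = self._body_mass[b]
            if m == 0:
                continue
            w = vs[b][0]
            v_origin = rot(ang[b]) @ vs[b][1:]
            cw = rot(ang[b]) @ self._body_com[b]
            v_com = v_origin + w * np.array([-cw[1], cw[0]])
            p += m * v_com
        return p

    def total_energy(self, q: np.ndarray, qdot: np.ndarray) -> float:
        """Kinetic + gravitational potential energy (no springs/muscles)."""
        qb, qdb = self._qb(q), qdot[self._body_dof]
        Es, rs, ang, pos = self.tree.kinematics(qb)
        vs = self.tree.body_velocities(qb, qdb, Es, rs)
        E = 0.0
        for b in range(self.tree.n):
            E += 0.5 * vs[b] @ self.tree.inertias[b] @ vs[b]
            m = self._body_mass[b]
            if m:
                com_y = pos[b][1] + (rot(ang[b]) @ self._body_com[b])[1]
                E += m * self.g * com_y
        return float(E)

    def head_acceleration(self, q, qdot, qdd) -> np.ndarray:
        """World acceleration of the head point (on the trunk)."""
        phi = -q[2]                      # trunk world angle (tilt is CW-positive)
        phid, phidd = -qdot[2], -qdd[2]
        r = rot(phi) @ self._head_loc
        zxr = np.array([-r[1], r[0]])
        return np.array([qdd[0], qdd[1]]) + phidd * zxr - phid * phid * r

    def heel_positions(self, q: np.ndarray) -> np.ndarray:
        """(2, 2) world positions of the left and right heel sphere centers."""
        qb = self._qb(q)
        _, _, ang, pos = self.tree.kinematics(qb)
        out = np.zeros((2, 2))
        for i, side in enumerate(("l", "r")):
            k = self._heel_idx[side]
            b = self._sph_body[k]
            out[i] = pos[b] + rot(ang[b]) @ self._sph_loc[k]
        return out

    # -- muscle algebra -----------------------------------------------------

    def tendon_forces(self, L: np.ndarray, lm_norm: np.ndarray) -> np.ndarray:
        """Tendon forces (N) from MTU lengths and normalized fiber lengths."""
        strain = (L - lm_norm * self.l_opt - self.l_slack) / self.l_slack
        return mtu.tendon_force_from_strain(strain, self.f_max, self.eps0)

    def implicit_fiber_update(self, lm_prev: np.ndarray, L: np.ndarray,
                              act: np.ndarray, dt: float,
                              max_iter: int = 25, tol: float = 1e-9) -> np.ndarray:
        """Backward-Euler fiber-length update via force equilibrium.

        Solves, per muscle, fiber force (with force-velocity evaluated at the
        implied velocity (lm - lm_prev)/dt) equal to tendon force at the new
        configuration.  Safeguarded vectorized Newton with a bisection
        bracket; unconditionally stable for the stiff tendon.
        """
        # Solve in normalized tendon force F: the fiber length is the linear
        # map lm(F) = (L - ls*(1 + eps(F)))/lopt with eps the log-form tendon
        # inverse, so the exponential tendon never enters the residual and
        # Newton converges in a handful of iterations from any state.
        inv_dt = 1.0 / dt
        kt = mtu.TENDON_KT
        ekt = np.exp(kt) - 1.0
        ls_over_lopt = self.l_slack / self.l_opt

        def lm_of(F):
            eps = self.eps0 * np.log1p(F * ekt) / kt
            return (L - self.l_slack * (1.0 + eps)) / self.l_opt

        def dlm_dF(F):
            deps = self.eps0 * ekt / (kt * (1.0 + F * ekt))
            return -ls_over_lopt * deps

        def rho_and_deriv(F):
            lm = lm_of(F)
            vm = (lm - lm_prev) * inv_dt
            f_l = mtu.active_force_length(lm)
            f_p = mtu.passive_force_length(lm, self.pas_scale)
            f_v = mtu.force_velocity(vm, self.v_max)
            r = act * f_l * f_v + f_p - F
            d_lm = dlm_dF(F)
            d = (act * (mtu.active_force_length_deriv(lm) * f_v
                        + f_l * mtu.force_velocity_deriv(vm, self.v_max) * inv_dt)
                 + mtu.passive_force_length_deriv(lm, self.pas_scale)) * d_lm - 1.0
            return r, d

        lo = np.zeros(18)
        hi = np.full(18, 10.0)
        strain_prev = (L - lm_prev * self.l_opt - self.l_slack) / self.l_slack
        F = mtu.tendon_force_from_strain(strain_prev, self.f_max, self.eps0) / self.f_max
        F = np.clip(F, lo + 1e-9, hi)
        for _ in range(max_iter):
            r, dr = rho_and_deriv(F)
            if np.max(np.abs(r)) < tol:
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(np.abs(dr) > 1e-12, -r / dr, 0.0)
            # rho is decreasing in F: r > 0 means the root lies above
            lo = np.where(r > 0, F, lo)
            hi = np.where(r <= 0, F, hi)
            cand = F + step
            mid = 0.5 * (lo + hi)
            F = np.where((cand > lo) & (cand < hi), cand, mid)
        return np.clip(lm_of(F), 0.05, 2.2)

    def equilibrium_fiber_lengths(self, L: np.ndarray, act: np.ndarray) -> np.ndarray:
        """Static (isometric) equilibrium fiber lengths for all muscles."""
        # backward Euler with huge dt degenerates to the static balance
        return self.implicit_fiber_update(np.ones(18), L, act, dt=1e9)

    # -- sensors ------------------------------------------------------------

    def sensors(self, t: float, state: SkeletalState, act: np.ndarray,
                lm_norm: np.ndarray, vm_norm: np.ndarray) -> Sensors:
        L, _ = self.muscle_geometry(state.q)
        f_t = self.tendon_forces(L, lm_norm)
        _, _, _, grf = self._contact(state.q, state.qdot)
        heel = self.heel_positions(state.q)
        return Sensors(
            time=t,
            lm_norm=lm_norm.copy(),
            vm_norm=vm_norm.copy(),
            force_norm=f_t / self.f_max,
            pelvis_tilt=float(state.q[2]),
            pelvis_tilt_rate=float(state.qdot[2]),
            grf_mag=np.array([np.hypot(*grf[0:2]), np.hypot(*grf[2:4])]),
            foot_pelvis_dx=np.array([heel[0, 0] - state.q[0],
                                     heel[1, 0] - state.q[0]]),
        )


# ---------------------------------------------------------------------------
# state initialization


INIT_PARAM_NAMES = (
    "pelvis_tilt", "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r",
    "pelvis_vx", "pelvis_vy", "pelvis_tilt_rate",
    "hip_l_rate", "hip_r_rate", "knee_l_rate", "knee_r_rate",
    "ankle_l_rate", "ankle_r_rate",
)


def initialize_state(free_params: np.ndarray, model: PlanarModel,
                     controller=None):
    """Initial skeletal and muscle states from the 16 free parameters.

    Pelvis x is 0; the 7 free angles and 9 free speeds come from
    ``free_params`` (order: :data:`INIT_PARAM_NAMES`); pelvis height is
    solved so the static vertical GRF equals half the model's weight; muscle
    states are equilibrated at the controller's initial excitations.

    Returns (state, activations (18,), lm_norm (18,)).
    """
    p = np.asarray(free_params, dtype=float)
    if p.shape != (16,):
        raise ValueError(f"expected 16 free parameters, got shape {p.shape}")
    q = np.zeros(9)
    q[2:9] = p[0:7]
    qdot = np.zeros(9)
    qdot[0:9] = p[7:16]

    target = 0.5 * model.total_mass * model.g

    def static_grf(y):
        qq = q.copy()
        qq[1] = y
        _, _, _, grf = model._contact(qq, np.zeros(9))
        return grf[1] + grf[3] - target

    y_hi = 2.0
    y_lo = None
    for y in np.arange(y_hi, 0.2, -0.02):
        if static_grf(y) > 0:
            y_lo = y
            break
    if y_lo is None:
        raise InitializationError(
            "no pelvis height puts the feet in ground contact with the "
            "required static load")
    y_up = y_lo + 0.02
    while static_grf(y_up) > 0:
        y_up += 0.05
        if y_up > y_hi + 1.0:
            raise InitializationError(
                "static GRF condition has no root above the contact height")
    try:
        q[1] = brentq(static_grf, y_lo, y_up)
    except ValueError as exc:
        raise InitializationError(f"pelvis-height root find failed: {exc}") from exc
    state = SkeletalState(q, qdot)

    # muscle states: equilibrate at the controller's initial excitations
    L, _ = model.muscle_geometry(q)
    act = np.full(18, 0.05)
    lm = model.equilibrium_fiber_lengths(L, act)
    if controller is not None:
        sens = model.sensors(0.0, state, act, lm, np.zeros(18))
        u0 = np.clip(controller.initial_excitations(sens),
                     mtu.EXCITATION_FLOOR, 1.0)
        act = np.clip(u0, mtu.ACTIVATION_FLOOR, 1.0)
        lm = model.equilibrium_fiber_lengths(L, act)
    return state, act, lm


# ---------------------------------------------------------------------------
# rollout


def rollout(model: PlanarModel, controller, init_params: np.ndarray,
            t_des: float, output_dt: float | None = None,
            fall_com_fraction: float = 0.8, n_substeps: int = 5) -> Trajectory:
    """Forward-simulate the closed-loop model until t_des or a fall.

    The controller is queried every ``controller.control_dt`` seconds (which
    is also the output sampling interval unless ``output_dt`` overrides it);
    within each interval the skeleton is advanced by ``n_substeps`` RK4 steps
    with excitations held constant, then activations (exact exponential) and
    fiber lengths (implicit equilibrium) are updated.
    """
    if t_des <= 0:
        raise ValueError("t_des must be > 0")
    dt = getattr(controller, "control_dt", 0.005)
    controller.reset()
    state, act, lm = initialize_state(init_params, model, controller)
    vm = np.zeros(18)
    com0 = model.com(state.q)
    fall_height = fall_com_fraction * com0[1]

    n_steps = int(round(t_des / dt))
    n = n_steps + 1
    rec = {
        "t": np.zeros(n), "q": np.zeros((n, 9)), "qdot": np.zeros((n, 9)),
        "exc": np.zeros((n, 18)), "act": np.zeros((n, 18)),
        "lm": np.zeros((n, 18)), "force": np.zeros((n, 18)),
        "grf": np.zeros((n, 4)), "jm": np.zeros((n, 6)), "lig": np.zeros((n, 6)),
        "head": np.zeros((n, 2)), "met": np.zeros(n), "com": np.zeros((n, 2)),
        "phase": np.zeros((n, 2), dtype=int),
    }

    termination = "completed"
    t_fall = None
    k_rec = 0

    def skeleton_rhs(q, qdot, act_c, lm_c):
        L, R = model.muscle_geometry(q)
        f_t = model.tendon_forces(L, lm_c)
        tau9 = np.zeros(9)
        tau9[3:9] = R.T @ f_t
        qdd, _ = model.forward_dynamics(q, qdot, tau9)
        return qdd

    for k in range(n_steps + 1):
        t = k * dt
        sens = model.sensors(t, state, act, lm, vm)
        u = controller.excitations(t, sens)
        u = np.clip(u, mtu.EXCITATION_FLOOR, 1.0)

        # record channels at this grid point
        L, R = model.muscle_geometry(state.q)
        f_t = model.tendon_forces(L, lm)
        tl = model.ligament_torques(state.q)
        tau9 = np.zeros(9)
        tau9[3:9] = R.T @ f_t
        qdd, grf = model.forward_dynamics(state.q, state.qdot, tau9)
        met = _metabolic_total(model, act, u, lm, vm, f_t)
        rec["t"][k_rec] = t
        rec["q"][k_rec] = state.q
        rec["qdot"][k_rec] = state.qdot
        rec["exc"][k_rec] = u
        rec["act"][k_rec] = act
        rec["lm"][k_rec] = lm
        rec["force"][k_rec] = f_t
        rec["grf"][k_rec] = grf
        rec["jm"][k_rec] = R.T @ f_t + tl
        rec["lig"][k_rec] = tl
        rec["head"][k_rec] = model.head_acceleration(state.q, state.qdot, qdd)
        rec["met"][k_rec] = met
        rec["com"][k_rec] = model.com(state.q)
        rec["phase"][k_rec] = getattr(controller, "phase_codes", lambda: (0, 0))()
        k_rec += 1
        if k == n_steps:
            break

        # integrate the interval; substep count adapts to the friction
        # stiffness (mu * f_n / (m_foot * v_t)) so stick-phase dynamics stay
        # inside the RK4 stability region
        a_new = _activation_exact(act, u, dt, model.tau_act, model.tau_deact)
        fn_max = max(grf[1], grf[3])
        lam = model._fric_mu * fn_max / (model._foot_mass * model._fric_vt)
        n_sub = max(n_substeps, min(int(np.ceil(dt * 1.5 * lam / 2.2)), 40))
        h = dt / n_sub
        q, qd = state.q, state.qdot
        ok = True
        for _ in range(n_sub):
            a1 = skeleton_rhs(q, qd, act, lm)
            q2, v2 = q + 0.5 * h * qd, qd + 0.5 * h * a1
            a2 = skeleton_rhs(q2, v2, act, lm)
            q3, v3 = q + 0.5 * h * v2, qd + 0.5 * h * a2
            a3 = skeleton_rhs(q3, v3, act, lm)
            q4, v4 = q + h * v3, qd + h * a3
            a4 = skeleton_rhs(q4, v4, act, lm)
            q = q + (h / 6.0) * (qd + 2 * v2 + 2 * v3 + v4)
            qd = qd + (h / 6.0) * (a1 + 2 * a2 + 2 * a3 + a4)
            if not np.all(np.isfinite(q)) or not np.all(np.isfinite(qd)):
                ok = False
                break
        if not ok:
            raise SimulationError("integration diverged", t, state.copy())
        state = SkeletalState(q, qd)
        L_new, _ = model.muscle_geometry(q)
        lm_new = model.implicit_fiber_update(lm, L_new, a_new, dt)
        vm = (lm_new - lm) / dt
        lm, act = lm_new, a_new

        com_y = model.com(state.q)[1]
        if com_y < fall_height:
            termination = "fell"
            t_fall = (k + 1) * dt
            # record the terminal state
            sens = model.sensors(t_fall, state, act, lm, vm)
            u = np.clip(controller.excitations(t_fall, sens),
                        mtu.EXCITATION_FLOOR, 1.0)
            L, R = model.muscle_geometry(state.q)
            f_t = model.tendon_forces(L, lm)
            tl = model.ligament_torques(state.q)
            tau9 = np.zeros(9)
            tau9[3:9] = R.T @ f_t
            qdd, grf = model.forward_dynamics(state.q, state.qdot, tau9)
            rec["t"][k_rec] = t_fall
            rec["q"][k_rec] = state.q
            rec["qdot"][k_rec] = state.qdot
            rec["exc"][k_rec] = u
            rec["act"][k_rec] = act
            rec["lm"][k_rec] = lm
            rec["force"][k_rec] = f_t
            rec["grf"][k_rec] = grf
            rec["jm"][k_rec] = R.T @ f_t + tl
            rec["lig"][k_rec] = tl
            rec["head"][k_rec] = model.head_acceleration(state.q, state.qdot, qdd)
            rec["met"][k_rec] = _metabolic_total(model, act, u, lm, vm, f_t)
            rec["com"][k_rec] = model.com(state.q)
            rec["phase"][k_rec] = getattr(controller, "phase_codes", lambda: (0, 0))()
            k_rec += 1
            break

    sl = slice(0, k_rec)
    traj = Trajectory(
        t=rec["t"][sl], q=rec["q"][sl], qdot=rec["qdot"][sl],
        excitations=rec["exc"][sl], activations=rec["act"][sl],
        norm_fiber_lengths=rec["lm"][sl], muscle_forces=rec["force"][sl],
        grf=rec["grf"][sl], joint_moments=rec["jm"][sl],
        ligament_torques=rec["lig"][sl], head_acc=rec["head"][sl],
        metabolic_rate_w=rec["met"][sl], com=rec["com"][sl],
        phases=rec["phase"][sl], termination=termination, t_fall=t_fall,
        t_des=t_des, total_mass_kg=model.total_mass,
    )
    if output_dt is not None and abs(output_dt - dt) > 1e-12:
        traj = _resample(traj, output_dt)
    return traj


def _activation_exact(a, u, dt, tau_act, tau_deact):
    tau = np.where(u > a, tau_act, tau_deact)
    return u + (a - u) * np.exp(-dt / tau)


def _metabolic_total(model: PlanarModel, act, exc, lm, vm, f_t) -> float:
    """Whole-body gross metabolic rate: basal + per-muscle Umberger rates."""
    total = mtu.BASAL_RATE_W_PER_KG * model.total_mass
    for i, p in enumerate(model.mus_params):
        st = mtu.MuscleState(activation=float(act[i]),
                             norm_fiber_length=float(lm[i]))
        out = mtu.MuscleOutput(
            tendon_force_n=float(f_t[i]), fiber_force_n=float(f_t[i]),
            active_fl=float(mtu.active_force_length(lm[i])),
            passive_fl=float(mtu.passive_force_length(lm[i], model.pas_scale[i])),
            fv=float(mtu.force_velocity(vm[i], model.v_max[i])))
        total += mtu.metabolic_rate(st, out, float(vm[i]), float(exc[i]),
                                    p, mass_kg=float(model.mus_mass[i]))
    return total


def _resample(traj: Trajectory, output_dt: float) -> Trajectory:
    t_new = np.arange(0.0, traj.t[-1] + 1e-12, output_dt)

    def interp(arr):
        if arr.ndim == 1:
            return np.interp(t_new, traj.t, arr)
        return np.column_stack([np.interp(t_new, traj.t, arr[:, j])
                                for j in range(arr.shape[1])])

    return Trajectory(
        t=t_new, q=interp(traj.q), qdot=interp(traj.qdot),
        excitations=interp(traj.excitations), activations=interp(traj.activations),
        norm_fiber_lengths=interp(traj.norm_fiber_lengths),
        muscle_forces=interp(traj.muscle_forces), grf=interp(traj.grf),
        joint_moments=interp(traj.joint_moments),
        ligament_torques=interp(traj.ligament_torques),
        head_acc=interp(traj.head_acc), metabolic_rate_w=interp(traj.metabolic_rate_w),
        com=interp(traj.com),
        phases=interp(traj.phases.astype(float)).round().astype(int),
        termination=traj.termination, t_fall=traj.t_fall, t_des=traj.t_des,
        total_mass_kg=traj.total_mass_kg,
    )
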