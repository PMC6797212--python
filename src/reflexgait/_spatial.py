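"""Planar spatial-vector algebra for tree-structured rigid-body dynamics.

Planar spatial motion vectors are (omega, vx, vy) and force vectors are
(tau, fx, fy), both expressed at a frame origin in that frame's coordinates.
This module provides the coordinate transforms, cross products, spatial
inertias, and the two workhorse algorithms -- recursive Newton-Euler (inverse
dynamics) and the composite-rigid-body algorithm (joint-space mass matrix) --
for a fixed topology of single-DOF joints (sliders and revolutes, with an
optional rotation-coupled translation for the knee).

The floating planar base is modelled as a chain slider-x -> slider-y ->
revolute through two massless intermediate bodies, which keeps every joint
single-DOF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# joint type codes
SLIDER_X = 0
SLIDER_Y = 1
REVOLUTE = 2


def rot(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def spatial_inertia(mass: float, inertia_com: float, com: tuple[float, float]) -> np.ndarray:
    """3x3 planar spatial inertia about the body-frame origin."""
    cx, cy = com
    return np.array([
        [inertia_com + mass * (cx * cx + cy * cy), -mass * cy, mass * cx],
        [-mass * cy, mass, 0.0],
        [mass * cx, 0.0, mass],
    ])


def crm(v: np.ndarray) -> np.ndarray:
    """Motion-cross-motion matrix: crm(v) @ m = v x m."""
    w, vx, vy = v
    return np.array([
        [0.0, 0.0, 0.0],
        [vy, 0.0, -w],
        [-vx, w, 0.0],
    ])


def crf(v: np.ndarray) -> np.ndarray:
    """Motion-cross-force matrix: crf(v) @ f = v x* f (= -crm(v).T @ f)."""
    return -crm(v).T


@dataclass
class JointModel:
    """Single-DOF joint connecting a parent frame to a child body frame.

    The child frame is placed at ``loc + p(q)`` in the parent frame (p is the
    coupling polynomial, zero for ordinary joints) and rotated by
    ``axis_sign * q`` for revolutes.  ``poly_x/poly_y`` hold polynomial
    coefficients [c1, c2, ...] meaning c1*q + c2*q^2 + ...
    """

    kind: int
    loc: tuple[float, float] = (0.0, 0.0)
    axis_sign: float = 1.0
    poly_x: tuple[float, ...] = ()
    poly_y: tuple[float, ...] = ()

    def _poly(self, coeffs, q):
        return sum(c * q ** (i + 1) for i, c in enumerate(coeffs))

    def _dpoly(self, coeffs, q):
        return sum((i + 1) * c * q**i for i, c in enumerate(coeffs))

    def _ddpoly(self, coeffs, q):
        return sum((i + 1) * i * c * q ** (i - 1) for i, c in enumerate(coeffs) if i >= 1)

    def transform(self, q: float):
        """(E, r): child-frame rotation (world-of-parent -> child coords) and
        child origin position in parent coords."""
        if self.kind == SLIDER_X:
            return np.eye(2), np.array([self.loc[0] + q, self.loc[1]])
        if self.kind == SLIDER_Y:
            return np.eye(2), np.array([self.loc[0], self.loc[1] + q])
        r = np.array([
            self.loc[0] + self._poly(self.poly_x, q),
            self.loc[1] + self._poly(self.poly_y, q),
        ])
        E = rot(self.axis_sign * q).T
        return E, r

    def motion_subspace(self, q: float, E: np.ndarray):
        """S(q) in child coords, and dS/dq for the velocity-product term."""
        if self.kind == SLIDER_X:
            return np.array([0.0, 1.0, 0.0]), np.zeros(3)
        if self.kind == SLIDER_Y:
            return np.array([0.0, 0.0, 1.0]), np.zeros(3)
        dp = np.array([self._dpoly(self.poly_x, q), self._dpoly(self.poly_y, q)])
        S = np.array([self.axis_sign, *(E @ dp)])
        if not self.poly_x and not self.poly_y:
            return S, np.zeros(3)
        ddp = np.array([self._ddpoly(self.poly_x, q), self._ddpoly(self.poly_y, q)])
        # d/dq (E @ dp) = E @ ddp - axis_sign * zhat x (E @ dp)
        Edp = E @ dp
        zcross = np.array([-Edp[1], Edp[0]])
        dS_lin = E @ ddp - self.axis_sign * zcross
        return S, np.array([0.0, *dS_lin])


def xform_motion(E: np.ndarray, r: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Transform a motion vector from parent coords to child coords."""
    w = m[0]
    v = m[1:] + w * np.array([-r[1], r[0]])
    return np.array([w, *(E @ v)])


def inv_xform_force(E: np.ndarray, r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Transform a force vector from child coords back to parent coords."""
    fv = E.T @ f[1:]
    tau = f[0] + r[0] * fv[1] - r[1] * fv[0]
    return np.array([tau, fv[0], fv[1]])


def xform_inertia(E: np.ndarray, r: np.ndarray, I_child: np.ndarray) -> np.ndarray:
    """Express a child-frame spatial inertia in the parent frame."""
    # X maps parent-coords motion to child coords; I_parent = X^T I_child X
    X = np.zeros((3, 3))
    X[0, 0] = 1.0
    X[1:, 0] = E @ np.array([-r[1], r[0]])
    X[1:, 1:] = E
    return X.T @ I_child @ X


@dataclass
class PlanarTree:
    """Fixed-topology planar kinematic tree with one DOF per body."""

    parents: list[int]            # parent body index, -1 = ground
    joints: list[JointModel]
    inertias: list[np.ndarray]    # spatial inertia per body, body frame
    gravity: float = 9.80665

    def __post_init__(self) -> None:
        self.n = len(self.parents)

    def kinematics(self, q: np.ndarray):
        """Per-body (E, r) joint transforms plus world pose of each body.

        Returns (Es, rs, world_angle, world_pos) where world_pos is each body
        origin in ground coordinates and world_angle its absolute rotation.
        """
        Es, rs = [], []
        ang = np.zeros(self.n)
        pos = np.zeros((self.n, 2))
        for i in range(self.n):
            E, r = self.joints[i].transform(q[i])
            Es.append(E)
            rs.append(r)
            p = self.parents[i]
            if p < 0:
                pa, pp = 0.0, np.zeros(2)
            else:
                pa, pp = ang[p], pos[p]
            R_p = rot(pa)
            pos[i] = pp + R_p @ r
            ang[i] = pa + _angle_of(E)
        return Es, rs, ang, pos

    def body_velocities(self, q, qd, Es, rs):
        """Spatial velocity of each body in its own frame."""
        vs = []
        for i in range(self.n):
            S, _ = self.joints[i].motion_subspace(q[i], Es[i])
            p = self.parents[i]
            v_par = np.zeros(3) if p < 0 else vs[p]
            vs.append(xform_motion(Es[i], rs[i], v_par) + S * qd[i])
        return vs

    def rnea(self, q, qd, qdd, f_ext=None):
        """Inverse dynamics: joint forces realizing qdd (gravity included).

        ``f_ext[i]`` is an external spatial force on body i, expressed in body
        i's frame at its origin.  Returns tau (n,).
        """
        n = self.n
        Es, rs = [], []
        Ss, dSs = [], []
        v = [None] * n
        a = [None] * n
        f = [None] * n
        a_base = np.array([0.0, 0.0, self.gravity])  # gravity trick
        for i in range(n):
            E, r = self.joints[i].transform(q[i])
            S, dS = self.joints[i].motion_subspace(q[i], E)
            Es.append(E); rs.append(r); Ss.append(S); dSs.append(dS)
            p = self.parents[i]
            v_par = np.zeros(3) if p < 0 else v[p]
            a_par = a_base if p < 0 else a[p]
            vJ = S * qd[i]
            v[i] = xform_motion(E, r, v_par) + vJ
            cJ = dS * (qd[i] * qd[i])
            a[i] = (xform_motion(E, r, a_par) + S * qdd[i] + cJ
                    + crm(v[i]) @ vJ)
            I = self.inertias[i]
            f[i] = I @ a[i] + crf(v[i]) @ (I @ v[i])
            if f_ext is not None and f_ext[i] is not None:
                f[i] = f[i] - f_ext[i]
        tau = np.zeros(n)
        for i in range(n - 1, -1, -1):
            tau[i] = Ss[i] @ f[i]
            p = self.parents[i]
            if p >= 0:
                f[p] = f[p] + inv_xform_force(Es[i], rs[i], f[i])
        return tau

    def crba(self, q):
        """Composite-rigid-body algorithm: joint-space mass matrix (n x n)."""
        n = self.n
        Es, rs, Ss = [], [], []
        for i in range(n):
            E, r = self.joints[i].transform(q[i])
            S, _ = self.joints[i].motion_subspace(q[i], E)
            Es.append(E); rs.append(r); Ss.append(S)
        Ic = [I.copy() for I in self.inertias]
        M = np.zeros((n, n))
        for i in range(n - 1, -1, -1):
            p = self.parents[i]
            if p >= 0:
                Ic[p] += xform_inertia(Es[i], rs[i], Ic[i])
            fh = Ic[i] @ Ss[i]
            M[i, i] = Ss[i] @ fh
            j = i
            while self.parents[j] >= 0:
                fh = inv_xform_force(Es[j], rs[j], fh)
                j = self.parents[j]
                M[i, j] = M[j, i] = Ss[j] @ fh
        return M


def _angle_of(E: np.ndarray) -> float:
    """Local rotation angle from E = rot(angle)^T."""
    return float(np.arctan2(-E[1, 0], E[0, 0]))


# ---------------------------------------------------------------------------
# scalar fast path
#
# The numpy implementations above are the readable reference; the functions
# below are algebraically identical but use plain floats and tuples, which is
# several times faster for this 9-body tree (the rollout inner loop).  Only
# pure pin/slider joints take the fast path; a knee with a nonzero coupling
# polynomial falls back to the reference implementation.


def compile_tree(tree: PlanarTree) -> dict:
    """Flatten tree constants for the scalar kernels."""
    n = tree.n
    jt = [j.kind for j in tree.joints]
    sg = [float(j.axis_sign) for j in tree.joints]
    lx = [float(j.loc[0]) for j in tree.joints]
    ly = [float(j.loc[1]) for j in tree.joints]
    # spatial inertia unique components: [[i00, a, b], [a, m, 0], [b, 0, m]]
    i00 = [float(I[0, 0]) for I in tree.inertias]
    ia = [float(I[0, 1]) for I in tree.inertias]
    ib = [float(I[0, 2]) for I in tree.inertias]
    im = [float(I[1, 1]) for I in tree.inertias]
    simple = all(not j.poly_x and not j.poly_y for j in tree.joints)
    return {"n": n, "parent": tuple(tree.parents), "jt": tuple(jt),
            "sg": tuple(sg), "lx": tuple(lx), "ly": tuple(ly),
            "i00": tuple(i00), "ia": tuple(ia), "ib": tuple(ib),
            "im": tuple(im), "g": tree.gravity, "simple": simple}


def fast_fk(comp: dict, q, qd):
    """Forward kinematics + velocities, scalar path.

    Returns per-body lists: world angle, world position (x, y), angular
    velocity, world-frame origin velocity (vx, vy), and the joint-frame
    cache (c, s, rx, ry) used by the dynamics kernels.
    """
    n = comp["n"]
    parent, jt, sg = comp["parent"], comp["jt"], comp["sg"]
    lx, ly = comp["lx"], comp["ly"]
    ang = [0.0] * n
    px = [0.0] * n
    py = [0.0] * n
    w = [0.0] * n
    vwx = [0.0] * n
    vwy = [0.0] * n
    cache = [None] * n
    for i in range(n):
        p = parent[i]
        if p < 0:
            pa = ppx = ppy = pw = pvx = pvy = 0.0
        else:
            pa, ppx, ppy, pw = ang[p], px[p], py[p], w[p]
            pvx, pvy = vwx[p], vwy[p]
        k = jt[i]
        if k == REVOLUTE:
            th = sg[i] * q[i]
            c, s = math.cos(th), math.sin(th)
            rx, ry = lx[i], ly[i]
            wd = sg[i] * qd[i]
            dvx = dvy = 0.0
        elif k == SLIDER_X:
            c, s = 1.0, 0.0
            rx, ry = lx[i] + q[i], ly[i]
            wd = 0.0
            dvx, dvy = qd[i], 0.0
        else:  # SLIDER_Y
            c, s = 1.0, 0.0
            rx, ry = lx[i], ly[i] + q[i]
            wd = 0.0
            dvx, dvy = 0.0, qd[i]
        cp, sp = math.cos(pa), math.sin(pa)
        rwx = cp * rx - sp * ry
        rwy = sp * rx + cp * ry
        px[i] = ppx + rwx
        py[i] = ppy + rwy
        ang[i] = pa + (sg[i] * q[i] if k == REVOLUTE else 0.0)
        w[i] = pw + wd
        # origin velocity in world frame: parent origin vel + pw x r_w + slider vel
        ca, sa = math.cos(pa), math.sin(pa)
        vwx[i] = pvx - pw * rwy + ca * dvx - sa * dvy
        vwy[i] = pvy + pw * rwx + sa * dvx + ca * dvy
        cache[i] = (c, s, rx, ry)
    return ang, px, py, w, vwx, vwy, cache


def fast_dynamics(comp: dict, q, qd, f_ext, tau_applied, need_M=True, M=None):
    """Scalar RNEA bias + (optionally) CRBA mass matrix + solve.

    ``f_ext[i]`` is (tau, fx, fy) in body i's frame at its origin or None.
    ``tau_applied`` is the generalized force (n,).  Returns (qdd, M).
    """
    n = comp["n"]
    parent, jt, sg = comp["parent"], comp["jt"], comp["sg"]
    lx, ly = comp["lx"], comp["ly"]
    i00, ia, ib, im = comp["i00"], comp["ia"], comp["ib"], comp["im"]
    grav = comp["g"]

    Ec = [0.0] * n
    Es = [0.0] * n
    Rx = [0.0] * n
    Ry = [0.0] * n
    S0 = [0.0] * n  # S = (S0, S1, S2)
    S1 = [0.0] * n
    S2 = [0.0] * n
    vw_ = [0.0] * n
    vx_ = [0.0] * n
    vy_ = [0.0] * n
    f0 = [0.0] * n
    f1 = [0.0] * n
    f2 = [0.0] * n

    # forward pass: velocities and bias accelerations (qdd = 0), gravity trick
    a0 = [0.0] * n
    a1 = [0.0] * n
    a2 = [0.0] * n
    for i in range(n):
        p = parent[i]
        k = jt[i]
        if k == REVOLUTE:
            th = sg[i] * q[i]
            c, s = math.cos(th), math.sin(th)
            rx, ry = lx[i], ly[i]
            s0, s1, s2 = sg[i], 0.0, 0.0
        elif k == SLIDER_X:
            c, s = 1.0, 0.0
            rx, ry = lx[i] + q[i], ly[i]
            s0, s1, s2 = 0.0, 1.0, 0.0
        else:
            c, s = 1.0, 0.0
            rx, ry = lx[i], ly[i] + q[i]
            s0, s1, s2 = 0.0, 0.0, 1.0
        Ec[i], Es[i], Rx[i], Ry[i] = c, s, rx, ry
        S0[i], S1[i], S2[i] = s0, s1, s2
        if p < 0:
            pw, pvx, pvy = 0.0, 0.0, 0.0
            paw, pax, pay = 0.0, 0.0, grav
        else:
            pw, pvx, pvy = vw_[p], vx_[p], vy_[p]
            paw, pax, pay = a0[p], a1[p], a2[p]
        # xform motion (E with rows [c, s; -s, c]): v' = E (v + w * (-ry, rx))
        tx = pvx - pw * ry
        ty = pvy + pw * rx
        vw = pw + s0 * qd[i]
        vx = c * tx + s * ty + s1 * qd[i]
        vy = -s * tx + c * ty + s2 * qd[i]
        vw_[i], vx_[i], vy_[i] = vw, vx, vy
        # bias acceleration: X a_parent + crm(v) S qdot
        tx = pax - paw * ry
        ty = pay + paw * rx
        aw = paw
        ax = c * tx + s * ty
        ay = -s * tx + c * ty
        # crm(v) @ (S qd): (0, vy*u0 - vw*u2, -vx*u0 + vw*u1) with u = S qd
        u0, u1, u2 = s0 * qd[i], s1 * qd[i], s2 * qd[i]
        ax += vy * u0 - vw * u2
        ay += -vx * u0 + vw * u1
        a0[i], a1[i], a2[i] = aw, ax, ay
        # f = I a + crf(v) I v - f_ext
        Iv0 = i00[i] * vw + ia[i] * vx + ib[i] * vy
        Iv1 = ia[i] * vw + im[i] * vx
        Iv2 = ib[i] * vw + im[i] * vy
        ff0 = i00[i] * aw + ia[i] * ax + ib[i] * ay \
            + (-vy * Iv1 + vx * Iv2)
        ff1 = ia[i] * aw + im[i] * ax - vw * Iv2
        ff2 = ib[i] * aw + im[i] * ay + vw * Iv1
        if f_ext is not None and f_ext[i] is not None:
            e = f_ext[i]
            ff0 -= e[0]
            ff1 -= e[1]
            ff2 -= e[2]
        f0[i], f1[i], f2[i] = ff0, ff1, ff2

    bias = [0.0] * n
    for i in range(n - 1, -1, -1):
        bias[i] = S0[i] * f0[i] + S1[i] * f1[i] + S2[i] * f2[i]
        p = parent[i]
        if p >= 0:
            c, s, rx, ry = Ec[i], Es[i], Rx[i], Ry[i]
            # inverse force transform: f_vec_parent = E^T f_vec
            gx = c * f1[i] - s * f2[i]
            gy = s * f1[i] + c * f2[i]
            f0[p] += f0[i] + rx * gy - ry * gx
            f1[p] += gx
            f2[p] += gy

    if M is None and need_M:
        # composite-rigid-body: accumulate inertias rootward
        ci00 = list(i00)
        cia = list(ia)
        cib = list(ib)
        cim = list(im)
        Mm = np.zeros((n, n))
        for i in range(n - 1, -1, -1):
            p = parent[i]
            if p >= 0:
                c, s, rx, ry = Ec[i], Es[i], Rx[i], Ry[i]
                # transform composite inertia child -> parent
                # X[1:,0] = E @ (-ry, rx); X[1:,1:] = E
                ux = c * -ry + s * rx
                uy = -s * -ry + c * rx
                a_, b_, m_, j_ = cia[i], cib[i], cim[i], ci00[i]
                # I_parent = X^T I X with I = [[j, a, b],[a, m, 0],[b, 0, m]]
                # columns of X: x0 = (1, ux, uy), x1 = (0, c, -s), x2 = (0, s, c)
                Ix0 = (j_ + a_ * ux + b_ * uy,
                       a_ + m_ * ux,
                       b_ + m_ * uy)
                Ix1 = (a_ * c - b_ * s, m_ * c, -m_ * s)
                Ix2 = (a_ * s + b_ * c, m_ * s, m_ * c)
                ci00[p] += Ix0[0] + ux * Ix0[1] + uy * Ix0[2]
                cia[p] += Ix1[0] + ux * Ix1[1] + uy * Ix1[2]
                cib[p] += Ix2[0] + ux * Ix2[1] + uy * Ix2[2]
                cim[p] += c * Ix1[1] - s * Ix1[2]
            # fh = Ic_i @ S_i
            h0 = ci00[i] * S0[i] + cia[i] * S1[i] + cib[i] * S2[i]
            h1 = cia[i] * S0[i] + cim[i] * S1[i]
            h2 = cib[i] * S0[i] + cim[i] * S2[i]
            Mm[i, i] = S0[i] * h0 + S1[i] * h1 + S2[i] * h2
            j = i
            while parent[j] >= 0:
                c, s, rx, ry = Ec[j], Es[j], Rx[j], Ry[j]
                gx = c * h1 - s * h2
                gy = s * h1 + c * h2
                h0 = h0 + rx * gy - ry * gx
                h1, h2 = gx, gy
                j = parent[j]
                Mm[i, j] = Mm[j, i] = S0[j] * h0 + S1[j] * h1 + S2[j] * h2
        M = Mm

    rhs = np.asarray(tau_applied, dtype=float) - np.array(bias)
    qdd = np.linalg.solve(M, rhs) if M is not None else None
    return qdd, M, np.array(bias)
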