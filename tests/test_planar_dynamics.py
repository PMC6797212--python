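import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from reflexgait import mtu
from reflexgait.planar_dynamics import (
    InitializationError,
    PlanarModel,
    contact_force,
    initialize_state,
    ligament_torque,
    rollout,
)
from reflexgait.reflex_controller import ConstantController, GaitController


class TestMuscleGeometry:
    def test_tendon_excursion_identity(self, planar_model):
        """moment arm = -dL/dtheta to < 1e-6 m (finite-difference oracle)."""
        rng = np.random.default_rng(1)
        h = 1e-7
        for _ in range(20):
            q = np.zeros(9)
            q[3:] = rng.uniform(-0.6, 0.6, 6)
            L, R = planar_model.muscle_geometry(q)
            for j in range(6):
                qp = q.copy()
                qp[3 + j] += h
                Lp, _ = planar_model.muscle_geometry(qp)
                assert np.max(np.abs(R[:, j] + (Lp - L) / h)) < 1e-6

    def test_uniarticular_ta_ignores_knee(self, planar_model):
        q = np.zeros(9)
        L0, _ = planar_model.muscle_geometry(q)
        q[5] = 0.8  # knee_l
        L1, _ = planar_model.muscle_geometry(q)
        i_ta = planar_model.muscle_names.index("TA_l")
        assert L1[i_ta] == L0[i_ta]

    def test_biarticular_gas_spans_knee_and_ankle(self, planar_model):
        i_gas = planar_model.muscle_names.index("GAS_l")
        q = np.zeros(9)
        L0, _ = planar_model.muscle_geometry(q)
        q_knee = q.copy()
        q_knee[5] = 0.5
        q_ankle = q.copy()
        q_ankle[7] = 0.3
        assert planar_model.muscle_geometry(q_knee)[0][i_gas] != L0[i_gas]
        assert planar_model.muscle_geometry(q_ankle)[0][i_gas] != L0[i_gas]


class TestNonlinearConfigurations:
    """The general (polynomial) joint and muscle-path code paths."""

    def _coupled_knee_model(self):
        import yaml
        from reflexgait import msk_model as mm_
        with open(mm_.default_model_path()) as fh:
            raw = yaml.safe_load(fh)
        # small anterior tibiofemoral translation, a few mm over flexion
        raw["joints"]["knee"]["coupling_poly_x"] = [0.004, -0.002]
        raw["muscles"]["VAS"]["path"]["joints"]["knee"] = [0.042, -0.008]
        return mm_._build_from_dict(raw)

    def test_coupled_knee_energy_conservation(self):
        """Energy is conserved with a q-dependent knee motion subspace."""
        pm = PlanarModel(self._coupled_knee_model())
        assert not pm._fast  # falls back to the reference implementation
        q0 = np.zeros(9)
        q0[1], q0[3], q0[5] = 2.0, 0.5, 0.4
        qd0 = np.zeros(9)
        qd0[5] = 1.0

        def rhs(t, y):
            qdd, _ = pm.forward_dynamics(y[:9], y[9:], contact=False,
                                         ligaments=False, locked=(0, 1, 2))
            return np.concatenate([y[9:], qdd])

        e0 = pm.total_energy(q0, qd0)
        sol = solve_ivp(rhs, (0, 2), np.concatenate([q0, qd0]),
                        rtol=1e-9, atol=1e-11)
        e1 = pm.total_energy(sol.y[:9, -1], sol.y[9:, -1])
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_polynomial_path_excursion_identity(self):
        """Angle-dependent moment arms still satisfy r = -dL/dtheta."""
        pm = PlanarModel(self._coupled_knee_model())
        rng = np.random.default_rng(8)
        h = 1e-7
        for _ in range(5):
            q = np.zeros(9)
            q[3:] = rng.uniform(-0.6, 0.6, 6)
            L, R = pm.muscle_geometry(q)
            for j in range(6):
                qp = q.copy()
                qp[3 + j] += h
                Lp, _ = pm.muscle_geometry(qp)
                assert np.max(np.abs(R[:, j] + (Lp - L) / h)) < 1e-6
        # the VAS knee moment arm now varies with knee angle
        i_vas = pm.muscle_names.index("VAS_l")
        q1, q2 = np.zeros(9), np.zeros(9)
        q2[5] = 0.8
        r1 = pm.muscle_geometry(q1)[1][i_vas, 2]
        r2 = pm.muscle_geometry(q2)[1][i_vas, 2]
        assert r1 != pytest.approx(r2)


class TestContactForce:
    def _heel(self, model_spec):
        return model_spec.contact["heel_l"]

    def test_no_penetration_no_force(self, model_spec):
        assert contact_force(0.0, 0.1, 1.0, self._heel(model_spec)) == (0.0, 0.0)
        assert contact_force(-0.01, 0.0, 0.0, self._heel(model_spec)) == (0.0, 0.0)

    def test_hunt_crossley_closed_form(self, model_spec):
        """Static normal force matches an independently coded Hertz formula."""
        depth = 0.005
        sphere = self._heel(model_spec)
        _, fn = contact_force(depth, 0.0, 0.0, sphere)
        expected = (4.0 / 3.0) * 500_000.0 * math.sqrt(0.05) * depth**1.5
        assert fn == pytest.approx(expected, rel=1e-12)

    def test_dissipation_scales_with_depth_rate(self, model_spec):
        sphere = self._heel(model_spec)
        _, fn_static = contact_force(0.005, 0.0, 0.0, sphere)
        _, fn_loading = contact_force(0.005, 0.2, 0.0, sphere)
        assert fn_loading == pytest.approx(
            fn_static * (1.0 + sphere.hc_dissipation_factor * 1.0 * 0.2))

    def test_normal_force_floored_at_zero(self, model_spec):
        _, fn = contact_force(0.005, -5.0, 0.0, self._heel(model_spec))
        assert fn == 0.0

    def test_friction_ratio_at_high_slip(self, model_spec):
        ft, fn = contact_force(0.01, 0.0, 1.0, self._heel(model_spec))
        assert abs(ft) / fn == pytest.approx(0.8, rel=0.01)
        assert ft < 0  # opposes the slip


class TestLigamentTorque:
    KNEE = (0.0, math.radians(140.0))
    ANKLE = (math.radians(-40.0), math.radians(20.0))
    HIP = (math.radians(-30.0), math.radians(120.0))

    def test_zero_inside_limits(self):
        assert ligament_torque(math.radians(60.0), self.KNEE) == 0.0

    def test_knee_hyperextension_resisted(self):
        tau = ligament_torque(math.radians(-5.0), self.KNEE)
        assert tau > 0.0  # pushes back toward flexion

    def test_excess_dorsiflexion_resisted(self):
        tau = ligament_torque(math.radians(25.0), self.ANKLE)
        assert tau < 0.0 and abs(tau) > 0.0

    def test_continuous_at_limit(self):
        eps = 1e-9
        assert abs(ligament_torque(self.HIP[1] + eps, self.HIP)) < 1e-5
        assert ligament_torque(self.HIP[1] - eps, self.HIP) == 0.0

    def test_monotone_beyond_limit(self):
        angles = np.radians(np.linspace(141, 160, 50))
        taus = [ligament_torque(a, self.KNEE) for a in angles]
        assert all(t2 < t1 for t1, t2 in zip(taus, taus[1:]))  # more resisting


class TestFastKernelConsistency:
    def test_fast_matches_reference_dynamics(self, planar_model):
        """Scalar fast path equals the numpy reference implementation."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            q = rng.uniform(-0.4, 0.4, 9)
            q[1] = rng.uniform(0.85, 1.05)
            qd = rng.uniform(-2, 2, 9)
            tau = rng.uniform(-50, 50, 9)
            planar_model._fast = True
            qdd_f, grf_f = planar_model.forward_dynamics(q, qd, tau)
            planar_model._fast = False
            try:
                qdd_r, grf_r = planar_model.forward_dynamics(q, qd, tau)
            finally:
                planar_model._fast = True
            np.testing.assert_allclose(qdd_f, qdd_r, rtol=1e-9, atol=1e-8)
            np.testing.assert_allclose(grf_f, grf_r, atol=1e-9)

    def test_mass_matrix_properties(self, planar_model):
        rng = np.random.default_rng(4)
        q = rng.uniform(-0.5, 0.5, 9)
        M = planar_model.mass_matrix(q)
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(M) > 0)
        # translational block equals total mass (Newton's second law)
        assert M[0, 0] == pytest.approx(planar_model.total_mass)
        assert M[1, 1] == pytest.approx(planar_model.total_mass)


class TestEnergyAndMomentum:
    def test_passive_pendulum_energy_conservation(self, planar_model):
        """Pelvis pinned, contact and muscles off: drift < 0.1% over 5 s."""
        pm = planar_model
        q0 = np.zeros(9)
        q0[1] = 2.0  # well above ground
        q0[3], q0[5] = 0.6, 0.3
        qd0 = np.zeros(9)
        locked = (0, 1, 2)

        def rhs(t, y):
            q, qd = y[:9], y[9:]
            qdd, _ = pm.forward_dynamics(q, qd, contact=False,
                                         ligaments=False, locked=locked)
            return np.concatenate([qd, qdd])

        e0 = pm.total_energy(q0, qd0)
        sol = solve_ivp(rhs, (0, 5), np.concatenate([q0, qd0]),
                        rtol=1e-8, atol=1e-10)
        e1 = pm.total_energy(sol.y[:9, -1], sol.y[9:, -1])
        assert abs(e1 - e0) / abs(e0) < 1e-3

    def test_impulse_momentum_audit(self, planar_model, short_rollout):
        """Momentum change equals the external-force impulse to < 1% per 1 s."""
        traj = short_rollout
        pm = planar_model
        t = traj.t
        grf = traj.grf[:, 0:2] + traj.grf[:, 2:4]
        weight = pm.total_mass * pm.g
        windows = [(a, a + 1.0) for a in np.arange(0.0, t[-1] - 1.0 + 1e-9, 0.5)]
        if not windows:
            windows = [(0.0, t[-1])]
        for t0, t1 in windows:
            m = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
            p0 = pm.momentum(traj.q[m][0], traj.qdot[m][0])
            p1 = pm.momentum(traj.q[m][-1], traj.qdot[m][-1])
            imp_x = np.trapezoid(grf[m, 0], t[m])
            imp_y = np.trapezoid(grf[m, 1] - weight, t[m])
            scale = weight * (t1 - t0)
            assert abs((p1 - p0)[0] - imp_x) / scale < 0.01
            assert abs((p1 - p0)[1] - imp_y) / scale < 0.01

    def test_reported_grf_is_sum_of_sphere_forces(self, planar_model):
        """Newton's third law bookkeeping: GRF = sum of per-sphere forces."""
        q = np.zeros(9)
        q[1] = 0.95
        qd = np.zeros(9)
        forces, _, _, grf = planar_model._contact(q, qd)
        left = forces[[planar_model._sph_left[k] for k in range(6)]].sum(axis=0)
        np.testing.assert_allclose(grf[0:2], left, atol=1e-9)
        np.testing.assert_allclose(grf[2:4] + left, forces.sum(axis=0), atol=1e-9)


class TestHeadAcceleration:
    def test_matches_finite_difference_of_head_position(self, planar_model):
        """Analytic point acceleration vs second differences on a smooth path."""
        pm = planar_model

        def head_pos(q):
            phi = -q[2]
            r = np.array([math.cos(phi) * pm._head_loc[0] - math.sin(phi) * pm._head_loc[1],
                          math.sin(phi) * pm._head_loc[0] + math.cos(phi) * pm._head_loc[1]])
            return q[:2] + r

        def qfun(t):
            q = np.zeros(9)
            q[0] = 0.3 * t
            q[1] = 1.0 + 0.05 * math.sin(3 * t)
            q[2] = 0.2 * math.sin(2 * t)
            return q

        t0, h = 0.4, 1e-5
        qm, q0, qp = qfun(t0 - h), qfun(t0), qfun(t0 + h)
        qd = (qp - qm) / (2 * h)
        qdd = (qp - 2 * q0 + qm) / h**2
        a_fd = (head_pos(qp) - 2 * head_pos(q0) + head_pos(qm)) / h**2
        a = pm.head_acceleration(q0, qd, qdd)
        np.testing.assert_allclose(a, a_fd, rtol=1e-4, atol=1e-4)


class TestInitializeState:
    def test_static_grf_is_half_body_weight(self, planar_model, default_init_params):
        state, act, lm = initialize_state(default_init_params, planar_model)
        _, _, _, grf = planar_model._contact(state.q, np.zeros(9))
        target = 0.5 * 75.16 * 9.80665
        assert grf[1] + grf[3] == pytest.approx(target, abs=0.1)
        assert grf[1] + grf[3] == pytest.approx(368.6, abs=0.5)

    def test_pelvis_x_is_zero(self, planar_model, default_init_params):
        state, _, _ = initialize_state(default_init_params, planar_model)
        assert state.q[0] == 0.0

    def test_wrong_arity_raises(self, planar_model):
        with pytest.raises(ValueError, match="16"):
            initialize_state(np.zeros(10), planar_model)

    def test_feet_above_ground_raises(self, planar_model):
        bad = np.zeros(16)
        bad[1] = bad[2] = 2.8  # both hips hyperflexed: feet forward, high
        bad[3] = bad[4] = 2.8
        with pytest.raises((InitializationError, ValueError)):
            initialize_state(bad, planar_model)

    def test_muscle_states_equilibrated(self, planar_model, topology,
                                        default_init_params):
        controller = GaitController(topology)
        state, act, lm = initialize_state(default_init_params, planar_model,
                                          controller)
        L, _ = planar_model.muscle_geometry(state.q)
        ft = planar_model.tendon_forces(L, lm) / planar_model.f_max
        fl = mtu.active_force_length(lm)
        fp = mtu.passive_force_length(lm, planar_model.pas_scale)
        assert np.max(np.abs(act * fl + fp - ft)) < 1e-6


class TestRollout:
    def test_silenced_muscles_collapse(self, planar_model, default_init_params):
        """With all muscles silenced the model falls and the fall is recorded."""
        traj = rollout(planar_model, ConstantController(0.0),
                       default_init_params, t_des=3.0)
        assert traj.termination == "fell"
        assert traj.t_fall is not None and traj.t_fall < 3.0
        assert traj.t[-1] == pytest.approx(traj.t_fall)

    def test_fall_detection_threshold(self, planar_model, default_init_params):
        """The COM criterion holds exactly at the recorded fall sample."""
        traj = rollout(planar_model, ConstantController(0.0),
                       default_init_params, t_des=3.0)
        com0 = traj.com[0, 1]
        assert traj.com[-1, 1] < 0.8 * com0
        assert np.all(traj.com[:-1, 1] >= 0.8 * com0)

    def test_duration_contract(self, planar_model, topology, default_init_params):
        """A parameter set stable over the horizon completes it exactly."""
        controller = GaitController(topology)
        traj = rollout(planar_model, controller, default_init_params, t_des=1.0)
        assert traj.termination == "completed"
        assert traj.t[-1] == pytest.approx(1.0)

    def test_pretrained_solution_completes(self, planar_model, topology):
        """The packaged optimized example stays upright over its horizon."""
        from reflexgait import shooting_optimizer as so
        from reflexgait.reflex_controller import ControllerParams

        dv = so.pretrained_design_vector(topology)
        ctrl_vals, init_vals = dv.split()
        controller = GaitController(topology,
                                    ControllerParams(topology, ctrl_vals))
        traj = rollout(planar_model, controller, init_vals, t_des=2.0)
        assert traj.termination == "completed"
        assert traj.com[-1, 1] >= 0.8 * traj.com[0, 1]

    def test_vertical_grf_nonnegative(self, short_rollout):
        assert np.all(short_rollout.grf[:, 1] >= 0)
        assert np.all(short_rollout.grf[:, 3] >= 0)

    def test_channels_shapes_consistent(self, short_rollout):
        n = len(short_rollout.t)
        assert short_rollout.q.shape == (n, 9)
        assert short_rollout.muscle_forces.shape == (n, 18)
        assert short_rollout.joint_moments.shape == (n, 6)
        assert short_rollout.metabolic_rate_w.shape == (n,)
        assert np.all(short_rollout.metabolic_rate_w >= 0)

    def test_bad_t_des_raises(self, planar_model, default_init_params):
        with pytest.raises(ValueError):
            rollout(planar_model, ConstantController(0.0),
                    default_init_params, t_des=0.0)
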