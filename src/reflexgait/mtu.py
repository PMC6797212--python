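"""Hill-type muscle-tendon unit dynamics and metabolic energetics.

Each MTU is a contractile fiber in series with an elastic tendon (zero
pennation; the planar model lumps muscle groups into straight-line
actuators).  Smooth analytic curve families are used:

* active force-length: Gaussian bell centered at the optimal fiber length,
* passive force-length: exponential (Thelen-style), scaled per muscle,
* force-velocity: Hill hyperbola for shortening with a saturating eccentric
  branch, invertible in closed form on both branches,
* tendon: exponential force-strain normalized so the tendon carries exactly
  the maximum isometric force at its characteristic strain (4.9% for most
  muscles, 10% for the plantarflexors).

Activation follows first-order dynamics with 10 ms / 40 ms activation /
deactivation time constants.  Metabolic rate follows the Umberger model with
the Uchida modifications (activation/maintenance heat, shortening and
lengthening heat, mechanical work, non-negative total).

Convention: normalized fiber velocity is negative for shortening, and the
force-velocity multiplier is zero at ``-v_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from reflexgait.msk_model import MuscleParams

# ---------------------------------------------------------------------------
# curve coefficients (config-level defaults)

#: Gaussian width parameter of the active force-length bell
ACTIVE_FL_GAMMA = 0.08
#: passive curve: exponential shape factor and strain at which f_p = 1
PASSIVE_KPE = 4.0
PASSIVE_E0 = 0.6
#: Hill shortening curvature and eccentric plateau
FV_AF = 0.25
FV_FLEN = 1.4
#: tendon exponential shape factor
TENDON_KT = 3.0

#: excitation floor applied before activation dynamics (configurable)
EXCITATION_FLOOR = 0.01
ACTIVATION_FLOOR = 0.01


class EquilibrationError(RuntimeError):
    """Fiber-tendon force balance failed to converge or is infeasible."""

    def __init__(self, muscle: str, message: str, residual: float = np.nan):
        super().__init__(f"{muscle}: {message} (residual={residual:.3e})")
        self.muscle = muscle
        self.residual = residual


@dataclass
class MuscleState:
    activation: float
    norm_fiber_length: float


@dataclass
class MTUKinematics:
    mtu_length_m: float
    mtu_velocity_m_s: float = 0.0


@dataclass
class MuscleOutput:
    tendon_force_n: float
    fiber_force_n: float
    active_fl: float
    passive_fl: float
    fv: float
    metabolic_rate_w: float = 0.0


# ---------------------------------------------------------------------------
# activation dynamics


def activation_step(a: float, u: float, dt: float,
                    tau_act: float = 0.010, tau_deact: float = 0.040) -> float:
    """Advance first-order activation dynamics by dt under constant excitation.

    da/dt = (u - a)/tau with tau = tau_act when u > a, else tau_deact.  The
    exact exponential solution for constant u is used, so sub-stepping is
    consistent to machine precision.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    u = min(max(u, 0.0), 1.0)
    a = min(max(a, 0.0), 1.0)
    tau = tau_act if u > a else tau_deact
    a_new = u + (a - u) * np.exp(-dt / tau)
    return float(min(max(a_new, 0.0), 1.0))


def activation_rate(a, u, tau_act: float = 0.010, tau_deact: float = 0.040):
    """da/dt for the same first-order model; vectorized over muscles."""
    tau = np.where(u > a, tau_act, tau_deact)
    return (u - a) / tau


# ---------------------------------------------------------------------------
# force curves (total, vectorized)


def active_force_length(lm_norm):
    return np.exp(-((np.asarray(lm_norm) - 1.0) ** 2) / ACTIVE_FL_GAMMA)


def passive_force_length(lm_norm, scale=1.0):
    lm = np.asarray(lm_norm, dtype=float)
    f = (np.exp(PASSIVE_KPE * (lm - 1.0) / PASSIVE_E0) - 1.0) / (np.exp(PASSIVE_KPE) - 1.0)
    return scale * np.where(lm > 1.0, f, 0.0)


def force_velocity(vm_norm, v_max: float = 15.0):
    """Force-velocity multiplier; vm_norm in optimal fiber lengths / s.

    Shortening (vm < 0): Hill hyperbola, 1 at vm=0, 0 at vm=-v_max.
    Lengthening (vm > 0): saturating branch approaching FV_FLEN, with
    matched slope at vm=0.
    """
    v = np.asarray(vm_norm, dtype=float) / v_max
    v = np.clip(v, -1.0, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = (1.0 + v) / (1.0 - v / FV_AF)
        slope0 = 1.0 + 1.0 / FV_AF
        k_ecc = slope0 / (FV_FLEN - 1.0)
        ecc = FV_FLEN - (FV_FLEN - 1.0) / (1.0 + k_ecc * v)
    return np.where(v < 0.0, conc, ecc)


def force_velocity_inverse(fv_mult, v_max: float = 15.0):
    """Closed-form inverse of :func:`force_velocity` (returns vm_norm)."""
    f = np.asarray(fv_mult, dtype=float)
    eps = 1e-6
    f = np.clip(f, eps, FV_FLEN - eps)
    # concentric branch: f = (1+v)/(1 - v/af)  ->  v = (f-1)/(1 + f/af)
    v_conc = (f - 1.0) / (1.0 + f / FV_AF)
    # eccentric branch: f = flen - (flen-1)/(1 + k v)  ->  v = ((flen-1)/(flen-f) - 1)/k
    slope0 = 1.0 + 1.0 / FV_AF
    k_ecc = slope0 / (FV_FLEN - 1.0)
    v_ecc = ((FV_FLEN - 1.0) / (FV_FLEN - f) - 1.0) / k_ecc
    v = np.where(f <= 1.0, v_conc, v_ecc)
    return v * v_max


def active_force_length_deriv(lm_norm):
    lm = np.asarray(lm_norm, dtype=float)
    return active_force_length(lm) * (-2.0 * (lm - 1.0) / ACTIVE_FL_GAMMA)


def passive_force_length_deriv(lm_norm, scale=1.0):
    lm = np.asarray(lm_norm, dtype=float)
    d = (PASSIVE_KPE / PASSIVE_E0) * np.exp(PASSIVE_KPE * (lm - 1.0) / PASSIVE_E0) \
        / (np.exp(PASSIVE_KPE) - 1.0)
    return scale * np.where(lm > 1.0, d, 0.0)


def force_velocity_deriv(vm_norm, v_max: float = 15.0):
    """d(fv)/d(vm_norm)."""
    v = np.asarray(vm_norm, dtype=float) / v_max
    v = np.clip(v, -1.0, np.inf)
    d_conc = (1.0 + 1.0 / FV_AF) / (1.0 - v / FV_AF) ** 2
    slope0 = 1.0 + 1.0 / FV_AF
    k_ecc = slope0 / (FV_FLEN - 1.0)
    d_ecc = (FV_FLEN - 1.0) * k_ecc / (1.0 + k_ecc * v) ** 2
    return np.where(v < 0.0, d_conc, d_ecc) / v_max


def tendon_force_deriv_strain(strain, f_max_iso, tendon_strain_at_fmax):
    """d(tendon force)/d(strain)."""
    e = np.asarray(strain, dtype=float) / tendon_strain_at_fmax
    d = f_max_iso * (TENDON_KT / tendon_strain_at_fmax) * np.exp(TENDON_KT * e) \
        / (np.exp(TENDON_KT) - 1.0)
    return np.where(e > 0.0, d, 0.0)


def force_multipliers(lm_norm, vm_norm, activation, v_max: float = 15.0,
                      passive_scale: float = 1.0):
    """(active_fl, passive_fl, fv) multiplier triple."""
    return (
        active_force_length(lm_norm),
        passive_force_length(lm_norm, passive_scale),
        force_velocity(vm_norm, v_max),
    )


def tendon_force_from_strain(strain, f_max_iso, tendon_strain_at_fmax):
    """Tendon force (N): 0 when slack, F_max at the characteristic strain.

    All arguments broadcast; parameters may be arrays for batched muscles.
    """
    if np.any(np.asarray(f_max_iso) <= 0) or np.any(np.asarray(tendon_strain_at_fmax) <= 0):
        raise ValueError("f_max_iso and tendon_strain_at_fmax must be > 0")
    e = np.asarray(strain, dtype=float) / tendon_strain_at_fmax
    f = f_max_iso * (np.exp(TENDON_KT * e) - 1.0) / (np.exp(TENDON_KT) - 1.0)
    return np.where(e > 0.0, f, 0.0)


def tendon_strain_from_force(force_n, f_max_iso: float, tendon_strain_at_fmax: float):
    """Inverse of :func:`tendon_force_from_strain` for force >= 0."""
    fn = np.asarray(force_n, dtype=float) / f_max_iso
    e = np.log1p(fn * (np.exp(TENDON_KT) - 1.0)) / TENDON_KT
    return np.where(fn > 0.0, e * tendon_strain_at_fmax, 0.0)


# ---------------------------------------------------------------------------
# fiber-tendon equilibrium


def fiber_tendon_residual(lm_norm: float, mtu_length: float, activation: float,
                          p: MuscleParams, vm_norm: float = 0.0) -> float:
    """Fiber force minus tendon force, in units of F_max (zero pennation)."""
    lt = mtu_length - lm_norm * p.l_opt_m
    strain = (lt - p.l_tendon_slack_m) / p.l_tendon_slack_m
    f_t = tendon_force_from_strain(strain, p.f_max_iso_n, p.tendon_strain_at_fmax)
    f_l = active_force_length(lm_norm)
    f_p = passive_force_length(lm_norm, p.passive_curve_scale)
    f_v = force_velocity(vm_norm, p.v_max_lopt_per_s)
    f_m = p.f_max_iso_n * (activation * f_l * f_v + f_p)
    return float((f_m - f_t) / p.f_max_iso_n)


def equilibrate(mtu: MTUKinematics, activation: float, p: MuscleParams,
                tol: float = 1e-9, max_iter: int = 100) -> MuscleState:
    """Solve for the fiber length balancing fiber and tendon force.

    Used to initialize muscle states at t=0 (isometric: fv = 1) and as the
    rigid-tendon/diagnostic path.  Damped bisection-Newton on the normalized
    fiber length; raises :class:`EquilibrationError` when the geometry is
    infeasible (MTU shorter than slack tendon plus a minimum fiber).
    """
    if not 0.0 <= activation <= 1.0:
        raise ValueError("activation must be in [0, 1]")
    if mtu.mtu_length_m <= 0:
        raise ValueError("mtu_length must be > 0")
    lm_min = 0.01
    lm_max = max((mtu.mtu_length_m - 0.5 * p.l_tendon_slack_m) / p.l_opt_m, lm_min + 1e-6)
    f = lambda lm: fiber_tendon_residual(lm, mtu.mtu_length_m, activation, p)
    r_lo, r_hi = f(lm_min), f(lm_max)
    # r(lm_min) < 0 (stretched tendon dominates), r(lm_max) > 0 (slack tendon,
    # passive fiber) for feasible geometry
    if r_lo >= 0.0 or r_hi <= 0.0:
        raise EquilibrationError(p.name, "infeasible fiber-tendon geometry",
                                 residual=min(abs(r_lo), abs(r_hi)))
    lo, hi = lm_min, lm_max
    lm = 0.5 * (lo + hi)
    for _ in range(max_iter):
        r = f(lm)
        if abs(r) < tol:
            break
        if r < 0.0:
            lo = lm
        else:
            hi = lm
        # damped Newton with bisection fallback
        h = 1e-7
        dr = (f(lm + h) - r) / h
        step = -r / dr if dr != 0 else 0.0
        cand = lm + step
        lm = cand if lo < cand < hi else 0.5 * (lo + hi)
    else:
        raise EquilibrationError(p.name, "equilibrium solve did not converge",
                                 residual=abs(f(lm)))
    return MuscleState(activation=activation, norm_fiber_length=float(lm))


def fiber_velocity_from_force(lm_norm, mtu_length, activation, p: MuscleParams,
                              min_denominator: float = 0.05):
    """Normalized fiber velocity from the force-velocity inversion.

    Given the tendon force implied by the current fiber length and the
    active/passive multipliers, solve the Hill relation for fiber velocity.
    The activation * active-fl denominator is floored to keep the ODE
    well-conditioned when the muscle is nearly inactive or far off-range.
    """
    lt = mtu_length - lm_norm * p.l_opt_m
    strain = (lt - p.l_tendon_slack_m) / p.l_tendon_slack_m
    f_t = tendon_force_from_strain(strain, p.f_max_iso_n, p.tendon_strain_at_fmax)
    f_l = active_force_length(lm_norm)
    f_p = passive_force_length(lm_norm, p.passive_curve_scale)
    denom = np.maximum(activation * f_l, min_denominator)
    fv_mult = (f_t / p.f_max_iso_n - f_p) / denom
    return force_velocity_inverse(fv_mult, p.v_max_lopt_per_s)


def muscle_output(state: MuscleState, mtu: MTUKinematics, p: MuscleParams,
                  vm_norm: float) -> MuscleOutput:
    lt = mtu.mtu_length_m - state.norm_fiber_length * p.l_opt_m
    strain = (lt - p.l_tendon_slack_m) / p.l_tendon_slack_m
    f_t = float(tendon_force_from_strain(strain, p.f_max_iso_n, p.tendon_strain_at_fmax))
    f_l = float(active_force_length(state.norm_fiber_length))
    f_p = float(passive_force_length(state.norm_fiber_length, p.passive_curve_scale))
    f_v = float(force_velocity(vm_norm, p.v_max_lopt_per_s))
    f_m = p.f_max_iso_n * (state.activation * f_l * f_v + f_p)
    return MuscleOutput(tendon_force_n=f_t, fiber_force_n=float(f_m),
                        active_fl=f_l, passive_fl=f_p, fv=f_v)


# ---------------------------------------------------------------------------
# metabolic energetics (Umberger model, Uchida modifications)

#: muscle density (kg/m^3) and specific tension (Pa) for mass estimation
MUSCLE_DENSITY = 1059.7
SPECIFIC_TENSION = 0.25e6
#: default fraction of slow-twitch fibers (per-muscle values would refine this)
DEFAULT_SLOW_TWITCH_FRACTION = 0.5
#: whole-body basal rate (W/kg); the characteristic value used with this
#: muscle energetics model in musculoskeletal simulation
BASAL_RATE_W_PER_KG = 1.2
#: aerobic scaling factor for steady-state (walking) conditions
AEROBIC_SCALE = 1.5


def muscle_mass_kg(p: MuscleParams) -> float:
    """Estimate muscle mass from F_max (at base strength), l_opt and density.

    The unimpaired F_max is used so that modelled weakness (a force-scaling
    transform) does not change the physical muscle mass.
    """
    pcsa = p.f_max_iso_base_n / SPECIFIC_TENSION
    return MUSCLE_DENSITY * pcsa * p.l_opt_base_m


def metabolic_rate(state: MuscleState, output: MuscleOutput, vm_norm: float,
                   excitation: float, p: MuscleParams,
                   mass_kg: float | None = None,
                   slow_twitch_fraction: float = DEFAULT_SLOW_TWITCH_FRACTION) -> float:
    """Gross metabolic rate of one muscle (W), Umberger-style.

    Terms: activation + maintenance heat (fiber-type weighted, scaled by the
    active force-length multiplier outside the optimal range), shortening /
    lengthening heat, and positive mechanical fiber work; the total is
    clamped at zero (energy cannot flow from muscle to metabolic stores).
    """
    if mass_kg is None:
        mass_kg = muscle_mass_kg(p)
    u = float(np.clip(excitation, 0.0, 1.0))
    a = float(np.clip(state.activation, 0.0, 1.0))
    ft = slow_twitch_fraction
    # intensity: excitation when rising, blended when falling (Umberger A)
    A = u if u > a else 0.5 * (u + a)
    A_am = A**0.6
    A_s = A**2.0

    # activation + maintenance heat rate (W/kg)
    h_am = 1.28 * (100.0 * ft) + 25.0
    f_iso = output.active_fl
    lm = state.norm_fiber_length
    scale = 1.0 if lm <= 1.0 else 0.4 + 0.6 * f_iso
    h_am_rate = h_am * A_am * scale

    # shortening / lengthening heat rate (W/kg)
    vmax_ft = p.v_max_lopt_per_s            # fast-twitch max velocity
    vmax_st = vmax_ft / 2.5                  # slow-twitch max velocity
    alpha_st = 4.0 * 25.0 / vmax_st          # 100/vmax_st
    alpha_ft = 1.0 * 153.0 / vmax_ft
    alpha_l = 0.3 * alpha_st
    if vm_norm <= 0.0:  # shortening
        h_sl = -alpha_st * vm_norm * ft - alpha_ft * vm_norm * (1.0 - ft)
        h_sl_rate = h_sl * A_s
        if lm > 1.0:
            h_sl_rate *= f_iso
    else:  # lengthening
        h_sl_rate = alpha_l * vm_norm * A
        if lm > 1.0:
            h_sl_rate *= f_iso
    # mechanical work rate of the fiber per unit mass; only positive (CE
    # shortening) work costs energy, eccentric work is not recovered (Uchida)
    vm_m_s = vm_norm * p.l_opt_m
    w_rate = max(-output.fiber_force_n * vm_m_s, 0.0) / mass_kg

    total = AEROBIC_SCALE * (h_am_rate + h_sl_rate) + w_rate
    return float(max(total, 0.0) * mass_kg)
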