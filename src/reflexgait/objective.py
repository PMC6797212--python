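"""Rollout objective: J = w_cot*J_cot + w_spd*J_spd + w_inj*J_inj + w_head*J_head.

The four terms express the high-level tasks of walking: minimize gross
metabolic cost of transport, keep every step's speed inside a prescribed
range without falling, avoid engaging the joint limit ligaments, and keep
head accelerations inside bounds observed in human walking.

The per-step speed penalty v_s,pen is 0 for a rollout that fell and
max(0, 1 m/s - Psi(v_s, v_min, v_max)) otherwise, where Psi is a linear
out-of-range penalty.  Step penalties are weighted by step duration and
normalized by the desired simulation time:

    J_spd = 1 - sum_s t_s * v_s,pen / (t_des * 1 m/s)

which is 0 for a completed rollout whose steps cover the simulation with
in-range speeds and 1 for an immediate fall.  All integrals use trapezoidal
quadrature on the trajectory's output grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

G_STANDARD = 9.80665


@dataclass(frozen=True)
class ObjectiveWeights:
    w_cot: float = 1.0        # kg*m/J
    w_spd: float = 10_000.0   # 1/s
    w_inj: float = 0.1        # (N*m)^-2 s^-1
    w_head: float = 0.25      # s^3/m^2

    def __post_init__(self) -> None:
        for f in ("w_cot", "w_spd", "w_inj", "w_head"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass(frozen=True)
class SpeedSpec:
    v_min_m_s: float
    v_max_m_s: float

    def __post_init__(self) -> None:
        if not self.v_min_m_s < self.v_max_m_s:
            raise ValueError("v_min must be < v_max")

    @classmethod
    def prescribed(cls, v_target: float, half_band: float = 0.05) -> "SpeedSpec":
        """Prescribed-speed protocol: v_target +- 0.05 m/s."""
        return cls(v_target - half_band, v_target + half_band)

    @classmethod
    def self_selected(cls, v_min: float = 0.75) -> "SpeedSpec":
        """Self-selected protocol: minimum speed only, no upper bound."""
        return cls(v_min, math.inf)


@dataclass(frozen=True)
class StepRecord:
    duration_s: float
    speed_m_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("step duration must be > 0")


@dataclass(frozen=True)
class HeadAccelBounds:
    ax_min: float = -0.25 * G_STANDARD
    ax_max: float = 0.25 * G_STANDARD
    ay_min: float = -0.50 * G_STANDARD
    ay_max: float = 0.50 * G_STANDARD

    def __post_init__(self) -> None:
        if not (self.ax_min < self.ax_max and self.ay_min < self.ay_max):
            raise ValueError("acceleration bounds must satisfy min < max")


@dataclass(frozen=True)
class ObjectiveBreakdown:
    j_total: float
    j_cot_raw: float
    j_spd_raw: float
    j_inj_raw: float
    j_head_raw: float
    weights: ObjectiveWeights

    @property
    def weighted(self) -> dict[str, float]:
        w = self.weights
        return {
            "cot": w.w_cot * self.j_cot_raw,
            "spd": w.w_spd * self.j_spd_raw,
            "inj": w.w_inj * self.j_inj_raw,
            "head": w.w_head * self.j_head_raw,
        }


def psi(phi: float, phi_min: float, phi_max: float) -> float:
    """Linear out-of-range penalty: 0 inside (phi_min, phi_max)."""
    if not phi_min < phi_max:
        raise ValueError("phi_min must be < phi_max")
    if phi < phi_min:
        return phi_min - phi
    if phi > phi_max:
        return phi - phi_max
    return 0.0


def j_spd(steps: list[StepRecord], t_end: float, t_des: float,
          t_fall: float | None, spec: SpeedSpec) -> float:
    """Speed/fall penalty in [0, 1]; 0 = completed with all steps in range."""
    fell = t_fall is not None
    total = 0.0
    for s in steps:
        if fell:
            pen = 0.0
        else:
            pen = max(0.0, 1.0 - psi(s.speed_m_s, spec.v_min_m_s, spec.v_max_m_s))
        total += s.duration_s * pen
    return float(np.clip(1.0 - total / (t_des * 1.0), 0.0, 1.0))


def j_cot(metabolic_rate_w: np.ndarray, t: np.ndarray, mass_kg: float,
          distance_m: float) -> float:
    """Gross cost of transport: integral of Edot over m*d, J/(kg*m)."""
    if distance_m <= 0:
        raise ValueError("distance travelled must be > 0 for cost of transport")
    energy = float(np.trapezoid(metabolic_rate_w, t))
    return energy / (mass_kg * distance_m)


def j_inj(ligament_torques_nm: np.ndarray, t: np.ndarray) -> float:
    """Injury penalty: integral of the sum of squared ligament torques."""
    torques = np.atleast_2d(np.asarray(ligament_torques_nm, dtype=float))
    if torques.shape[0] != len(t):
        torques = torques.T
    return float(np.trapezoid((torques**2).sum(axis=1), t))


def j_head(head_acc: np.ndarray, t: np.ndarray,
           bounds: HeadAccelBounds = HeadAccelBounds()) -> float:
    """Head-stability penalty: integral of squared out-of-bound accelerations."""
    ax, ay = head_acc[:, 0], head_acc[:, 1]
    px = np.maximum(bounds.ax_min - ax, 0.0) + np.maximum(ax - bounds.ax_max, 0.0)
    py = np.maximum(bounds.ay_min - ay, 0.0) + np.maximum(ay - bounds.ay_max, 0.0)
    return float(np.trapezoid(px**2 + py**2, t))


def evaluate(trajectory, spec: SpeedSpec,
             weights: ObjectiveWeights = ObjectiveWeights(),
             bounds: HeadAccelBounds = HeadAccelBounds(),
             distance_floor_m: float | None = None) -> ObjectiveBreakdown:
    """Score a rollout: returns the raw terms, weights and total J.

    Steps are segmented from the trajectory's GRF channels.  ``distance_floor_m``
    optionally clamps the distance travelled from below so that rollouts that
    barely move score a finite (large) cost of transport instead of raising;
    the shooting optimizer uses this to keep the search space total.
    """
    from reflexgait import gait_metrics

    for ch in ("metabolic_rate_w", "ligament_torques", "head_acc", "grf", "com"):
        if getattr(trajectory, ch, None) is None:
            raise ValueError(f"trajectory is missing required channel {ch!r}")

    events = gait_metrics.segment_steps(trajectory)
    steps = [StepRecord(duration_s=s.duration_s, speed_m_s=s.speed_m_s)
             for s in events.steps]
    jspd = j_spd(steps, t_end=float(trajectory.t[-1]), t_des=trajectory.t_des,
                 t_fall=trajectory.t_fall, spec=spec)
    distance = float(trajectory.com[-1, 0] - trajectory.com[0, 0])
    if distance_floor_m is not None:
        distance = max(distance, distance_floor_m)
    jcot = j_cot(trajectory.metabolic_rate_w, trajectory.t,
                 trajectory.total_mass_kg, distance)
    jinj = j_inj(trajectory.ligament_torques, trajectory.t)
    jhead = j_head(trajectory.head_acc, trajectory.t, bounds)
    total = (weights.w_cot * jcot + weights.w_spd * jspd
             + weights.w_inj * jinj + weights.w_head * jhead)
    return ObjectiveBreakdown(j_total=total, j_cot_raw=jcot, j_spd_raw=jspd,
                              j_inj_raw=jinj, j_head_raw=jhead, weights=weights)
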