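"""Planar musculoskeletal model definition, construction and deficit transforms.

The model is a sagittal-plane walker: a lumped trunk (pelvis + torso + head +
arms, lumbar locked at 5 deg flexion) connected to the ground by a 3-DOF planar
joint, with a pin hip, a 1-DOF knee (optionally with coupled tibiofemoral
translation) and a pin ankle per leg -- nine mobile degrees of freedom in
total.  Eighteen Hill-type muscle-tendon units (nine per leg) actuate the
model: GMAX, HAMS, ILPSO, RF, VAS, BFSH, GAS, SOL and TA.

Weakness is modelled by scaling a muscle's maximum isometric force to 25%,
12.5% or 6.25% of its unimpaired value; contracture by scaling its optimal
fiber length to 85%, 70% or 55%.  Transforms always scale from the stored
unimpaired base value, so chains of increasing severity do not compound, and
are applied bilaterally.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

MUSCLE_GROUPS = ("GMAX", "HAMS", "ILPSO", "RF", "VAS", "BFSH", "GAS", "SOL", "TA")
SIDES = ("l", "r")

DEFICIT_TARGETS = ("SOL", "GAS", "PF")
DEFICIT_KINDS = ("weakness", "contracture")
DEFICIT_SEVERITIES = ("mild", "moderate", "severe")

#: fraction of the unimpaired value retained per severity
WEAKNESS_SCALE = {"mild": 0.25, "moderate": 0.125, "severe": 0.0625}
CONTRACTURE_SCALE = {"mild": 0.85, "moderate": 0.70, "severe": 0.55}

MOBILE_DOF_NAMES = (
    "pelvis_x", "pelvis_y", "pelvis_tilt",
    "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r",
)

#: canonical ordering of the 18 MTUs used by all array-valued interfaces
MUSCLE_ORDER = tuple(f"{g}_{s}" for s in SIDES for g in MUSCLE_GROUPS)


class ModelConfigError(ValueError):
    """Raised when a model file is missing entries or violates invariants."""


class DeficitError(ValueError):
    """Raised for an unknown deficit target, kind or severity."""


@dataclass(frozen=True)
class SegmentSpec:
    name: str
    mass_kg: float
    moment_of_inertia_kgm2: float
    length_m: float
    com_offset_m: float
    com_drop_m: float = 0.0

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ModelConfigError(f"segment {self.name}: mass must be > 0")
        if self.length_m <= 0:
            raise ModelConfigError(f"segment {self.name}: length must be > 0")
        if self.moment_of_inertia_kgm2 < 0:
            raise ModelConfigError(f"segment {self.name}: inertia must be >= 0")


@dataclass(frozen=True)
class JointSpec:
    name: str
    kind: str  # planar-3dof | pin-1dof | coupled-knee-1dof | locked
    parent: str
    child: str
    location_in_parent_m: tuple[float, float] = (0.0, 0.0)
    axis_sign: int = 1
    locked_angle_rad: float = 0.0
    range_limits_rad: tuple[float, float] | None = None
    coupling_poly_x: tuple[float, ...] = ()
    coupling_poly_y: tuple[float, ...] = ()

    KINDS = ("planar-3dof", "pin-1dof", "coupled-knee-1dof", "locked")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ModelConfigError(f"joint {self.name}: unknown kind {self.kind!r}")

    @property
    def n_dof(self) -> int:
        return {"planar-3dof": 3, "pin-1dof": 1, "coupled-knee-1dof": 1, "locked": 0}[self.kind]


@dataclass
class MusclePath:
    """MTU length as reference length plus per-joint polynomials of angle.

    ``L(q) = ref_length_m + sum_j poly_j(theta_j)`` with
    ``poly_j(theta) = c1*theta + c2*theta**2 + ...``; the moment arm about
    joint j is ``-d(poly_j)/d(theta_j)`` (tendon-excursion identity).
    """

    ref_length_m: float
    joint_coeffs: dict[str, tuple[float, ...]]

    def length(self, angles: Mapping[str, float]) -> float:
        total = self.ref_length_m
        for joint, coeffs in self.joint_coeffs.items():
            th = angles[joint]
            total += sum(c * th ** (i + 1) for i, c in enumerate(coeffs))
        return total

    def moment_arm(self, joint: str, angle: float) -> float:
        coeffs = self.joint_coeffs.get(joint)
        if not coeffs:
            return 0.0
        return -sum((i + 1) * c * angle**i for i, c in enumerate(coeffs))


@dataclass
class MuscleParams:
    name: str          # e.g. "SOL_l"
    group: str         # e.g. "SOL"
    side: str          # "l" | "r"
    f_max_iso_n: float
    l_opt_m: float
    l_tendon_slack_m: float
    tendon_strain_at_fmax: float
    v_max_lopt_per_s: float
    tau_act_s: float
    tau_deact_s: float
    passive_curve_scale: float
    path: MusclePath
    # unimpaired values; deficit transforms always scale from these
    f_max_iso_base_n: float = 0.0
    l_opt_base_m: float = 0.0

    def __post_init__(self) -> None:
        if self.f_max_iso_n <= 0 or self.l_opt_m <= 0:
            raise ModelConfigError(f"muscle {self.name}: F_max and l_opt must be > 0")
        if self.f_max_iso_base_n == 0.0:
            self.f_max_iso_base_n = self.f_max_iso_n
        if self.l_opt_base_m == 0.0:
            self.l_opt_base_m = self.l_opt_m

    @property
    def spanned_joints(self) -> tuple[str, ...]:
        return tuple(self.path.joint_coeffs)


@dataclass(frozen=True)
class ContactSphereSpec:
    name: str
    segment: str
    radius_m: float
    location_m: tuple[float, float]
    plane_strain_modulus_n_m2: float = 500_000.0
    dissipation_s_m: float = 1.0
    mu_static: float = 0.8
    mu_dynamic: float = 0.8
    mu_viscous: float = 0.0
    transition_velocity_m_s: float = 0.1
    hc_dissipation_factor: float = 1.5


@dataclass(frozen=True)
class DeficitSpec:
    target: str    # SOL | GAS | PF
    kind: str      # weakness | contracture
    severity: str  # mild | moderate | severe

    def __post_init__(self) -> None:
        if self.target not in DEFICIT_TARGETS:
            raise DeficitError(f"unknown deficit target {self.target!r}")
        if self.kind not in DEFICIT_KINDS:
            raise DeficitError(f"unknown deficit kind {self.kind!r}")
        if self.severity not in DEFICIT_SEVERITIES:
            raise DeficitError(f"unknown deficit severity {self.severity!r}")

    @property
    def muscle_groups(self) -> tuple[str, ...]:
        return ("SOL", "GAS") if self.target == "PF" else (self.target,)

    @property
    def scale(self) -> float:
        table = WEAKNESS_SCALE if self.kind == "weakness" else CONTRACTURE_SCALE
        return table[self.severity]

    def label(self) -> str:
        return f"{self.target}_{self.kind}_{self.severity}"


@dataclass
class LigamentConfig:
    torque_scale_nm: float = 10.0
    exp_rate_per_rad: float = 20.0


@dataclass
class ModelSpec:
    name: str
    gravity_m_s2: float
    segments: dict[str, SegmentSpec]
    joints: dict[str, JointSpec]
    muscles: dict[str, MuscleParams]
    contact: dict[str, ContactSphereSpec]
    ligaments: LigamentConfig
    head_point: tuple[str, tuple[float, float]]
    deficits: tuple[DeficitSpec, ...] = ()

    @property
    def total_mass_kg(self) -> float:
        per_leg = ("femur", "tibia", "foot")
        m = self.segments["trunk"].mass_kg
        m += 2 * sum(self.segments[s].mass_kg for s in per_leg)
        return m

    @property
    def mobile_dof(self) -> int:
        # hip/knee/ankle entries are templates mirrored to both legs
        n = 0
        for j in self.joints.values():
            mult = 2 if j.name in ("hip", "knee", "ankle") else 1
            n += mult * j.n_dof
        return n

    def muscle(self, name: str) -> MuscleParams:
        try:
            return self.muscles[name]
        except KeyError:
            raise ModelConfigError(f"unknown muscle {name!r}") from None

    def validate(self) -> None:
        expected = {f"{g}_{s}" for g in MUSCLE_GROUPS for s in SIDES}
        missing = expected - set(self.muscles)
        if missing:
            raise ModelConfigError(f"missing muscle entries: {sorted(missing)}")
        if self.mobile_dof != 9:
            raise ModelConfigError(f"mobile DOF count {self.mobile_dof} != 9")
        lumbar = self.joints.get("lumbar")
        if lumbar is None or lumbar.kind != "locked":
            raise ModelConfigError("lumbar joint must be present and locked")
        n_planar = sum(1 for j in self.joints.values() if j.kind == "planar-3dof")
        if n_planar != 1:
            raise ModelConfigError("exactly one planar-3dof joint is required")
        heel = [s for s in self.contact.values() if s.radius_m == 0.05]
        toe = [s for s in self.contact.values() if s.radius_m == 0.025]
        if len(heel) != 2 or len(toe) != 4:
            raise ModelConfigError(
                "each foot needs one 0.05 m heel sphere and two 0.025 m toe spheres"
            )
        if not self.deficits:
            self.check_symmetry()

    def check_symmetry(self) -> None:
        """Left/right muscle parameter vectors must be equal when unimpaired."""
        for g in MUSCLE_GROUPS:
            left, right = self.muscles[f"{g}_l"], self.muscles[f"{g}_r"]
            fields = ("f_max_iso_n", "l_opt_m", "l_tendon_slack_m",
                      "tendon_strain_at_fmax", "v_max_lopt_per_s",
                      "tau_act_s", "tau_deact_s", "passive_curve_scale")
            for f_ in fields:
                if getattr(left, f_) != getattr(right, f_):
                    raise ModelConfigError(f"asymmetric unimpaired model: {g}.{f_}")

    def census(self) -> dict[str, int]:
        return {
            "mobile_dof": self.mobile_dof,
            "muscles": len(self.muscles),
            "contact_spheres": len(self.contact),
            "segments": len(self.segments),
        }


def default_model_path() -> Path:
    return Path(str(resources.files("reflexgait").joinpath("data/default_model.yaml")))


def build_default_model(param_table: str | Path | None = None) -> ModelSpec:
    """Build the unimpaired planar model from a YAML parameter table.

    With no argument, the packaged default table is used.  Muscle definitions
    describe one leg and are mirrored to both sides, which makes the
    unimpaired model bilaterally symmetric by construction.
    """
    path = Path(param_table) if param_table is not None else default_model_path()
    if not path.exists():
        raise ModelConfigError(f"model file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _build_from_dict(raw)


def _build_from_dict(raw: Mapping) -> ModelSpec:
    try:
        seg_raw = raw["segments"]
        joints_raw = raw["joints"]
        muscles_raw = raw["muscles"]
        contact_raw = raw["contact"]
    except KeyError as exc:
        raise ModelConfigError(f"model file missing section: {exc}") from None

    segments = {}
    for name, d in seg_raw.items():
        segments[name] = SegmentSpec(
            name=name,
            mass_kg=d["mass_kg"],
            moment_of_inertia_kgm2=d["moment_of_inertia_kgm2"],
            length_m=d["length_m"],
            com_offset_m=d["com_offset_m"],
            com_drop_m=d.get("com_drop_m", 0.0),
        )

    joints = {}
    for name, d in joints_raw.items():
        limits = d.get("range_limits_deg")
        joints[name] = JointSpec(
            name=name,
            kind=d["kind"],
            parent=d["parent"],
            child=d["child"],
            location_in_parent_m=tuple(d.get("location_in_parent_m", (0.0, 0.0))),
            axis_sign=int(d.get("axis_sign", 1)),
            locked_angle_rad=math.radians(d.get("locked_angle_deg", 0.0)),
            range_limits_rad=tuple(math.radians(v) for v in limits) if limits else None,
            coupling_poly_x=tuple(d.get("coupling_poly_x", ()) or ()),
            coupling_poly_y=tuple(d.get("coupling_poly_y", ()) or ()),
        )
    if joints.get("lumbar") is not None:
        lumbar = joints["lumbar"]
        if abs(lumbar.locked_angle_rad - math.radians(5.0)) > 1e-9:
            raise ModelConfigError("lumbar joint must be locked at 5 deg of flexion")

    missing_groups = set(MUSCLE_GROUPS) - set(muscles_raw)
    if missing_groups:
        raise ModelConfigError(f"missing muscle entries: {sorted(missing_groups)}")
    extra = set(muscles_raw) - set(MUSCLE_GROUPS)
    if extra:
        raise ModelConfigError(f"unknown muscle entries: {sorted(extra)}")

    muscles: dict[str, MuscleParams] = {}
    for group, d in muscles_raw.items():
        p = d.get("path", {})
        ref = d["l_opt_m"] + d["l_tendon_slack_m"] + p.get("ref_length_offset_m", 0.0)
        for side in SIDES:
            joint_coeffs = {
                f"{jname}_{side}": tuple(coeffs)
                for jname, coeffs in p.get("joints", {}).items()
            }
            muscles[f"{group}_{side}"] = MuscleParams(
                name=f"{group}_{side}",
                group=group,
                side=side,
                f_max_iso_n=d["f_max_iso_n"],
                l_opt_m=d["l_opt_m"],
                l_tendon_slack_m=d["l_tendon_slack_m"],
                tendon_strain_at_fmax=d["tendon_strain_at_fmax"],
                v_max_lopt_per_s=d.get("v_max_lopt_per_s", 15.0),
                tau_act_s=d.get("tau_act_s", 0.010),
                tau_deact_s=d.get("tau_deact_s", 0.040),
                passive_curve_scale=d.get("passive_curve_scale", 1.0),
                path=MusclePath(ref_length_m=ref, joint_coeffs=joint_coeffs),
            )

    defaults = {k: v for k, v in contact_raw.items() if k != "spheres"}
    contact: dict[str, ContactSphereSpec] = {}
    for side in SIDES:
        for sname, d in contact_raw["spheres"].items():
            contact[f"{sname}_{side}"] = ContactSphereSpec(
                name=f"{sname}_{side}",
                segment=f"foot_{side}",
                radius_m=d["radius_m"],
                location_m=tuple(d["location_m"]),
                plane_strain_modulus_n_m2=defaults.get("plane_strain_modulus_n_m2", 500_000.0),
                dissipation_s_m=defaults.get("dissipation_s_m", 1.0),
                mu_static=defaults.get("mu_static", 0.8),
                mu_dynamic=defaults.get("mu_dynamic", 0.8),
                mu_viscous=defaults.get("mu_viscous", 0.0),
                transition_velocity_m_s=defaults.get("transition_velocity_m_s", 0.1),
                hc_dissipation_factor=defaults.get("hc_dissipation_factor", 1.5),
            )

    lig_raw = raw.get("ligaments", {})
    ligaments = LigamentConfig(
        torque_scale_nm=lig_raw.get("torque_scale_nm", 10.0),
        exp_rate_per_rad=lig_raw.get("exp_rate_per_rad", 20.0),
    )

    hp_raw = raw.get("head_point", {"segment": "trunk", "location_m": [0.0, 0.68]})
    head_point = (hp_raw["segment"], tuple(hp_raw["location_m"]))

    model = ModelSpec(
        name=raw.get("name", "planar-model"),
        gravity_m_s2=raw.get("gravity_m_s2", 9.80665),
        segments=segments,
        joints=joints,
        muscles=muscles,
        contact=contact,
        ligaments=ligaments,
        head_point=head_point,
    )
    model.validate()
    return model


def apply_deficit(model: ModelSpec, deficit: DeficitSpec) -> ModelSpec:
    """Return a new model with the deficit applied bilaterally.

    Scaling is always relative to the stored unimpaired base value, so
    applying a severity chain (mild, then moderate, ...) to successive copies
    does not compound, and re-applying the same deficit is idempotent.
    """
    if not isinstance(deficit, DeficitSpec):
        raise DeficitError(f"expected DeficitSpec, got {type(deficit).__name__}")
    out = copy.deepcopy(model)
    for group in deficit.muscle_groups:
        for side in SIDES:
            m = out.muscles[f"{group}_{side}"]
            if deficit.kind == "weakness":
                m.f_max_iso_n = m.f_max_iso_base_n * deficit.scale
            else:
                m.l_opt_m = m.l_opt_base_m * deficit.scale
    out.deficits = tuple(model.deficits) + (deficit,)
    return out


def apply_deficits(model: ModelSpec, deficits: Iterable[DeficitSpec]) -> ModelSpec:
    for d in deficits:
        model = apply_deficit(model, d)
    return model


def enumerate_deficit_cases() -> list[DeficitSpec]:
    """All 18 deficit cases: 3 targets x 2 kinds x 3 severities.

    Within each (target, kind) pair the ordering is mild, moderate, severe,
    which is the order used by the optimization seeding chain.
    """
    return [
        DeficitSpec(target=t, kind=k, severity=s)
        for t in DEFICIT_TARGETS
        for k in DEFICIT_KINDS
        for s in DEFICIT_SEVERITIES
    ]
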