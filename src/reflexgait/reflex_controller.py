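"""Phase-based reflex gait controller.

A high-level state machine with five phases per leg -- early stance (ES),
mid-stance (MS), pre-swing (PS), swing (S) and landing preparation (LP) --
gates a set of low-level control laws that map delayed muscle and pelvis
sensors to muscle excitations:

    u_C  = K_C
    u_L+ = max(0, K_L+ * [l(t - t_D) - l_o])
    u_V+ = max(0, K_V+ * v(t - t_D))
    u_F+- = +- K_F+- * F(t - t_D)
    u_PD = K_p * [theta(t - t_D) - theta_o] + K_v * thetadot(t - t_D)

Muscle length and velocity are sensed as normalized fiber length and its
rate, force as tendon force over maximum isometric force, and theta is the
pelvis tilt (positive anterior).  Neural delays are fixed per law by the
most proximal joint the target muscle spans: 5 ms (hip), 10 ms (knee), 20 ms
(ankle), and 40 ms for the SOL->TA negative force feedback.  Contributions
of the laws active in a leg's current phase are summed and clamped to [0,1].

Four of the five phase transitions are threshold-gated (the thresholds are
free parameters of the optimization); MS->PS fires when the contralateral
leg enters early stance.  The law-to-muscle-to-phase wiring itself is data:
the packaged default topology exposes exactly 70 gain/offset parameters plus
the 4 thresholds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from reflexgait.msk_model import MUSCLE_ORDER

SIDES = ("l", "r")

#: neural delay (s) by the most proximal joint spanned by each muscle group
MUSCLE_DELAY_S = {
    "GMAX": 0.005, "HAMS": 0.005, "ILPSO": 0.005, "RF": 0.005,
    "VAS": 0.010, "BFSH": 0.010, "GAS": 0.010,
    "SOL": 0.020, "TA": 0.020,
}
SOL_TA_DELAY_S = 0.040

PD_TARGETS = ("ILPSO", "GMAX", "HAMS")

LAW_KINDS = ("C", "L+", "V+", "F+", "F-", "PD")


class ControllerConfigError(ValueError):
    """Raised for an invalid topology or parameter file."""


class GaitPhase(enum.IntEnum):
    ES = 0
    MS = 1
    PS = 2
    S = 3
    LP = 4


_PHASE_ORDER = [GaitPhase.ES, GaitPhase.MS, GaitPhase.PS, GaitPhase.S, GaitPhase.LP]


def next_phase(phase: GaitPhase) -> GaitPhase:
    return _PHASE_ORDER[(int(phase) + 1) % 5]


@dataclass(frozen=True)
class TransitionThresholds:
    es_to_ms_m: float
    ps_to_s_n: float
    s_to_lp_m: float
    lp_to_es_n: float

    NAMES = ("es_to_ms_m", "ps_to_s_n", "s_to_lp_m", "lp_to_es_n")


def update_phase(phases: dict[str, GaitPhase], foot_pelvis_dx: dict[str, float],
                 grf_mag: dict[str, float],
                 thresholds: TransitionThresholds) -> dict[str, GaitPhase]:
    """Advance the per-leg state machine by at most one transition per leg.

    Transitions: ES->MS when the foot-pelvis horizontal distance drops below
    a threshold; MS->PS when the contralateral leg enters ES; PS->S when the
    ipsilateral GRF magnitude drops below a threshold; S->LP when the
    foot-pelvis distance exceeds a threshold; LP->ES when the GRF magnitude
    exceeds a threshold.  Decisions use the previous snapshot of both legs.
    """
    out = {}
    for leg in phases:
        contra = "r" if leg == "l" else "l"
        ph = phases[leg]
        if ph == GaitPhase.ES and foot_pelvis_dx[leg] < thresholds.es_to_ms_m:
            out[leg] = GaitPhase.MS
        elif ph == GaitPhase.MS and phases[contra] == GaitPhase.ES:
            out[leg] = GaitPhase.PS
        elif ph == GaitPhase.PS and grf_mag[leg] < thresholds.ps_to_s_n:
            out[leg] = GaitPhase.S
        elif ph == GaitPhase.S and foot_pelvis_dx[leg] > thresholds.s_to_lp_m:
            out[leg] = GaitPhase.LP
        elif ph == GaitPhase.LP and grf_mag[leg] > thresholds.lp_to_es_n:
            out[leg] = GaitPhase.ES
        else:
            out[leg] = ph
    return out


# ---------------------------------------------------------------------------
# delayed sensing


class HistoryBuffer:
    """Uniformly sampled sensor history with linear-interpolated lookback.

    Before t = 0 the buffer returns the pre-filled initial values.
    """

    def __init__(self, capacity_s: float, dt: float):
        self.capacity_s = capacity_s
        self.dt = dt
        self.n = int(np.ceil(capacity_s / dt)) + 2
        self._data: dict[str, list] = {}
        self._t: list[float] = []

    def reset(self) -> None:
        self._data.clear()
        self._t.clear()

    def append(self, t: float, channels: dict[str, np.ndarray | float]) -> None:
        self._t.append(t)
        for k, v in channels.items():
            self._data.setdefault(k, []).append(np.array(v, dtype=float, ndmin=1))
        if len(self._t) > self.n:
            self._t.pop(0)
            for buf in self._data.values():
                buf.pop(0)

    def value(self, channel: str, t_query: float) -> np.ndarray:
        if t_query < self._t[0] - self.capacity_s - self.dt:
            raise ControllerConfigError(
                f"requested delay exceeds buffer capacity {self.capacity_s}s")
        buf = self._data[channel]
        ts = self._t
        if t_query <= ts[0]:
            return buf[0]
        if t_query >= ts[-1]:
            return buf[-1]
        # uniform grid: locate the bracketing pair
        i = int((t_query - ts[0]) / self.dt)
        i = min(max(i, 0), len(ts) - 2)
        while ts[i + 1] < t_query:
            i += 1
        while ts[i] > t_query:
            i -= 1
        w = (t_query - ts[i]) / (ts[i + 1] - ts[i])
        return (1.0 - w) * buf[i] + w * buf[i + 1]


def sense_delayed(buffer: HistoryBuffer, channel: str, t: float, t_d: float):
    """Channel value at t - t_d, interpolated on the stored history."""
    if t_d > buffer.capacity_s:
        raise ControllerConfigError(
            f"delay {t_d}s exceeds buffer capacity {buffer.capacity_s}s")
    return buffer.value(channel, t - t_d)


# ---------------------------------------------------------------------------
# topology and parameters


@dataclass
class ReflexLaw:
    kind: str                    # C | L+ | V+ | F+ | F- | PD
    target: str                  # muscle group
    phases: tuple[GaitPhase, ...]
    source: str                  # muscle group or "pelvis_tilt"
    delay_s: float
    param_names: tuple[str, ...]  # fully qualified names, in vector order

    def __post_init__(self) -> None:
        if self.kind not in LAW_KINDS:
            raise ControllerConfigError(f"unknown law kind {self.kind!r}")


_LAW_PARAM_FIELDS = {
    "C": ("K",), "L+": ("K", "l_o"), "V+": ("K",), "F+": ("K",),
    "F-": ("K",), "PD": ("kp", "kv", "theta_o"),
}


@dataclass
class ParamSpec:
    name: str
    value: float
    lower: float
    upper: float
    init_sd: float


class ControllerTopology:
    """Declarative law set plus named parameter metadata (bounds, SDs)."""

    def __init__(self, laws: list[ReflexLaw], param_specs: list[ParamSpec],
                 control_dt_s: float = 0.005, history_capacity_s: float = 0.2):
        self.laws = laws
        self.param_specs = param_specs
        self.param_index = {p.name: i for i, p in enumerate(param_specs)}
        self.control_dt_s = control_dt_s
        self.history_capacity_s = history_capacity_s
        self.lint()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "ControllerTopology":
        if path is None:
            path = resources.files("reflexgait").joinpath("data/default_controller.yaml")
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh)
        laws: list[ReflexLaw] = []
        specs: list[ParamSpec] = []
        for entry in raw["laws"]:
            kind = entry["kind"]
            target = entry["target"]
            if target not in MUSCLE_DELAY_S:
                raise ControllerConfigError(f"law targets unknown muscle {target!r}")
            phases = tuple(GaitPhase[p] for p in entry["phases"])
            source = entry.get("source", "pelvis_tilt" if kind == "PD" else target)
            if source != "pelvis_tilt" and source not in MUSCLE_DELAY_S:
                raise ControllerConfigError(f"law senses unknown muscle {source!r}")
            if kind == "F-" and (source, target) != ("SOL", "TA"):
                raise ControllerConfigError(
                    "the only negative force feedback law is SOL -> TA")
            if kind == "PD" and target not in PD_TARGETS:
                raise ControllerConfigError(
                    f"PD laws may only target {PD_TARGETS}, got {target}")
            delay = SOL_TA_DELAY_S if kind == "F-" else MUSCLE_DELAY_S[target]
            tag = "".join(p.name for p in phases)
            names = []
            for pf in _LAW_PARAM_FIELDS[kind]:
                if pf not in entry["params"]:
                    raise ControllerConfigError(
                        f"law {target}/{kind}/{tag}: missing parameter {pf!r}")
                val, lo, hi, sd = entry["params"][pf]
                nm = f"{target}_{kind}_{tag}_{pf}"
                names.append(nm)
                specs.append(ParamSpec(nm, float(val), float(lo), float(hi), float(sd)))
            laws.append(ReflexLaw(kind=kind, target=target, phases=phases,
                                  source=source, delay_s=delay,
                                  param_names=tuple(names)))
        for tname in TransitionThresholds.NAMES:
            val, lo, hi, sd = raw["thresholds"][tname]
            specs.append(ParamSpec(f"threshold_{tname}", float(val), float(lo),
                                   float(hi), float(sd)))
        return cls(laws, specs,
                   control_dt_s=raw.get("control_dt_s", 0.005),
                   history_capacity_s=raw.get("history_capacity_s", 0.2))

    # -- census / lint ------------------------------------------------------

    @property
    def n_gains_offsets(self) -> int:
        return len(self.param_specs) - 4

    @property
    def n_thresholds(self) -> int:
        return 4

    def census(self) -> dict[str, int]:
        return {
            "laws": len(self.laws),
            "gains_offsets": self.n_gains_offsets,
            "thresholds": self.n_thresholds,
            "controller_parameters": len(self.param_specs),
        }

    def lint(self) -> list[str]:
        """Validate structural constraints; returns human-readable notes."""
        notes = []
        seen = set()
        for p in self.param_specs:
            if p.name in seen:
                raise ControllerConfigError(f"duplicate parameter name {p.name}")
            seen.add(p.name)
            if not (p.lower <= p.value <= p.upper):
                raise ControllerConfigError(
                    f"parameter {p.name}: default {p.value} outside bounds")
        for law in self.laws:
            if law.kind == "PD" and law.target not in PD_TARGETS:
                raise ControllerConfigError("PD law on non-hip muscle")
            if law.source != law.target and law.source != "pelvis_tilt" \
                    and (law.source, law.target) != ("SOL", "TA"):
                raise ControllerConfigError(
                    f"cross-muscle law {law.source}->{law.target} not allowed")
        notes.append(f"{len(self.laws)} law instances")
        notes.append(f"{self.n_gains_offsets} gain/offset parameters")
        notes.append(f"{self.n_thresholds} transition thresholds")
        return notes

    # -- parameter vector ---------------------------------------------------

    def default_params(self) -> "ControllerParams":
        return ControllerParams(self, np.array([p.value for p in self.param_specs]))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([p.lower for p in self.param_specs]),
                np.array([p.upper for p in self.param_specs]))

    def init_sds(self) -> np.ndarray:
        return np.array([p.init_sd for p in self.param_specs])

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.param_specs)


@dataclass
class ControllerParams:
    """Name-addressable flat value vector over a topology's parameters."""

    topology: ControllerTopology
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.topology.param_specs),):
            raise ControllerConfigError(
                f"expected {len(self.topology.param_specs)} controller values, "
                f"got {self.values.shape}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.topology.param_index[name]])

    def replace(self, **updates: float) -> "ControllerParams":
        v = self.values.copy()
        for k, val in updates.items():
            v[self.topology.param_index[k]] = val
        return ControllerParams(self.topology, v)

    def thresholds(self) -> TransitionThresholds:
        return TransitionThresholds(*(
            self[f"threshold_{n}"] for n in TransitionThresholds.NAMES))

    def to_dict(self) -> dict[str, float]:
        return {p.name: float(v)
                for p, v in zip(self.topology.param_specs, self.values)}

    @classmethod
    def from_dict(cls, topology: ControllerTopology,
                  d: dict[str, float]) -> "ControllerParams":
        missing = set(topology.param_names) - set(d)
        if missing:
            raise ControllerConfigError(f"missing parameters: {sorted(missing)}")
        return cls(topology, np.array([d[n] for n in topology.param_names]))


# ---------------------------------------------------------------------------
# excitation computation


def compute_excitations(topology: ControllerTopology, params: ControllerParams,
                        delayed, phases: dict[str, GaitPhase]) -> np.ndarray:
    """Sum active-law contributions per muscle, clamped to [0, 1].

    ``delayed(channel, side, delay_s)`` must return the delayed sensor value:
    channel is one of 'length', 'velocity', 'force' (with a muscle group
    encoded as 'length:SOL') or 'pelvis_tilt'/'pelvis_tilt_rate'.
    """
    u = np.zeros(len(MUSCLE_ORDER))
    idx = {nm: i for i, nm in enumerate(MUSCLE_ORDER)}
    for law in topology.laws:
        for side in SIDES:
            if phases[side] not in law.phases:
                continue
            tgt = idx[f"{law.target}_{side}"]
            if law.kind == "C":
                contrib = params[law.param_names[0]]
            elif law.kind == "L+":
                K = params[law.param_names[0]]
                l_o = params[law.param_names[1]]
                l_del = delayed(f"length:{law.source}", side, law.delay_s)
                contrib = max(0.0, K * (l_del - l_o))
            elif law.kind == "V+":
                K = params[law.param_names[0]]
                v_del = delayed(f"velocity:{law.source}", side, law.delay_s)
                contrib = max(0.0, K * v_del)
            elif law.kind in ("F+", "F-"):
                K = params[law.param_names[0]]
                f_del = delayed(f"force:{law.source}", side, law.delay_s)
                contrib = K * f_del if law.kind == "F+" else -K * f_del
            else:  # PD
                kp = params[law.param_names[0]]
                kv = params[law.param_names[1]]
                th_o = params[law.param_names[2]]
                th = delayed("pelvis_tilt", side, law.delay_s)
                thd = delayed("pelvis_tilt_rate", side, law.delay_s)
                contrib = kp * (th - th_o) + kv * thd
            u[tgt] += contrib
    return np.clip(u, 0.0, 1.0)


# ---------------------------------------------------------------------------
# runtime controller


class GaitController:
    """Stateful closed-loop controller driven at a fixed control rate."""

    def __init__(self, topology: ControllerTopology | None = None,
                 params: ControllerParams | np.ndarray | None = None):
        self.topology = topology or ControllerTopology.from_yaml()
        if params is None:
            self.params = self.topology.default_params()
        elif isinstance(params, ControllerParams):
            self.params = params
        else:
            self.params = ControllerParams(self.topology, params)
        self.control_dt = self.topology.control_dt_s
        self._group_idx = {}
        for i, nm in enumerate(MUSCLE_ORDER):
            g, s = nm.rsplit("_", 1)
            self._group_idx[(g, s)] = i
        self.reset()

    def reset(self) -> None:
        self.buffer = HistoryBuffer(self.topology.history_capacity_s, self.control_dt)
        self.phases: dict[str, GaitPhase] | None = None
        self._last_t = None

    # -- phase bookkeeping --------------------------------------------------

    def _init_phases(self, sens) -> dict[str, GaitPhase]:
        th = self.params.thresholds()
        phases = {}
        for i, leg in enumerate(SIDES):
            loaded = sens.grf_mag[i] > 0.5 * th.ps_to_s_n
            dx = sens.foot_pelvis_dx[i]
            if loaded:
                phases[leg] = GaitPhase.ES if dx >= th.es_to_ms_m else GaitPhase.MS
            else:
                # an airborne foot in front of the pelvis is about to land
                phases[leg] = GaitPhase.LP if dx > 0.0 else GaitPhase.S
        if all(p == GaitPhase.MS for p in phases.values()):
            # break the double-mid-stance tie: rear leg begins pre-swing
            rear = "l" if sens.foot_pelvis_dx[0] < sens.foot_pelvis_dx[1] else "r"
            phases[rear] = GaitPhase.PS
        return phases

    def phase_codes(self) -> tuple[int, int]:
        if self.phases is None:
            return (0, 0)
        return (int(self.phases["l"]), int(self.phases["r"]))

    # -- main entry points --------------------------------------------------

    def _append_history(self, t: float, sens) -> None:
        self.buffer.append(t, {
            "length": sens.lm_norm,
            "velocity": sens.vm_norm,
            "force": sens.force_norm,
            "pelvis_tilt": sens.pelvis_tilt,
            "pelvis_tilt_rate": sens.pelvis_tilt_rate,
        })

    def _delayed_getter(self, t: float):
        def delayed(channel: str, side: str, t_d: float) -> float:
            if ":" in channel:
                ch, group = channel.split(":")
                arr = sense_delayed(self.buffer, ch, t, t_d)
                return float(arr[self._group_idx[(group, side)]])
            val = sense_delayed(self.buffer, channel, t, t_d)
            return float(np.atleast_1d(val)[0])
        return delayed

    def initial_excitations(self, sens) -> np.ndarray:
        """Excitations at t = 0 (also primes the history and phases)."""
        self.phases = self._init_phases(sens)
        if not self.buffer._t:
            self._append_history(sens.time, sens)
        return compute_excitations(self.topology, self.params,
                                   self._delayed_getter(sens.time), self.phases)

    def excitations(self, t: float, sens) -> np.ndarray:
        if self.phases is None:
            return self.initial_excitations(sens)
        if self._last_t is None or t > self._last_t:
            self._append_history(t, sens)
            self._last_t = t
            self.phases = update_phase(
                self.phases,
                {"l": float(sens.foot_pelvis_dx[0]), "r": float(sens.foot_pelvis_dx[1])},
                {"l": float(sens.grf_mag[0]), "r": float(sens.grf_mag[1])},
                self.params.thresholds(),
            )
        return compute_excitations(self.topology, self.params,
                                   self._delayed_getter(t), self.phases)


class ConstantController:
    """Open-loop controller emitting fixed excitations (testing utility)."""

    def __init__(self, u: np.ndarray | float = 0.0, control_dt: float = 0.005):
        self.u = np.full(len(MUSCLE_ORDER), u, dtype=float) \
            if np.isscalar(u) else np.asarray(u, dtype=float)
        self.control_dt = control_dt

    def reset(self) -> None:
        pass

    def initial_excitations(self, sens) -> np.ndarray:
        return self.u.copy()

    def excitations(self, t, sens) -> np.ndarray:
        return self.u.copy()

    def phase_codes(self) -> tuple[int, int]:
        return (0, 0)
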