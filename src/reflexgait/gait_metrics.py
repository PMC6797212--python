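"""Gait analysis: step/cycle segmentation, spatiotemporal measures,
cycle-normalized trajectories, and comparison metrics against normative bands.

Foot contact and lift events are detected from each foot's vertical ground
reaction force crossing a small threshold (1% body weight by default) with a
few-sample hysteresis.  A *step* runs from one foot's contact to the next
contact of the other foot; a *gait cycle* runs between successive contacts
of the same foot.  The first two steps of a rollout are excluded from all
summary statistics (start-up transient).

Comparison metrics follow common gait-lab practice: trajectories are
resampled to 101 points at every 1% of the gait cycle; the RMSE against a
normative band is the root-mean-square of per-sample Z-scores (simulation
minus band mean, over band SD); shape similarity is the zero-lag normalized
cross-correlation (Pearson form) of mean-centered trajectories; scalar
measures are compared as Z-scores, flagged when |Z| > 2.

Because normative pediatric/adult gait datasets cannot be redistributed, a
synthetic fixture generator provides smooth, gait-like mean +- SD bands for
testing the metric pipeline; these are *synthetic stand-ins*, not
experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_CYCLE_SAMPLES = 101  # every 1% of the gait cycle


class MetricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# event segmentation


@dataclass(frozen=True)
class Step:
    """Contralateral foot contact to foot contact."""
    t_start: float
    t_end: float
    side: str            # side of the foot whose contact ENDS the step
    speed_m_s: float     # COM forward displacement over duration
    length_m: float      # COM forward displacement between the two contacts
    excluded: bool = False

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class GaitCycle:
    """Ipsilateral foot contact to next ipsilateral contact."""
    side: str
    t_start: float
    t_end: float
    t_liftoff: float | None   # within the cycle; None if foot never unloaded

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start

    @property
    def percent_stance(self) -> float | None:
        if self.t_liftoff is None:
            return None
        return 100.0 * (self.t_liftoff - self.t_start) / self.duration_s


@dataclass
class StepEvents:
    steps: list[Step]
    cycles: list[GaitCycle]
    contacts: dict[str, list[float]]
    liftoffs: dict[str, list[float]]
    status: str = "ok"     # "ok" | "no-contacts" | "continuous-support"

    @property
    def included_steps(self) -> list[Step]:
        return [s for s in self.steps if not s.excluded]


def _loaded_mask(fy: np.ndarray, threshold: float, hysteresis: int = 3) -> np.ndarray:
    """Debounced contact mask: state flips only after `hysteresis` samples."""
    raw = fy > threshold
    out = np.empty_like(raw)
    state = bool(raw[0])
    run = 0
    run_start = 0
    for i, r in enumerate(raw):
        if r != state:
            if run == 0:
                run_start = i
            run += 1
            if run >= hysteresis:
                # debounce confirmed: backdate the flip to the first crossing
                state = r
                out[run_start:i + 1] = state
                run = 0
                continue
        else:
            run = 0
        out[i] = state
    return out


def segment_steps(trajectory, bw_fraction: float = 0.01,
                  hysteresis_samples: int = 3, n_excluded: int = 2) -> StepEvents:
    """Detect contacts/lifts from vertical GRFs and build steps and cycles."""
    t = trajectory.t
    bw = trajectory.total_mass_kg * 9.80665
    threshold = bw_fraction * bw
    contacts: dict[str, list[float]] = {"l": [], "r": []}
    liftoffs: dict[str, list[float]] = {"l": [], "r": []}
    masks = {}
    for side, col in (("l", 1), ("r", 3)):
        fy = trajectory.grf[:, col]
        mask = _loaded_mask(fy, threshold, hysteresis_samples)
        masks[side] = mask
        flips = np.flatnonzero(np.diff(mask.astype(int)))
        for i in flips:
            (contacts if mask[i + 1] else liftoffs)[side].append(float(t[i + 1]))

    if not contacts["l"] and not contacts["r"]:
        if masks["l"].all() and masks["r"].all():
            status = "continuous-support"
        else:
            status = "no-contacts"
        return StepEvents(steps=[], cycles=[], contacts=contacts,
                          liftoffs=liftoffs, status=status)

    com_x = trajectory.com[:, 0]

    def com_at(tq: float) -> float:
        return float(np.interp(tq, t, com_x))

    # interleave contacts from both feet in time; a step ends at each contact
    # whose predecessor was a contact of the other foot
    all_contacts = sorted(
        [(tc, side) for side in ("l", "r") for tc in contacts[side]])
    steps: list[Step] = []
    for (t0, s0), (t1, s1) in zip(all_contacts, all_contacts[1:]):
        if s1 == s0 or t1 <= t0:
            continue
        d = com_at(t1) - com_at(t0)
        steps.append(Step(t_start=t0, t_end=t1, side=s1,
                          speed_m_s=d / (t1 - t0), length_m=d))
    steps = [Step(s.t_start, s.t_end, s.side, s.speed_m_s, s.length_m,
                  excluded=(i < n_excluded)) for i, s in enumerate(steps)]

    cycles: list[GaitCycle] = []
    for side in ("l", "r"):
        cs = contacts[side]
        for t0, t1 in zip(cs, cs[1:]):
            lifts = [tl for tl in liftoffs[side] if t0 < tl < t1]
            cycles.append(GaitCycle(side=side, t_start=t0, t_end=t1,
                                    t_liftoff=lifts[0] if lifts else None))
    cycles.sort(key=lambda c: c.t_start)
    return StepEvents(steps=steps, cycles=cycles, contacts=contacts,
                      liftoffs=liftoffs)


# ---------------------------------------------------------------------------
# spatiotemporal summary


@dataclass
class GaitSummary:
    step_speeds_m_s: np.ndarray
    step_lengths_m: np.ndarray
    cadences_steps_min: np.ndarray
    percent_stance: np.ndarray
    mean_speed_m_s: float
    mean_step_length_m: float
    mean_cadence_steps_min: float
    mean_percent_stance: float
    cost_of_transport_j_kg_m: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_speed_m_s": self.mean_speed_m_s,
            "mean_step_length_m": self.mean_step_length_m,
            "mean_cadence_steps_min": self.mean_cadence_steps_min,
            "mean_percent_stance": self.mean_percent_stance,
            "cost_of_transport_j_kg_m": self.cost_of_transport_j_kg_m,
        }


def spatiotemporal(events: StepEvents, trajectory=None) -> GaitSummary:
    """Per-step spatiotemporal measures over the included (post-transient) steps."""
    steps = events.included_steps
    if not steps:
        raise MetricsError("no included steps to summarize")
    speeds = np.array([s.speed_m_s for s in steps])
    lengths = np.array([s.length_m for s in steps])
    cadences = np.array([60.0 / s.duration_s for s in steps])
    t_incl0 = steps[0].t_start
    stance = np.array([c.percent_stance for c in events.cycles
                       if c.percent_stance is not None and c.t_start >= t_incl0])
    if stance.size and (np.any(stance <= 0) or np.any(stance >= 100)):
        raise MetricsError("degenerate stance fraction outside (0, 100)")
    cot = None
    if trajectory is not None:
        t, com = trajectory.t, trajectory.com[:, 0]
        m = (t >= t_incl0)
        d = float(com[m][-1] - com[m][0])
        if d > 0:
            energy = float(np.trapezoid(trajectory.metabolic_rate_w[m], t[m]))
            cot = energy / (trajectory.total_mass_kg * d)
    return GaitSummary(
        step_speeds_m_s=speeds, step_lengths_m=lengths,
        cadences_steps_min=cadences,
        percent_stance=stance,
        mean_speed_m_s=float(speeds.mean()),
        mean_step_length_m=float(lengths.mean()),
        mean_cadence_steps_min=float(cadences.mean()),
        mean_percent_stance=float(stance.mean()) if stance.size else float("nan"),
        cost_of_transport_j_kg_m=cot,
    )


# ---------------------------------------------------------------------------
# cycle normalization


@dataclass
class CycleTrajectory:
    label: str
    mean: np.ndarray                  # (101,)
    sd: np.ndarray | None = None      # (101,) for reference bands
    percent: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 100.0, N_CYCLE_SAMPLES))

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.shape != (N_CYCLE_SAMPLES,):
            raise MetricsError(
                f"{self.label}: expected {N_CYCLE_SAMPLES} samples, "
                f"got {self.mean.shape}")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


def normalize_cycle(t: np.ndarray, values: np.ndarray,
                    cycles: list[GaitCycle] | list[tuple[float, float]],
                    label: str = "channel") -> CycleTrajectory:
    """Resample a channel onto 0-100% of the gait cycle, averaged over cycles."""
    if not cycles:
        raise MetricsError("at least one complete cycle is required")
    rows = []
    for c in cycles:
        t0, t1 = (c.t_start, c.t_end) if isinstance(c, GaitCycle) else c
        if t1 <= t0 or t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
            raise MetricsError(f"cycle ({t0}, {t1}) not covered by the trace")
        tq = np.linspace(t0, t1, N_CYCLE_SAMPLES)
        rows.append(np.interp(tq, t, values))
    return CycleTrajectory(label=label, mean=np.mean(rows, axis=0))


# ---------------------------------------------------------------------------
# normative bands and comparison metrics


@dataclass
class NormativeBand:
    channels: dict[str, CycleTrajectory]           # mean + sd trajectories
    scalars: dict[str, tuple[float, float]]        # measure -> (mean, sd)


def rmse_sd(sim: CycleTrajectory, ref: CycleTrajectory) -> float:
    """Root-mean-square of per-sample Z-scores of sim against the ref band."""
    if ref.sd is None:
        raise MetricsError("reference band has no SD trajectory")
    if np.any(ref.sd <= 0):
        raise MetricsError("reference SD must be positive everywhere")
    z = (sim.mean - ref.mean) / ref.sd
    return float(np.sqrt(np.mean(z**2)))


def ncc(sim: CycleTrajectory, ref: CycleTrajectory) -> float:
    """Zero-lag normalized cross-correlation of mean-centered trajectories."""
    a = sim.mean - sim.mean.mean()
    b = ref.mean - ref.mean.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise MetricsError("zero-variance trajectory in NCC")
    return float(np.dot(a, b) / (na * nb))


def zscore_panel(measures: dict[str, float], bands: NormativeBand,
                 flag_threshold: float = 2.0) -> dict[str, dict]:
    """Z-scores of scalar gait measures; |Z| strictly above threshold is flagged."""
    out = {}
    for name, value in measures.items():
        if name not in bands.scalars:
            raise MetricsError(f"no normative band for measure {name!r}")
        mean, sd = bands.scalars[name]
        if sd <= 0:
            raise MetricsError(f"non-positive SD for measure {name!r}")
        z = (value - mean) / sd
        # strictly greater than the threshold, with a round-off guard
        out[name] = {"value": value, "mean": mean, "sd": sd, "z": z,
                     "flagged": abs(z) > flag_threshold * (1.0 + 1e-9)}
    return out


def save_normative_bands(band: NormativeBand, directory) -> None:
    """Write bands as one CSV per channel (percent, mean, sd) + scalars JSON."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(directory)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, ch in band.channels.items():
        pd.DataFrame({"percent": ch.percent, "mean": ch.mean, "sd": ch.sd}) \
            .to_csv(outdir / f"{label}.csv", index=False, float_format="%.10g")
    with open(outdir / "scalars.json", "w") as fh:
        json.dump({k: {"mean": m, "sd": s} for k, (m, s) in band.scalars.items()},
                  fh, indent=1, sort_keys=True)


def load_normative_bands(directory) -> NormativeBand:
    """Read a band directory written by :func:`save_normative_bands`."""
    import json
    from pathlib import Path

    import pandas as pd

    indir = Path(directory)
    channels = {}
    for path in sorted(indir.glob("*.csv")):
        frame = pd.read_csv(path)
        channels[path.stem] = CycleTrajectory(
            label=path.stem, mean=frame["mean"].to_numpy(),
            sd=frame["sd"].to_numpy())
    scalars_path = indir / "scalars.json"
    scalars = {}
    if scalars_path.exists():
        with open(scalars_path) as fh:
            scalars = {k: (v["mean"], v["sd"])
                       for k, v in json.load(fh).items()}
    if not channels and not scalars:
        raise MetricsError(f"no normative bands found in {indir}")
    return NormativeBand(channels=channels, scalars=scalars)


DEFAULT_CHANNEL_MENU = (
    "hip_flexion_deg", "knee_flexion_deg", "ankle_dorsiflexion_deg",
    "hip_moment_nm_kg", "knee_moment_nm_kg", "ankle_moment_nm_kg",
    "grf_horizontal_bw", "grf_vertical_bw",
)

DEFAULT_SCALAR_BANDS = {
    "gait_speed_m_s": (1.25, 0.15),
    "percent_stance": (62.0, 3.0),
    "cadence_steps_min": (113.0, 9.0),
    "step_length_m": (0.70, 0.07),
    "peak_plantarflexion_moment_nm_kg": (1.40, 0.20),
    "peak_horizontal_grf_bw": (0.20, 0.04),
    "peak_dorsiflexion_stance_deg": (12.0, 4.0),
    "ankle_angle_at_contact_deg": (0.0, 4.0),
    "mean_stance_hip_flexion_deg": (15.0, 7.0),
    "mean_stance_knee_flexion_deg": (15.0, 7.0),
}


def make_normative_fixture(seed: int = 0,
                           channel_menu: tuple[str, ...] = DEFAULT_CHANNEL_MENU
                           ) -> NormativeBand:
    """Generate synthetic, gait-like normative mean +- SD bands.

    Smooth sinusoid mixtures with phase structure matching typical
    stance/swing proportions (toe-off near 62%), deterministic per seed.
    A stand-in for experimental reference data, for exercising the metric
    pipeline; not a measured dataset.
    """
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, N_CYCLE_SAMPLES)
    base_shapes = {
        "hip_flexion_deg": 20 * np.cos(2 * np.pi * s) + 10,
        "knee_flexion_deg": 18 - 15 * np.cos(2 * np.pi * (s - 0.7))
        + 8 * np.sin(2 * np.pi * 2 * (s - 0.05)),
        "ankle_dorsiflexion_deg": 8 * np.sin(2 * np.pi * (s - 0.08))
        - 12 * np.exp(-((s - 0.62) / 0.08) ** 2),
        "hip_moment_nm_kg": 0.6 * np.cos(2 * np.pi * s)
        * np.exp(-((s - 0.3) / 0.45) ** 2),
        "knee_moment_nm_kg": 0.4 * np.sin(2 * np.pi * 2 * s)
        * np.exp(-((s - 0.25) / 0.3) ** 2),
        "ankle_moment_nm_kg": 1.4 * np.sin(np.pi * np.clip(s / 0.62, 0, 1)) ** 2,
        "grf_horizontal_bw": 0.2 * np.sin(2 * np.pi * np.clip(s / 0.62, 0, 1))
        * (s < 0.62),
        "grf_vertical_bw": (1.0 + 0.15 * np.sin(2 * np.pi * 1.6 * s / 0.62 + 2.0))
        * np.sin(np.pi * np.clip(s / 0.62, 0, 1)) ** 0.5,
    }
    channels = {}
    for label in channel_menu:
        shape = base_shapes.get(label)
        if shape is None:
            shape = np.sin(2 * np.pi * s + rng.uniform(0, 2 * np.pi))
        amp = np.max(np.abs(shape)) or 1.0
        jitter = 0.03 * amp * np.sin(2 * np.pi * s * rng.integers(1, 4)
                                     + rng.uniform(0, 2 * np.pi))
        sd = 0.08 * amp * (1.0 + 0.5 * np.sin(2 * np.pi * s
                                              + rng.uniform(0, 2 * np.pi))**2) + 0.02 * amp
        channels[label] = CycleTrajectory(label=label, mean=shape + jitter, sd=sd)
    scalars = {k: (m + 0.0 * rng.standard_normal(), sd)
               for k, (m, sd) in DEFAULT_SCALAR_BANDS.items()}
    return NormativeBand(channels=channels, scalars=scalars)
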