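"""Run management, configuration and file I/O.

Motion tables use an OpenSim ``.sto``-style dialect: a small key=value
header (version, nRows, nColumns, inDegrees) terminated by ``endheader``,
then a tab-separated table whose first column is time.  Configurations are
YAML with units encoded in field names; every optimization run directory is
self-describing (config snapshot, content hashes, per-generation log, best
solution, replay seed) so results can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from reflexgait import objective as obj
from reflexgait import shooting_optimizer as so
from reflexgait.msk_model import build_default_model
from reflexgait.planar_dynamics import PlanarModel, Trajectory, rollout
from reflexgait.reflex_controller import ControllerParams, ControllerTopology, GaitController


class IntegrityError(RuntimeError):
    """A run record's inputs no longer match their recorded hashes."""


# ---------------------------------------------------------------------------
# motion tables (.sto dialect)


def write_motion_table(path: str | Path, frame: pd.DataFrame,
                       name: str = "trajectory") -> None:
    """Write a time-indexed channel table in the .sto header dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={len(frame)}\n")
        fh.write(f"nColumns={len(frame.columns)}\n")
        fh.write("inDegrees=no\n")
        fh.write("endheader\n")
        fh.write("\t".join(frame.columns) + "\n")
        for _, row in frame.iterrows():
            fh.write("\t".join(format(v, ".10g") for v in row.to_numpy()) + "\n")


def read_motion_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
    except StopIteration:
        raise ValueError(f"{path}: not a motion table (no endheader)") from None
    cols = lines[end + 1].rstrip("\n").split("\t")
    data = [[float(v) for v in ln.split("\t")] for ln in lines[end + 2:] if ln.strip()]
    return pd.DataFrame(data, columns=cols)


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    write_motion_table(path, traj.channel_frame())


#: Trajectory array fields stored in the binary container
_TRAJ_ARRAYS = ("t", "q", "qdot", "excitations", "activations",
                "norm_fiber_lengths", "muscle_forces", "grf", "joint_moments",
                "ligament_torques", "head_acc", "metabolic_rate_w", "com",
                "phases")


def write_trajectory_h5(path: str | Path, traj: Trajectory) -> None:
    """Compact binary container (HDF5) for the full channel set."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name in _TRAJ_ARRAYS:
            fh.create_dataset(name, data=getattr(traj, name))
        fh.attrs["termination"] = traj.termination
        fh.attrs["t_fall"] = np.nan if traj.t_fall is None else traj.t_fall
        fh.attrs["t_des"] = traj.t_des
        fh.attrs["total_mass_kg"] = traj.total_mass_kg


def read_trajectory_h5(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        arrays = {name: fh[name][...] for name in _TRAJ_ARRAYS}
        t_fall = float(fh.attrs["t_fall"])
        return Trajectory(
            **arrays,
            termination=str(fh.attrs["termination"]),
            t_fall=None if np.isnan(t_fall) else t_fall,
            t_des=float(fh.attrs["t_des"]),
            total_mass_kg=float(fh.attrs["total_mass_kg"]),
        )


def trajectory_from_frame(frame: pd.DataFrame, t_des: float | None = None,
                          total_mass_kg: float = 75.16) -> Trajectory:
    """Rebuild a Trajectory from a channel table written by write_trajectory.

    Termination is inferred: if the table ends before t_des the rollout is
    treated as fallen at its last sample.
    """
    from reflexgait.msk_model import MUSCLE_ORDER
    from reflexgait.planar_dynamics import JOINT_DOF_NAMES, MOBILE_DOF_NAMES

    t = frame["time"].to_numpy()
    if t_des is None:
        t_des = float(t[-1])

    def cols(names):
        return np.column_stack([frame[n].to_numpy() for n in names])

    q = cols([f"{nm}_m" if i < 2 else f"{nm}_rad"
              for i, nm in enumerate(MOBILE_DOF_NAMES)])
    fell = t[-1] < t_des - 1e-9
    return Trajectory(
        t=t, q=q,
        qdot=cols([f"{nm}_rate" for nm in MOBILE_DOF_NAMES]),
        excitations=cols([f"exc_{nm}" for nm in MUSCLE_ORDER]),
        activations=cols([f"act_{nm}" for nm in MUSCLE_ORDER]),
        norm_fiber_lengths=np.ones((len(t), 18)),
        muscle_forces=cols([f"force_{nm}_n" for nm in MUSCLE_ORDER]),
        grf=cols(["grf_l_x_n", "grf_l_y_n", "grf_r_x_n", "grf_r_y_n"]),
        joint_moments=cols([f"moment_{nm}_nm" for nm in JOINT_DOF_NAMES]),
        ligament_torques=cols([f"lig_{nm}_nm" for nm in JOINT_DOF_NAMES]),
        head_acc=cols(["head_acc_x_m_s2", "head_acc_y_m_s2"]),
        metabolic_rate_w=frame["metabolic_rate_w"].to_numpy(),
        com=cols(["com_x_m", "com_y_m"]),
        phases=cols(["phase_l", "phase_r"]).round().astype(int),
        termination="fell" if fell else "completed",
        t_fall=float(t[-1]) if fell else None,
        t_des=t_des, total_mass_kg=total_mass_kg,
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    model_file: str | None = None          # None = packaged default
    controller_file: str | None = None
    preset: str = "desk-self-selected"
    rng_seed: int = 1
    output_dir: str = "run"
    deficits: list[dict] = field(default_factory=list)
    weights: dict = field(default_factory=lambda: dataclasses.asdict(obj.ObjectiveWeights()))
    overrides: dict = field(default_factory=dict)  # protocol field overrides

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def build(self):
        """(PlanarModel, ControllerTopology, OptimizationProtocol, weights)."""
        from reflexgait.msk_model import DeficitSpec, apply_deficits

        spec = build_default_model(self.model_file)
        if self.deficits:
            spec = apply_deficits(spec, [DeficitSpec(**d) for d in self.deficits])
        topology = ControllerTopology.from_yaml(self.controller_file)
        presets = so.protocol_presets()
        if self.preset not in presets:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {sorted(presets)}")
        proto = dataclasses.replace(presets[self.preset],
                                    rng_seed=self.rng_seed, **self.overrides)
        weights = obj.ObjectiveWeights(**self.weights)
        return PlanarModel(spec), topology, proto, weights


def content_hash(*texts: str) -> str:
    h = hashlib.sha256()
    for t in texts:
        h.update(t.encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# run records


@dataclass
class RunRecord:
    directory: Path
    config: RunConfig
    input_hash: str
    best_f: float
    best_values: dict[str, float]
    rng_seed: int

    MANIFEST = "manifest.json"

    @classmethod
    def load(cls, directory: str | Path) -> "RunRecord":
        directory = Path(directory)
        with open(directory / cls.MANIFEST) as fh:
            man = json.load(fh)
        with open(directory / "config.yaml") as fh:
            config = RunConfig.from_yaml(fh.read())
        with open(directory / "best_solution.json") as fh:
            best = json.load(fh)
        return cls(directory=directory, config=config,
                   input_hash=man["input_hash"], best_f=man["best_f"],
                   best_values=best, rng_seed=man["rng_seed"])


def save_run(directory: str | Path, config: RunConfig,
             result: so.OptimizationResult) -> RunRecord:
    """Write a self-describing run directory: snapshot, log, best solution."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg_text = config.to_yaml()
    (directory / "config.yaml").write_text(cfg_text)
    ih = content_hash(cfg_text)
    log = pd.DataFrame([dataclasses.asdict(g) for g in result.history])
    log.to_csv(directory / "generations.csv", index=False)
    best = result.best.to_dict()
    with open(directory / "best_solution.json", "w") as fh:
        json.dump(best, fh, indent=1, sort_keys=True)
    manifest = {
        "input_hash": ih,
        "best_f": result.best_f,
        "rng_seed": result.rng_seed,
        "n_evaluations": result.n_evaluations,
    }
    with open(directory / RunRecord.MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return RunRecord(directory=directory, config=config, input_hash=ih,
                     best_f=result.best_f, best_values=best,
                     rng_seed=result.rng_seed)


def run_optimization(config: RunConfig) -> tuple[so.OptimizationResult, RunRecord]:
    """Execute a single optimization run described by a RunConfig."""
    model, topology, proto, weights = config.build()
    x0 = so.DesignVector.default(topology)
    objective_fn = so.make_rollout_objective(model, topology, proto, weights)
    result = so.optimize(objective_fn, x0, proto)
    record = save_run(config.output_dir, config, result)
    return result, record


def reproduce(record: RunRecord, rtol: float = 0.0) -> dict:
    """Re-execute a run from its snapshot + seed and compare best J.

    With the default rtol=0 the comparison is bitwise.  Raises
    :class:`IntegrityError` when the stored config hash does not match.
    """
    cfg_text = (record.directory / "config.yaml").read_text()
    if content_hash(cfg_text) != record.input_hash:
        raise IntegrityError("config snapshot hash mismatch")
    config = RunConfig.from_yaml(cfg_text)
    model, topology, proto, weights = config.build()
    x0 = so.DesignVector.default(topology)
    objective_fn = so.make_rollout_objective(model, topology, proto, weights)
    result = so.optimize(objective_fn, x0, proto)
    if rtol == 0.0:
        match = result.best_f == record.best_f
    else:
        match = abs(result.best_f - record.best_f) <= rtol * abs(record.best_f)
    return {
        "status": "PASS" if match else "FAIL",
        "recorded_best_f": record.best_f,
        "replayed_best_f": result.best_f,
    }


# ---------------------------------------------------------------------------
# convenience: simulate from files


def simulate_from_files(model_file: str | None, controller_file: str | None,
                        params_file: str | None, t_des: float,
                        deficits: list[dict] | None = None) -> Trajectory:
    from reflexgait.msk_model import DeficitSpec, apply_deficits

    spec = build_default_model(model_file)
    if deficits:
        spec = apply_deficits(spec, [DeficitSpec(**d) for d in deficits])
    model = PlanarModel(spec)
    topology = ControllerTopology.from_yaml(controller_file)
    x = so.DesignVector.default(topology)
    if params_file:
        with open(params_file) as fh:
            x = so.DesignVector.from_dict(x, json.load(fh))
    ctrl_vals, init_vals = x.split()
    controller = GaitController(topology, ControllerParams(topology, ctrl_vals))
    return rollout(model, controller, init_vals, t_des)
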