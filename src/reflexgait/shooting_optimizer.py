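"""CMA-ES single-shooting optimization of the gait controller.

The design vector has 90 entries under the default topology: 74 controller
values (70 reflex gains/offsets + 4 phase-transition thresholds) followed by
16 initial-state values (7 joint angles, 9 generalized speeds; pelvis x is
fixed at 0 and pelvis height is solved from the half-body-weight condition).

The optimizer is a standard Covariance Matrix Adaptation Evolution Strategy
(rank-one + rank-mu covariance update, cumulative step-size adaptation) with
population size lambda = 16 and mu = 8 parents by default, per-parameter
initial standard deviations, and box constraints handled by resampling.
Because the search landscape is noisy and non-convex, sets of parallel runs
are restarted from the best solution of the previous set until the set best
improves by less than 5%, and harder cases (slower/faster speeds, more
severe deficits) are seeded from the solution of the neighboring easier
case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from reflexgait import objective as obj
from reflexgait.planar_dynamics import (
    INIT_PARAM_NAMES,
    InitializationError,
    PlanarModel,
    SimulationError,
    rollout,
)
from reflexgait.reflex_controller import (
    ControllerParams,
    ControllerTopology,
    GaitController,
)

#: objective value assigned when a rollout cannot even be initialized
FAILURE_OBJECTIVE = 1.0e7

#: defaults for the 16 initial-state design variables:
#: name -> (value, lower, upper, cma initial SD)
INIT_STATE_DEFAULTS = {
    "pelvis_tilt": (0.02, -0.30, 0.40, 0.03),
    "hip_l": (0.35, -0.80, 1.20, 0.05),
    "hip_r": (-0.02, -0.80, 1.20, 0.05),
    "knee_l": (0.15, -0.05, 1.50, 0.05),
    "knee_r": (0.10, -0.05, 1.50, 0.05),
    "ankle_l": (0.00, -0.60, 0.35, 0.03),
    "ankle_r": (0.00, -0.60, 0.35, 0.03),
    "pelvis_vx": (0.85, -0.50, 2.50, 0.10),
    "pelvis_vy": (0.00, -1.00, 1.00, 0.05),
    "pelvis_tilt_rate": (0.00, -3.00, 3.00, 0.10),
    "hip_l_rate": (0.00, -5.00, 5.00, 0.20),
    "hip_r_rate": (0.00, -5.00, 5.00, 0.20),
    "knee_l_rate": (0.00, -5.00, 5.00, 0.20),
    "knee_r_rate": (0.00, -5.00, 5.00, 0.20),
    "ankle_l_rate": (0.00, -5.00, 5.00, 0.20),
    "ankle_r_rate": (0.00, -5.00, 5.00, 0.20),
}


class OptimizationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# design vector


@dataclass
class DesignVector:
    """Name-addressable optimization vector with bounds and initial SDs."""

    names: tuple[str, ...]
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    init_sd: np.ndarray
    n_controller: int = 0     # leading entries that belong to the controller

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        for f_ in ("values", "lower", "upper", "init_sd"):
            if getattr(self, f_).shape != (n,):
                raise ValueError(f"{f_} must have shape ({n},)")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def with_values(self, values: np.ndarray) -> "DesignVector":
        return replace(self, values=np.asarray(values, dtype=float).copy())

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(controller values, initial-state values)."""
        return self.values[: self.n_controller], self.values[self.n_controller:]

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    @classmethod
    def from_dict(cls, template: "DesignVector", d: dict[str, float]) -> "DesignVector":
        missing = set(template.names) - set(d)
        if missing:
            raise ValueError(f"missing design variables: {sorted(missing)}")
        return template.with_values(np.array([d[n] for n in template.names]))

    @classmethod
    def default(cls, topology: ControllerTopology | None = None) -> "DesignVector":
        topology = topology or ControllerTopology.from_yaml()
        lo_c, hi_c = topology.bounds()
        names = list(topology.param_names)
        values = [p.value for p in topology.param_specs]
        lower, upper = list(lo_c), list(hi_c)
        sds = list(topology.init_sds())
        for nm in INIT_PARAM_NAMES:
            v, lo, hi, sd = INIT_STATE_DEFAULTS[nm]
            names.append(f"init_{nm}")
            values.append(v)
            lower.append(lo)
            upper.append(hi)
            sds.append(sd)
        return cls(names=tuple(names), values=np.array(values),
                   lower=np.array(lower), upper=np.array(upper),
                   init_sd=np.array(sds),
                   n_controller=len(topology.param_specs))

    def random_feasible(self, rng: np.random.Generator) -> "DesignVector":
        """Uniform sample inside the box (a naive starting guess)."""
        return self.with_values(rng.uniform(self.lower, self.upper))


# ---------------------------------------------------------------------------
# protocol


@dataclass
class OptimizationProtocol:
    lambda_: int = 16
    mu: int = 8
    max_generations: int = 1500
    n_parallel: int = 10
    t_des_s: float = 30.0
    improvement_threshold: float = 0.05
    rng_seed: int = 0
    speed_spec: obj.SpeedSpec = field(
        default_factory=lambda: obj.SpeedSpec.self_selected())
    f_target: float | None = None

    def __post_init__(self) -> None:
        if self.mu > self.lambda_:
            raise ValueError("mu must be <= lambda")
        if not 0.0 < self.improvement_threshold < 1.0:
            raise ValueError("improvement threshold must be in (0, 1)")


def protocol_presets() -> dict[str, OptimizationProtocol]:
    """Named optimization protocols.

    ``prescribed-speed`` and ``self-selected`` reproduce the full protocols
    (10 s rollouts / 20 parallel runs / 3000 generations, and 30 s rollouts /
    10 parallel runs / 1500 generations); the ``desk-*`` variants are
    reduced-scale versions for a single workstation CPU.
    """
    return {
        "prescribed-speed": OptimizationProtocol(
            lambda_=16, mu=8, max_generations=3000, n_parallel=20,
            t_des_s=10.0, speed_spec=obj.SpeedSpec.prescribed(1.25)),
        "self-selected": OptimizationProtocol(
            lambda_=16, mu=8, max_generations=1500, n_parallel=10,
            t_des_s=30.0, speed_spec=obj.SpeedSpec.self_selected()),
        "desk-prescribed": OptimizationProtocol(
            lambda_=8, mu=4, max_generations=30, n_parallel=2,
            t_des_s=5.0, speed_spec=obj.SpeedSpec.prescribed(1.25)),
        "desk-self-selected": OptimizationProtocol(
            lambda_=8, mu=4, max_generations=30, n_parallel=2,
            t_des_s=5.0, speed_spec=obj.SpeedSpec.self_selected()),
    }


def pretrained_design_vector(topology: ControllerTopology | None = None
                             ) -> DesignVector:
    """The packaged desk-scale optimized example solution.

    Produced by this package's own CMA-ES shooting optimization of the
    default model (self-selected speed objective) at workstation scale; a
    partial solution that walks for a few seconds, shipped as a starting
    point and demo, not converged steady gait.
    """
    import json
    from importlib import resources

    path = resources.files("reflexgait").joinpath(
        "data/pretrained_self_selected.json")
    with open(str(path)) as fh:
        payload = json.load(fh)
    template = DesignVector.default(topology)
    return DesignVector.from_dict(template, payload["values"])


def prescribed_speed_ladder() -> list[tuple[float, float | None]]:
    """(speed, seed-speed) pairs: train 1.25 m/s first, then seed outward."""
    speeds = [0.50 + 0.25 * i for i in range(7)]
    ladder: list[tuple[float, float | None]] = [(1.25, None)]
    below = [s for s in reversed(speeds) if s < 1.25]
    above = [s for s in speeds if s > 1.25]
    prev = 1.25
    for s in below:
        ladder.append((s, prev))
        prev = s
    prev = 1.25
    for s in above:
        ladder.append((s, prev))
        prev = s
    return ladder


def deficit_seed_chain(target: str, kind: str) -> list[str]:
    """Seeding chain for one deficit family: unimpaired -> mild -> ... -> severe."""
    return ["unimpaired"] + [f"{target}_{kind}_{sev}"
                             for sev in ("mild", "moderate", "severe")]


# ---------------------------------------------------------------------------
# CMA-ES


@dataclass
class GenerationLog:
    generation: int
    best_f: float
    median_f: float
    sigma: float


@dataclass
class OptimizationResult:
    best: DesignVector
    best_f: float
    history: list[GenerationLog]
    rng_seed: int
    n_evaluations: int


class CMAES:
    """Covariance Matrix Adaptation ES with rank-one + rank-mu update.

    Operates in coordinates scaled by the per-parameter initial SDs, so the
    global step size starts at 1.  Box constraints by resampling (with a
    clip fallback after ``max_resample`` draws).
    """

    def __init__(self, x0: np.ndarray, scales: np.ndarray, lower: np.ndarray,
                 upper: np.ndarray, lambda_: int, mu: int,
                 seed: int, sigma0: float = 1.0, max_resample: int = 50):
        self.n = len(x0)
        self.scales = np.where(scales > 0, scales, 1.0)
        self.lower_s = lower / self.scales
        self.upper_s = upper / self.scales
        self.m = np.clip(x0 / self.scales, self.lower_s, self.upper_s)
        self.sigma = sigma0
        self.lambda_ = lambda_
        self.mu = mu
        self.max_resample = max_resample
        self.rng = np.random.default_rng(seed)

        w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
        self.weights = w / w.sum()
        self.mu_eff = 1.0 / np.sum(self.weights**2)
        n, mu_eff = self.n, self.mu_eff
        self.c_sigma = (mu_eff + 2.0) / (n + mu_eff + 5.0)
        self.d_sigma = 1.0 + 2.0 * max(0.0, math.sqrt((mu_eff - 1.0) / (n + 1.0)) - 1.0) \
            + self.c_sigma
        self.c_c = (4.0 + mu_eff / n) / (n + 4.0 + 2.0 * mu_eff / n)
        self.c_1 = 2.0 / ((n + 1.3) ** 2 + mu_eff)
        self.c_mu = min(1.0 - self.c_1,
                        2.0 * (mu_eff - 2.0 + 1.0 / mu_eff) / ((n + 2.0) ** 2 + mu_eff))
        self.chi_n = math.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n * n))

        self.C = np.eye(n)
        self.p_sigma = np.zeros(n)
        self.p_c = np.zeros(n)
        self._decompose()
        self.generation = 0

    def _decompose(self) -> None:
        self.C = 0.5 * (self.C + self.C.T)
        evals, B = np.linalg.eigh(self.C)
        evals = np.maximum(evals, 1e-20)
        self.B = B
        self.D = np.sqrt(evals)
        self.inv_sqrt_C = B @ np.diag(1.0 / self.D) @ B.T

    def ask(self) -> np.ndarray:
        """Sample lambda candidates (in original coordinates)."""
        xs = np.empty((self.lambda_, self.n))
        self._zs = np.empty((self.lambda_, self.n))
        for k in range(self.lambda_):
            for _ in range(self.max_resample):
                z = self.rng.standard_normal(self.n)
                y = self.B @ (self.D * z)
                x = self.m + self.sigma * y
                if np.all(x >= self.lower_s) and np.all(x <= self.upper_s):
                    break
            else:
                x = np.clip(x, self.lower_s, self.upper_s)
                y = (x - self.m) / self.sigma
            self._zs[k] = (x - self.m) / self.sigma
            xs[k] = x
        self._xs = xs
        return xs * self.scales

    def tell(self, f_values: np.ndarray) -> None:
        order = np.argsort(f_values)
        sel = self._xs[order[: self.mu]]
        ys = (sel - self.m) / self.sigma
        y_w = self.weights @ ys
        self.m = self.m + self.sigma * y_w

        self.p_sigma = (1.0 - self.c_sigma) * self.p_sigma + math.sqrt(
            self.c_sigma * (2.0 - self.c_sigma) * self.mu_eff) * (self.inv_sqrt_C @ y_w)
        ps_norm = np.linalg.norm(self.p_sigma)
        h_sigma = ps_norm / math.sqrt(
            1.0 - (1.0 - self.c_sigma) ** (2 * (self.generation + 1))) \
            < (1.4 + 2.0 / (self.n + 1.0)) * self.chi_n
        self.p_c = (1.0 - self.c_c) * self.p_c + (
            math.sqrt(self.c_c * (2.0 - self.c_c) * self.mu_eff) * y_w
            if h_sigma else 0.0)

        rank_mu = sum(w * np.outer(y, y) for w, y in zip(self.weights, ys))
        delta_h = (1.0 - int(h_sigma)) * self.c_c * (2.0 - self.c_c)
        self.C = ((1.0 - self.c_1 - self.c_mu) * self.C
                  + self.c_1 * (np.outer(self.p_c, self.p_c) + delta_h * self.C)
                  + self.c_mu * rank_mu)
        self.sigma *= math.exp((self.c_sigma / self.d_sigma)
                               * (ps_norm / self.chi_n - 1.0))
        self.sigma = min(self.sigma, 1e6)
        self._decompose()
        self.generation += 1


def optimize(objective_fn, x0: DesignVector,
             protocol: OptimizationProtocol) -> OptimizationResult:
    """Run one CMA-ES optimization; returns the best-ever solution.

    ``objective_fn`` maps a raw value vector to a scalar J (lower is
    better).  Candidates that raise are scored FAILURE_OBJECTIVE; if every
    candidate of a generation raises, the optimization aborts.
    """
    es = CMAES(x0.values, x0.init_sd, x0.lower, x0.upper,
               lambda_=protocol.lambda_, mu=protocol.mu,
               seed=protocol.rng_seed)
    best_f = math.inf
    best_x = x0.values.copy()
    history: list[GenerationLog] = []
    n_eval = 0
    for gen in range(protocol.max_generations):
        xs = es.ask()
        fs = np.empty(len(xs))
        n_failed = 0
        for k, x in enumerate(xs):
            try:
                fs[k] = objective_fn(x)
            except Exception:
                fs[k] = FAILURE_OBJECTIVE
                n_failed += 1
            n_eval += 1
        if n_failed == len(xs):
            raise OptimizationError(
                f"every candidate of generation {gen} failed to evaluate")
        es.tell(fs)
        gen_best = float(np.min(fs))
        if gen_best < best_f:
            best_f = gen_best
            best_x = xs[int(np.argmin(fs))].copy()
        history.append(GenerationLog(generation=gen, best_f=gen_best,
                                     median_f=float(np.median(fs)),
                                     sigma=float(es.sigma)))
        if protocol.f_target is not None and best_f <= protocol.f_target:
            break
    return OptimizationResult(best=x0.with_values(best_x), best_f=best_f,
                              history=history, rng_seed=protocol.rng_seed,
                              n_evaluations=n_eval)


def restart_protocol(objective_fn, x0: DesignVector,
                     protocol: OptimizationProtocol,
                     max_sets: int = 20) -> OptimizationResult:
    """Sets of parallel runs re-seeded from the best of the previous set.

    Each set runs ``n_parallel`` optimizations from the same initial guess
    (differing only in RNG seed), takes the best, and seeds the next set
    with it.  Stops when a set's best improves on the previous set's best by
    less than the improvement threshold.
    """
    if protocol.n_parallel < 1:
        raise ValueError("n_parallel must be >= 1")
    seed_x = x0
    prev_best = math.inf
    overall: OptimizationResult | None = None
    for set_idx in range(max_sets):
        set_best: OptimizationResult | None = None
        for run in range(protocol.n_parallel):
            run_proto = replace(protocol,
                                rng_seed=protocol.rng_seed + 1000 * set_idx + run)
            res = optimize(objective_fn, seed_x, run_proto)
            if set_best is None or res.best_f < set_best.best_f:
                set_best = res
        assert set_best is not None
        if overall is None or set_best.best_f < overall.best_f:
            overall = set_best
        improvement = (prev_best - set_best.best_f) / abs(prev_best) \
            if math.isfinite(prev_best) and prev_best != 0 else math.inf
        if improvement < protocol.improvement_threshold:
            break
        prev_best = set_best.best_f
        seed_x = set_best.best
    assert overall is not None
    return overall


# ---------------------------------------------------------------------------
# rollout objective


def make_rollout_objective(model: PlanarModel, topology: ControllerTopology,
                           protocol: OptimizationProtocol,
                           weights: obj.ObjectiveWeights | None = None,
                           distance_floor_m: float = 0.001,
                           n_substeps: int = 5):
    """Build the J(x) callable evaluated by the shooting optimization.

    Each call instantiates the controller from the leading design-vector
    entries, simulates the rollout from the trailing initial-state entries,
    and scores it with the four-term objective.  The distance travelled is
    floored so candidates that stand still receive a finite, heavily
    penalized cost of transport.
    """
    weights = weights or obj.ObjectiveWeights()
    n_ctrl = len(topology.param_specs)

    def objective_fn(x: np.ndarray) -> float:
        ctrl = GaitController(topology, ControllerParams(topology, x[:n_ctrl]))
        try:
            traj = rollout(model, ctrl, x[n_ctrl:], protocol.t_des_s,
                           n_substeps=n_substeps)
        except (InitializationError, SimulationError):
            return FAILURE_OBJECTIVE
        breakdown = obj.evaluate(traj, protocol.speed_spec, weights,
                                 distance_floor_m=distance_floor_m)
        return breakdown.j_total

    return objective_fn
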