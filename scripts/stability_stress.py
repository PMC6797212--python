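"""Optional long-horizon stability stress test (not part of the test suite).

Rolls out a given (or default) parameter set for a long target time —
up to an hour of simulated walking — and reports whether and when the
model fell.  Useful for checking that an optimized solution is stable far
beyond the horizon it was trained on.

Usage:
    python scripts/stability_stress.py --tdes 3600 --params best_solution.json
"""

import argparse
import json
import time

from reflexgait import shooting_optimizer as so
from reflexgait.msk_model import build_default_model
from reflexgait.planar_dynamics import PlanarModel, rollout
from reflexgait.reflex_controller import ControllerParams, ControllerTopology, GaitController


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--tdes", type=float, default=3600.0,
                    help="target simulation time (s)")
    ap.add_argument("--params", type=str, default=None,
                    help="JSON design-vector values (default: shipped defaults)")
    ap.add_argument("--model", type=str, default=None)
    args = ap.parse_args()

    model = PlanarModel(build_default_model(args.model))
    topology = ControllerTopology.from_yaml()
    x = so.DesignVector.default(topology)
    if args.params:
        with open(args.params) as fh:
            x = so.DesignVector.from_dict(x, json.load(fh))
    ctrl_vals, init_vals = x.split()
    controller = GaitController(topology, ControllerParams(topology, ctrl_vals))

    t0 = time.time()
    traj = rollout(model, controller, init_vals, t_des=args.tdes)
    wall = time.time() - t0
    dist = traj.com[-1, 0] - traj.com[0, 0]
    print(f"termination: {traj.termination}"
          + (f" at t={traj.t_fall:.2f} s" if traj.fell else ""))
    print(f"simulated {traj.t[-1]:.2f} s in {wall:.0f} s wall time; "
          f"travelled {dist:.2f} m")


if __name__ == "__main__":
    main()
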