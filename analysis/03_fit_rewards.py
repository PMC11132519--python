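#!/usr/bin/env python
"""Learn implicit rewards from the trajectories by maximum-entropy IRL.

Follows the reward-learning protocol: training-task trajectories from
trials 6-10 (behaviour is assumed stationary by then; transfer trials are
all used), split by target triangle (T2 vs T3), one L1-penalized fit per
(condition, triangle, feature family) with the penalty chosen by 5-fold
cross-validation.  Writes one fit JSON per cell and a normalized reward map.

The full protocol grid {0, 0.1, ..., 2} is used with ``--full``; the
default is a coarse sub-grid so the script finishes in a few minutes.
"""

import argparse
import json
from pathlib import Path

from toh_feedback import FeatureMap, build_graph, cross_validate, triangle_of
from toh_feedback.features import normalize_rewards
from toh_feedback.irl import REWARD_LAMBDA_GRID
from toh_feedback.trajectories import read_jsonl


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/trajectories.jsonl"))
    ap.add_argument("--outdir", type=Path, default=Path("results/irl"))
    ap.add_argument("--conditions", type=int, nargs="+", default=[1, 2, 5])
    ap.add_argument("--task", default="train4", choices=["train4", "transfer5"])
    ap.add_argument("--features", nargs="+", default=["sparse8"],
                    choices=["sparse8", "all_states"])
    ap.add_argument("--full", action="store_true",
                    help="use the full 21-point lambda grid")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    grid = REWARD_LAMBDA_GRID if args.full else (0.0, 0.1, 0.5, 1.0, 2.0)
    n_disks = 4 if args.task == "train4" else 5
    graph = build_graph(n_disks)
    fmaps = {
        "sparse8": FeatureMap.sparse(graph),
        "all_states": FeatureMap.all_states(graph),
    }

    trajs = read_jsonl(args.data)
    trajs = [t for t in trajs if t.task == args.task]
    if args.task == "train4":
        trajs = [t for t in trajs if t.trial >= 6]  # stationary trials only

    for cond in args.conditions:
        for tri in ("T2", "T3"):
            cell = [
                t for t in trajs
                if t.condition == cond and triangle_of(t.target) == tri
            ]
            if len(cell) < 5:
                print(f"condition {cond} {tri}: too few trajectories, skipped")
                continue
            for fname in args.features:
                fm = fmaps[fname]
                res = cross_validate(cell, fm, lambda_grid=grid, folds=5,
                                     seed=args.seed)
                obj = res.to_json_obj(fm)
                obj["normalized_rewards"] = normalize_rewards(
                    res.reward_by_state(fm)
                )
                obj["condition"] = cond
                obj["triangle"] = tri
                obj["task"] = args.task
                out = args.outdir / f"fit_c{cond}_{tri}_{fname}_{args.task}.json"
                out.write_text(json.dumps(obj, indent=1))
                print(
                    f"condition {cond} {tri} {fname}: n={len(cell)} "
                    f"best_lambda={res.best_lambda} logL={res.logL_unpenalized:.1f}"
                )


if __name__ == "__main__":
    main()
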