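#!/usr/bin/env python
"""Score every trial and tabulate performance.

Derives the per-trial score record (move counts, good/bad feedback counts,
sub-goal flag, points, percentage score) for each trajectory, then writes
the success-rate table, the per-trial mean percentage scores, box plots of
percentage scores, and two-sample t-tests comparing the feedback conditions
with the no-feedback baseline.
"""

import argparse
import json
from pathlib import Path

from toh_feedback import Simulator, ExperimentConfig, build_graph
from toh_feedback.planning import records_to_frame, score_trajectory
from toh_feedback.report import (
    score_boxplot,
    success_table,
    trial_mean_barplot,
    trial_means,
    two_sample_t,
)
from toh_feedback.trajectories import read_jsonl


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/trajectories.jsonl"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    trajs = read_jsonl(args.data)
    sim = Simulator(ExperimentConfig())
    records = []
    for t in trajs:
        g = build_graph(4 if t.task == "train4" else 5)
        records.append(score_trajectory(t, sim.values(g, t.target)))
    df = records_to_frame(records)
    df.to_csv(args.outdir / "scores.csv", index=False)

    tab = success_table(df)
    tab.to_csv(args.outdir / "success_table.csv")
    print("success rate (%) by task x condition:")
    print(tab.round(1).to_string())

    tm = trial_means(df)
    tm.to_csv(args.outdir / "trial_means.csv", index=False)

    for task in ("train4", "transfer5"):
        score_boxplot(df, task, args.outdir / f"scores_{task}.png")
        score_boxplot(df, task, args.outdir / f"scores_{task}_solved.png",
                      positive_only=True)
        trial_mean_barplot(df, task, args.outdir / f"trial_means_{task}.png")

    tests = {}
    for task in ("train4", "transfer5"):
        base = df[(df.condition == 1) & (df.task == task)]["pct"]
        for cond in (2, 5):
            other = df[(df.condition == cond) & (df.task == task)]["pct"]
            if len(base) > 1 and len(other) > 1:
                out = two_sample_t(other, base)
                tests[f"cond{cond}_vs_cond1_{task}"] = {"t": out.t, "p": out.p}
    (args.outdir / "t_tests.json").write_text(json.dumps(tests, indent=1))
    print("t-tests (feedback vs no feedback):")
    for k, v in tests.items():
        print(f"  {k}: t={v['t']:.2f}, p={v['p']:.2e}")


if __name__ == "__main__":
    main()
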