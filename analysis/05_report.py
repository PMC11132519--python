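#!/usr/bin/env python
"""Render the reward-map figure grids from the saved IRL fits.

Each figure is a 2 x 3 panel grid: rows are the target triangle of the
fitted data (T2 top, T3 bottom), columns the conditions (no feedback,
numeric feedback, sub-goal with numeric feedback).  Warm colours mark high
normalized rewards.
"""

import argparse
import json
from pathlib import Path

from toh_feedback import build_graph
from toh_feedback.report import reward_panel_grid


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fits", type=Path, default=Path("results/irl"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    by_family: dict = {}
    for path in sorted(args.fits.glob("fit_*.json")):
        obj = json.loads(path.read_text())
        family = (obj["features"], obj["task"])
        by_family.setdefault(family, {})[
            (obj["triangle"], f"cond {obj['condition']}")
        ] = obj["normalized_rewards"]

    if not by_family:
        print(f"no fit files found under {args.fits}; run 03_fit_rewards.py first")
        return
    for (features, task), panels in by_family.items():
        n_disks = 4 if task == "train4" else 5
        graph = build_graph(n_disks)
        out = args.outdir / f"reward_maps_{features}_{task}.png"
        cols = sorted({c for _, c in panels})
        reward_panel_grid(panels, graph, out, row_order=["T2", "T3"],
                          col_order=cols)
        print(f"wrote {out} ({len(panels)} panels)")


if __name__ == "__main__":
    main()
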