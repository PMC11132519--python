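"""Summary tables, significance tests, and reward-map figures.

The reward maps use the recursive triangle embedding of the puzzle graph:
the figure's top corner is the start configuration, the lower-left triangle
is T2 and the lower-right is T3, matching the orientation used throughout
the package.  Every figure helper has a machine-readable twin (the caller
writes the underlying table next to the image).
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .env import TohGraph, TRIANGLE_TO_PEG, _third_peg


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .planning import records_to_frame

    return records_to_frame(records)


def success_table(records) -> pd.DataFrame:
    """Percentage of successful trials per condition and task.

    Empty condition/task cells are reported as missing (NaN), never as zero.
    """
    df = _records_frame(records)
    table = (
        df.groupby(["task", "condition"])["success"]
        .mean()
        .mul(100.0)
        .unstack("condition")
    )
    return table


def trial_means(records) -> pd.DataFrame:
    """Mean percentage score by condition, task, and trial."""
    df = _records_frame(records)
    return (
        df.groupby(["condition", "task", "trial"])["pct"]
        .mean()
        .rename("mean_pct")
        .reset_index()
    )


@dataclass
class TTestOutcome:
    t: float
    p: float
    welch: bool
    degenerate: bool  # both samples had (near-)zero variance


def two_sample_t(a, b, welch: bool = False) -> TTestOutcome:
    """Two-sample t-test on score samples (pooled by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two observations")
    degenerate = bool(np.var(a) == 0 and np.var(b) == 0)
    import warnings

    with warnings.catch_warnings():
        if degenerate:
            warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, equal_var=not welch)
    t = 0.0 if degenerate else float(res.statistic)
    p = 1.0 if degenerate else float(res.pvalue)
    return TTestOutcome(t=t, p=p, welch=welch, degenerate=degenerate)


def sierpinski_layout(graph: TohGraph) -> dict:
    """Deterministic planar coordinates for every configuration.

    Recursive construction: the sub-triangle of the largest remaining disk
    on peg p occupies the corner of peg p, and its corner holding the
    smaller disks on peg q points towards the sub-triangle of the third peg
    (the bridge between the two passes there).  Sub-triangles are scaled by
    slightly less than one half: at exactly one half the two endpoints of
    every bridge edge would land on the same point (the puzzle graph has
    twin bridge vertices where the ideal Sierpinski gasket has one).
    """
    shrink = 0.48
    h = np.sqrt(3.0) / 2.0
    base = {
        TRIANGLE_TO_PEG["T1"]: np.array([0.5, h]),  # start corner on top
        TRIANGLE_TO_PEG["T2"]: np.array([0.0, 0.0]),  # lower-left
        TRIANGLE_TO_PEG["T3"]: np.array([1.0, 0.0]),  # lower-right
    }
    layout = {}
    for state in graph.states:
        corners = dict(base)
        for digit in reversed(state):
            corners = {
                q: corners[digit]
                if q == digit
                else corners[digit]
                + shrink * (corners[_third_peg(digit, q)] - corners[digit])
                for q in corners
            }
        layout[state] = tuple(corners[state[0]])
    return layout


def reward_heatmap(
    reward_by_state: dict,
    graph: TohGraph,
    ax=None,
    path=None,
    title: str | None = None,
    node_size: float = 28.0,
):
    """Draw one reward map on the triangle-embedded graph.

    Warm colours mark high (normalized) rewards, dark blue marks rewards
    near zero, matching the usual presentation of these maps.
    """
    created = ax is None
    if created:
        _, ax = plt.subplots(figsize=(5, 4.5))
    pos = sierpinski_layout(graph)
    for a, b in graph.nx_graph.edges:
        xs, ys = zip(pos[a], pos[b])
        ax.plot(xs, ys, color="0.8", lw=0.5, zorder=1)
    xy = np.array([pos[s] for s in graph.states])
    vals = np.array([reward_by_state.get(s, 0.0) for s in graph.states])
    sc = ax.scatter(
        xy[:, 0], xy[:, 1], c=vals, cmap="jet", vmin=0.0, vmax=1.0,
        s=node_size, zorder=2,
    )
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=9)
    if created and path is not None:
        plt.colorbar(sc, ax=ax, shrink=0.8)
        plt.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def reward_panel_grid(panels: dict, graph: TohGraph, path, col_order=None, row_order=None):
    """A row x column grid of reward maps (e.g. target triangle x condition).

    ``panels`` maps ``(row_label, col_label)`` to a normalized
    reward-by-state dict.
    """
    rows = row_order or sorted({r for r, _ in panels})
    cols = col_order or sorted({c for _, c in panels})
    fig, axes = plt.subplots(
        len(rows), len(cols), figsize=(3.2 * len(cols), 3.0 * len(rows)),
        squeeze=False,
    )
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            ax = axes[i][j]
            if (r, c) in panels:
                reward_heatmap(panels[(r, c)], graph, ax=ax, title=f"{r} | {c}",
                               node_size=14.0)
            else:
                ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def score_boxplot(records, task: str, path, positive_only: bool = False):
    """Box plots of percentage scores per condition for one task.

    Quantile convention: median line, boxes at the 25th/75th percentiles,
    whiskers at the most extreme points within 1.5 IQR, outliers beyond.
    """
    df = _records_frame(records)
    df = df[df["task"] == task]
    if positive_only:
        df = df[df["pct"] > 0]
    conditions = sorted(df["condition"].unique())
    data = [df.loc[df["condition"] == c, "pct"].to_numpy() for c in conditions]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=[str(c) for c in conditions], whis=1.5)
    ax.set_xlabel("condition")
    ax.set_ylabel("percentage score")
    ax.set_title(f"{task}" + (" (solved trials only)" if positive_only else ""))
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def trial_mean_barplot(records, task: str, path):
    """Bar plot of mean percentage score per trial, grouped by condition."""
    tm = trial_means(records)
    tm = tm[tm["task"] == task]
    conditions = sorted(tm["condition"].unique())
    trials = sorted(tm["trial"].unique())
    width = 0.8 / max(len(conditions), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, c in enumerate(conditions):
        sub = tm[tm["condition"] == c].set_index("trial")["mean_pct"]
        ax.bar(
            [t + (i - len(conditions) / 2) * width for t in trials],
            [sub.get(t, np.nan) for t in trials],
            width=width,
            label=f"cond {c}",
        )
    ax.set_xlabel("trial")
    ax.set_ylabel("mean percentage score")
    ax.set_title(task)
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
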