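"""Trajectory records and their JSONL serialization.

One record per trial: the participant, condition, task (4-disk training or
5-disk transfer), the target, the visited state path starting from the
all-on-peg-0 configuration, per-move evaluative feedback (+1/-1, or null
where none was displayed), and the success flag.  The reader re-validates
every structural invariant on load, so downstream stages can trust the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx

from .env import TohGraph, build_graph, legal_moves
from .planning import move_budget

TASKS = ("train4", "transfer5")
TASK_DISKS = {"train4": 4, "transfer5": 5}


class TrajectoryError(ValueError):
    """A trajectory violates a structural invariant."""


@dataclass
class Trajectory:
    """One trial's path with feedback and success metadata."""

    participant_id: str
    condition: int
    task: str
    trial: int
    target: str
    path: list[str]
    feedback: list = field(default_factory=list)
    success: bool = False

    @property
    def moves_used(self) -> int:
        return len(self.path) - 1

    @property
    def steps(self) -> list[tuple[str, str]]:
        """The (state, next_state) pairs of the path."""
        return list(zip(self.path, self.path[1:]))

    def validate(self, graph: TohGraph | None = None) -> "Trajectory":
        if self.task not in TASKS:
            raise TrajectoryError(f"unknown task {self.task!r}")
        if graph is None:
            graph = build_graph(TASK_DISKS[self.task])
        n = graph.n_disks
        if len(self.target) != n:
            raise TrajectoryError(f"target {self.target!r} is not an {n}-disk state")
        if not self.path or self.path[0] != graph.start_state:
            raise TrajectoryError("path must start with all disks on peg 0")
        for a, b in self.steps:
            if b not in legal_moves(a):
                raise TrajectoryError(f"illegal move {a} -> {b}")
        if len(self.feedback) != self.moves_used:
            raise TrajectoryError("feedback list must have one entry per move")
        m_min = _distance(n, self.path[0], self.target)
        m_allowed = move_budget(m_min)
        if self.moves_used > m_allowed:
            raise TrajectoryError(
                f"path uses {self.moves_used} moves, budget is {m_allowed}"
            )
        solved = self.path[-1] == self.target and self.moves_used <= m_allowed
        if self.success != solved:
            raise TrajectoryError("success flag inconsistent with the path")
        return self


@lru_cache(maxsize=4096)
def _distance(n_disks: int, a: str, b: str) -> int:
    return nx.shortest_path_length(build_graph(n_disks).nx_graph, a, b)


def to_json_obj(traj: Trajectory) -> dict:
    return {
        "participant_id": traj.participant_id,
        "condition": traj.condition,
        "task": traj.task,
        "trial": traj.trial,
        "target": traj.target,
        "path": list(traj.path),
        "feedback": [None if h is None else int(h) for h in traj.feedback],
        "success": bool(traj.success),
    }


def write_jsonl(trajectories: list[Trajectory], path) -> None:
    with open(path, "w") as fh:
        for traj in trajectories:
            fh.write(json.dumps(to_json_obj(traj)) + "\n")


def read_jsonl(path, validate: bool = True) -> list[Trajectory]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            traj = Trajectory(
                participant_id=obj["participant_id"],
                condition=int(obj["condition"]),
                task=obj["task"],
                trial=int(obj["trial"]),
                target=obj["target"],
                path=list(obj["path"]),
                feedback=list(obj["feedback"]),
                success=bool(obj["success"]),
            )
            if validate:
                traj.validate()
            out.append(traj)
    return out
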