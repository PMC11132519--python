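"""Optimal planning, evaluative feedback, and trial scoring.

The puzzle is treated as a deterministic MDP whose only reward is earned at
the target configuration.  The target is made absorbing with unit per-step
reward, so the optimal value has the closed form

    V(s) = gamma**d(s) / (1 - gamma),

with ``d`` the breadth-first move distance to the target; value iteration
and the BFS closed form must therefore agree, which the tests exploit.
Evaluative feedback for a move is the sign of the value change: a move that
strictly increases the value (equivalently, decreases the distance) is
"good" (+1), every other move — including the rare move between equidistant
neighbours — is "bad" (-1), since the binary signal shown to players has no
neutral category and a non-improving move wastes budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .env import TohGraph, triangle_of, validate_state
from .softq import graph_arrays

CONDITIONS = (1, 2, 3, 4, 5)

#: points shown to the player for good / bad moves
FEEDBACK_POINTS = 2


@dataclass(frozen=True)
class TaskMdp:
    """One puzzle instance: the graph, a target, and a discount."""

    graph: TohGraph
    target: str
    gamma: float = 0.95

    def __post_init__(self):
        validate_state(self.target)
        if self.target not in set(self.graph.states):
            raise ValueError(f"target {self.target!r} is not a state of the graph")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")

    def reward(self, state: str) -> float:
        return 1.0 if state == self.target else 0.0


@dataclass(eq=False)
class ValueTable:
    """Optimal values and BFS distances for one target."""

    mdp: TaskMdp
    V: dict = field(repr=False)
    dist: dict = field(repr=False)

    def Q(self, state: str, nxt: str) -> float:
        """Optimal action value of the move ``state -> nxt``."""
        if nxt not in self.mdp.graph.nx_graph[state]:
            raise ValueError(f"{state} -> {nxt} is not a legal move")
        return self.mdp.reward(state) + self.mdp.gamma * self.V[nxt]


def solve(mdp: TaskMdp, tol: float = 1e-10, max_iter: int = 100000) -> ValueTable:
    """Value iteration to a sup-norm fixed point, plus BFS distances.

    The absorbing-target convention collects one unit of reward per step at
    the target, so ``V(target) = 1/(1-gamma)`` and ``V(s) = gamma**d/(1-gamma)``
    elsewhere.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    arrays = graph_arrays(mdp.graph)
    t = arrays.index[mdp.target]
    V = np.zeros(arrays.n_states)
    for _ in range(max_iter):
        nbr_vals = np.where(arrays.mask, V[arrays.nbr], -np.inf)
        V_new = mdp.gamma * nbr_vals.max(axis=1)
        V_new[t] = 1.0 + mdp.gamma * V[t]
        residual = np.max(np.abs(V_new - V))
        V = V_new
        if residual <= tol:
            break
    else:
        raise RuntimeError(f"value iteration did not converge (residual {residual:.2e})")
    dist = nx.single_source_shortest_path_length(mdp.graph.nx_graph, mdp.target)
    return ValueTable(
        mdp=mdp,
        V={s: float(V[i]) for i, s in enumerate(arrays.states)},
        dist=dict(dist),
    )


def feedback_for_move(values: ValueTable, s: str, s_next: str) -> int:
    """+1 if the move strictly increases the optimal value, else -1."""
    if s_next not in values.mdp.graph.nx_graph[s]:
        raise ValueError(f"{s} -> {s_next} is not a legal move")
    return 1 if values.V[s_next] > values.V[s] else -1


def feedback_signal(values: ValueTable) -> dict:
    """The full good/bad map H(s, a) keyed by ``(state, next_state)``."""
    return {
        (a, b): feedback_for_move(values, a, b)
        for a in values.mdp.graph.states
        for b in values.mdp.graph.nx_graph[a]
    }


def feedback_array(values: ValueTable) -> np.ndarray:
    """H as a padded ``(S, 3)`` array (+1 good, -1 bad, 0 on padded slots)."""
    arrays = graph_arrays(values.mdp.graph)
    v = np.array([values.V[s] for s in arrays.states])
    H = np.where(v[arrays.nbr] > v[:, None], 1.0, -1.0)
    return np.where(arrays.mask, H, 0.0)


def move_budget(m_min: int) -> int:
    """Allowed moves for a trial: ceil(1.5 * minimum path length)."""
    if not isinstance(m_min, int) or m_min < 1:
        raise ValueError(f"m_min must be a positive integer, got {m_min!r}")
    return math.ceil(1.5 * m_min)


@dataclass
class ScoreRecord:
    """Move counts, feedback counts, and derived scores for one trial."""

    participant: str
    condition: int
    task: str
    trial: int
    m_min: int
    m_allowed: int
    m_used: int
    m_good: int = 0
    m_bad: int = 0
    f_optional: int = 0
    s_subgoal: int = 0
    success: bool = False
    S: float = 0.0
    pct: float = 0.0


class InconsistentRecordError(ValueError):
    pass


def score(condition: int, record: ScoreRecord) -> float:
    """Points for one trial under the given experimental condition.

    Condition 1 (and every transfer trial) earns the base
    ``10 (m_allowed - m_used + 1)``; condition 2 adds ``2 (m_good - m_bad)``;
    condition 3 subtracts one point per feedback request; condition 4 adds 5
    for reaching the sub-goal; condition 5 combines the numeric-feedback and
    sub-goal bonuses.  An unsolved trial scores 0.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if not record.success:
        return 0.0
    if record.m_used > record.m_allowed:
        raise InconsistentRecordError(
            f"solved with m_used={record.m_used} > m_allowed={record.m_allowed}"
        )
    base = 10.0 * (record.m_allowed - record.m_used + 1)
    bonus = FEEDBACK_POINTS * (record.m_good - record.m_bad)
    if condition == 1:
        return base
    if condition == 2:
        return base + bonus
    if condition == 3:
        return base - record.f_optional
    if condition == 4:
        return base + 5.0 * record.s_subgoal
    return base + bonus + 5.0 * record.s_subgoal


def percent_score(record: ScoreRecord) -> float:
    """Percentage score in [0, 100]: 100 at a perfect solve, 0 if unsolved."""
    if record.m_min > record.m_allowed:
        raise InconsistentRecordError("m_min exceeds m_allowed")
    if not record.success:
        return 0.0
    if record.m_used > record.m_allowed:
        raise InconsistentRecordError(
            f"solved with m_used={record.m_used} > m_allowed={record.m_allowed}"
        )
    return 100.0 * (record.m_allowed - record.m_used + 1) / (record.m_allowed - record.m_min + 1)


def score_trajectory(traj, values: ValueTable) -> ScoreRecord:
    """Derive the full :class:`ScoreRecord` for one trajectory.

    Good/bad counts come from the sign of the optimal-value change on every
    move; the optional-feedback request count is the number of moves whose
    feedback was actually displayed (condition 3); the sub-goal flag is set
    when the path visits the T1-side gate of the target triangle.
    """
    graph = values.mdp.graph
    m_min = int(values.dist[traj.path[0]])
    m_allowed = move_budget(m_min)
    m_used = len(traj.path) - 1
    m_good = m_bad = 0
    for a, b in zip(traj.path, traj.path[1:]):
        if feedback_for_move(values, a, b) > 0:
            m_good += 1
        else:
            m_bad += 1
    f_optional = (
        sum(1 for h in traj.feedback if h is not None) if traj.condition == 3 else 0
    )
    gate = graph.gate_state(triangle_of(traj.target))
    s_subgoal = int(gate in traj.path)
    record = ScoreRecord(
        participant=traj.participant_id,
        condition=traj.condition,
        task=traj.task,
        trial=traj.trial,
        m_min=m_min,
        m_allowed=m_allowed,
        m_used=m_used,
        m_good=m_good,
        m_bad=m_bad,
        f_optional=f_optional,
        s_subgoal=s_subgoal,
        success=traj.success,
    )
    # transfer trials always use the no-feedback scoring rule
    cond = traj.condition if traj.task == "train4" else 1
    record.S = score(cond, record)
    record.pct = percent_score(record)
    return record


def records_to_frame(records: list[ScoreRecord]) -> pd.DataFrame:
    """Tabulate score records with the canonical column order."""
    cols = [
        "participant", "condition", "task", "trial", "m_min", "m_allowed",
        "m_used", "m_good", "m_bad", "f_optional", "s_subgoal", "S", "pct",
        "success",
    ]
    return pd.DataFrame([asdict(r) for r in records])[cols]
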