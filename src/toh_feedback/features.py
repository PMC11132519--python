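"""Linear reward features over the state space.

The learned reward is r(s) = theta . f(s).  Two feature families are used:
a one-hot indicator per state (``all_states``, |f| = 3**n) and a one-hot
indicator over the eight sub-triangle vertex states (``sparse8``), which
forces the reward to zero everywhere else and yields much sparser, more
comparable maps.  Arbitrary custom indicator sets are also supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .env import TohGraph, sparse_vertex_states
from .softq import graph_arrays


@dataclass(frozen=True, eq=False)
class FeatureMap:
    """State features as a dense ``(S, F)`` matrix in canonical state order."""

    name: str
    graph: TohGraph
    matrix: np.ndarray
    feature_states: tuple[str, ...] | None = None

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def all_states(cls, graph: TohGraph) -> "FeatureMap":
        n = len(graph.states)
        return cls(
            name="all_states",
            graph=graph,
            matrix=np.eye(n),
            feature_states=graph.states,
        )

    @classmethod
    def sparse(cls, graph: TohGraph, states: list[str] | None = None, name: str = "sparse8") -> "FeatureMap":
        """One-hot features over ``states`` (default: the eight vertex states),
        zero vector elsewhere."""
        if states is None:
            states = sparse_vertex_states(graph.n_disks)
        arrays = graph_arrays(graph)
        mat = np.zeros((arrays.n_states, len(states)))
        for j, s in enumerate(states):
            mat[arrays.index[s], j] = 1.0
        return cls(name=name, graph=graph, matrix=mat, feature_states=tuple(states))

    def reward_vector(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_features,):
            raise ValueError(f"theta must have shape ({self.n_features},)")
        return self.matrix @ theta

    def reward_by_state(self, theta: np.ndarray) -> dict:
        r = self.reward_vector(theta)
        return {s: float(r[i]) for i, s in enumerate(self.graph.states)}


def normalize_rewards(reward_by_state: dict) -> dict:
    """Min-max rescale rewards to [0, 1] for display.

    A constant reward map carries no ordering information and is mapped to
    0.5 everywhere by convention.
    """
    vals = np.array(list(reward_by_state.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi - lo == 0:
        return {s: 0.5 for s in reward_by_state}
    return {s: float((v - lo) / (hi - lo)) for s, v in reward_by_state.items()}
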