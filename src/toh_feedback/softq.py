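"""Soft (maximum-entropy) Bellman machinery on the puzzle graph.

Every state has at most three outgoing moves, so the whole MDP is held in
padded ``(S, 3)`` arrays: ``nbr[s, a]`` is the successor state index of
action ``a`` from state ``s`` and ``mask[s, a]`` marks which slots are real
moves.  The soft backup replaces the max of the classical Bellman operator
with a log-sum-exp,

    V(s) = log sum_a exp( r(s, a) + gamma * V(s') ),

whose fixed point defines the Boltzmann policy P(a|s) = exp(Q - V).  For
gamma < 1 the operator is a sup-norm contraction (log-sum-exp is a
non-expansion), so plain fixed-point iteration converges geometrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .env import TohGraph

MAX_ACTIONS = 3


class SoftSolveError(RuntimeError):
    """Soft value iteration failed to reach the requested tolerance."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"soft value iteration did not converge within {max_iter} sweeps "
            f"(residual {residual:.3e})"
        )
        self.residual = residual


@dataclass(frozen=True, eq=False)
class GraphArrays:
    """Index-based view of a :class:`~toh_feedback.env.TohGraph`."""

    graph: TohGraph
    states: tuple[str, ...]
    index: dict
    nbr: np.ndarray  # (S, 3) int, padded with the state's own index
    mask: np.ndarray  # (S, 3) bool

    @property
    def n_states(self) -> int:
        return len(self.states)

    def action_index(self, state: str, nxt: str) -> int:
        """Slot of the move ``state -> nxt`` in the padded action axis."""
        s, j = self.index[state], self.index[nxt]
        for a in range(MAX_ACTIONS):
            if self.mask[s, a] and self.nbr[s, a] == j:
                return a
        raise ValueError(f"{state} -> {nxt} is not a legal move")


@lru_cache(maxsize=8)
def graph_arrays(graph: TohGraph) -> GraphArrays:
    states = graph.states
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    nbr = np.tile(np.arange(n)[:, None], (1, MAX_ACTIONS))
    mask = np.zeros((n, MAX_ACTIONS), dtype=bool)
    for s in states:
        i = index[s]
        for a, t in enumerate(graph.neighbors(s)):
            nbr[i, a] = index[t]
            mask[i, a] = True
    nbr.setflags(write=False)
    mask.setflags(write=False)
    return GraphArrays(graph=graph, states=states, index=index, nbr=nbr, mask=mask)


def masked_logsumexp(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp over the unmasked entries of ``(S, 3)`` arrays."""
    x = np.where(mask, x, -np.inf)
    m = x.max(axis=1)
    with np.errstate(invalid="ignore"):
        out = m + np.log(np.exp(x - m[:, None]).sum(axis=1))
    return out


@dataclass
class SoftPlanningResult:
    """Fixed point of the soft Bellman operator for one reward function."""

    arrays: GraphArrays
    gamma: float
    V: np.ndarray  # (S,)
    Q: np.ndarray  # (S, 3), -inf on padded slots
    policy: np.ndarray  # (S, 3), zero on padded slots
    n_iter: int
    residual: float

    def policy_dict(self) -> dict:
        """Per-state action distributions keyed by (state, next_state)."""
        out = {}
        for i, s in enumerate(self.arrays.states):
            for a in range(MAX_ACTIONS):
                if self.arrays.mask[i, a]:
                    out[(s, self.arrays.states[self.arrays.nbr[i, a]])] = float(
                        self.policy[i, a]
                    )
        return out


def soft_solve(
    arrays: GraphArrays,
    reward_sa: np.ndarray,
    gamma: float,
    tol: float = 1e-8,
    max_iter: int = 20000,
    v0: np.ndarray | None = None,
) -> SoftPlanningResult:
    """Iterate the soft Bellman operator to a sup-norm fixed point.

    ``reward_sa`` is a ``(S, 3)`` state-action reward (padded slots are
    ignored).  ``v0`` warm-starts the iteration, which matters when the
    solver is called repeatedly inside an optimizer loop.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must lie in [0, 1), got {gamma}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    mask, nbr = arrays.mask, arrays.nbr
    V = np.zeros(arrays.n_states) if v0 is None else v0.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        Q = np.where(mask, reward_sa + gamma * V[nbr], -np.inf)
        V_new = masked_logsumexp(Q, mask)
        residual = float(np.max(np.abs(V_new - V)))
        V = V_new
        if residual <= tol:
            break
    else:
        raise SoftSolveError(residual, max_iter)
    Q = np.where(mask, reward_sa + gamma * V[nbr], -np.inf)
    # renormalize against the final Q so the policy sums to one exactly
    V = masked_logsumexp(Q, mask)
    policy = np.where(mask, np.exp(Q - V[:, None]), 0.0)
    return SoftPlanningResult(
        arrays=arrays, gamma=gamma, V=V, Q=Q, policy=policy, n_iter=it, residual=residual
    )


def value_gradients(
    arrays: GraphArrays, policy: np.ndarray, phi: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the soft fixed point w.r.t. linear reward parameters.

    For rewards r(s,a) = sum_j theta_j * phi_j(s,a), implicit differentiation
    of the fixed point gives the linear system

        dV = Pi (phi + gamma * dV[nbr]),

    where Pi averages over actions with the converged policy.  Returns
    ``(dV, dQ)`` of shapes ``(S, P)`` and ``(S, 3, P)``.  ``phi`` must be
    zero on padded action slots.
    """
    S = arrays.n_states
    M = np.zeros((S, S))
    rows = np.repeat(np.arange(S), MAX_ACTIONS)
    np.add.at(M, (rows, arrays.nbr.ravel()), policy.ravel())
    B = np.einsum("sa,saf->sf", policy, phi)
    dV = np.linalg.solve(np.eye(S) - gamma * M, B)
    dQ = phi + gamma * dV[arrays.nbr]
    return dV, dQ
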