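"""Synthetic noisy-optimal participants.

The generator emulates the statistical structure the downstream analyses
assume: softmax (Boltzmann) agents pursuing an implicit sparse reward —
mass on the trial's target and on the critical states of the target
triangle — whose decision precision improves linearly across trials, faster
under conditions that display evaluative feedback.  Each participant solves
ten 4-disk training trials followed by five 5-disk transfer trials; every
trial's target is drawn uniformly from the two non-start triangles and the
move budget is ceil(1.5 * minimum path length).  Feedback is displayed (and
recorded) only in the conditions that show it, and never in transfer trials.

The five conditions mirror the experimental designs: (1) no feedback,
(2) numeric feedback on every move, (3) feedback only on request (a
Bernoulli request per move, rare by default), (4) an intermediate sub-goal
only, and (5) sub-goal plus numeric feedback.  Conditions that display
per-move feedback use a precision schedule with a larger slope and an agent
that folds the signal into its action values (model 2); the sub-goal
conditions add reward mass on the sub-goal configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .env import TohGraph, build_graph, triangle_of
from .planning import TaskMdp, ValueTable, feedback_array, move_budget, solve
from .softq import graph_arrays, masked_logsumexp
from .likelihood import model_logits
from .trajectories import Trajectory

#: default implicit-reward weights (chosen once; see docs/methods.md).
#: Guidance mass on critical/sub-goal states is kept below half the target
#: weight so that no pair of adjacent non-target states offers a per-step
#: soft return matching the target's — otherwise high-precision agents can
#: loiter at a reward pocket instead of finishing the puzzle.
TARGET_WEIGHT = 2.0
CRITICAL_WEIGHT = 0.5
SUBGOAL_BONUS = 0.5

#: per-trial precision slopes: beta_t = beta0 + eta * (t - 1)
ETA_FEEDBACK = 0.3
ETA_NO_FEEDBACK = 0.05


@dataclass(frozen=True)
class AgentSpec:
    """Ground-truth behavioural parameters of one synthetic participant."""

    model_id: int = 1
    k_true: float = 0.0
    beta0: float = 1.0
    eta: float = ETA_NO_FEEDBACK
    p_request: float = 0.0
    target_weight: float = TARGET_WEIGHT
    critical_weight: float = CRITICAL_WEIGHT
    subgoal_bonus: float = 0.0
    #: explicit state -> weight map overriding the target-relative default
    theta_override: tuple = ()

    def beta(self, trial: int) -> float:
        """Decision precision on 1-based trial ``trial``."""
        return self.beta0 + self.eta * (trial - 1)

    def theta_for(self, graph: TohGraph, target: str) -> dict:
        """Implicit reward: target state plus the target triangle's critical
        states, with an optional bonus on the sub-goal configuration."""
        if self.theta_override:
            return dict(self.theta_override)
        tri = triangle_of(target)
        other = ({"T2", "T3"} - {tri}).pop()
        theta = {target: self.target_weight}
        for neighbour_tri in ("T1", other):
            crit = graph.critical_pair(tri, neighbour_tri)[0]
            theta[crit] = theta.get(crit, 0.0) + self.critical_weight
        if self.subgoal_bonus:
            gate = graph.gate_state(tri)
            theta[gate] = theta.get(gate, 0.0) + self.subgoal_bonus
        return theta


def condition_spec(condition: int) -> AgentSpec:
    """Default agent for each experimental condition."""
    if condition == 1:
        return AgentSpec()
    if condition == 2:
        return AgentSpec(model_id=2, k_true=0.5, eta=ETA_FEEDBACK)
    if condition == 3:
        return AgentSpec(p_request=0.1)
    if condition == 4:
        return AgentSpec(subgoal_bonus=SUBGOAL_BONUS)
    if condition == 5:
        return AgentSpec(model_id=2, k_true=0.5, eta=ETA_FEEDBACK,
                         subgoal_bonus=SUBGOAL_BONUS)
    raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Cohort layout: participants, trials, tasks, and the master seed."""

    n_participants: int = 20
    conditions: tuple = (1, 2, 3, 4, 5)
    n_train: int = 10
    n_transfer: int = 5
    train_disks: int = 4
    transfer_disks: int = 5
    gamma: float = 0.95
    master_seed: int = 0


def sample_target(graph: TohGraph, rng: np.random.Generator) -> str:
    """Uniform draw from the states of the two non-start triangles."""
    candidates = [s for s in graph.states if triangle_of(s) != "T1"]
    return candidates[int(rng.integers(len(candidates)))]


class Simulator:
    """Runs synthetic cohorts, caching plans and policies across trials.

    Optimal value tables are cached per (disk count, target); agent policies
    per (target, model, precision, gain, reward signature), so replicated
    cohorts re-use the expensive planning work and only the rollouts differ.
    """

    def __init__(self, config: ExperimentConfig = ExperimentConfig()):
        self.config = config
        self._values: dict = {}
        self._policies: dict = {}

    def values(self, graph: TohGraph, target: str) -> ValueTable:
        key = (graph.n_disks, target)
        if key not in self._values:
            self._values[key] = solve(
                TaskMdp(graph=graph, target=target, gamma=self.config.gamma)
            )
        return self._values[key]

    def policy(self, spec: AgentSpec, graph: TohGraph, target: str, trial: int,
               effective_model: int | None = None) -> np.ndarray:
        model_id = spec.model_id if effective_model is None else effective_model
        beta = spec.beta(trial)
        theta = spec.theta_for(graph, target)
        key = (
            graph.n_disks, target, model_id, round(beta, 12),
            spec.k_true, tuple(sorted(theta.items())),
        )
        if key not in self._policies:
            self._policies[key] = agent_policy(
                spec, graph, target, trial, gamma=self.config.gamma,
                values=self.values(graph, target), effective_model=model_id,
            )
        return self._policies[key]

    def run_trial(
        self,
        spec: AgentSpec,
        graph: TohGraph,
        target: str,
        trial: int,
        rng: np.random.Generator,
        task: str,
        participant_id: str,
        condition: int,
        feedback_shown: bool,
        effective_model: int | None = None,
    ) -> Trajectory:
        arrays = graph_arrays(graph)
        values = self.values(graph, target)
        policy = self.policy(spec, graph, target, trial, effective_model)
        budget = move_budget(int(values.dist[graph.start_state]))
        path = [graph.start_state]
        feedback: list = []
        s = arrays.index[graph.start_state]
        t = arrays.index[target]
        for _ in range(budget):
            probs = policy[s]
            a = int(rng.choice(3, p=probs / probs.sum()))
            s_next = int(arrays.nbr[s, a])
            good = 1 if values.V[arrays.states[s_next]] > values.V[arrays.states[s]] else -1
            if not feedback_shown:
                feedback.append(None)
            elif condition == 3:
                feedback.append(good if rng.random() < spec.p_request else None)
            else:
                feedback.append(good)
            path.append(arrays.states[s_next])
            s = s_next
            if s == t:
                break
        return Trajectory(
            participant_id=participant_id,
            condition=condition,
            task=task,
            trial=trial,
            target=target,
            path=path,
            feedback=feedback,
            success=path[-1] == target,
        )


def agent_policy(
    spec: AgentSpec,
    graph: TohGraph,
    target: str,
    trial: int,
    gamma: float = 0.95,
    values: ValueTable | None = None,
    effective_model: int | None = None,
) -> np.ndarray:
    """Per-state action distribution of a noisy-optimal agent.

    The soft action values are computed from the precision-scaled implicit
    reward ``beta_t * theta`` and then modified according to the agent's
    feedback-integration mechanism with gain ``k_true``.
    """
    model_id = spec.model_id if effective_model is None else effective_model
    arrays = graph_arrays(graph)
    theta = spec.theta_for(graph, target)
    r_state = np.zeros(arrays.n_states)
    for s, w in theta.items():
        r_state[arrays.index[s]] = w
    r_state = spec.beta(trial) * r_state
    H = None
    if model_id != 1:
        if values is None:
            values = solve(TaskMdp(graph=graph, target=target, gamma=gamma))
        H = feedback_array(values)
    phi = r_state[arrays.nbr][:, :, None] * arrays.mask[:, :, None]
    L, _, _ = model_logits(
        model_id, arrays, phi, H, np.ones(1), spec.k_true, gamma, want_grad=False
    )
    V = masked_logsumexp(L, arrays.mask)
    return np.where(arrays.mask, np.exp(L - V[:, None]), 0.0)


def run_experiment(
    config: ExperimentConfig = ExperimentConfig(),
    specs: dict | None = None,
    simulator: Simulator | None = None,
) -> list[Trajectory]:
    """Simulate the full multi-condition experiment.

    ``specs`` may override the per-condition agent defaults.  Per-participant
    random streams are derived from ``(master_seed, condition, participant)``,
    so the output is reproducible and independent of iteration order.
    """
    sim = simulator or Simulator(config)
    train_graph = build_graph(config.train_disks)
    transfer_graph = build_graph(config.transfer_disks)
    out: list[Trajectory] = []
    for condition in config.conditions:
        spec = (specs or {}).get(condition) or condition_spec(condition)
        for pid in range(config.n_participants):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.master_seed, condition, pid))
            )
            participant = f"C{condition}P{pid:02d}"
            for trial in range(1, config.n_train + 1):
                target = sample_target(train_graph, rng)
                feedback_shown = condition in (2, 3, 5)
                out.append(
                    sim.run_trial(
                        spec, train_graph, target, trial, rng, "train4",
                        participant, condition, feedback_shown,
                    )
                )
            for trial in range(1, config.n_transfer + 1):
                target = sample_target(transfer_graph, rng)
                # no feedback in transfer: the agent falls back to its
                # reward-only mechanism, precision carries over from training
                out.append(
                    sim.run_trial(
                        replace(spec, k_true=0.0), transfer_graph, target,
                        config.n_train + trial, rng, "transfer5",
                        participant, condition, feedback_shown=False,
                        effective_model=1,
                    )
                )
    return out


#: stationary precision and reward layout of the recovery cohorts
RECOVERY_BETA = 3.0
RECOVERY_K = 1.0


def recovery_theta(graph: TohGraph, triangle: str) -> dict:
    """Implicit reward used by recovery cohorts heading into ``triangle``.

    Mass sits on sub-triangle vertex states only (so the reward is exactly
    expressible in the sparse feature set): the T1-side gate of the target
    triangle, the two corners of the start sub-triangle, and the two
    non-critical corners of the triangle's entry sub-triangle — the layout
    the fitted human reward maps exhibit.
    """
    n = graph.n_disks
    gate = graph.gate_state(triangle)
    entry_sub_corners = {
        "T2": ["0" * (n - 2) + "12", "2" * (n - 2) + "12"],
        "T3": ["1" * (n - 2) + "21", "0" * (n - 2) + "21"],
    }[triangle]
    theta = {gate: 1.0, "1" * (n - 2) + "00": 0.5, "2" * (n - 2) + "00": 0.5}
    for s in entry_sub_corners:
        theta[s] = 0.75
    return theta


def generate_recovery_groups(
    graph: TohGraph,
    seed: int,
    model_id: int = 2,
    k_true: float = RECOVERY_K,
    beta: float = RECOVERY_BETA,
    n_per_group: int = 30,
    gamma: float = 0.95,
) -> list[Trajectory]:
    """Trajectories for a model-recovery replicate: for each of the six
    sub-triangles of T2/T3, a stationary agent of the given mechanism heads
    for the sub-triangle's top vertex."""
    out: list[Trajectory] = []
    for g_idx, (tri, idx) in enumerate(
        [(t, i) for t in ("T2", "T3") for i in (1, 2, 3)]
    ):
        target = graph.subtriangle_top_vertex(tri, idx)
        theta = recovery_theta(graph, tri)
        # extra mass on the agent's own target: enough that the far
        # sub-triangles are reached within budget in most attempts, small
        # enough that behaviour stays visibly stochastic
        theta[target] = theta.get(target, 0.0) + 1.25
        spec = AgentSpec(
            model_id=model_id,
            k_true=k_true,
            beta0=beta,
            eta=0.0,
            theta_override=tuple(sorted(theta.items())),
        )
        out.extend(
            generate_irl_dataset(
                graph, target, n_per_group, seed=seed * 101 + g_idx,
                spec=spec, gamma=gamma, condition=2,
            )
        )
    return out


def generate_irl_dataset(
    graph: TohGraph,
    target: str,
    n_trajectories: int,
    seed: int,
    spec: AgentSpec | None = None,
    gamma: float = 0.95,
    condition: int = 1,
) -> list[Trajectory]:
    """Fixed-target demonstration set from a stationary agent (eta = 0).

    Used for parameter- and model-recovery studies, where every trajectory
    shares one target and the agent's precision does not drift.
    """
    spec = spec or AgentSpec(beta0=5.0, eta=0.0)
    task = {4: "train4", 5: "transfer5"}.get(graph.n_disks)
    if task is None:
        raise ValueError("recovery datasets are defined for 4- or 5-disk puzzles")
    config = ExperimentConfig(gamma=gamma)
    sim = Simulator(config)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 991)))
    out = []
    for i in range(n_trajectories):
        out.append(
            sim.run_trial(
                spec, graph, target, trial=1, rng=rng, task=task,
                participant_id=f"S{seed}D{i:03d}", condition=condition,
                feedback_shown=condition in (2, 3, 5),
            )
        )
    return out
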