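"""Feedback-integration models, trajectory grouping, and AIC/BIC selection.

Because the displayed good/bad signal is defined relative to the trial's
target, and targets are randomized within the two non-start triangles, the
data are first partitioned into six groups by the sub-triangle containing
each trajectory's target.  Each group adopts the sub-triangle's top vertex
(its corner nearest the start side) as a designated target, and every
trajectory is truncated at its first state inside the target sub-triangle;
trajectories that never enter it are dropped and counted.  The good/bad
signal used for fitting is recomputed against the designated target, since
truncation redefines the task.

Within a group, the four candidate mechanisms for folding feedback into
choice are fitted by penalized maximum likelihood and compared with AIC and
BIC normalized by the number of observations, where an observation is one
(state, action) step of a truncated trajectory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .env import TohGraph, subtriangle_of, triangle_of
from .features import FeatureMap
from .likelihood import (
    MODEL_IDS,
    fit_choice_model,
    loglik,
    model_logits,
    next_state_features,
    param_count,
    step_counts,
)
from .planning import TaskMdp, feedback_array, solve
from .softq import graph_arrays, masked_logsumexp
from .trajectories import Trajectory

#: the L1 grid used for model comparison: {0, 0.2, ..., 1}
MODEL_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.2), 10))


@dataclass
class Group:
    """Trajectories sharing a target sub-triangle, truncated at first entry."""

    triangle: str
    index: int
    designated_target: str
    paths: list = field(default_factory=list)  # truncated state paths
    n_dropped: int = 0  # never entered their target sub-triangle

    @property
    def key(self) -> tuple[str, int]:
        return (self.triangle, self.index)

    @property
    def n_trajectories(self) -> int:
        return len(self.paths)

    @property
    def n_obs(self) -> int:
        return sum(len(p) - 1 for p in self.paths)


@dataclass
class GroupPartition:
    groups: dict
    n_dropped: int


def partition_groups(trajectories: list[Trajectory], graph: TohGraph) -> GroupPartition:
    """Partition 4-disk trajectories into the six sub-triangle groups."""
    groups: dict = {}
    n_dropped = 0
    for traj in trajectories:
        tri = triangle_of(traj.target)
        if tri == "T1":
            raise ValueError(f"target {traj.target} lies in the start triangle")
        key = subtriangle_of(traj.target)
        if key not in groups:
            groups[key] = Group(
                triangle=key[0],
                index=key[1],
                designated_target=graph.subtriangle_top_vertex(*key),
            )
        entry = next(
            (i for i, s in enumerate(traj.path) if subtriangle_of(s) == key), None
        )
        if entry is None or entry == 0:
            groups[key].n_dropped += 1
            n_dropped += 1
            continue
        groups[key].paths.append(traj.path[: entry + 1])
    return GroupPartition(groups=groups, n_dropped=n_dropped)


def modified_policy(
    model_id: int,
    graph: TohGraph,
    features: FeatureMap,
    theta: np.ndarray,
    k: float,
    H: np.ndarray,
    gamma: float = 0.95,
) -> np.ndarray:
    """Per-state action distribution of one feedback-integration model,
    as a padded ``(S, 3)`` array."""
    arrays = graph_arrays(graph)
    phi = next_state_features(arrays, features.matrix)
    L, _, _ = model_logits(
        model_id, arrays, phi, H, np.asarray(theta, float), k, gamma, want_grad=False
    )
    V = masked_logsumexp(L, arrays.mask)
    return np.where(arrays.mask, np.exp(L - V[:, None]), 0.0)


@dataclass
class ModelFit:
    """One model fitted to one group, with its information criteria."""

    model_id: int
    group_key: tuple
    theta: np.ndarray
    k: float | None
    logL: float  # unpenalized, at the penalized optimum
    p: int
    o: int
    best_lambda: float
    cv_table: list = field(default_factory=list)
    converged: bool = True

    @property
    def aic(self) -> float:
        """(2p - 2 log L) / o."""
        return (2 * self.p - 2 * self.logL) / self.o

    @property
    def bic(self) -> float:
        """(p log o - 2 log L) / o."""
        return (self.p * math.log(self.o) - 2 * self.logL) / self.o

    def to_json_obj(self) -> dict:
        return {
            "model": self.model_id,
            "group": list(self.group_key),
            "p": self.p,
            "o": self.o,
            "logL": self.logL,
            "AIC": self.aic,
            "BIC": self.bic,
            "best_lambda": self.best_lambda,
            "theta": [float(t) for t in self.theta],
            "k": self.k,
        }


def group_feedback(group: Group, graph: TohGraph, gamma: float = 0.95) -> np.ndarray:
    """Good/bad signal H against the group's designated target."""
    values = solve(TaskMdp(graph=graph, target=group.designated_target, gamma=gamma))
    return feedback_array(values)


def fit_model(
    group: Group,
    model_id: int,
    features: FeatureMap,
    lambda_grid=MODEL_LAMBDA_GRID,
    folds: int = 5,
    gamma: float = 0.95,
    seed: int = 0,
    warm_theta: np.ndarray | None = None,
) -> ModelFit:
    """Penalized MLE of one model on one group, with CV over the L1 grid.

    A degenerate one-element grid skips cross-validation.  ``warm_theta``
    seeds the optimizer (used to start models 2 and 3 from the model-1
    optimum, which also guarantees the nested-likelihood ordering).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    if not group.paths:
        raise ValueError(f"group {group.key} has no trajectories")
    lambda_grid = list(lambda_grid)
    graph = features.graph
    arrays = graph_arrays(graph)
    H = group_feedback(group, graph, gamma=gamma)
    C, n_obs = step_counts(arrays, group.paths)

    def fit_at(lam, C_fit, n_fit):
        return fit_choice_model(
            model_id, arrays, features.matrix, H, C_fit, n_fit,
            lam=lam, gamma=gamma, x0_theta=warm_theta,
        )

    cv_table = []
    if len(lambda_grid) > 1:
        if len(group.paths) < folds:
            raise ValueError(f"group {group.key} has fewer trajectories than folds")
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(np.arange(len(group.paths))))
        for lam in lambda_grid:
            scores = []
            for tr, va in splits:
                C_tr, n_tr = step_counts(arrays, [group.paths[i] for i in tr])
                C_va, _ = step_counts(arrays, [group.paths[i] for i in va])
                f = fit_at(lam, C_tr, n_tr)
                scores.append(
                    loglik(model_id, arrays, features.matrix, H, C_va,
                           f.theta, f.k or 0.0, gamma=gamma)
                )
            cv_table.append((float(lam), float(np.mean(scores))))
        best_lambda = max(cv_table, key=lambda t: (t[1], -t[0]))[0]
    else:
        best_lambda = float(lambda_grid[0])

    res = fit_at(best_lambda, C, n_obs)
    return ModelFit(
        model_id=model_id,
        group_key=group.key,
        theta=res.theta,
        k=res.k,
        logL=res.logL,
        p=param_count(model_id, features.n_features),
        o=n_obs,
        best_lambda=best_lambda,
        cv_table=cv_table,
        converged=res.converged,
    )


def fit_all_models(
    group: Group,
    features: FeatureMap,
    lambda_grid=MODEL_LAMBDA_GRID,
    folds: int = 5,
    gamma: float = 0.95,
    seed: int = 0,
) -> list[ModelFit]:
    """Fit models 1-4 on a group; models 2 and 3 warm-start from model 1."""
    fits = []
    m1 = fit_model(group, 1, features, lambda_grid, folds, gamma, seed)
    fits.append(m1)
    for mid in (2, 3):
        fits.append(
            fit_model(group, mid, features, lambda_grid, folds, gamma, seed,
                      warm_theta=m1.theta)
        )
    fits.append(fit_model(group, 4, features, lambda_grid, folds, gamma, seed))
    return fits


def select_model(fits: list[ModelFit]) -> dict:
    """Independent AIC and BIC rankings over fits of one group."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    keys = {f.group_key for f in fits}
    if len(keys) != 1:
        raise ValueError(f"fits mix groups: {sorted(keys)}")
    by_aic = sorted(fits, key=lambda f: f.aic)
    by_bic = sorted(fits, key=lambda f: f.bic)
    return {
        "group": list(keys.pop()),
        "aic_ranking": [f.model_id for f in by_aic],
        "bic_ranking": [f.model_id for f in by_bic],
        "aic_winner": by_aic[0].model_id,
        "bic_winner": by_bic[0].model_id,
        "criteria_agree": by_aic[0].model_id == by_bic[0].model_id,
    }


def comparison_report(all_fits: dict, path=None) -> dict:
    """JSON report per group x model, plus per-criterion winners."""
    report = {"groups": []}
    for key, fits in sorted(all_fits.items()):
        entry = {
            "group": list(key),
            "models": {str(f.model_id): f.to_json_obj() for f in fits},
            "selection": select_model(fits),
        }
        report["groups"].append(entry)
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1)
    return report
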