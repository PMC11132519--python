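"""Maximum-entropy inverse reinforcement learning of state rewards.

Given demonstration trajectories, the module recovers linear reward weights
theta maximizing the soft-Bellman step likelihood with an L1 penalty, and
selects the penalty strength by trajectory-level k-fold cross-validation
(folds split whole trajectories, since steps within a trajectory are
dependent).  The transition structure of the puzzle does not depend on the
target — the target enters only through which rewards the data support — so
trajectories with different targets can share a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .features import FeatureMap
from .likelihood import FitResult, fit_choice_model, loglik, step_counts
from .softq import graph_arrays
from .trajectories import Trajectory

#: the L1 grid used for reward learning: {0, 0.1, ..., 2}
REWARD_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10))


@dataclass
class RewardWeights:
    theta: np.ndarray
    lam: float
    features: str


@dataclass
class IrlFit:
    """A fitted reward with its cross-validation trace."""

    weights: RewardWeights
    logL: float  # penalized objective value at the optimum
    logL_unpenalized: float
    best_lambda: float
    cv_table: list = field(default_factory=list)  # (lambda, mean validation logL)
    converged: bool = True
    n_obs: int = 0
    features: str = ""

    def reward_by_state(self, feature_map: FeatureMap) -> dict:
        return feature_map.reward_by_state(self.weights.theta)

    def to_json_obj(self, feature_map: FeatureMap | None = None) -> dict:
        obj = {
            "features": self.features,
            "lambda_grid": [lam for lam, _ in self.cv_table],
            "cv_table": [m for _, m in self.cv_table],
            "best_lambda": self.best_lambda,
            "theta": [float(t) for t in self.weights.theta],
            "logL": self.logL_unpenalized,
            "n_obs": self.n_obs,
        }
        if feature_map is not None:
            obj["reward_by_state"] = self.reward_by_state(feature_map)
        return obj


def _paths(trajectories: list[Trajectory]) -> list[list[str]]:
    return [t.path for t in trajectories]


def fit(
    trajectories: list[Trajectory],
    features: FeatureMap,
    lam: float = 0.0,
    gamma: float = 0.95,
    gtol: float = 1e-6,
    seed: int = 0,
) -> IrlFit:
    """Penalized maximum-likelihood reward weights at a fixed L1 strength.

    The optimization is deterministic (single analytic-gradient L-BFGS-B run
    from zero); ``seed`` is accepted for interface symmetry with
    :func:`cross_validate`.
    """
    if not trajectories:
        raise ValueError("cannot fit on an empty dataset")
    arrays = graph_arrays(features.graph)
    C, n_obs = step_counts(arrays, _paths(trajectories))
    res: FitResult = fit_choice_model(
        1, arrays, features.matrix, None, C, n_obs, lam=lam, gamma=gamma, gtol=gtol
    )
    return IrlFit(
        weights=RewardWeights(theta=res.theta, lam=lam, features=features.name),
        logL=res.logL_penalized,
        logL_unpenalized=res.logL,
        best_lambda=lam,
        cv_table=[],
        converged=res.converged,
        n_obs=n_obs,
        features=features.name,
    )


def cross_validate(
    trajectories: list[Trajectory],
    features: FeatureMap,
    lambda_grid=REWARD_LAMBDA_GRID,
    folds: int = 5,
    gamma: float = 0.95,
    seed: int = 0,
) -> IrlFit:
    """Select the L1 strength by k-fold CV, then refit on all trajectories.

    Folds are split at the trajectory level; the score of a candidate lambda
    is the mean (over folds) of the unpenalized validation log-likelihood.
    Ties break toward the smaller lambda.
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda grid must be non-empty")
    if len(trajectories) < folds:
        raise ValueError(
            f"need at least {folds} trajectories for {folds}-fold CV, "
            f"got {len(trajectories)}"
        )
    arrays = graph_arrays(features.graph)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    idx = np.arange(len(trajectories))
    splits = list(kf.split(idx))

    cv_table = []
    for lam in lambda_grid:
        fold_scores = []
        for train_idx, val_idx in splits:
            train = [trajectories[i] for i in train_idx]
            val = [trajectories[i] for i in val_idx]
            f = fit(train, features, lam=lam, gamma=gamma)
            C_val, _ = step_counts(arrays, _paths(val))
            fold_scores.append(
                loglik(1, arrays, features.matrix, None, C_val, f.weights.theta, gamma=gamma)
            )
        cv_table.append((float(lam), float(np.mean(fold_scores))))

    best_lambda = max(cv_table, key=lambda t: (t[1], -t[0]))[0]
    final = fit(trajectories, features, lam=best_lambda, gamma=gamma)
    final.cv_table = cv_table
    final.best_lambda = best_lambda
    return final
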