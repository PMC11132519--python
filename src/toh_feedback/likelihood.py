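"""Maximum-entropy trajectory likelihood and penalized fitting.

The likelihood of observed moves under a candidate reward is local to the
observed steps,

    log P(D | r) = sum_i sum_t ( Q(s_t, a_t) - V(s_t) ),

with Q and V from the soft Bellman fixed point.  The four feedback-
integration hypotheses differ only in how the per-state action logits are
assembled from the soft solution Q and the good/bad signal H:

* model 1 ignores H (logits = Q),
* model 2 biases action choice post hoc (logits = Q + k H, no re-propagation),
* model 3 shifts the reward itself (r' = r + k H) and re-solves,
* model 4 discards the reward entirely (logits = k H).

Gradients are exact: the soft fixed point is differentiated implicitly
(a linear solve), so the optimizer sees machine-precision gradients rather
than finite differences.  The L1 penalty on the reward weights is handled by
splitting theta into non-negative positive and negative parts, which keeps
the objective smooth and lets L-BFGS-B produce exact zeros; the feedback
gain k is never penalized (it is not a reward weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .softq import (
    GraphArrays,
    masked_logsumexp,
    soft_solve,
    value_gradients,
)

MODEL_IDS = (1, 2, 3, 4)


def param_count(model_id: int, n_features: int) -> int:
    """Learned-parameter count: |f| for model 1, |f|+1 for models 2 and 3,
    and a single gain for model 4."""
    if model_id == 1:
        return n_features
    if model_id in (2, 3):
        return n_features + 1
    if model_id == 4:
        return 1
    raise ValueError(f"unknown model id {model_id!r}")


def step_counts(arrays: GraphArrays, paths: list[list[str]]) -> tuple[np.ndarray, int]:
    """Aggregate observed (state, action) steps into a padded count matrix."""
    C = np.zeros((arrays.n_states, 3))
    n = 0
    for path in paths:
        for a, b in zip(path, path[1:]):
            C[arrays.index[a], arrays.action_index(a, b)] += 1.0
            n += 1
    return C, n


def next_state_features(arrays: GraphArrays, feature_matrix: np.ndarray) -> np.ndarray:
    """Arrival-state features phi(s, a) = f(s') as an ``(S, 3, F)`` tensor,
    zeroed on padded action slots."""
    phi = feature_matrix[arrays.nbr]
    return phi * arrays.mask[:, :, None]


def model_logits(
    model_id: int,
    arrays: GraphArrays,
    phi: np.ndarray,
    H: np.ndarray | None,
    theta: np.ndarray,
    k: float,
    gamma: float,
    soft_tol: float = 1e-8,
    v0: np.ndarray | None = None,
    want_grad: bool = True,
):
    """Per-state action logits L(s, a) and their parameter gradients.

    Returns ``(L, dL, V)`` where ``dL`` has shape ``(S, 3, P)`` (the gain k
    is the last column for models 2 and 3) and ``V`` is the soft value used,
    returned so callers can warm-start the next solve.  ``dL`` is ``None``
    when ``want_grad`` is false.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    if model_id != 1 and H is None:
        raise ValueError(f"model {model_id} requires a feedback signal H")
    if model_id == 4:
        L = np.where(arrays.mask, k * H, -np.inf)
        dL = H[:, :, None].copy() if want_grad else None
        return L, dL, None

    reward = np.einsum("saf,f->sa", phi, theta)
    if model_id == 3:
        reward = reward + k * H
    res = soft_solve(arrays, reward, gamma, tol=soft_tol, v0=v0)
    L = res.Q
    if model_id == 2:
        L = np.where(arrays.mask, L + k * H, -np.inf)
    if not want_grad:
        return L, None, res.V

    grad_phi = phi
    if model_id == 3:
        grad_phi = np.concatenate([phi, (H * arrays.mask)[:, :, None]], axis=2)
    _, dQ = value_gradients(arrays, res.policy, grad_phi, gamma)
    if model_id == 2:
        dL = np.concatenate([dQ, (H * arrays.mask)[:, :, None]], axis=2)
    else:
        dL = dQ
    return L, dL, res.V


def loglik_from_logits(
    L: np.ndarray, mask: np.ndarray, C: np.ndarray, dL: np.ndarray | None = None
):
    """Total step log-likelihood (and gradient) from logits and step counts."""
    V = masked_logsumexp(L, mask)
    c_state = C.sum(axis=1)
    Lsafe = np.where(mask, L, 0.0)
    logL = float((C * Lsafe).sum() - c_state @ V)
    if dL is None:
        return logL, None
    policy = np.where(mask, np.exp(L - V[:, None]), 0.0)
    grad = np.einsum("sa,saf->f", C, dL) - np.einsum(
        "s,sa,saf->f", c_state, policy, dL
    )
    return logL, grad


@dataclass
class FitResult:
    """Outcome of one penalized maximum-likelihood fit."""

    model_id: int
    theta: np.ndarray  # empty for model 4
    k: float | None
    logL: float  # unpenalized, at the penalized optimum
    logL_penalized: float
    lam: float
    n_obs: int
    converged: bool
    n_evals: int


def fit_choice_model(
    model_id: int,
    arrays: GraphArrays,
    feature_matrix: np.ndarray,
    H: np.ndarray | None,
    C: np.ndarray,
    n_obs: int,
    lam: float = 0.0,
    gamma: float = 0.95,
    gtol: float = 1e-6,
    soft_tol: float = 1e-8,
    x0_theta: np.ndarray | None = None,
    x0_k: float = 0.0,
    max_iter: int = 500,
) -> FitResult:
    """Maximize the step log-likelihood minus ``lam * ||theta||_1``.

    Deterministic: the optimizer is L-BFGS-B from a fixed start (zeros unless
    a warm start is supplied), and every gradient is computed analytically.
    """
    F = feature_matrix.shape[1]
    uses_theta = model_id != 4
    uses_k = model_id != 1
    phi = next_state_features(arrays, feature_matrix)
    warm = {"v0": None}

    def unpack(z):
        if model_id == 4:
            return np.zeros(F), float(z[0])
        theta = z[:F] - z[F : 2 * F]
        k = float(z[2 * F]) if uses_k else 0.0
        return theta, k

    def objective(z):
        theta, k = unpack(z)
        L, dL, V = model_logits(
            model_id, arrays, phi, H, theta, k, gamma, soft_tol=soft_tol, v0=warm["v0"]
        )
        if V is not None:
            warm["v0"] = V
        logL, grad = loglik_from_logits(L, arrays.mask, C, dL)
        val = -logL
        if uses_theta:
            g_theta = -grad[:F]
            pieces = [g_theta + lam, -g_theta + lam]
            if uses_k:
                pieces.append(-grad[F:])
            g = np.concatenate(pieces)
            val += lam * float(z[: 2 * F].sum())
        else:
            g = -grad
        return val, g

    if model_id == 4:
        x0 = np.array([x0_k])
        bounds = [(None, None)]
    else:
        u0 = np.zeros(F) if x0_theta is None else np.maximum(x0_theta, 0.0)
        w0 = np.zeros(F) if x0_theta is None else np.maximum(-x0_theta, 0.0)
        x0 = np.concatenate([u0, w0] + ([np.array([x0_k])] if uses_k else []))
        bounds = [(0.0, None)] * (2 * F) + ([(None, None)] if uses_k else [])

    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    theta, k = unpack(res.x)
    L, _, _ = model_logits(
        model_id, arrays, phi, H, theta, k, gamma, soft_tol=soft_tol,
        v0=warm["v0"], want_grad=False,
    )
    logL, _ = loglik_from_logits(L, arrays.mask, C)
    return FitResult(
        model_id=model_id,
        theta=theta if uses_theta else np.zeros(0),
        k=k if uses_k else None,
        logL=logL,
        logL_penalized=logL - lam * float(np.abs(theta).sum()),
        lam=lam,
        n_obs=n_obs,
        converged=bool(res.success),
        n_evals=int(res.nfev),
    )


def loglik(
    model_id: int,
    arrays: GraphArrays,
    feature_matrix: np.ndarray,
    H: np.ndarray | None,
    C: np.ndarray,
    theta: np.ndarray,
    k: float = 0.0,
    gamma: float = 0.95,
    soft_tol: float = 1e-8,
) -> float:
    """Unpenalized step log-likelihood at fixed parameters."""
    phi = next_state_features(arrays, feature_matrix)
    L, _, _ = model_logits(
        model_id, arrays, phi, H, theta, k, gamma, soft_tol=soft_tol, want_grad=False
    )
    val, _ = loglik_from_logits(L, arrays.mask, C)
    return val
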