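"""Generalized-utility evaluation of learned models on goal-directed tasks.

A model snapshot is judged by how well the policies *it* recommends
perform in the *true* world, without any further learning:

* navigation — reach a target state in as few expected steps as
  possible; the loss is the extra expected steps of the model-derived
  policy over the true optimum, averaged over start/target pairs;
* reward acquisition — collect state rewards over a fixed undiscounted
  horizon; the loss is the expected reward forgone by the model-derived
  time-indexed policy, averaged over start states.

Evaluation is side-effect-free: models are read, never updated.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import rankdata

from .structure import optimal_hitting_policy

_HUGE = 1e9


@dataclasses.dataclass
class TaskResult:
    navigation_loss: float
    reward_loss: float
    strategy_name: str | None = None
    world_id: str | None = None
    benchmark_step: int | None = None


def _theta(world) -> np.ndarray:
    return world.theta if hasattr(world, "theta") else np.asarray(world, float)


def _policy_hitting_values(theta: np.ndarray, policy: np.ndarray,
                           target: int) -> np.ndarray:
    """Exact expected steps-to-target of a fixed policy, by solving the
    linear policy-evaluation system; +inf where the policy fails."""
    n = theta.shape[1]
    p = theta[policy, np.arange(n), :]
    others = np.flatnonzero(np.arange(n) != target)
    a = np.eye(len(others)) - p[np.ix_(others, others)]
    v = np.full(n, np.inf)
    v[target] = 0.0
    try:
        sol = np.linalg.solve(a, np.ones(len(others)))
    except np.linalg.LinAlgError:
        return v
    ok = np.isfinite(sol) & (sol >= 0) & (sol < _HUGE)
    v[others[ok]] = sol[ok]
    v[others[~ok]] = np.inf
    return v


def navigation_loss(model_theta, world, true_hitting=None) -> float:
    """Mean extra expected steps of model-derived navigation policies.

    For each (start, target) pair the hitting policy optimal under the
    model is evaluated exactly under the true world and compared with
    the true optimum.  Pairs with an infinite true optimum are
    excluded (as are the rare pairs where the model policy itself never
    arrives); the result is an average over the remaining pairs.
    """
    model_theta = _theta(model_theta)
    theta = _theta(world)
    n = theta.shape[1]
    if model_theta.shape != theta.shape:
        raise ValueError("model and world shapes differ")
    if true_hitting is None:
        true_hitting = [optimal_hitting_policy(theta, t) for t in range(n)]
    diffs = []
    for target in range(n):
        v_true = true_hitting[target].expected_steps
        starts = [s for s in range(n) if s != target and np.isfinite(v_true[s])]
        if not starts:
            continue
        model_policy = optimal_hitting_policy(model_theta, target).policy
        v_model = _policy_hitting_values(theta, model_policy, target)
        for s in starts:
            if np.isfinite(v_model[s]):
                diffs.append(v_model[s] - v_true[s])
    if not diffs:
        raise ValueError("no (start, target) pair is reachable in the true world")
    return float(np.mean(diffs))


def _finite_horizon_policies(theta: np.ndarray, rewards: np.ndarray,
                             horizon: int) -> np.ndarray:
    """Backward induction of the undiscounted finite-horizon problem;
    returns the time-indexed greedy policy array of shape (horizon, N)."""
    m, n, _ = theta.shape
    v = np.zeros(n)
    policies = np.empty((horizon, n), dtype=int)
    flat = theta.reshape(-1, n)
    for t in range(horizon - 1, -1, -1):
        q = (flat @ (rewards + v)).reshape(m, n)
        policies[t] = np.argmax(q, axis=0)
        v = q.max(axis=0)
    return policies


def _evaluate_time_policy(theta: np.ndarray, policies: np.ndarray,
                          rewards: np.ndarray) -> np.ndarray:
    """Expected cumulative reward of a time-indexed policy, per start."""
    n = theta.shape[1]
    horizon = policies.shape[0]
    w = np.zeros(n)
    idx = np.arange(n)
    for t in range(horizon - 1, -1, -1):
        p = theta[policies[t], idx, :]
        w = p @ (rewards + w)
    return w


def reward_loss(model_theta, world, rewards, horizon: int = 100) -> float:
    """Expected reward forgone by planning with the model.

    The model yields an undiscounted ``horizon``-step time-indexed
    policy; its exact expected cumulative reward under the true world
    is subtracted from the true optimum and averaged over start states.
    Reward ``rewards[s']`` is collected on every arrival in ``s'``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    model_theta = _theta(model_theta)
    theta = _theta(world)
    rewards = np.asarray(rewards, dtype=float)
    if rewards.shape != (theta.shape[1],):
        raise ValueError("need one reward per state")
    model_policies = _finite_horizon_policies(model_theta, rewards, horizon)
    realized = _evaluate_time_policy(theta, model_policies, rewards)
    true_policies = _finite_horizon_policies(theta, rewards, horizon)
    optimal = _evaluate_time_policy(theta, true_policies, rewards)
    return float(np.mean(optimal - realized))


def rank_strategies(losses: dict) -> dict:
    """Average rank of each strategy across worlds (rank 1 = lowest
    loss; ties share the mean rank)."""
    names = list(losses)
    lengths = {len(losses[k]) for k in names}
    if len(lengths) != 1:
        raise ValueError("every strategy needs a loss for the same world set")
    table = np.asarray([losses[k] for k in names], dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, table)
    return {name: float(r) for name, r in zip(names, ranks.mean(axis=1))}
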