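"""Structural metrics of worlds and learning-curve comparisons.

* equilibrium distribution and structure index — how strongly the world
  biases a randomly acting agent's long-run state occupancy;
* control index — mutual information between the first action and the
  state ``t`` steps later, a measure of controllability;
* optimal hitting policies and mean path length — the spatial extent of
  a world under stochastic-shortest-path navigation;
* embodiment index — relative difference in learning-curve area between
  the embodied greedy explorer and the unembodied teleporting control.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .environments import CMCKernel


class ConvergenceError(RuntimeError):
    """Iterative computation failed to converge within its cap."""


@dataclasses.dataclass
class WorldMetrics:
    structure_index: float
    control_index: np.ndarray
    mean_path_length: float
    embodiment_index: float | None = None


@dataclasses.dataclass
class HittingResult:
    """Optimal stochastic-shortest-path solution for one target.

    ``expected_steps[s]`` is +inf for states from which no policy
    reaches the target with probability one.
    """

    policy: np.ndarray
    expected_steps: np.ndarray
    target: int


def _theta(world) -> np.ndarray:
    return world.theta if hasattr(world, "theta") else np.asarray(world, float)


def random_action_chain(world) -> np.ndarray:
    """Transition matrix of the uniform-random-action Markov chain."""
    return _theta(world).mean(axis=0)


def equilibrium_distribution(world, tol: float = 1e-12,
                             max_iter: int = 1_000_000) -> np.ndarray:
    """Stationary distribution of the random-action chain by power
    iteration from the uniform start.

    Power iteration (rather than eigendecomposition) keeps reducible
    chains well-behaved: the limit from the uniform start is returned.
    """
    t = random_action_chain(world)
    n = t.shape[0]
    psi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = psi @ t
        if np.abs(nxt - psi).sum() < tol:
            return nxt
        psi = nxt
    raise ConvergenceError(
        f"equilibrium distribution did not converge for world "
        f"{getattr(world, 'world_id', None)!r}"
    )


def structure_index(psi) -> float:
    """Relative entropy deficit of the equilibrium distribution:
    ``(H(U) - H(psi)) / H(U)``; 0 for uniform, 1 for a point mass."""
    psi = np.asarray(psi, dtype=float)
    n = psi.size
    if n < 2:
        raise ValueError("structure index undefined for a single state")
    if not np.isclose(psi.sum(), 1.0, atol=1e-9):
        raise ValueError("psi must be normalized")
    mask = psi > 0
    h = -np.sum(psi[mask] * np.log2(psi[mask]))
    return float((np.log2(n) - h) / np.log2(n))


def control_index(world, t: int) -> float:
    """Mutual information (bits) between a uniformly random first action
    and the state ``t`` steps later, averaged over uniform starts.
    Steps after the first follow the uniform-random-action chain."""
    if t < 1:
        raise ValueError("t must be >= 1")
    theta = _theta(world)
    m, n, _ = theta.shape
    chain = np.linalg.matrix_power(random_action_chain(world), t - 1)
    # joint[s0, a, s_t] with a uniform; marg is p(s_t | s0)
    joint = np.einsum("asn,nm->sam", theta, chain) / m
    marg = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log2(m * joint / marg), 0.0)
    mi_per_start = terms.sum(axis=(1, 2))
    return float(mi_per_start.mean())


def _almost_sure_reach(support: np.ndarray, target: int):
    """States (and surviving actions) from which some policy reaches
    ``target`` with probability one.

    Classic attractor computation: repeatedly discard actions whose
    support leaks outside the current candidate set, then recompute
    positive-probability reachability with the surviving actions.
    """
    m, n, _ = support.shape
    alive = np.ones((m, n), dtype=bool)
    candidate = np.ones(n, dtype=bool)
    while True:
        # positive-prob backward reachability with alive actions
        reach = np.zeros(n, dtype=bool)
        reach[target] = True
        frontier = True
        while frontier:
            can = (support[:, :, reach].any(axis=2)) & alive
            newly = can.any(axis=0) & ~reach
            frontier = bool(newly.any())
            reach |= newly
        stays = ~(support[:, :, ~reach].any(axis=2))
        new_alive = alive & stays
        new_candidate = reach
        if np.array_equal(new_alive, alive) and np.array_equal(new_candidate,
                                                               candidate):
            return candidate, alive
        alive, candidate = new_alive, new_candidate


def optimal_hitting_policy(world, target: int, tol: float = 1e-9,
                           max_iter: int = 100_000) -> HittingResult:
    """Policy minimizing the expected number of steps to ``target``.

    Solves ``V(target) = 0``, ``V(s) = 1 + min_a sum_s' theta[a,s,s']
    V(s')`` by value iteration, restricted to states from which the
    target is reachable with probability one under some policy; all
    other states are flagged with ``+inf`` (never an exception).
    """
    theta = _theta(world)
    m, n, _ = theta.shape
    if not 0 <= target < n:
        raise ValueError("target out of range")
    proper, alive = _almost_sure_reach(theta > 0, target)
    v = np.zeros(n)
    q_pen = np.where(alive, 0.0, np.inf)
    for _ in range(max_iter):
        q = 1.0 + theta @ v + q_pen
        new_v = np.min(q, axis=0)
        new_v[target] = 0.0
        new_v[~proper] = 0.0  # masked; set to inf afterwards
        if np.max(np.abs(new_v - v)) < tol:
            v = new_v
            break
        v = new_v
    q = 1.0 + theta @ v + q_pen
    policy = np.argmin(q, axis=0)
    v = v.copy()
    v[~proper] = np.inf
    v[target] = 0.0
    policy = np.asarray(policy, dtype=int)
    policy[target] = 0
    return HittingResult(policy=policy, expected_steps=v, target=target)


def mean_path_length(world, return_excluded: bool = False):
    """Average minimum expected path length over ordered state pairs.

    Pairs whose optimal expected hitting time is infinite (no policy
    reaches the target almost surely) are excluded; their count is
    available via ``return_excluded``.
    """
    theta = _theta(world)
    n = theta.shape[1]
    finite_vals = []
    excluded = 0
    for target in range(n):
        v = optimal_hitting_policy(world, target).expected_steps
        for s in range(n):
            if s == target:
                continue
            if np.isfinite(v[s]):
                finite_vals.append(v[s])
            else:
                excluded += 1
    if not finite_vals:
        raise ConvergenceError("no ordered pair has a finite expected path")
    mpl = float(np.mean(finite_vals))
    return (mpl, excluded) if return_excluded else mpl


def auc(trace) -> float:
    """Trapezoidal area under a missing-information learning curve."""
    return float(np.trapezoid(trace.missing_info, trace.eval_times))


def embodiment_index(curve_greedy, curve_unembodied) -> float:
    """Relative difference in learning-curve areas,
    ``(AUC_greedy - AUC_unembodied) / AUC_unembodied``: positive when
    embodiment slows learning relative to the teleporting control."""
    if not np.array_equal(curve_greedy.eval_times, curve_unembodied.eval_times):
        raise ValueError("learning curves must share their evaluation grid")
    a_g = auc(curve_greedy)
    a_u = auc(curve_unembodied)
    return float((a_g - a_u) / a_u)


def world_metrics(world, lags=range(1, 11),
                  include_path_length: bool = False) -> WorldMetrics:
    """Convenience bundle of the structural metrics for one world."""
    psi = equilibrium_distribution(world)
    ci = np.array([control_index(world, t) for t in lags])
    mpl = mean_path_length(world) if include_path_length else float("nan")
    return WorldMetrics(structure_index=structure_index(psi), control_index=ci,
                        mean_path_length=mpl)
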