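"""Action-selection policies and the exploration loop.

Strategies fall into four groups:

* controls — uniform ``random`` action (negative control) and the
  ``unembodied`` agent that teleports to the globally highest-PIG
  (action, state) pair each step (positive control);
* one-step utility maximizers — greedy or value-iterated maximization
  of PIG / PMC / PLC, with ``pig-vi+`` a positive control that plans
  with the true kernel instead of the learned one;
* count heuristics — least-taken action (``lta``) and counter-based
  (``cb``) exploration;
* ``peig-q`` — model-free Q-learning on the surprise (posterior
  expected information gain) of each update.

All ties are broken uniformly at random from the run's seeded stream.
``run_exploration`` wires a strategy to a world and records the missing
information of the learned model over time.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import information as info
from .environments import CMCKernel, step
from .inference import PosteriorModel


@dataclasses.dataclass
class QTable:
    """Value-iterated utility totals ``q[a, s]`` for a finite horizon."""

    q: np.ndarray
    horizon: int
    gamma: float


@dataclasses.dataclass
class ExplorationTrace:
    """Record of one exploration run.

    ``missing_info[i]`` is the model's missing information (bits) after
    ``eval_times[i]`` steps; index 0 is the prior's missing information.
    """

    states: np.ndarray
    actions: np.ndarray
    eval_times: np.ndarray
    missing_info: np.ndarray
    strategy_name: str
    world_id: str | None = None
    seed: int | None = None
    snapshots: dict | None = None

    @property
    def n_steps(self) -> int:
        return len(self.actions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(self.n_steps),
            "state": self.states[:-1],
            "action": self.actions,
        })

    def summary(self) -> dict:
        return {
            "strategy": self.strategy_name,
            "world_id": self.world_id,
            "seed": self.seed,
            "n_steps": int(self.n_steps),
            "eval_times": self.eval_times.tolist(),
            "missing_info": self.missing_info.tolist(),
        }


def _tiebreak(values: np.ndarray, rng: np.random.Generator,
              minimize: bool = False) -> int:
    ext = values.min() if minimize else values.max()
    idx = np.flatnonzero(values == ext)
    return int(idx[rng.integers(idx.size)]) if idx.size > 1 else int(idx[0])


# ---------------------------------------------------------------------
# functional selection rules
# ---------------------------------------------------------------------

def choose_random(n_actions: int, rng) -> int:
    """Uniform action, independent of state."""
    return int(rng.integers(n_actions))


def choose_unembodied(model: PosteriorModel, rng, pig_values=None):
    """Globally highest-PIG (action, state) pair, ties uniform."""
    if pig_values is None:
        pig_values = info.utility_table(model, "pig").values
    flat = _tiebreak(pig_values.ravel(), rng)
    a, s = divmod(flat, model.n_states)
    return int(a), int(s)


def choose_greedy(model: PosteriorModel, s: int, utility, rng) -> int:
    """Highest-utility action in the current state, ties uniform."""
    values = utility.values if hasattr(utility, "values") else np.asarray(utility)
    return _tiebreak(values[:, s], rng)


def choose_lta(action_counts: np.ndarray, s: int, rng) -> int:
    """Least-often-taken action in the current state, ties uniform."""
    return _tiebreak(action_counts[:, s], rng, minimize=True)


def choose_cb(model: PosteriorModel, state_counts: np.ndarray, s: int, rng) -> int:
    """Action minimizing the model-expected visit count of the next state."""
    expected = model.theta_hat[:, s, :] @ state_counts
    return _tiebreak(expected, rng, minimize=True)


def value_iterate(utility, kernel, gamma: float = 0.95,
                  horizon: int = 10) -> QTable:
    """Finite-horizon discounted backup of a per-(action, state) utility.

    ``Q_0 = U``; ``Q_{tau-1}(a,s) = U(a,s) + gamma * sum_s' K[a,s,s'] *
    max_a' Q_tau(a',s')`` repeated ``horizon`` times.  ``kernel`` may be
    a CMCKernel or a raw (M, N, N) tensor; rows must be normalized.
    """
    values = utility.values if hasattr(utility, "values") else np.asarray(utility, float)
    theta = kernel.theta if hasattr(kernel, "theta") else np.asarray(kernel, float)
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    if theta.shape != (values.shape[0], values.shape[1], values.shape[1]):
        raise ValueError("utility and kernel shapes disagree")
    if not np.allclose(theta.sum(axis=2), 1.0, atol=1e-9, rtol=0.0):
        raise ValueError("kernel rows must be normalized")
    q = _vi(values, theta.reshape(-1, theta.shape[2]), gamma, horizon)
    return QTable(q=q, horizon=horizon, gamma=gamma)


def _vi(values: np.ndarray, theta_flat: np.ndarray, gamma: float,
        horizon: int) -> np.ndarray:
    q = values.copy()
    for _ in range(horizon):
        v = q.max(axis=0)
        q = values + gamma * (theta_flat @ v).reshape(values.shape)
    return q


# ---------------------------------------------------------------------
# strategy objects
# ---------------------------------------------------------------------

class _UtilityCache:
    """Per-(action, state) one-step utility values, refreshed one row at
    a time as observations arrive."""

    def __init__(self, model: PosteriorModel, kind: str):
        self.model = model
        self.kind = kind
        self.values = info.utility_table(model, kind).values

    def refresh(self, a: int, s: int) -> None:
        self.values[a, s] = info.utility_row(self.model, self.kind, a, s)


class Strategy:
    """Base class: hold references set at reset, pick actions, observe."""

    label = "strategy"
    teleports = False

    def reset(self, model: PosteriorModel, world: CMCKernel,
              rng: np.random.Generator) -> None:
        self.model = model
        self.world = world
        self.rng = rng

    def select(self, s: int):
        raise NotImplementedError

    def observe(self, a: int, s: int, s_next: int,
                old_row: np.ndarray) -> None:
        pass


class RandomStrategy(Strategy):
    label = "random"

    def select(self, s):
        return choose_random(self.model.n_actions, self.rng)


class UnembodiedPIG(Strategy):
    label = "unembodied"
    teleports = True

    def reset(self, model, world, rng):
        super().reset(model, world, rng)
        self.cache = _UtilityCache(model, "pig")

    def select(self, s):
        return choose_unembodied(self.model, self.rng, self.cache.values)

    def observe(self, a, s, s_next, old_row):
        self.cache.refresh(a, s)


class GreedyUtility(Strategy):
    def __init__(self, kind: str = "pig"):
        self.kind = kind
        self.label = f"{kind}-greedy"

    def reset(self, model, world, rng):
        super().reset(model, world, rng)
        self.cache = _UtilityCache(model, self.kind)

    def select(self, s):
        return choose_greedy(self.model, s, self.cache, self.rng)

    def observe(self, a, s, s_next, old_row):
        self.cache.refresh(a, s)


class VIUtility(Strategy):
    """Value-iterated maximization of a one-step utility.

    The backup kernel is the learned posterior mean, or the true kernel
    for the ``plus`` positive control.  Q tables are recomputed every
    step because the utility changes as the model learns.
    """

    def __init__(self, kind: str = "pig", gamma: float = 0.95,
                 horizon: int = 10, plus: bool = False):
        self.kind = kind
        self.gamma = gamma
        self.horizon = horizon
        self.plus = plus
        self.label = f"{kind}-vi+" if plus else f"{kind}-vi"

    def reset(self, model, world, rng):
        super().reset(model, world, rng)
        self.cache = _UtilityCache(model, self.kind)
        self._true_flat = world.theta.reshape(-1, world.n_states) if self.plus else None

    def select(self, s):
        if self.plus:
            flat = self._true_flat
        else:
            flat = self.model.theta_hat.reshape(-1, self.model.n_states)
        q = _vi(self.cache.values, flat, self.gamma, self.horizon)
        return _tiebreak(q[:, s], self.rng)

    def observe(self, a, s, s_next, old_row):
        self.cache.refresh(a, s)


class LeastTakenAction(Strategy):
    label = "lta"

    def reset(self, model, world, rng):
        super().reset(model, world, rng)
        self.action_counts = np.zeros((model.n_actions, model.n_states))

    def select(self, s):
        return choose_lta(self.action_counts, s, self.rng)

    def observe(self, a, s, s_next, old_row):
        self.action_counts[a, s] += 1


class CounterBased(Strategy):
    label = "cb"

    def reset(self, model, world, rng):
        super().reset(model, world, rng)
        self.state_counts = np.zeros(model.n_states)

    def start_state(self, s):
        self.state_counts[s] += 1

    def select(self, s):
        return choose_cb(self.model, self.state_counts, s, self.rng)

    def observe(self, a, s, s_next, old_row):
        self.state_counts[s_next] += 1


class PEIGQ(Strategy):
    """Q-learning on the surprise of each model update.

    After a real transition the reward is the KL divergence of the
    freshly updated row from its previous value; Q values start at 0
    and actions are epsilon-greedy on Q.
    """

    label = "peig-q"

    def __init__(self, learning_rate: float = 0.1, gamma: float = 0.95,
                 epsilon: float = 0.1):
        if not 0 < learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if not 0 <= epsilon <= 1:
            raise ValueError("epsilon must lie in [0, 1]")
        self.eta = learning_rate
        self.gamma = gamma
        self.epsilon = epsilon

    def reset(self, model, world, rng):
        super().reset(model, world, rng)
        self.q = np.zeros((model.n_actions, model.n_states))

    def select(self, s):
        if self.rng.random() < self.epsilon:
            return choose_random(self.model.n_actions, self.rng)
        return _tiebreak(self.q[:, s], self.rng)

    def observe(self, a, s, s_next, old_row):
        r = info.posterior_expected_information_gain(old_row,
                                                     self.model.row(a, s))
        target = r + self.gamma * self.q[:, s_next].max()
        self.q[a, s] = (1 - self.eta) * self.q[a, s] + self.eta * target


def peig_q_agent(learning_rate: float = 0.1, gamma: float = 0.95,
                 epsilon: float = 0.1) -> PEIGQ:
    """Construct the surprise-driven Q-learning strategy."""
    return PEIGQ(learning_rate=learning_rate, gamma=gamma, epsilon=epsilon)


STRATEGIES = {
    "random": RandomStrategy,
    "unembodied": UnembodiedPIG,
    "pig-greedy": lambda: GreedyUtility("pig"),
    "pig-vi": lambda: VIUtility("pig"),
    "pig-vi+": lambda: VIUtility("pig", plus=True),
    "pmc-vi": lambda: VIUtility("pmc"),
    "plc-vi": lambda: VIUtility("plc"),
    "lta": LeastTakenAction,
    "cb": CounterBased,
    "peig-q": PEIGQ,
}


def make_strategy(label: str, **params) -> Strategy:
    if isinstance(label, Strategy):
        return label
    if label not in STRATEGIES:
        raise ValueError(f"unknown strategy {label!r}; "
                         f"known: {sorted(STRATEGIES)}")
    factory = STRATEGIES[label]
    if params:
        if label == "peig-q":
            return PEIGQ(**params)
        if label in ("pig-vi", "pmc-vi", "plc-vi"):
            return VIUtility(label.split("-")[0], **params)
        if label == "pig-vi+":
            return VIUtility("pig", plus=True, **params)
        raise ValueError(f"strategy {label!r} takes no parameters")
    return factory()


def run_exploration(world: CMCKernel, strategy, n_steps: int,
                    eval_every: int = 10, seed=None, rng=None,
                    model: PosteriorModel | None = None,
                    world_id: str | None = None, extra=None,
                    snapshot_steps=None, **strategy_params) -> ExplorationTrace:
    """Run one agent in one world and trace its missing information.

    The agent starts in a uniformly random state.  Each step it selects
    an action (the unembodied control also selects, and teleports to, a
    state), the world transitions, and the observation updates the
    posterior model.  Missing information against the true kernel is
    recorded at step 0 and every ``eval_every`` steps (plus the final
    step).  ``snapshot_steps`` optionally collects copies of the
    posterior-mean kernel at the named step counts.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if eval_every < 1:
        raise ValueError("eval_every must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if model is None:
        from .inference import model_for_world
        model = model_for_world(world, extra)
    strategy = make_strategy(strategy, **strategy_params)
    strategy.reset(model, world, rng)

    row_kl = info.missing_information_rows(world, model.theta_hat)
    eval_times = [0]
    missing = [float(row_kl.sum())]
    snapshot_steps = set(snapshot_steps or ())
    snapshots = {}
    if 0 in snapshot_steps:
        snapshots[0] = model.theta_hat.copy()

    s = int(rng.integers(world.n_states))
    if isinstance(strategy, CounterBased):
        strategy.start_state(s)
    states = [s]
    actions = []
    for t in range(1, n_steps + 1):
        if strategy.teleports:
            a, s = strategy.select(s)
            states[-1] = s
        else:
            a = strategy.select(s)
        s_next = step(world, s, a, rng)
        old_row = model.theta_hat[a, s].copy()
        model.record_observation(a, s, s_next)
        strategy.observe(a, s, s_next, old_row)
        row_kl[a, s] = info.missing_information_rows(
            world.theta[a:a + 1, s:s + 1], model.theta_hat[a:a + 1, s:s + 1]
        )[0, 0]
        actions.append(a)
        states.append(s_next)
        if t % eval_every == 0 or t == n_steps:
            eval_times.append(t)
            missing.append(float(row_kl.sum()))
        if t in snapshot_steps:
            snapshots[t] = model.theta_hat.copy()
        s = s_next

    return ExplorationTrace(
        states=np.asarray(states),
        actions=np.asarray(actions, dtype=int),
        eval_times=np.asarray(eval_times),
        missing_info=np.asarray(missing),
        strategy_name=strategy.label,
        world_id=world_id or world.world_id,
        seed=seed,
        snapshots=snapshots or None,
    )
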