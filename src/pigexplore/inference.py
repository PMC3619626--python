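"""Bayesian inference of CMC transition kernels from observed steps.

The agent's internal model is the posterior mean of the transition
tensor given its observation counts and a prior matched to the world's
generative class:

* **Dirichlet family** (dense worlds and, with per-row concentrations,
  mazes): conjugate updating gives the familiar smoothed-frequency
  estimate ``(counts + alpha) / (row total + sum(alpha))``.

* **Discrete-support family** (1-2-3 worlds): action label ``a`` is
  uniform on an unknown size-``a`` set of targets, itself uniform over
  all size-``a`` subsets.  The supports consistent with ``k`` distinct
  observed outcomes are exactly those containing them, and by symmetry
  each unobserved state belongs to the support with probability
  ``(a-k)/(N-k)``, so the posterior mean puts ``1/a`` on each observed
  state and ``(a-k)/(a*(N-k))`` on each unobserved one.

For mazes the layout-conditional matched prior follows from the
aggregation property of the Dirichlet distribution: the generator draws
4 direction weights from ``Dirichlet(20, 1, 1, 1)`` and routes them
through walls, so the observable row over *distinct destination rooms*
is Dirichlet with concentrations summed over the directions mapping to
each destination.  Updating is then conjugate per row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .environments import CMCKernel, MazeLayout, WorldError

FAMILIES = ("dirichlet", "onetwothree")


class InconsistentDataError(ValueError):
    """Observation impossible under the discrete-support generative model."""


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Prior family and (for the Dirichlet family) its symmetric
    per-row concentration parameter."""

    family: str
    concentration: float = 1.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "dirichlet" and not self.concentration > 0:
            raise ValueError("concentration must be positive")


def posterior_mean_dirichlet(row_counts, alpha) -> np.ndarray:
    """Posterior-mean row ``(c_i + alpha_i) / (sum c + sum alpha)``.

    ``alpha`` may be a scalar (symmetric prior) or a vector of
    per-component concentrations (e.g. a layout-matched maze row, where
    components outside the support carry concentration 0).
    """
    c = np.asarray(row_counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    a = np.broadcast_to(np.asarray(alpha, dtype=float), c.shape)
    if np.any(a < 0) or not np.any(a > 0):
        raise ValueError("concentrations must be non-negative with positive sum")
    base = c + a
    return base / base.sum()


def posterior_mean_123(a_label: int, observed_outcomes, n_states: int) -> np.ndarray:
    """Posterior-mean row for a 1-2-3 action after the given outcomes.

    Each of the ``k`` distinct observed states gets ``1/a``; each
    unobserved state gets ``(a-k)/(a*(N-k))``.
    """
    if a_label < 1:
        raise ValueError("a_label must be a positive action label")
    observed = set(int(x) for x in observed_outcomes)
    if any(not 0 <= x < n_states for x in observed):
        raise ValueError("observed outcome out of range")
    k = len(observed)
    if k > a_label:
        raise InconsistentDataError(
            f"{k} distinct outcomes observed for an action with {a_label} targets"
        )
    row = np.zeros(n_states)
    if observed:
        row[sorted(observed)] = 1.0 / a_label
    if k < a_label:
        rest = (a_label - k) / (a_label * (n_states - k))
        mask = np.ones(n_states, dtype=bool)
        mask[sorted(observed)] = False
        row[mask] = rest
    return row


@dataclasses.dataclass
class TransitionCounts:
    """Observation history as integer counts per (action, origin, result)."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


class PosteriorModel:
    """Counts plus prior, maintaining the posterior-mean kernel.

    Parameters
    ----------
    prior
        A :class:`PriorSpec`.
    n_states, n_actions
        Kernel dimensions.
    alpha
        Optional ``(M, N, N)`` tensor of per-row Dirichlet
        concentrations, overriding the symmetric ``prior.concentration``
        (used for the layout-matched maze prior).  Dirichlet family
        only.
    """

    def __init__(self, prior: PriorSpec, n_states: int, n_actions: int,
                 alpha: np.ndarray | None = None):
        self.prior = prior
        self.n_states = int(n_states)
        self.n_actions = int(n_actions)
        if self.n_states < 2 or self.n_actions < 1:
            raise ValueError("need n_states >= 2 and n_actions >= 1")
        shape = (self.n_actions, self.n_states, self.n_states)
        self.counts = np.zeros(shape)
        self.total = 0
        if prior.family == "dirichlet":
            if alpha is None:
                alpha = np.full(shape, float(prior.concentration))
            else:
                alpha = np.asarray(alpha, dtype=float)
                if alpha.shape != shape:
                    raise ValueError("alpha tensor has wrong shape")
                if np.any(alpha < 0) or np.any(alpha.sum(axis=2) <= 0):
                    raise ValueError("invalid concentration tensor")
            self._alpha = alpha
        else:
            if alpha is not None:
                raise ValueError("alpha tensor only applies to the Dirichlet family")
            if self.n_actions > self.n_states:
                raise ValueError("1-2-3 family needs action labels <= n_states")
            self._alpha = None
            self._n_distinct = np.zeros((self.n_actions, self.n_states), dtype=int)
        self.theta_hat = np.empty(shape)
        for a in range(self.n_actions):
            for s in range(self.n_states):
                self._refresh_row(a, s)

    # -- constructors -------------------------------------------------
    @classmethod
    def for_dense(cls, n_states: int = 10, n_actions: int = 4,
                  concentration: float = 1.0) -> "PosteriorModel":
        return cls(PriorSpec("dirichlet", concentration), n_states, n_actions)

    @classmethod
    def for_onetwothree(cls, n_states: int = 10) -> "PosteriorModel":
        return cls(PriorSpec("onetwothree"), n_states, 3)

    @classmethod
    def maze_matched(cls, layout: MazeLayout,
                     noise_concentration: float = 20.0) -> "PosteriorModel":
        """Layout-conditional matched prior for a maze world."""
        alpha = maze_matched_alpha(layout, noise_concentration)
        return cls(PriorSpec("dirichlet", 1.0), layout.n_states, 4, alpha=alpha)

    # -- core ---------------------------------------------------------
    def _check_indices(self, a: int, s: int, s_next: int | None = None) -> None:
        if not 0 <= a < self.n_actions:
            raise ValueError(f"action {a} out of range")
        if not 0 <= s < self.n_states:
            raise ValueError(f"state {s} out of range")
        if s_next is not None and not 0 <= s_next < self.n_states:
            raise ValueError(f"state {s_next} out of range")

    def _refresh_row(self, a: int, s: int) -> None:
        if self._alpha is not None:
            base = self.counts[a, s] + self._alpha[a, s]
            self.theta_hat[a, s] = base / base.sum()
        else:
            label = a + 1
            observed = np.flatnonzero(self.counts[a, s])
            self.theta_hat[a, s] = posterior_mean_123(
                label, observed, self.n_states
            )

    def record_observation(self, a: int, s: int, s_next: int) -> "PosteriorModel":
        """Add one observed transition; only row (a, s) is recomputed."""
        self._check_indices(a, s, s_next)
        if self._alpha is None:
            label = a + 1
            if (self.counts[a, s, s_next] == 0
                    and self._n_distinct[a, s] >= label):
                raise InconsistentDataError(
                    f"action label {label} already has {label} known targets"
                )
            if self.counts[a, s, s_next] == 0:
                self._n_distinct[a, s] += 1
        self.counts[a, s, s_next] += 1
        self.total += 1
        self._refresh_row(a, s)
        return self

    def row(self, a: int, s: int) -> np.ndarray:
        """Current posterior-mean row (a view; do not mutate)."""
        self._check_indices(a, s)
        return self.theta_hat[a, s]

    def hypothetical_row(self, a: int, s: int, s_star: int) -> np.ndarray:
        """Row (a, s) after hypothetically observing ``s_star`` once,
        without mutating the model."""
        self._check_indices(a, s, s_star)
        if self._alpha is not None:
            base = self.counts[a, s] + self._alpha[a, s]
            base = base.copy()
            base[s_star] += 1.0
            return base / base.sum()
        label = a + 1
        if self.counts[a, s, s_star] > 0:
            return self.theta_hat[a, s].copy()
        if self._n_distinct[a, s] >= label:
            raise InconsistentDataError(
                f"outcome {s_star} impossible: all {label} targets known"
            )
        observed = list(np.flatnonzero(self.counts[a, s])) + [s_star]
        return posterior_mean_123(label, observed, self.n_states)

    def hypothetical_rows(self, a: int, s: int) -> np.ndarray:
        """All one-step hypothetical updates of row (a, s) as an
        ``(N, N)`` matrix; row ``j`` is the update after outcome ``j``.

        Outcomes with zero posterior probability keep the current row
        (they carry zero weight in every one-step utility).
        """
        self._check_indices(a, s)
        n = self.n_states
        if self._alpha is not None:
            base = self.counts[a, s] + self._alpha[a, s]
            h = (base[None, :] + np.eye(n)) / (base.sum() + 1.0)
            return h
        row = self.theta_hat[a, s]
        h = np.tile(row, (n, 1))
        label = a + 1
        if self._n_distinct[a, s] < label:
            observed = list(np.flatnonzero(self.counts[a, s]))
            for j in np.flatnonzero(row):
                if self.counts[a, s, j] == 0:
                    h[j] = posterior_mean_123(label, observed + [j], n)
        return h

    def copy(self) -> "PosteriorModel":
        out = object.__new__(PosteriorModel)
        out.prior = self.prior
        out.n_states = self.n_states
        out.n_actions = self.n_actions
        out.counts = self.counts.copy()
        out.total = self.total
        out.theta_hat = self.theta_hat.copy()
        out._alpha = None if self._alpha is None else self._alpha
        if self._alpha is None:
            out._n_distinct = self._n_distinct.copy()
        return out

    # -- serialization ------------------------------------------------
    def to_checkpoint(self) -> dict:
        return {
            "prior": dataclasses.asdict(self.prior),
            "n_states": self.n_states,
            "n_actions": self.n_actions,
            "counts": self.counts.astype(int).tolist(),
            "alpha": None if self._alpha is None else self._alpha.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_checkpoint()))

    @classmethod
    def from_checkpoint(cls, doc: dict) -> "PosteriorModel":
        prior = PriorSpec(**doc["prior"])
        alpha = doc.get("alpha")
        model = cls(prior, doc["n_states"], doc["n_actions"],
                    alpha=None if alpha is None else np.asarray(alpha))
        counts = np.asarray(doc["counts"], dtype=float)
        for a, s, s_next in zip(*np.nonzero(counts)):
            for _ in range(int(counts[a, s, s_next])):
                model.record_observation(int(a), int(s), int(s_next))
        return model

    @classmethod
    def load(cls, path) -> "PosteriorModel":
        return cls.from_checkpoint(json.loads(Path(path).read_text()))


def maze_matched_alpha(layout: MazeLayout,
                       noise_concentration: float = 20.0) -> np.ndarray:
    """Per-row Dirichlet concentrations matched to the maze generator.

    For each (state, action), every direction's concentration (the
    noise concentration for the intended direction, 1 otherwise) is
    added onto the destination that direction resolves to, merging
    directions that hit the same room.
    """
    n = layout.n_states
    alpha = np.zeros((4, n, n))
    for s in range(n):
        dests = [layout.resolve(s, d) for d in range(4)]
        for a in range(4):
            for d in range(4):
                alpha[a, s, dests[d]] += noise_concentration if d == a else 1.0
    return alpha


def model_for(world_class: str, n_states: int | None = None,
              n_actions: int | None = None, layout: MazeLayout | None = None,
              concentration: float = 1.0, matched: bool = False,
              noise_concentration: float = 20.0) -> PosteriorModel:
    """Default agent model for a world class.

    Dense worlds get a flat Dirichlet and 1-2-3 worlds the
    discrete-support prior (both exactly matched to their generators).
    Maze agents default to a flat Dirichlet over all rooms: discovering
    the wall and transporter topology is part of the maze learning
    task.  Pass ``matched=True`` (with a layout) for the
    layout-conditional matched prior instead, which knows each row's
    possible destinations and learns only the translation noise.
    """
    if world_class == "dense":
        return PosteriorModel.for_dense(n_states or 10, n_actions or 4,
                                        concentration)
    if world_class in ("onetwothree", "123"):
        return PosteriorModel.for_onetwothree(n_states or 10)
    if world_class == "maze":
        if matched and layout is not None:
            return PosteriorModel.maze_matched(layout, noise_concentration)
        if n_states is None:
            if layout is None:
                raise ValueError("need n_states or layout for a maze model")
            n_states = layout.n_states
        return PosteriorModel.for_dense(n_states, 4, concentration)
    raise WorldError(f"unknown world class {world_class!r}")


def model_for_world(world: CMCKernel, extra=None, **kwargs) -> PosteriorModel:
    """Convenience wrapper inferring dimensions from a kernel."""
    layout = extra if isinstance(extra, MazeLayout) else None
    return model_for(world.world_class or "dense", n_states=world.n_states,
                     n_actions=world.n_actions, layout=layout, **kwargs)
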