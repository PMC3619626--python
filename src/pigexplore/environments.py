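"""Controllable Markov chain (CMC) worlds and their generators.

A CMC is a Markov decision process stripped of rewards: a finite state
set of size ``N``, a finite action set of size ``M``, and one transition
distribution per (action, state) pair, collected in a probability tensor
``theta[a, s, s']``.  An agent occupying state ``s`` that emits action
``a`` is moved to a state drawn from ``theta[a, s, :]``.

Three stochastic world families with very different structure are
provided, each with its own generative process:

``dense``
    Every transition row is an independent draw from the flat Dirichlet
    on the simplex (N=10 states, M=4 actions by default).  These worlds
    are maximally unstructured: every state is reachable from every
    other in one step with positive probability.

``maze``
    States are the rooms of a square grid (6x6 by default).  The four
    actions are noisy translations in the cardinal directions.  Interior
    walls are carved from a uniform spanning tree (so the room graph is
    connected) and a fraction of the remaining interior walls is then
    opened to give rooms multiple exits.  A number of wall segments are
    one-way transporters into a randomly chosen absorbing state, which
    self-loops under every action.  Direction noise is Dirichlet with a
    high concentration on the intended direction, and each direction's
    probability mass is routed through the layout: through an opening to
    the adjacent room, into a plain wall back to the same room, or
    through a transporter to the absorbing state.

``onetwothree``
    N=10 states and M=3 actions.  Action ``a`` (labelled 1, 2, 3) moves
    the agent uniformly to one of ``a`` distinct target states; targets
    are drawn independently per (action, state).  Rows are supported on
    a small discrete set, so these worlds probe discrete-support priors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

ROW_TOL = 1e-9

WORLD_CLASSES = ("dense", "maze", "onetwothree")

#: Cardinal directions in grid mazes: North, East, South, West.
#: Cells are indexed row-major with row 0 at the top, so North is row-1.
DIRECTIONS = ((-1, 0), (0, 1), (1, 0), (0, -1))
OPPOSITE = (2, 3, 0, 1)


class WorldError(ValueError):
    """Invalid argument or malformed kernel in the environments layer."""


def _as_rng(rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclasses.dataclass
class CMCKernel:
    """Ground-truth transition kernel of a controllable Markov chain.

    Parameters
    ----------
    theta
        Array of shape ``(n_actions, n_states, n_states)``; each row
        ``theta[a, s, :]`` is a probability distribution over the
        resultant state.
    world_class, world_id
        Optional provenance labels carried through experiment outputs.
    """

    theta: np.ndarray
    world_class: str | None = None
    world_id: str | None = None

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self._cumsum = None
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        th = self.theta
        if th.ndim != 3 or th.shape[1] != th.shape[2]:
            raise WorldError(f"kernel must have shape (M, N, N), got {th.shape}")
        m, n, _ = th.shape
        if n < 2:
            raise WorldError("a CMC needs at least 2 states")
        if m < 1:
            raise WorldError("a CMC needs at least 1 action")
        if np.any(th < -1e-12):
            raise WorldError("negative transition probability")
        row_sums = th.sum(axis=2)
        if not np.allclose(row_sums, 1.0, atol=ROW_TOL, rtol=0.0):
            bad = np.unravel_index(np.argmax(np.abs(row_sums - 1.0)), row_sums.shape)
            raise WorldError(f"row {bad} sums to {row_sums[bad]!r}, expected 1")

    @property
    def n_actions(self) -> int:
        return self.theta.shape[0]

    @property
    def n_states(self) -> int:
        return self.theta.shape[1]

    @property
    def cumsum(self) -> np.ndarray:
        """Per-row cumulative sums, cached for fast sampling."""
        if self._cumsum is None:
            self._cumsum = np.cumsum(self.theta, axis=2)
        return self._cumsum

    def row(self, a: int, s: int) -> np.ndarray:
        return self.theta[a, s]

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_states": self.n_states,
            "n_actions": self.n_actions,
            "theta": self.theta.tolist(),
        }
        if self.world_class is not None:
            d["world_class"] = self.world_class
        if self.world_id is not None:
            d["world_id"] = self.world_id
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CMCKernel":
        kernel = cls(
            np.asarray(d["theta"], dtype=float),
            world_class=d.get("world_class"),
            world_id=d.get("world_id"),
        )
        if kernel.n_states != d.get("n_states", kernel.n_states):
            raise WorldError("n_states field disagrees with theta shape")
        if kernel.n_actions != d.get("n_actions", kernel.n_actions):
            raise WorldError("n_actions field disagrees with theta shape")
        return kernel


@dataclasses.dataclass(frozen=True)
class MazeLayout:
    """Wall topology of a grid maze.

    ``wall_set`` holds *directed* wall segments ``(cell, direction)``:
    an interior wall between two rooms appears once per side, and all
    boundary segments are present.  ``transporter_set`` is the subset of
    segments that teleport into ``absorbing_state`` (one-way).
    """

    grid_side: int
    wall_set: frozenset
    transporter_set: frozenset
    absorbing_state: int

    def __post_init__(self):
        if not self.transporter_set <= self.wall_set:
            raise WorldError("transporters must sit on wall segments")

    @property
    def n_states(self) -> int:
        return self.grid_side * self.grid_side

    def neighbor(self, cell: int, direction: int) -> int | None:
        """Adjacent cell in ``direction`` or None beyond the boundary."""
        side = self.grid_side
        r, c = divmod(cell, side)
        dr, dc = DIRECTIONS[direction]
        r, c = r + dr, c + dc
        if 0 <= r < side and 0 <= c < side:
            return r * side + c
        return None

    def resolve(self, cell: int, direction: int) -> int:
        """Destination of one unit of probability mass sent from ``cell``
        in ``direction``: the adjacent room through an opening, ``cell``
        itself off a plain wall, or the absorbing state through a
        transporter.  The absorbing state maps everything to itself.
        """
        if cell == self.absorbing_state:
            return self.absorbing_state
        seg = (cell, direction)
        if seg in self.transporter_set:
            return self.absorbing_state
        if seg in self.wall_set:
            return cell
        nb = self.neighbor(cell, direction)
        assert nb is not None  # boundary segments are always walls
        return nb

    def to_dict(self) -> dict:
        return {
            "grid_side": self.grid_side,
            "wall_set": sorted(map(list, self.wall_set)),
            "transporter_set": sorted(map(list, self.transporter_set)),
            "absorbing_state": self.absorbing_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MazeLayout":
        return cls(
            grid_side=int(d["grid_side"]),
            wall_set=frozenset(tuple(x) for x in d["wall_set"]),
            transporter_set=frozenset(tuple(x) for x in d["transporter_set"]),
            absorbing_state=int(d["absorbing_state"]),
        )


@dataclasses.dataclass(frozen=True)
class OneTwoThreeSupports:
    """Target sets of a 1-2-3 world.

    ``support[(a, s)]`` is the frozenset of the ``a+1`` distinct states
    action index ``a`` (label ``a+1``) can move to from state ``s``.
    """

    support: dict
    n_states: int

    @property
    def n_actions(self) -> int:
        return max(a for a, _ in self.support) + 1

    def to_dict(self) -> dict:
        m = self.n_actions
        nested = [
            [sorted(self.support[(a, s)]) for s in range(self.n_states)]
            for a in range(m)
        ]
        return {"n_states": self.n_states, "support": nested}

    @classmethod
    def from_dict(cls, d: dict) -> "OneTwoThreeSupports":
        nested = d["support"]
        support = {
            (a, s): frozenset(targets)
            for a, per_state in enumerate(nested)
            for s, targets in enumerate(per_state)
        }
        return cls(support=support, n_states=int(d["n_states"]))


# ---------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------

def sample_dense_world(n_states: int = 10, n_actions: int = 4, rng=None) -> CMCKernel:
    """Draw a dense world: every row an independent flat-Dirichlet draw."""
    if n_states < 2:
        raise WorldError("n_states must be >= 2")
    if n_actions < 1:
        raise WorldError("n_actions must be >= 1")
    rng = _as_rng(rng)
    theta = rng.dirichlet(np.ones(n_states), size=(n_actions, n_states))
    return CMCKernel(theta, world_class="dense")


def _grid_neighbors(side: int):
    nbrs = []
    for cell in range(side * side):
        r, c = divmod(cell, side)
        out = []
        for dr, dc in DIRECTIONS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < side and 0 <= cc < side:
                out.append(rr * side + cc)
        nbrs.append(out)
    return nbrs


def _uniform_spanning_tree(side: int, rng: np.random.Generator) -> set:
    """Wilson's loop-erased random walk; returns undirected edges as
    sorted cell pairs.  Samples uniformly over all spanning trees of the
    grid graph."""
    n = side * side
    nbrs = _grid_neighbors(side)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[int(rng.integers(n))] = True
    nxt = np.full(n, -1, dtype=int)
    edges: set = set()
    for start in range(n):
        if in_tree[start]:
            continue
        u = start
        while not in_tree[u]:
            choices = nbrs[u]
            nxt[u] = choices[int(rng.integers(len(choices)))]
            u = nxt[u]
        u = start
        while not in_tree[u]:
            in_tree[u] = True
            v = nxt[u]
            edges.add((min(u, v), max(u, v)))
            u = v
    return edges


def sample_maze_world(
    grid_side: int = 6,
    n_transporters: int = 30,
    noise_concentration: float = 20.0,
    wall_opening_fraction: float = 0.5,
    rng=None,
):
    """Draw a maze world and its layout.

    Construction: (i) interior walls are the grid edges left out of a
    uniform spanning tree, minus a fraction ``wall_opening_fraction``
    opened at random; (ii) the absorbing state is uniform over rooms;
    (iii) ``n_transporters`` distinct directed wall segments become
    transporters; (iv) per (state, intended direction) a 4-vector of
    direction weights is drawn from a Dirichlet with concentration
    ``noise_concentration`` on the intended direction and 1 elsewhere,
    then routed through the layout; (v) the absorbing state self-loops.

    Returns ``(kernel, layout)``.
    """
    if grid_side < 2:
        raise WorldError("grid_side must be >= 2")
    if noise_concentration <= 0:
        raise WorldError("noise_concentration must be positive")
    if not 0.0 <= wall_opening_fraction <= 1.0:
        raise WorldError("wall_opening_fraction must lie in [0, 1]")
    rng = _as_rng(rng)
    n = grid_side * grid_side

    tree = _uniform_spanning_tree(grid_side, rng)
    interior = set()
    for cell in range(n):
        r, c = divmod(cell, grid_side)
        if c + 1 < grid_side:
            interior.add((cell, cell + 1))
        if r + 1 < grid_side:
            interior.add((cell, cell + grid_side))
    candidates = sorted(interior - tree)
    n_open = int(round(wall_opening_fraction * len(candidates)))
    open_idx = rng.choice(len(candidates), size=n_open, replace=False) if n_open else []
    opened = {candidates[i] for i in np.atleast_1d(open_idx)} if n_open else set()
    walls_undirected = set(candidates) - opened

    wall_set = set()
    for cell in range(n):
        r, c = divmod(cell, grid_side)
        for d, (dr, dc) in enumerate(DIRECTIONS):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < grid_side and 0 <= cc < grid_side):
                wall_set.add((cell, d))
    for u, v in walls_undirected:
        d = 1 if v == u + 1 else 2  # East or South from u
        wall_set.add((u, d))
        wall_set.add((v, OPPOSITE[d]))

    if n_transporters > len(wall_set):
        raise WorldError(
            f"requested {n_transporters} transporters but only "
            f"{len(wall_set)} wall segments exist"
        )
    absorbing = int(rng.integers(n))
    segments = sorted(wall_set)
    idx = rng.choice(len(segments), size=n_transporters, replace=False)
    transporters = frozenset(segments[i] for i in np.atleast_1d(idx))

    layout = MazeLayout(
        grid_side=grid_side,
        wall_set=frozenset(wall_set),
        transporter_set=transporters,
        absorbing_state=absorbing,
    )

    return maze_kernel_from_layout(layout, noise_concentration, rng), layout


def maze_kernel_from_layout(layout: MazeLayout,
                            noise_concentration: float = 20.0,
                            rng=None) -> CMCKernel:
    """Draw the noisy-translation kernel induced by a maze layout."""
    if noise_concentration <= 0:
        raise WorldError("noise_concentration must be positive")
    rng = _as_rng(rng)
    n = layout.n_states
    absorbing = layout.absorbing_state
    theta = np.zeros((4, n, n))
    for s in range(n):
        if s == absorbing:
            theta[:, s, absorbing] = 1.0
            continue
        dests = [layout.resolve(s, d) for d in range(4)]
        for a in range(4):
            conc = np.ones(4)
            conc[a] = noise_concentration
            w = rng.dirichlet(conc)
            for d in range(4):
                theta[a, s, dests[d]] += w[d]
    return CMCKernel(theta, world_class="maze")


def sample_onetwothree_world(n_states: int = 10, rng=None):
    """Draw a 1-2-3 world: action label ``a`` moves uniformly onto a
    random size-``a`` set of distinct targets, independent per (a, s).

    Returns ``(kernel, supports)``.
    """
    if n_states < 3:
        raise WorldError("1-2-3 worlds need at least 3 states")
    rng = _as_rng(rng)
    support = {}
    theta = np.zeros((3, n_states, n_states))
    for a in range(3):
        size = a + 1
        for s in range(n_states):
            targets = rng.choice(n_states, size=size, replace=False)
            support[(a, s)] = frozenset(int(t) for t in targets)
            theta[a, s, targets] = 1.0 / size
    kernel = CMCKernel(theta, world_class="onetwothree")
    return kernel, OneTwoThreeSupports(support=support, n_states=n_states)


def step(kernel: CMCKernel, s: int, a: int, rng) -> int:
    """Sample the next state from ``theta[a, s, :]``."""
    if not 0 <= a < kernel.n_actions:
        raise WorldError(f"action {a} out of range")
    if not 0 <= s < kernel.n_states:
        raise WorldError(f"state {s} out of range")
    u = rng.random()
    j = int(np.searchsorted(kernel.cumsum[a, s], u, side="right"))
    return min(j, kernel.n_states - 1)


# ---------------------------------------------------------------------
# world files
# ---------------------------------------------------------------------

def save_world(path, kernel: CMCKernel, layout: MazeLayout | None = None,
               supports: OneTwoThreeSupports | None = None) -> None:
    """Write a kernel (plus optional maze layout / 1-2-3 supports) to JSON."""
    doc = kernel.to_dict()
    if layout is not None:
        doc["layout"] = layout.to_dict()
    if supports is not None:
        doc["supports"] = supports.to_dict()
    Path(path).write_text(json.dumps(doc))


def load_world(path):
    """Read a world JSON document.

    Returns ``(kernel, extra)`` where ``extra`` is a MazeLayout, a
    OneTwoThreeSupports, or None.
    """
    doc = json.loads(Path(path).read_text())
    kernel = CMCKernel.from_dict(doc)
    extra = None
    if "layout" in doc:
        extra = MazeLayout.from_dict(doc["layout"])
    elif "supports" in doc:
        extra = OneTwoThreeSupports.from_dict(doc["supports"])
    return kernel, extra


def save_kernels_npz(path, kernels) -> None:
    """Compact array archive for batches of same-shape kernels."""
    np.savez_compressed(path, theta=np.stack([k.theta for k in kernels]))


def load_kernels_npz(path, world_class: str | None = None):
    data = np.load(path)
    return [CMCKernel(t, world_class=world_class) for t in data["theta"]]


def sample_world(world_class: str, rng=None, **kwargs):
    """Generate one world of the named class.

    Returns ``(kernel, extra)``; ``extra`` is None for dense worlds.
    """
    if world_class == "dense":
        return sample_dense_world(rng=rng, **kwargs), None
    if world_class == "maze":
        return sample_maze_world(rng=rng, **kwargs)
    if world_class in ("onetwothree", "123"):
        return sample_onetwothree_world(rng=rng, **kwargs)
    raise WorldError(f"unknown world class {world_class!r}")
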