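"""Information-theoretic quantities driving and assessing exploration.

All quantities are in bits (base-2 logarithms) and use the convention
``0 * log(0/q) = 0``.  A true transition probability falling where the
estimate is zero yields ``+inf`` rather than an exception, so callers
can decide how to treat genuinely impossible-under-the-model events.

Utility functions of one more observation of a row (a, s):

* ``predicted_information_gain`` (PIG): the posterior-expected decrease
  in missing information; the model-expected KL divergence of the
  one-step-updated row from the current row.
* ``predicted_mode_change`` (PMC): expected change in the row's modal
  probability.
* ``predicted_L1_change`` (PLC): expected mean absolute change of the
  row.
* ``posterior_expected_information_gain`` (PEIG, "surprise"): the KL
  divergence of the already-updated row from its predecessor, available
  only after acting.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .inference import PosteriorModel

_UTILITIES = ("pig", "pmc", "plc")


@dataclasses.dataclass
class UtilityTable:
    """Per-(action, state) utility values.

    PIG values are in bits; PMC in probability units; PLC in mean-L1
    units.
    """

    values: np.ndarray  # (M, N)
    utility_name: str

    def to_frame(self) -> pd.DataFrame:
        m, n = self.values.shape
        a, s = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
        return pd.DataFrame({
            "action": a.ravel(),
            "state": s.ravel(),
            "value": self.values.ravel(),
            "utility_name": self.utility_name,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def kl_divergence(p, q) -> float:
    """``sum p_i log2(p_i / q_i)``; +inf where p puts mass where q has none."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share support size")
    mask = p > 0
    if np.any(q[mask] == 0):
        return float("inf")
    pm = p[mask]
    return float(np.sum(pm * np.log2(pm / q[mask])))


def missing_information(world, theta_hat) -> float:
    """Unweighted sum of per-row KL divergences of the estimate from the
    true kernel: the agent's learning objective."""
    return float(missing_information_rows(world, theta_hat).sum())


def missing_information_rows(world, theta_hat) -> np.ndarray:
    """Per-(action, state) KL divergences as an (M, N) array."""
    theta = world.theta if hasattr(world, "theta") else np.asarray(world, float)
    that = np.asarray(theta_hat, dtype=float)
    if theta.shape != that.shape:
        raise ValueError("kernel and estimate shapes differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(theta > 0, theta * np.log2(theta / that), 0.0)
    terms = np.where((theta > 0) & (that == 0), np.inf, terms)
    return terms.sum(axis=2)


def information_gain(world_row, old_row, new_row) -> float:
    """Realized decrease in a row's missing information after an update:
    ``sum_s' theta[s'] log2(new[s'] / old[s'])``.  May be negative for a
    single unlucky observation."""
    w = np.asarray(world_row, dtype=float)
    old = np.asarray(old_row, dtype=float)
    new = np.asarray(new_row, dtype=float)
    if not w.shape == old.shape == new.shape:
        raise ValueError("rows must share support size")
    mask = w > 0
    if np.any(old[mask] == 0) or np.any(new[mask] == 0):
        return float("inf")
    return float(np.sum(w[mask] * np.log2(new[mask] / old[mask])))


def posterior_expected_information_gain(old_row, new_row) -> float:
    """Surprise of an update already made: KL(new || old)."""
    return kl_divergence(new_row, old_row)


def _hypothetical_kl(model: PosteriorModel, a: int, s: int):
    """Current row p and the vector of KL(hypothetical_j || current)."""
    p = model.row(a, s)
    h = model.hypothetical_rows(a, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(h > 0, h * np.log2(h / p[None, :]), 0.0)
    terms = np.where((h > 0) & (p[None, :] == 0), np.inf, terms)
    return p, h, terms.sum(axis=1)


def predicted_information_gain(model: PosteriorModel, a: int, s: int) -> float:
    """PIG(a, s): model-probability-weighted KL divergence of each
    one-step hypothetical update from the current row.  Outcomes the
    model rules out contribute nothing."""
    p, _, kl = _hypothetical_kl(model, a, s)
    mask = p > 0
    return float(np.sum(p[mask] * kl[mask]))


def predicted_mode_change(model: PosteriorModel, a: int, s: int) -> float:
    """PMC(a, s): expected change of the row's maximum probability."""
    p = model.row(a, s)
    h = model.hypothetical_rows(a, s)
    diff = h.max(axis=1) - p.max()
    return float(np.sum(np.where(p > 0, p * diff, 0.0)))


def predicted_L1_change(model: PosteriorModel, a: int, s: int) -> float:
    """PLC(a, s): expected mean absolute coordinate change of the row."""
    p = model.row(a, s)
    h = model.hypothetical_rows(a, s)
    l1 = np.abs(h - p[None, :]).mean(axis=1)
    return float(np.sum(np.where(p > 0, p * l1, 0.0)))


def utility_row(model: PosteriorModel, kind: str, a: int, s: int) -> float:
    if kind == "pig":
        return predicted_information_gain(model, a, s)
    if kind == "pmc":
        return predicted_mode_change(model, a, s)
    if kind == "plc":
        return predicted_L1_change(model, a, s)
    raise ValueError(f"unknown utility {kind!r}")


def utility_table(model: PosteriorModel, kind: str = "pig") -> UtilityTable:
    """Evaluate a one-step utility for every (action, state)."""
    if kind not in _UTILITIES:
        raise ValueError(f"unknown utility {kind!r}")
    values = np.empty((model.n_actions, model.n_states))
    for a in range(model.n_actions):
        for s in range(model.n_states):
            values[a, s] = utility_row(model, kind, a, s)
    return UtilityTable(values=values, utility_name=kind)


# ---------------------------------------------------------------------
# closed-form batch paths (used by the predicted-vs-realized audit)
# ---------------------------------------------------------------------

def pig_dirichlet_rows(base: np.ndarray) -> np.ndarray:
    """PIG for a batch of Dirichlet-posterior rows.

    ``base = counts + alpha`` with shape (B, N); components with zero
    concentration and zero count (impossible outcomes) are handled.
    Agrees with :func:`predicted_information_gain` on Dirichlet models.
    """
    base = np.asarray(base, dtype=float)
    n = base.sum(axis=1, keepdims=True)
    p = base / n
    shrink = n / (n + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = shrink * (1.0 - p) * np.log2(shrink)
        grown = (n * p + 1.0) / (n + 1.0)
        t2 = grown * np.log2(grown / p)
    kl_j = np.where(p > 0, t1 + t2, 0.0)
    return np.sum(p * kl_j, axis=1)


def information_gain_dirichlet_rows(base: np.ndarray, outcome: np.ndarray,
                                    true_rows: np.ndarray) -> np.ndarray:
    """Realized information gain for one observation per Dirichlet row.

    ``outcome[b]`` is the observed next state for row ``b``; the prior
    must give it positive mass (matched priors do).
    """
    base = np.asarray(base, dtype=float)
    true_rows = np.asarray(true_rows, dtype=float)
    b = np.arange(base.shape[0])
    n = base.sum(axis=1)
    p_j = base[b, outcome] / n
    w_j = true_rows[b, outcome]
    shrink = np.log2(n / (n + 1.0))
    grow = np.log2((n * p_j + 1.0) / ((n + 1.0) * p_j))
    return (1.0 - w_j) * shrink + w_j * grow


def _q_unobserved(a_label, k, n_states):
    return (a_label - k) / (a_label * (n_states - k))


def pig_onetwothree(a_label: int, k, n_states: int) -> np.ndarray:
    """PIG for a 1-2-3 row with ``k`` of its ``a_label`` targets known.

    Vectorized over ``k``; agrees with the generic implementation.
    """
    a = float(a_label)
    k = np.asarray(k, dtype=float)
    n = float(n_states)
    out = np.zeros_like(k)
    active = k < a
    ka = k[active]
    q_u = _q_unobserved(a, ka, n)
    term = (1.0 / a) * np.log2((1.0 / a) / q_u)
    more = a - ka - 1 > 0
    q_u2 = np.where(more, _q_unobserved(a, ka + 1, n), 1.0)
    term = term + np.where(more, (n - ka - 1) * q_u2 * np.log2(q_u2 / q_u), 0.0)
    out[active] = ((a - ka) / a) * term
    return out


def information_gain_onetwothree_new(a_label: int, k, n_states: int) -> np.ndarray:
    """Realized information gain of a 1-2-3 observation revealing a new
    target, given ``k`` targets were known before (vectorized over k).
    An observation of an already-known target gains exactly zero."""
    a = float(a_label)
    k = np.asarray(k, dtype=float)
    n = float(n_states)
    out = np.zeros_like(k)
    active = k < a
    ka = k[active]
    q_u = _q_unobserved(a, ka, n)
    gain = np.log2(1.0 / (a * q_u))
    more = a - ka - 1 > 0
    q_u2 = np.where(more, _q_unobserved(a, ka + 1, n), 1.0)
    gain = gain + np.where(more, (a - ka - 1) * np.log2(q_u2 / q_u), 0.0)
    out[active] = gain / a
    return out
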