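"""Config-driven batch experiments with full seed provenance.

Every batch derives one sub-stream per world (and per purpose) from a
single master seed via ``numpy.random.SeedSequence``, so any figure-
level experiment is reproducible — and strategy comparisons are run on
matched world instances with matched run seeds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import environments as env
from . import information as info
from . import structure, tasks
from .inference import PosteriorModel, maze_matched_alpha, model_for_world
from .strategies import STRATEGIES, run_exploration

#: Default exploration horizons per world class: roughly the time for
#: the unembodied control's class-mean missing information to fall to a
#: small fraction of its prior value.
DEFAULT_STEPS = {"dense": 1000, "maze": 3000, "onetwothree": 1500}

_STREAM_WORLD = 0
_STREAM_RUN = 1
_STREAM_AUDIT = 2
_STREAM_REWARD = 3


def derive_rng(master_seed: int, *keys: int) -> np.random.Generator:
    """Deterministic independent stream for (master seed, keys)."""
    return np.random.default_rng(np.random.SeedSequence((int(master_seed),) +
                                                        tuple(int(k) for k in keys)))


@dataclasses.dataclass
class WorldBundle:
    world: env.CMCKernel
    extra: object
    world_id: str
    index: int


def generate_worlds(world_class: str, n_worlds: int, master_seed: int,
                    **world_kwargs):
    """Generate a reproducible batch of worlds of one class."""
    if n_worlds < 1:
        raise ValueError("n_worlds must be >= 1")
    bundles = []
    for i in range(n_worlds):
        rng = derive_rng(master_seed, _STREAM_WORLD, i)
        world, extra = env.sample_world(world_class, rng=rng, **world_kwargs)
        world.world_id = f"{world_class}-{master_seed}-{i}"
        bundles.append(WorldBundle(world=world, extra=extra,
                                   world_id=world.world_id, index=i))
    return bundles


def make_model(bundle: WorldBundle, matched: bool = False,
               concentration: float = 1.0) -> PosteriorModel:
    return model_for_world(bundle.world, bundle.extra, matched=matched,
                           concentration=concentration)


def _resolve_steps(world_class: str, n_steps) -> int:
    if n_steps is not None:
        return int(n_steps)
    try:
        return DEFAULT_STEPS[world_class]
    except KeyError:
        raise env.WorldError(f"no default horizon for class {world_class!r}")


# ---------------------------------------------------------------------
# learning-curve batches
# ---------------------------------------------------------------------

def strategy_curves(world_class: str, strategies, n_worlds: int,
                    master_seed: int, n_steps=None, eval_every: int = 10,
                    matched: bool = False, world_kwargs=None):
    """Run each strategy on the same batch of worlds with matched seeds.

    Returns ``(eval_times, curves, traces)`` where ``curves[label]`` is
    an (n_worlds, n_evals) array of missing-information values.
    """
    n_steps = _resolve_steps(world_class, n_steps)
    for label in strategies:
        if label not in STRATEGIES:
            raise ValueError(f"unknown strategy {label!r}")
    bundles = generate_worlds(world_class, n_worlds, master_seed,
                              **(world_kwargs or {}))
    curves = {label: [] for label in strategies}
    traces = {label: [] for label in strategies}
    eval_times = None
    for b in bundles:
        for label in strategies:
            rng = derive_rng(master_seed, _STREAM_RUN, b.index)
            trace = run_exploration(
                b.world, label, n_steps, eval_every=eval_every, rng=rng,
                model=make_model(b, matched=matched), world_id=b.world_id,
            )
            curves[label].append(trace.missing_info)
            traces[label].append(trace)
            eval_times = trace.eval_times
    curves = {k: np.asarray(v) for k, v in curves.items()}
    return eval_times, curves, traces


def curves_frame(eval_times, curves) -> pd.DataFrame:
    """Per-strategy mean and standard-error learning curves."""
    rows = []
    for label, arr in curves.items():
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
            else np.zeros(arr.shape[1])
        for t, m, e in zip(eval_times, mean, se):
            rows.append({"strategy": label, "step": int(t),
                         "mean_missing_info": m, "se": e})
    return pd.DataFrame(rows)


def embodiment_batch(world_class: str, n_worlds: int, master_seed: int,
                     n_steps=None, eval_every: int = 10, matched: bool = False,
                     world_kwargs=None) -> pd.DataFrame:
    """Per-world embodiment indices of greedy-PIG vs the unembodied
    control, with the structure index alongside."""
    eval_times, curves, traces = strategy_curves(
        world_class, ("pig-greedy", "unembodied"), n_worlds, master_seed,
        n_steps=n_steps, eval_every=eval_every, matched=matched,
        world_kwargs=world_kwargs,
    )
    bundles = generate_worlds(world_class, n_worlds, master_seed,
                              **(world_kwargs or {}))
    rows = []
    for i in range(n_worlds):
        tg = traces["pig-greedy"][i]
        tu = traces["unembodied"][i]
        psi = structure.equilibrium_distribution(bundles[i].world)
        rows.append({
            "world_id": tg.world_id,
            "world_class": world_class,
            "embodiment_index": structure.embodiment_index(tg, tu),
            "auc_greedy": structure.auc(tg),
            "auc_unembodied": structure.auc(tu),
            "initial_missing_info": tg.missing_info[0],
            "structure_index": structure.structure_index(psi),
            "master_seed": master_seed,
        })
    return pd.DataFrame(rows)


def metrics_batch(world_class: str, n_worlds: int, master_seed: int,
                  lags=range(1, 11), include_path_length: bool = False,
                  world_kwargs=None) -> pd.DataFrame:
    """Structure index, control index at each lag, optional mean path
    length — one row per generated world."""
    bundles = generate_worlds(world_class, n_worlds, master_seed,
                              **(world_kwargs or {}))
    rows = []
    for b in bundles:
        wm = structure.world_metrics(b.world, lags=lags,
                                     include_path_length=include_path_length)
        row = {"world_id": b.world_id, "world_class": world_class,
               "structure_index": wm.structure_index,
               "mean_path_length": wm.mean_path_length,
               "master_seed": master_seed}
        for t, v in zip(lags, wm.control_index):
            row[f"control_index_t{t}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# predicted vs realized information gain audit
# ---------------------------------------------------------------------

def _sample_rows(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a batch of distributions."""
    u = rng.random(p.shape[0])
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def predicted_gain_audit(world_class: str, n_worlds: int = 50, n_trials: int = 50,
                   n_observations: int = 20, master_seed: int = 0,
                   world_kwargs=None) -> pd.DataFrame:
    """Mean predicted vs mean realized information gain per observation
    count, over fresh worlds drawn from the class prior.

    For every transition row of every world, ``n_trials`` independent
    observation sequences are simulated; before each observation the
    model's predicted information gain is recorded, after it the
    realized gain against the true row.  With matched priors the two
    agree in expectation, so the per-count means should sit on the
    unity line within sampling error.
    """
    if n_observations < 1:
        raise ValueError("n_observations must be >= 1")
    bundles = generate_worlds(world_class, n_worlds, master_seed,
                              **(world_kwargs or {}))
    pig_all = [[] for _ in range(n_observations)]
    ig_all = [[] for _ in range(n_observations)]
    for b in bundles:
        rng = derive_rng(master_seed, _STREAM_AUDIT, b.index)
        if world_class in ("onetwothree", "123"):
            n = b.world.n_states
            for a in range(3):
                label = a + 1
                batch = b.world.n_states * n_trials
                k = np.zeros(batch)
                for t in range(n_observations):
                    pig_all[t].append(info.pig_onetwothree(label, k, n))
                    new = rng.random(batch) < (label - k) / label
                    gain = np.where(
                        new, info.information_gain_onetwothree_new(label, k, n),
                        0.0)
                    ig_all[t].append(gain)
                    k = k + new
        else:
            theta = b.world.theta
            m, n, _ = theta.shape
            p_true = np.repeat(theta.reshape(-1, n), n_trials, axis=0)
            if world_class == "maze":
                alpha = maze_matched_alpha(b.extra)
                a_rows = np.repeat(alpha.reshape(-1, n), n_trials, axis=0)
            else:
                a_rows = np.ones_like(p_true)
            counts = np.zeros_like(p_true)
            idx = np.arange(p_true.shape[0])
            for t in range(n_observations):
                base = counts + a_rows
                pig_all[t].append(info.pig_dirichlet_rows(base))
                j = _sample_rows(p_true, rng)
                ig_all[t].append(
                    info.information_gain_dirichlet_rows(base, j, p_true))
                counts[idx, j] += 1.0
    rows = []
    for t in range(n_observations):
        pig = np.concatenate(pig_all[t])
        ig = np.concatenate(ig_all[t])
        diff = pig - ig
        rows.append({
            "world_class": world_class,
            "obs_count": t,
            "mean_pig": pig.mean(),
            "mean_realized_ig": ig.mean(),
            "se_diff": diff.std(ddof=1) / np.sqrt(diff.size),
            "n": diff.size,
        })
    return pd.DataFrame(rows)


def audit_max_z(audit: pd.DataFrame) -> float:
    """Largest |mean PIG - mean realized gain| in standard errors."""
    z = (audit["mean_pig"] - audit["mean_realized_ig"]).abs() / audit["se_diff"]
    return float(z.max())


# ---------------------------------------------------------------------
# goal-directed task evaluation
# ---------------------------------------------------------------------

def task_ranking(world_class: str, strategies, n_worlds: int, master_seed: int,
                 n_steps=None, n_reward_draws: int = 10,
                 reward_horizon: int = 100, matched: bool = False,
                 world_kwargs=None):
    """Navigation and reward losses of each strategy's end-of-run model.

    Returns ``(losses, nav_ranks, reward_ranks)`` where ``losses`` is a
    tidy DataFrame and the rank dicts come from
    :func:`pigexplore.tasks.rank_strategies`.
    """
    n_steps = _resolve_steps(world_class, n_steps)
    bundles = generate_worlds(world_class, n_worlds, master_seed,
                              **(world_kwargs or {}))
    nav_losses = {s: [] for s in strategies}
    rew_losses = {s: [] for s in strategies}
    rows = []
    for b in bundles:
        n = b.world.n_states
        true_hitting = [structure.optimal_hitting_policy(b.world, t)
                        for t in range(n)]
        reward_rng = derive_rng(master_seed, _STREAM_REWARD, b.index)
        reward_sets = [reward_rng.normal(size=n) for _ in range(n_reward_draws)]
        for label in strategies:
            rng = derive_rng(master_seed, _STREAM_RUN, b.index)
            trace = run_exploration(
                b.world, label, n_steps, eval_every=n_steps or 1, rng=rng,
                model=make_model(b, matched=matched), world_id=b.world_id,
                snapshot_steps=[n_steps],
            )
            snap = trace.snapshots[n_steps]
            nav = tasks.navigation_loss(snap, b.world, true_hitting)
            rew = float(np.mean([
                tasks.reward_loss(snap, b.world, r, horizon=reward_horizon)
                for r in reward_sets
            ]))
            nav_losses[label].append(nav)
            rew_losses[label].append(rew)
            rows.append({"world_id": b.world_id, "strategy": label,
                         "benchmark_step": n_steps, "navigation_loss": nav,
                         "reward_loss": rew, "master_seed": master_seed})
    return (pd.DataFrame(rows), tasks.rank_strategies(nav_losses),
            tasks.rank_strategies(rew_losses))


# ---------------------------------------------------------------------
# config-driven benchmark
# ---------------------------------------------------------------------

@dataclasses.dataclass
class ExperimentConfig:
    world_class: str
    n_worlds: int = 50
    strategies: tuple = ("random", "unembodied")
    n_steps: int | None = None
    eval_every: int = 10
    master_seed: int = 0
    matched_prior: bool = False
    compute_metrics: bool = True
    run_tasks: bool = False
    n_reward_draws: int = 10
    outdir: str | None = None
    world_kwargs: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.world_class not in env.WORLD_CLASSES:
            raise ValueError(f"unknown world class {self.world_class!r}")
        if self.n_worlds < 1:
            raise ValueError("n_worlds must be >= 1")
        unknown = [s for s in self.strategies if s not in STRATEGIES]
        if unknown:
            raise ValueError(f"unknown strategies {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "strategies" in doc:
            doc["strategies"] = tuple(doc["strategies"])
        return cls(**doc)


@dataclasses.dataclass
class BenchmarkResults:
    config: ExperimentConfig
    curves: pd.DataFrame
    embodiment: pd.DataFrame | None
    metrics: pd.DataFrame | None
    task_losses: pd.DataFrame | None
    nav_ranks: dict | None
    reward_ranks: dict | None


def run_benchmark(config: ExperimentConfig) -> BenchmarkResults:
    """Run the configured strategies over a matched world batch; emit
    mean curves, per-world embodiment indices (when both greedy-PIG and
    the unembodied control are present), structural metrics, and
    optional task rankings.  Deterministic given the master seed."""
    eval_times, curves, traces = strategy_curves(
        config.world_class, config.strategies, config.n_worlds,
        config.master_seed, n_steps=config.n_steps,
        eval_every=config.eval_every, matched=config.matched_prior,
        world_kwargs=config.world_kwargs,
    )
    curve_df = curves_frame(eval_times, curves)
    embodiment = None
    if {"pig-greedy", "unembodied"} <= set(config.strategies):
        rows = []
        for tg, tu in zip(traces["pig-greedy"], traces["unembodied"]):
            rows.append({"world_id": tg.world_id,
                         "embodiment_index": structure.embodiment_index(tg, tu),
                         "master_seed": config.master_seed})
        embodiment = pd.DataFrame(rows)
    metrics = None
    if config.compute_metrics:
        metrics = metrics_batch(config.world_class, config.n_worlds,
                                config.master_seed,
                                world_kwargs=config.world_kwargs)
    task_losses = nav_ranks = reward_ranks = None
    if config.run_tasks:
        task_losses, nav_ranks, reward_ranks = task_ranking(
            config.world_class, config.strategies, config.n_worlds,
            config.master_seed, n_steps=config.n_steps,
            n_reward_draws=config.n_reward_draws,
            matched=config.matched_prior, world_kwargs=config.world_kwargs,
        )
    results = BenchmarkResults(config=config, curves=curve_df,
                               embodiment=embodiment, metrics=metrics,
                               task_losses=task_losses, nav_ranks=nav_ranks,
                               reward_ranks=reward_ranks)
    if config.outdir:
        _write_results(results)
    return results


def _write_results(results: BenchmarkResults) -> None:
    out = Path(results.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results.curves.to_csv(out / "curves.csv", index=False)
    if results.embodiment is not None:
        results.embodiment.to_csv(out / "embodiment.csv", index=False)
    if results.metrics is not None:
        results.metrics.to_csv(out / "metrics.csv", index=False)
    if results.task_losses is not None:
        results.task_losses.to_csv(out / "task_losses.csv", index=False)
        (out / "task_ranks.json").write_text(json.dumps(
            {"navigation": results.nav_ranks, "reward": results.reward_ranks},
            indent=2))
    cfg = dataclasses.asdict(results.config)
    cfg["strategies"] = list(cfg["strategies"])
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
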