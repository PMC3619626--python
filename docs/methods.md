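# Methods

## The model

`pigexplore` simulates reward-free exploration of a controllable Markov
chain (CMC): a finite state set `S` (|S| = N), a finite action set `A`
(|A| = M), and a transition tensor `Θ[a, s, s']` giving
`p(s' | a, s)`.  A CMC is an MDP without a reward function.  States are
fully observed.  The agent's task is to learn an accurate internal
model `Θ̂` of the kernel; its learning progress is measured by the
*missing information*

    I_M(Θ ‖ Θ̂) = Σ_{s,a} D_KL(Θ[a,s,·] ‖ Θ̂[a,s,·])        [bits]

the unweighted sum of per-row KL divergences from the true kernel to
the estimate.  All information quantities in the package use base-2
logarithms with the convention `0·log 0 = 0`; a true transition with
zero estimated probability yields an explicit `+inf` rather than an
exception.

## Bayesian inference

The agent maintains transition counts and the posterior-mean kernel
under a prior matched to the world's generative family:

* **Dirichlet rows** — conjugate updating gives
  `Θ̂[a,s,s'] = (c[a,s,s'] + α[a,s,s']) / (Σ c[a,s,·] + Σ α[a,s,·])`.
  Concentrations may be symmetric (flat `α = 1` for Dense Worlds) or an
  arbitrary per-component tensor.
* **Discrete supports (1-2-3 Worlds)** — action label `a` is uniform on
  an unknown size-`a` target set, itself uniform over all size-`a`
  subsets.  With `k` distinct observed outcomes, each observed state
  has posterior mean `1/a` and each unobserved state
  `(a−k)/(a(N−k))`; this follows from the symmetry of the supports
  consistent with the data and is verified against exhaustive support
  enumeration in the tests.

The posterior mean is the estimate that minimizes the posterior
expected missing information; the acceptance suite checks this
numerically on a grid of alternative estimates.

## Predicted information gain and its rivals

The one-step utilities compare each hypothetical one-observation
update `Θ̂^{a,s→s*}` of row (a, s) with the current row:

* `PIG(a,s) = Σ_{s*} Θ̂[a,s,s*] · D_KL(Θ̂^{a,s→s*} ‖ Θ̂[a,s,·])` — the
  posterior-expected decrease in missing information from one more
  observation of the row.  Its defining identity — PIG equals the
  model-expected *realized* gain — holds exactly when the prior matches
  the generative process, and is audited empirically per class
  (`runner.predicted_gain_audit`).
* `PMC` — expected change of the row's modal probability.
* `PLC` — expected mean absolute (L1/N) change of the row.
* `PEIG` ("surprise") — `D_KL(new row ‖ old row)` of an update already
  made; the retrospective analogue of PIG, used as the reward of the
  Q-learning strategy.

## World classes

* **Dense Worlds** (N=10, M=4): every row an independent flat-Dirichlet
  draw.  Unstructured, fast mixing; exploration is easy.
* **Mazes** (6×6 rooms, M=4 noisy cardinal translations): interior
  walls are carved by removing a uniform spanning tree from the grid's
  edge set and then opening half of the remaining interior walls;
  30 directed wall segments become one-way transporters into a
  uniformly chosen absorbing room; direction weights per (state,
  action) are Dirichlet with concentration 20 on the intended direction
  and 1 on the other three, routed through the layout (opening →
  neighbor, wall → stay, transporter → absorbing).  The spanning tree
  keeps the room graph connected; the absorbing state makes long-run
  state occupancy maximally biased (structure index 1).
* **1-2-3 Worlds** (N=10, M=3): action label `a` moves uniformly to one
  of `a` distinct targets drawn independently per (action, state).
  Discrete-support rows make the Bayesian updates qualitatively
  different from the Dirichlet families.

### Maze priors: flat by default, layout-matched for the audit

Maze agents default to a *flat* Dirichlet (α=1 over all 36 rooms):
discovering the wall and transporter topology is treated as part of
the learning task.  A *layout-matched* prior is also provided
(`PosteriorModel.maze_matched`): conditioned on the layout, each row is
Dirichlet over its ≤4 distinct destinations with concentrations summed
over the directions mapping there (exact, by the aggregation property
of the Dirichlet).  The predicted-vs-realized gain audit always uses
the matched prior, because the identity it checks presumes a prior
matched to the generative process; exploration experiments use the
flat default.  Both are config options everywhere.

## Exploration strategies

Controls: uniform `random` action; the `unembodied` control teleports
each step to the globally highest-PIG (action, state) pair — an upper
bound that turns exploration into independent sampling.  Utility
maximizers: `pig-greedy` (argmax over actions in the current state) and
value-iterated variants (`pig-vi`, `pmc-vi`, `plc-vi`) that back up the
utility through the learned kernel for `horizon = 10` steps with
discount `γ = 0.95`, recomputing the Q table every step because the
utility shrinks as rows are learned; `pig-vi+` is a positive control
that backs up through the *true* kernel.  Heuristics: least-taken
action (`lta`), counter-based (`cb`, minimizing the expected visit
count of the next state), and `peig-q` (ε-greedy Q-learning with the
PEIG surprise as reward; η=0.1, γ=0.95, ε=0.1, zero-initialized Q — the
original hyperparameters are not recorded, so these are exposed
defaults).  All argmax/argmin ties are broken uniformly at random from
the run's seeded stream; agents start in a uniformly random state.

## Measures of world structure

* *Structure index*: `1 − H(Ψ)/log2 N` where Ψ is the stationary
  distribution of the uniform-random-action chain, computed by power
  iteration from the uniform start (L1 tolerance 1e-12) — robust on
  reducible chains, where it returns the limit from the uniform start.
* *Control index*: mutual information between a uniformly random first
  action and the state `t` steps later (later steps follow the
  random-action chain), averaged over uniform starts.
* *Mean path length*: the average over ordered state pairs of the
  minimum expected hitting time, solved as a stochastic shortest path.
  States from which no policy reaches the target with probability one
  are detected exactly by the classic attractor computation
  (iteratively discarding actions whose support leaks outside the
  candidate set) and reported as `+inf`; infinite pairs are excluded
  from the average and counted.  In mazes the transporter noise makes
  most non-absorbing targets unreachable with probability one, so the
  maze statistic is dominated by paths into the absorbing state.
* *Embodiment index*: `(AUC_greedy − AUC_unembodied)/AUC_unembodied`
  over the missing-information curves of `pig-greedy` and `unembodied`
  run on the same world with the same seed, areas by the trapezoidal
  rule on a shared evaluation grid (every 10 steps by default).

## Goal-directed task evaluation

Model snapshots are evaluated without further learning.  *Navigation*:
the hitting policy optimal under the snapshot is evaluated exactly
under the true world (linear policy evaluation) and compared with the
true optimum, averaged over (start, target) pairs; pairs with an
infinite true optimum — and the rare pairs where the snapshot's policy
never arrives — are excluded.  *Reward acquisition*: rewards are i.i.d.
standard normal per state (10 draws per world); the snapshot yields an
undiscounted 100-step time-indexed policy by backward induction, whose
exact expected return under the truth is subtracted from the true
optimum, averaged over start states.  Strategies are ranked per world
by loss (ties share mean ranks) and ranks averaged over worlds.

## Experiment conditions and problem sizes

Batches derive all randomness from one master seed through
`numpy.random.SeedSequence` sub-streams (world generation, run,
reward-draw and audit streams are separate), so every experiment is
reproducible and strategies are compared on matched worlds with
matched run seeds.  Default horizons are 1000 steps (Dense), 1500
(1-2-3) and 3000 (Mazes); learning curves are evaluated every 10
steps.  The headline embodiment-index batches use 200 Dense, 200
1-2-3 and 50 Maze worlds; the predicted-vs-realized audit uses 50
worlds × 50 trials per row over observation counts 0–19; the strategy
and task comparisons in the test suite use 50 and 30 worlds per class
respectively.

## What the synthetic worlds do and do not show

All data are generated by the package's own world classes, so results
validate the estimators, utilities and policies under their intended
generative assumptions — matched priors, fully observed discrete
states, stationary kernels.  They say nothing about partial
observability, non-stationary dynamics, continuous state spaces, or
priors learned from data, and the maze conclusions are conditional on
this package's specific layout/noise generator (wall-opening fraction
0.5, direction concentration 20, 30 transporters), parameters that are
all exposed in the API.

## Known limitations

* PIG computation is O(N²) per row and value iteration O(M·N²) per
  step; worlds much beyond a few hundred states need sparser methods.
* In mazes generated with these defaults the absorbing state dominates
  embodied exploration: agents of every embodied strategy are absorbed
  within tens of steps, so differences *between* embodied strategies
  in mazes are small, and the maze embodiment index is sensitive to
  the generator's noise and transporter parameters.
* The Q-learning surprise agent and the counter-based heuristic are
  faithful to their published forms but their hyperparameters are
  conventional defaults, not calibrated values.
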