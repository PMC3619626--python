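# pigexplore

Curiosity-driven exploration of discrete worlds, for researchers in
computational neuroscience, reinforcement learning and active
sensing who want a fully reproducible sandbox for *learning-driven*
(reward-free) behavior.

An agent lives in a **controllable Markov chain** (CMC): `N` discrete
states, `M` actions, and a transition tensor `Θ[a, s, s']` it cannot
see.  The agent keeps a Bayesian posterior-mean model `Θ̂` of the
kernel, and its learning progress is the **missing information**

```
I_M(Θ ‖ Θ̂) = Σ_{s,a} D_KL(Θ_{as·} ‖ Θ̂_{as·})      [bits]
```

The package's central quantity is the **predicted information gain**

```
PIG(a, s) = Σ_{s*} Θ̂_{ass*} · D_KL(Θ̂^{a,s→s*}_{as·} ‖ Θ̂_{as·})
```

the model-expected decrease in missing information from one more
observation of row (a, s), where `Θ̂^{a,s→s*}` is the hypothetical
posterior after observing `s*`.  Under a prior matched to the world's
generative process, PIG equals the expected realized gain — the
package audits this identity empirically.  Exploration strategies
built on PIG (greedy, value-iterated with `γ = 0.95` over a 10-step
horizon, and teleporting/random controls) are compared against
classic reward-free heuristics (least-taken action, counter-based
exploration, Q-learning on surprise) across three world families:
unstructured *Dense Worlds*, 6×6 *Mazes* with noisy moves, one-way
transporters and an absorbing room, and discrete-support *1-2-3
Worlds*.  Tools are included to quantify world structure (state-bias,
controllability, mean path length), the cost of embodiment, and the
downstream utility of the learned models on navigation and
reward-gathering tasks.

## Worked example

```python
import numpy as np
from pigexplore import (sample_onetwothree_world, PosteriorModel,
                        run_exploration, embodiment_index)

world, supports = sample_onetwothree_world(rng=np.random.default_rng(0))

greedy = run_exploration(world, "pig-greedy", n_steps=1500, seed=1,
                         model=PosteriorModel.for_onetwothree())
unemb = run_exploration(world, "unembodied", n_steps=1500, seed=1,
                        model=PosteriorModel.for_onetwothree())

print(f"prior missing information: {greedy.missing_info[0]:.1f} bits")
print(f"greedy final: {greedy.missing_info[-1]:.3f} bits, "
      f"unembodied final: {unemb.missing_info[-1]:.3f} bits")
print(f"embodiment index: {embodiment_index(greedy, unemb):.2f}")
```

prints

```
prior missing information: 73.8 bits
greedy final: 0.000 bits, unembodied final: 0.000 bits
embodiment index: 0.41
```

Both agents eventually identify every transition support of this
1-2-3 world (missing information 0), but the embodied greedy agent —
which can only sample the rows of whatever state it occupies — covers
the state space more slowly than the teleporting control; the
embodiment index 0.41 says its learning-curve area is 41% larger.

The same machinery scales to batch experiments from one master seed:

```bash
pigexplore explore --class maze --strategy pig-vi --steps 3000 --seed 7
pigexplore pig-audit --class dense --worlds 50 --trials 50
pigexplore benchmark --config examples/benchmark.yaml --outdir out/
```

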