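# rsrp — reward-optimized stochastic release plasticity

`rsrp` is a research package for studying a biologically motivated learning
rule in which every synapse is a Bernoulli random variable.  A synapse with
release probability ρ transmits (θ = 1) or fails (θ = 0) on each trial, and
the network's behavior — and hence the reward it earns — depends on the
realized release pattern θ.  Learning never backpropagates an error signal:
it adjusts the release probabilities directly, by stochastic natural-gradient
ascent on the expected reward

```
J(ρ) = E_{θ ~ B(ρ)} [ R(θ) ].
```

Because the Fisher information of independent Bernoulli synapses is diagonal,
`diag(1 / (ρ(1 − ρ)))`, the natural-gradient ascent step collapses to a
strikingly simple, local, reward-modulated rule:

```
Δρ = (η / N) · Σᵢ (θᵢ − ρ) · Rᵢ ,      ρ ← clip(ρ + Δρ, ε, 1 − ε)
```

where the sum runs over a population of N release samples, each held fixed
for one whole evaluation episode, and Rᵢ is that episode's (shaped) reward.
Each synapse only needs to know whether it released and how good the global
outcome was — the kind of information a neuromodulatory signal could carry.

The package is aimed at computational-neuroscience and bio-plausible-learning
researchers who want a compact, fully testable implementation of this family
of rules, including:

- **core** (`rsrp.core`): the Bernoulli release model, the natural-gradient
  update, the raw score-function (likelihood-ratio) estimator, Fisher
  diagonal, release-entropy bookkeeping, and a classic sigmoid-parameterized
  "hedonistic synapse" baseline;
- **rewards** (`rsrp.rewards`): centered-rank fitness shaping
  (`R′ᵢ = −½ + (1/N)·#{j : Rᵢ > Rⱼ}`), a running zero-mean baseline, and the
  three sparse classification rewards (accuracy, soft recall / mean
  reciprocal rank, negative cross-entropy);
- **models** (`rsrp.models`): Dale-consistent positive-weight networks —
  an EI-balanced rectifier MLP and a recurrent spiking network of leaky
  integrate-and-fire neurons with a leaky-integrator readout, plus a
  reservoir variant with frozen recurrent connectivity;
- **environments** (`rsrp.environments`): a self-contained classic cart-pole
  simulator (semi-implicit Euler, 500-step cap) and a generic reset/step
  episode contract for external simulators;
- **synthetic_data** (`rsrp.synthetic_data`): noise-corrupted 8×8 digit
  glyphs, Gaussian cluster tasks, tabulated bandit rewards with an exact
  enumeration oracle, and an IDX reader for real digit files;
- **trainers** (`rsrp.trainers`): the two-stage population-evaluation /
  plasticity-optimization loop for reinforcement learning, sparse-reward
  classification, and bandits, with logging, checkpointing, presets and a
  CLI (`rsrp train-rl`, `rsrp train-cls`, `rsrp sweep`).

## Worked example

Train the EI-balanced MLP on the bundled synthetic digit task with the
sparse soft-recall reward and centered-rank shaping:

```python
from rsrp import make_digit_patterns, preset, train

dataset = make_digit_patterns(n_per_class=40, pixel_noise=0.1, seed=0)
result = train(preset("desk", "classification", seed=1), dataset=dataset)
print(f"holdout accuracy: {result.final_score:.2f}")
print(f"release entropy:  {result.initial_entropy:.0f} -> {result.final_entropy:.0f} nats")
```

prints

```
holdout accuracy: 0.94
release entropy:  3048 -> 900 nats
```

The accuracy is measured on a held-out quarter of the data using the
deterministic expected-weight network (weights `gain · ρ`).  The entropy
line summarizes what learning does to the synapses themselves: training
starts at the maximum-entropy point ρ = 0.5 everywhere (ln 2 ≈ 0.693 nats
per synapse, ≈ 3061 nats over all 4416 synapses; the first logged value is
taken just after the first update) and commits most release probabilities
toward 0 or 1, so the total Bernoulli entropy falls — the network has
absorbed information about the task.

The same loop drives the spiking network on cart-pole:

```python
result = train(preset("desk", "rl", seed=4))
print(result.final_score)   # 500.0 — the episode cap — on this seed
```

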