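# Methods

## The model

Every synapse is modeled as an independent Bernoulli random variable: on
each trial it transmits (θ = 1) with probability ρ and fails (θ = 0)
otherwise.  A network realization is a full binary release pattern θ; the
weight of a realized connection is `gain · θ` with a fixed per-layer gain,
so the release probabilities are the only learned parameters.  The
objective is the expected reward `J(ρ) = E_{θ~B(ρ)}[R(θ)]`, where `R` is a
black box: an episodic return, a batch classification reward, or a
tabulated bandit payoff.

The gradient of `J` is estimated with the score-function (likelihood-ratio)
identity — no differentiation through the network is ever needed:

    ∇J ≈ (1/N) Σᵢ Rᵢ (θᵢ − ρ) / (ρ(1 − ρ)).

Preconditioning with the inverse Fisher information of the product-Bernoulli
family, `F = diag(1/(ρ(1−ρ)))`, cancels the variance factor and leaves the
natural-gradient plasticity step

    Δρ = (η/N) Σᵢ (θᵢ − ρ) Rᵢ,     ρ ← clip(ρ + Δρ, ε, 1−ε).

The identity between the update and `η F⁻¹∇J` is algebraic and is asserted
exactly (to 1e−12) in the tests.  Clipping keeps every probability inside
`[ε, 1−ε]`; at the bounds a synapse retains a small exploration probability
and the Fisher factor stays finite.

Release samples are drawn once per evaluation unit and held fixed: one
sample per episode in reinforcement learning, one per forward batch in
classification.  This episode-level sampling keeps recurrent dynamics
self-consistent and reduces learning-signal variance.

## Reward shaping

Raw rewards enter the update only after shaping:

- **centered rank** (default): `R′ᵢ = −½ + (1/N)·#{j : Rᵢ > Rⱼ}`, with ties
  sharing a value (strict comparisons).  Values lie in [−½, ½); the update
  becomes invariant to monotone reward rescaling and robust to outliers.
- **zero mean**: subtract the running mean of all previously seen rewards
  (first batch passes through).  Keeps task units, removes the offset.
- **identity**: raw rewards, retained for ablations.

Classification rewards: top-k hit rate (k = 1 by default, i.e. accuracy),
soft recall (mean reciprocal rank of the true class, normalized by the
batch size so a perfect batch scores 1 — every instance contributes exactly
one prediction, making predicted positives equal the batch size), and the
negative mean cross-entropy of max-stabilized softmax scores.  Score ties
are broken toward the smaller class index (stable descending sort),
degenerate but deterministic.

## Architectures

All weight matrices are elementwise nonnegative (Dale-consistent);
inhibition enters only through a sign flip on the activations of the
inhibitory half of each presynaptic population.  Raw inputs are duplicated
so the copy drives the inhibitory half — equivalently, the input is
concatenated with its negation, giving every positive-weight layer a
balanced, zero-sum drive.  No bias terms anywhere.

**Classification** uses a rectifier MLP (balanced input → hidden ReLU
layer, EI-split 50/50 → linear class scores) with per-layer gain
`2/√fan_in`.

**Reinforcement learning** uses a recurrent spiking network: balanced
observation → input layer → one recurrent hidden layer of discrete-time
leaky integrate-and-fire neurons (EI split 50/50) → non-spiking leaky
integrator readout; the action is the argmax of the readout.  The LIF
update is `i ← α·i + input`, `v ← β·v + i`, spike and reset at threshold.

Defaults (all configurable), chosen so that the *bounded* weights — a
connection can never exceed its gain — still let observations drive the
network decisively:

| parameter | default | rationale |
|---|---|---|
| membrane decay β | 0.3 | 1–2-step reaction time; balance control needs fast switching |
| synaptic decay α | 0.1 | short current memory, same reason |
| threshold | 0.6 | units fire when meaningfully driven, activity stays sparse-ish |
| reset | 0 (hard) | soft reset was tried and performed worse here |
| readout decay | 0.5 | smooths single-step spike noise without adding latency |
| input gain scale | 48/√fan_in | normalized observations must cross threshold on their own |
| recurrent gain scale | 0.5/√fan_in | recurrence modulates rather than drowns the sensory drive |
| readout gain scale | 2/√fan_in | scale-free (argmax readout) |

Cart-pole observations are normalized by their characteristic ranges
(track half-width 2.4 m, angle limit 12°, velocities by 3) before entering
the network, so each state variable is expressed in units of "how close to
failure"; with bounded weights the network cannot learn this rescaling
itself.

The **reservoir** variant freezes the recurrent connectivity to a single
Bernoulli(0.5) realization drawn at construction and trains only input and
readout probabilities; at desk scale it matches the full model's cart-pole
return (ratio ≈ 1.0 in the tests).

## Training loop

Each iteration: draw N release-sample sets → collect one reward per set →
shape rewards → one plasticity step per trainable layer.  Logged per
iteration: raw-reward statistics, the transformed-reward checksum, total
Bernoulli entropy per layer, and (at the evaluation interval) a
deterministic evaluation — expected weights `gain·ρ` on fresh episodes or
the held-out split.  Training stops early once the evaluation reaches the
configured target (the cart-pole cap).

All randomness derives from seed sequences keyed by
`(master seed, stream tag, iteration, index)`, so runs are bit-reproducible
and population members are independent of evaluation order.

Two trainer choices matter for population methods at small N:

- **Initialization.**  Release probabilities start at 0.5 by default (the
  maximum-entropy point).  For reinforcement learning the presets use a
  jittered initialization, ρ ~ U(ε, 1−ε) per synapse: the fully symmetric
  start makes all hidden units statistically exchangeable, so per-synapse
  reward covariances vanish at ρ = 0.5 and the first phase of learning is
  spent breaking symmetry by drift.  Jitter removes that stall.
- **Common random numbers.**  All N population members of one iteration
  face the same episode initialization (rotated every iteration).  Return
  differences are then caused only by the release samples, which sharpens
  the centered-rank signal; independent per-member episodes remain
  available (`shared_scenarios=False`) and are the default for the generic
  external-environment path.

For classification, `shared_batch` evaluates every release sample on the
same batch; `per_trial_random` gives each sample a fresh batch drawn
without replacement within an epoch.  Learning rates are tuned per
configuration (the reward transforms put rewards on very different scales):
the desk digit task uses η = 3.0 for centered-rank and identity rewards and
η = 10.0 for zero-mean rewards.

## Synthetic data

The digit generator emulates a small handwritten-digit task: ten fixed 8×8
binary glyphs, each pixel flipped independently with probability
`pixel_noise` (default runs use 0.1, 40 instances per class).  It preserves
the features that matter for sparse-reward classification — 10 classes,
overlapping pixel statistics, controllable difficulty — but not the
within-class style variability, stroke correlations, or 28×28 resolution of
real handwriting; passing tests therefore demonstrate that the rule learns
a nontrivial visual discrimination at desk scale, not that it reaches any
particular accuracy on real digit benchmarks (an IDX reader is provided for
that).  The cluster generator places class centers on a scaled simplex with
isotropic Gaussian noise; separation 0 collapses to chance, large
separation is trivially separable.  Tabulated bandit rewards over K ≤ 12
synapses admit exact enumeration of `J(ρ)` and `∇J`, which serves as the
independent oracle for the Monte-Carlo estimator tests and gives noise-free
evaluation curves for parameter-recovery studies.

## Problem sizes

Two presets ship: `paper` (N = 10,240, hidden 256 for RL; N = 20,000,
hidden 64 for classification) mirrors the reference operating point;
`desk` (N = 512, hidden 64; N = 128, hidden 32, 300 iterations) is the
scale at which every experiment in the test suite runs in seconds to a few
minutes on one CPU.  Population rollouts are vectorized across members and
streamed in memory-bounded chunks.

## Known limitations

- **Desk-scale cart-pole convergence.**  With centered-rank rewards the
  per-synapse update magnitude is bounded by `η·max|R′| ≈ η/2` per
  iteration, and realistically by `η·cov(θ, R′)`, which is far smaller.
  From a cold start the drive to a committed policy (probabilities near
  their bounds) is therefore rate-limited by η.  At η = 0.15 the desk
  configuration (N = 512, hidden 64) reaches the 500-step cap at roughly
  iteration 120–250 depending on seed, so runs capped at 100 iterations
  typically end mid-convergence with mean final evaluation returns in the
  200–400 range (some seeds reach the cap in time).  Moderately larger
  scale clears the budget comfortably: N = 2048 with hidden 128 reaches
  the cap by iteration ~75 under the same learning rate.
- The update treats synapses as independent (diagonal Fisher); correlated
  release is out of scope.
- Only probabilities are learned; weight magnitudes are fixed gains, so
  tasks needing fine-grained weight amplitudes are representable only
  through population averaging.
- The vectorized reinforcement-learning path is specific to the bundled
  cart-pole; external environments run through the (slower) generic
  episode contract.
- Momentum, Adam and weight decay are config hooks only; plain stochastic
  updates are the supported mode.
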