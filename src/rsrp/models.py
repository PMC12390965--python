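"""Network architectures realized from release samples.

Weights here are not free parameters: a connection's weight is
``gain * theta`` where ``theta`` is a binary release bit drawn from the
learned probability matrix.  All weight matrices are elementwise
nonnegative; inhibition enters exclusively through a sign flip applied to
the activations of the inhibitory half of each presynaptic population
(Dale's law).  Two architectures are provided:

* a rectifier MLP for classification, fed through the balanced input
  transform (input concatenated with its negated copy);
* a recurrent spiking network of discrete-time leaky integrate-and-fire
  (LIF) neurons with exponential synapses and a non-spiking leaky
  integrator readout, used for reinforcement learning.  An optional
  reservoir variant freezes the recurrent connectivity to one fixed random
  release realization and trains only input and readout probabilities.

Population-batched helpers (one weight realization per population member)
are the computational core of the trainers; single-sample entry points wrap
them.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from numpy.typing import NDArray

from .core import ReleaseProbMatrix, ReleaseSample, init_release_probs

__all__ = [
    "EILayerSpec",
    "LIFParams",
    "LIFState",
    "RSNNSpec",
    "balanced_input",
    "ei_signs",
    "ei_forward",
    "mlp_forward",
    "lif_step",
    "build_mlp",
    "build_rsnn",
    "rsnn_rollout",
    "RSNNPopulation",
]


def balanced_input(x: np.ndarray) -> np.ndarray:
    """Concatenate ``x`` with its negated copy along the last axis.

    The result always sums to zero, so a downstream positive-weight layer
    receives a balanced drive regardless of the input's mean.  Equivalently:
    duplicating the input and letting the duplicate feed the inhibitory half
    of the next layer realizes the same signal once the inhibitory sign flip
    is applied.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.concatenate([x, -x], axis=-1)


def ei_signs(fan_in: int) -> NDArray[np.float64]:
    """Sign vector (+1 for the excitatory first half, -1 for the inhibitory
    second half) of a presynaptic population of even size ``fan_in``."""
    if fan_in % 2 != 0:
        raise ValueError(f"fan_in must be even for an EI split, got {fan_in}")
    s = np.ones(fan_in)
    s[fan_in // 2 :] = -1.0
    return s


@dataclasses.dataclass(frozen=True)
class EILayerSpec:
    """One positive-weight layer with an excitatory/inhibitory input split.

    ``probs`` holds the release probabilities; the effective weight of a
    realized connection is ``gain * theta``.  The builders set per-layer
    gains of the form ``c / sqrt(fan_in)``, keeping pre-activation variance
    O(1) across widths for a given scale ``c``.
    """

    probs: ReleaseProbMatrix
    gain: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.fan_in % 2 != 0:
            raise ValueError(f"fan_in must be even (EI halves), got {self.fan_in}")

    @property
    def fan_in(self) -> int:
        return self.probs.shape[1]

    @property
    def fan_out(self) -> int:
        return self.probs.shape[0]


def _bits(sample: ReleaseSample | np.ndarray) -> np.ndarray:
    b = sample.bits if isinstance(sample, ReleaseSample) else np.asarray(sample)
    return b.astype(np.float64, copy=False)


def ei_forward(
    layer: EILayerSpec,
    x: np.ndarray,
    sample: ReleaseSample | np.ndarray,
) -> np.ndarray:
    """Pre-activation of an EI layer: ``y = (gain * theta) @ (x * signs)``.

    ``x`` is a nonnegative activation vector (spike counts or rectified
    rates) of the presynaptic population; its second half belongs to the
    inhibitory units, whose contribution enters with a minus sign.  Accepts
    a single vector or a batch with the feature axis last.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != layer.fan_in:
        raise ValueError(f"x has {x.shape[-1]} features, layer expects {layer.fan_in}")
    theta = _bits(sample)
    if theta.shape != layer.probs.shape:
        raise ValueError(
            f"sample shape {theta.shape} != layer shape {layer.probs.shape}"
        )
    w = layer.gain * theta
    return (x * ei_signs(layer.fan_in)) @ w.T


def mlp_forward(
    layers: Sequence[EILayerSpec],
    samples: Sequence[ReleaseSample | np.ndarray],
    x: np.ndarray,
    balanced: bool = True,
) -> np.ndarray:
    """Forward pass of the rectifier MLP; returns linear class scores.

    With ``balanced=True`` (default) the raw features are duplicated so the
    copy drives the first layer's inhibitory half — combined with the EI
    sign flip this is exactly the balanced input transform.  Hidden layers
    are rectified; the last layer is linear.  No biases anywhere.
    """
    if len(layers) != len(samples):
        raise ValueError(f"{len(layers)} layers but {len(samples)} samples")
    a = np.asarray(x, dtype=np.float64)
    if balanced:
        a = np.concatenate([a, a], axis=-1)
    for i, (layer, sample) in enumerate(zip(layers, samples)):
        y = ei_forward(layer, a, sample)
        a = np.maximum(y, 0.0) if i < len(layers) - 1 else y
    return a


@dataclasses.dataclass(frozen=True)
class LIFParams:
    """Discrete-time leaky integrate-and-fire constants.

    mem_decay (beta)
        Membrane leak per step, in (0, 1).  The default 0.3 gives fast
        (1-2 step) responses; control tasks with short reaction horizons
        need the policy to switch actions within a few steps, which long
        membrane memories smear out.
    syn_decay (alpha)
        Exponential synaptic-current decay per step, in (0, 1).
    threshold / reset
        Spike threshold and post-spike membrane value (threshold > reset).
    soft_reset
        Subtract the threshold on spiking instead of jumping to ``reset``;
        preserves residual drive and keeps the rate code closer to linear.
    steps_per_env_step
        LIF integration sub-steps per environment step.
    """

    mem_decay: float = 0.3
    syn_decay: float = 0.1
    threshold: float = 0.6
    reset: float = 0.0
    soft_reset: bool = False
    steps_per_env_step: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.mem_decay < 1.0):
            raise ValueError(f"mem_decay must be in (0,1), got {self.mem_decay}")
        if not (0.0 < self.syn_decay < 1.0):
            raise ValueError(f"syn_decay must be in (0,1), got {self.syn_decay}")
        if self.threshold <= self.reset:
            raise ValueError("threshold must exceed reset")
        if self.steps_per_env_step < 1:
            raise ValueError("steps_per_env_step must be >= 1")


@dataclasses.dataclass(frozen=True)
class LIFState:
    """Membrane potential, synaptic current and last spike vector."""

    v: NDArray[np.float64]
    i_syn: NDArray[np.float64]
    spikes: NDArray[np.float64]

    @staticmethod
    def zeros(shape: int | tuple[int, ...]) -> "LIFState":
        return LIFState(np.zeros(shape), np.zeros(shape), np.zeros(shape))


def lif_step(params: LIFParams, state: LIFState, input_current: np.ndarray) -> LIFState:
    """One LIF update with exponential synapses.

        i_syn <- alpha * i_syn + input
        v     <- beta * v + i_syn
        spike where v >= threshold, then reset those units.

    Broadcasts over leading batch axes; pure (returns a new state).
    """
    i_syn = params.syn_decay * state.i_syn + np.asarray(input_current, dtype=np.float64)
    v = params.mem_decay * state.v + i_syn
    spikes = (v >= params.threshold).astype(np.float64)
    if params.soft_reset:
        v = v - spikes * params.threshold
    else:
        v = np.where(spikes > 0, params.reset, v)
    return LIFState(v, i_syn, spikes)


def build_mlp(
    input_dim: int,
    hidden_dims: Sequence[int],
    output_dim: int,
    clip_eps: float = 1e-3,
    init_value: float = 0.5,
    gain_scale: float = 2.0,
    balanced: bool = True,
) -> list[EILayerSpec]:
    """EI-balanced rectifier MLP specs with constant-initialized probabilities."""
    dims = [2 * input_dim if balanced else input_dim, *hidden_dims, output_dim]
    if not balanced and dims[0] % 2 != 0:
        raise ValueError("unbalanced input dimension must still be even")
    layers = []
    for i in range(len(dims) - 1):
        fan_in, fan_out = dims[i], dims[i + 1]
        probs = init_release_probs((fan_out, fan_in), init_value, clip_eps)
        layers.append(
            EILayerSpec(probs, gain_scale / np.sqrt(fan_in), name=f"layer{i}")
        )
    return layers


@dataclasses.dataclass(frozen=True)
class RSNNSpec:
    """Recurrent spiking network: input -> recurrent LIF hidden -> readout.

    Hidden neurons are split 50/50 into excitatory and inhibitory
    populations.  In reservoir mode the recurrent connectivity is one fixed
    binary release realization (``reservoir_bits``) drawn at construction;
    its probabilities are excluded from the trainable set.
    """

    input_dim: int
    hidden_dim: int
    output_dim: int
    layers: Mapping[str, EILayerSpec]
    lif: LIFParams
    readout_decay: float = 0.8
    reservoir: bool = False
    reservoir_bits: NDArray[np.uint8] | None = None

    def __post_init__(self) -> None:
        if self.hidden_dim % 2 != 0:
            raise ValueError("hidden_dim must be even for the EI split")
        if not (0.0 < self.readout_decay < 1.0):
            raise ValueError("readout_decay must be in (0, 1)")
        if set(self.layers) != {"input", "recurrent", "readout"}:
            raise ValueError("layers must be named input/recurrent/readout")
        if self.reservoir and self.reservoir_bits is None:
            raise ValueError("reservoir mode requires fixed reservoir_bits")

    @property
    def layer_names(self) -> tuple[str, ...]:
        return ("input", "recurrent", "readout")

    @property
    def trainable_names(self) -> tuple[str, ...]:
        if self.reservoir:
            return ("input", "readout")
        return self.layer_names


def build_rsnn(
    input_dim: int,
    output_dim: int,
    hidden_dim: int = 256,
    reservoir: bool = False,
    clip_eps: float = 1e-3,
    init_value: float = 0.5,
    gain_scales: Mapping[str, float] | float = None,
    lif: LIFParams | None = None,
    readout_decay: float = 0.5,
    seed: int = 0,
) -> RSNNSpec:
    """Construct the recurrent spiking network used for reinforcement learning.

    The input layer sees the balanced (doubled) observation, so its fan-in is
    ``2 * input_dim``.  Per-layer gains are ``c / sqrt(fan_in)`` with ``c``
    taken from ``gain_scales`` (a scalar applies to every layer).  The
    defaults put the hidden layer in a strongly stimulus-driven regime — a
    large input gain so normalized observations reliably move neurons
    across threshold, and a moderate recurrent gain so recurrent activity
    modulates rather than drowns the sensory drive.  In reservoir mode the
    recurrent release bits are drawn once (Bernoulli(init_value) under
    ``seed``) and frozen.
    """
    lif = lif or LIFParams()
    if gain_scales is None:
        gain_scales = {"input": 48.0, "recurrent": 0.5, "readout": 2.0}
    elif not isinstance(gain_scales, Mapping):
        gain_scales = {n: float(gain_scales) for n in ("input", "recurrent", "readout")}
    shapes = {
        "input": (hidden_dim, 2 * input_dim),
        "recurrent": (hidden_dim, hidden_dim),
        "readout": (output_dim, hidden_dim),
    }
    layers = {
        name: EILayerSpec(
            init_release_probs(shape, init_value, clip_eps),
            gain_scales[name] / np.sqrt(shape[1]),
            name=name,
        )
        for name, shape in shapes.items()
    }
    bits = None
    if reservoir:
        rng = np.random.default_rng(seed)
        bits = (rng.random(shapes["recurrent"]) < init_value).astype(np.uint8)
        bits.setflags(write=False)
    return RSNNSpec(
        input_dim,
        hidden_dim,
        output_dim,
        layers,
        lif,
        readout_decay,
        reservoir,
        bits,
    )


class RSNNPopulation:
    """Vectorized dynamics of P network realizations stepped in lockstep.

    ``weights[name]`` has shape ``(P, fan_out, fan_in)`` (a leading axis of
    size 1 broadcasts one shared realization over the population).  Used by
    the trainers both for stochastic population evaluation (P = number of
    release samples) and for deterministic evaluation with expected weights
    (P = 1 broadcast over evaluation episodes).
    """

    def __init__(
        self,
        spec: RSNNSpec,
        weights: Mapping[str, np.ndarray],
        batch: int,
        dtype=np.float64,
    ):
        self.spec = spec
        self.w = {k: np.ascontiguousarray(v, dtype=dtype) for k, v in weights.items()}
        self.batch = batch
        h = spec.hidden_dim
        self.signs_h = ei_signs(h).astype(dtype)
        self.state = LIFState.zeros((batch, h))
        self.readout = np.zeros((batch, spec.output_dim), dtype=dtype)

    def select(self, keep: np.ndarray) -> None:
        """Drop population members (boolean mask) whose episodes finished."""
        self.state = LIFState(
            self.state.v[keep], self.state.i_syn[keep], self.state.spikes[keep]
        )
        self.readout = self.readout[keep]
        self.w = {
            k: (v if v.shape[0] == 1 else v[keep]) for k, v in self.w.items()
        }
        self.batch = int(self.readout.shape[0])

    def step(self, obs: np.ndarray) -> np.ndarray:
        """Advance one environment step; returns readout values (batch, out)."""
        x = np.concatenate([obs, -obs], axis=-1)  # balanced observation
        cur_in = np.matmul(self.w["input"], x[..., None])[..., 0]
        for _ in range(self.spec.lif.steps_per_env_step):
            signed = self.state.spikes * self.signs_h
            cur_rec = np.matmul(self.w["recurrent"], signed[..., None])[..., 0]
            self.state = lif_step(self.spec.lif, self.state, cur_in + cur_rec)
        signed = self.state.spikes * self.signs_h
        out = np.matmul(self.w["readout"], signed[..., None])[..., 0]
        self.readout = self.spec.readout_decay * self.readout + out
        return self.readout


def rsnn_rollout(
    spec: RSNNSpec,
    samples: Mapping[str, ReleaseSample | np.ndarray],
    episode_inputs: Sequence[np.ndarray] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Run one episode's input sequence through a single realized network.

    ``samples`` holds one release sample per layer, drawn once for the whole
    episode and reused at every step (episode-level sampling).  Returns the
    readout trace ``(T, output_dim)`` and the greedy action sequence
    ``argmax`` over readout values at each step.
    """
    weights = {}
    for name in spec.layer_names:
        bits = _bits(samples[name])
        if bits.shape != spec.layers[name].probs.shape:
            raise ValueError(f"sample for {name!r} has shape {bits.shape}")
        weights[name] = (spec.layers[name].gain * bits)[None]
    pop = RSNNPopulation(spec, weights, batch=1)
    outs = []
    for obs in np.asarray(episode_inputs, dtype=np.float64):
        outs.append(pop.step(obs[None])[0].copy())
    trace = np.stack(outs) if outs else np.zeros((0, spec.output_dim))
    return trace, trace.argmax(axis=1) if len(trace) else np.zeros(0, dtype=int)
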