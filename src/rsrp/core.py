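"""Bernoulli release model and reward-modulated plasticity rules.

A synapse is modelled as a Bernoulli random variable: with probability
``rho`` it transmits (release bit 1), otherwise it fails (bit 0).  Learning
adjusts ``rho`` by stochastic natural-gradient ascent on the expected reward

    J(rho) = E_{theta ~ B(rho)}[ R(theta) ],

where ``R`` is a scalar reward obtained by running the network with a fixed
release sample ``theta``.  Because the Fisher information of a product of
independent Bernoullis is diagonal, ``diag(1 / (rho (1 - rho)))``, the
natural-gradient update collapses to the remarkably simple rule

    delta_rho = (eta / N) * sum_i (theta_i - rho) * R_i,

followed by clipping into ``[eps, 1 - eps]`` to keep the parameters inside
the open unit interval.  This module implements that rule, the plain
(score-function / likelihood-ratio) gradient estimator it is derived from,
and a sigmoid-parameterized "hedonistic synapse" baseline used for
comparison.

All operations are pure: they return new objects and never mutate their
inputs, so population evaluation and parameter updates stay cleanly
separated in the trainers.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence, Union

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "ReleaseProbMatrix",
    "ReleaseSample",
    "RewardVector",
    "UpdateConfig",
    "HedonisticParams",
    "init_release_probs",
    "sample_release",
    "sample_release_array",
    "rsrp_update",
    "score_function_gradient",
    "fisher_diagonal",
    "bernoulli_entropy",
    "hedonistic_update",
]


def _readonly(a: np.ndarray) -> np.ndarray:
    a = np.array(a, copy=True)
    a.setflags(write=False)
    return a


@dataclasses.dataclass(frozen=True)
class ReleaseProbMatrix:
    """Per-synapse release probabilities ``rho`` for one connection matrix.

    Parameters
    ----------
    values
        Array of shape ``(fan_out, fan_in)``; every entry must lie in
        ``[clip_eps, 1 - clip_eps]``.
    clip_eps
        Clipping threshold ``eps`` in ``(0, 0.5)`` keeping probabilities away
        from the degenerate values 0 and 1 (where the Fisher information
        diverges and exploration stops).
    """

    values: NDArray[np.float64]
    clip_eps: float = 1e-3

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2 or vals.size == 0:
            raise ValueError(
                f"values must be a non-empty 2-D matrix, got shape {vals.shape}"
            )
        if not (0.0 < self.clip_eps < 0.5):
            raise ValueError(f"clip_eps must lie in (0, 0.5), got {self.clip_eps}")
        lo, hi = self.clip_eps, 1.0 - self.clip_eps
        if vals.min() < lo or vals.max() > hi:
            raise ValueError(
                "values out of the admissible range "
                f"[{lo}, {hi}]: min={vals.min()}, max={vals.max()}"
            )
        object.__setattr__(self, "values", _readonly(vals))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def clipped(self, new_values: np.ndarray) -> "ReleaseProbMatrix":
        """Return a copy with ``new_values`` clipped into the admissible range."""
        lo, hi = self.clip_eps, 1.0 - self.clip_eps
        return ReleaseProbMatrix(np.clip(new_values, lo, hi), self.clip_eps)


@dataclasses.dataclass(frozen=True)
class ReleaseSample:
    """One binary release outcome ``theta`` (same shape as its probabilities)."""

    bits: NDArray[np.uint8]

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("release bits must be exactly 0 or 1")
        object.__setattr__(self, "bits", _readonly(bits.astype(np.uint8)))


@dataclasses.dataclass(frozen=True)
class RewardVector:
    """Per-trial rewards: raw task rewards and, optionally, shaped ones."""

    raw: NDArray[np.float64]
    transformed: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        raw = np.atleast_1d(np.asarray(self.raw, dtype=np.float64))
        if raw.ndim != 1 or raw.size < 1:
            raise ValueError("raw rewards must be a non-empty 1-D vector")
        object.__setattr__(self, "raw", _readonly(raw))
        if self.transformed is not None:
            tr = np.asarray(self.transformed, dtype=np.float64)
            if tr.shape != raw.shape:
                raise ValueError(
                    f"transformed length {tr.shape} != raw length {raw.shape}"
                )
            object.__setattr__(self, "transformed", _readonly(tr))

    def __len__(self) -> int:
        return self.raw.size

    @property
    def effective(self) -> NDArray[np.float64]:
        """Rewards the update rule should consume: transformed when present."""
        return self.raw if self.transformed is None else self.transformed


@dataclasses.dataclass(frozen=True)
class UpdateConfig:
    """Hyperparameters of one plasticity update.

    ``learning_rate`` is eta, ``n_samples`` is the population size N, and
    ``clip_eps`` the projection threshold.
    """

    learning_rate: float
    n_samples: int
    clip_eps: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if not (0.0 < self.clip_eps < 0.5):
            raise ValueError(f"clip_eps must lie in (0, 0.5), got {self.clip_eps}")


SampleStack = Union[Sequence[ReleaseSample], np.ndarray]


def _stack_bits(samples: SampleStack, shape: tuple[int, int]) -> np.ndarray:
    """Normalize samples to a float array of shape (N, fan_out, fan_in)."""
    if isinstance(samples, np.ndarray):
        bits = samples
    else:
        bits = np.stack([s.bits for s in samples])
    bits = np.asarray(bits)
    if bits.ndim == 2:
        bits = bits[None]
    if bits.shape[1:] != shape:
        raise ValueError(f"sample shape {bits.shape[1:]} != probability shape {shape}")
    return bits


def init_release_probs(
    shape: tuple[int, int],
    init_value: float = 0.5,
    clip_eps: float = 1e-3,
    jitter: float = 0.0,
    seed: int | None = None,
) -> ReleaseProbMatrix:
    """Construct a release-probability matrix filled with ``init_value``.

    The default 0.5 is the maximum-entropy Bernoulli: the synapse starts
    maximally uncertain and training collapses it toward 0 or 1.  With
    ``jitter > 0`` each entry is perturbed by ``Uniform(-jitter, +jitter)``
    (then clipped into the admissible domain) under ``seed``.
    """
    if len(shape) != 2 or any(int(s) < 1 for s in shape):
        raise ValueError(f"shape must be two positive counts, got {shape}")
    if not (0.0 < init_value < 1.0):
        raise ValueError(f"init_value must lie in (0, 1), got {init_value}")
    if not (clip_eps < init_value < 1.0 - clip_eps):
        raise ValueError(
            f"init_value {init_value} outside the clipped domain "
            f"[{clip_eps}, {1.0 - clip_eps}]"
        )
    vals = np.full(shape, float(init_value))
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.uniform(-jitter, jitter, size=shape)
        vals = np.clip(vals, clip_eps, 1.0 - clip_eps)
    return ReleaseProbMatrix(vals, clip_eps)


def sample_release_array(
    probs: ReleaseProbMatrix,
    n_samples: int,
    rng: np.random.Generator | int,
) -> NDArray[np.uint8]:
    """Draw ``n_samples`` independent release samples as a stacked bit array.

    Returns a ``(n_samples, fan_out, fan_in)`` uint8 array.  This is the
    vectorized workhorse behind :func:`sample_release`; trainers use it
    directly to avoid per-sample object overhead.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    u = rng.random((n_samples, *probs.shape))
    return (u < probs.values).astype(np.uint8)


def sample_release(
    probs: ReleaseProbMatrix, n_samples: int, seed: int
) -> list[ReleaseSample]:
    """Draw independent Bernoulli release samples; seeded and reproducible."""
    bits = sample_release_array(probs, n_samples, np.random.default_rng(seed))
    return [ReleaseSample(b) for b in bits]


def rsrp_update(
    probs: ReleaseProbMatrix,
    samples: SampleStack,
    rewards: RewardVector,
    config: UpdateConfig,
) -> ReleaseProbMatrix:
    """One natural-gradient plasticity step.

        rho' = clip(rho + (eta / N) * sum_i (theta_i - rho) * R_i, eps, 1-eps)

    ``R_i`` is the transformed reward when the vector carries one, otherwise
    the raw reward.  Pure: the input matrix is not modified.
    """
    theta = _stack_bits(samples, probs.shape)
    n = theta.shape[0]
    r = rewards.effective
    if r.size != n:
        raise ValueError(f"{n} samples but {r.size} rewards")
    if n != config.n_samples:
        raise ValueError(f"config.n_samples={config.n_samples} but got {n} samples")
    acc = _weighted_bit_sum(r, theta) - probs.values * r.sum()
    delta = (config.learning_rate / n) * acc
    return probs.clipped(probs.values + delta)


def _weighted_bit_sum(r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """sum_i R_i * theta_i accumulated in double precision, in chunks so
    large integer bit stacks never materialize as one float copy."""
    rows, cols = theta.shape[1], theta.shape[2]
    chunk = max(1, 134_217_728 // (8 * rows * cols))
    acc = np.zeros((rows, cols))
    for start in range(0, theta.shape[0], chunk):
        block = theta[start : start + chunk].astype(np.float64, copy=False)
        acc += np.tensordot(r[start : start + chunk], block, axes=(0, 0))
    return acc


def score_function_gradient(
    probs: ReleaseProbMatrix,
    samples: SampleStack,
    rewards: RewardVector,
) -> NDArray[np.float64]:
    """Monte-Carlo likelihood-ratio estimate of the reward gradient.

        grad_hat = (1/N) sum_i R_i * (theta_i - rho) / (rho (1 - rho))

    This estimator needs no differentiation through the network: the network
    only appears inside the black-box reward ``R_i``.
    """
    theta = _stack_bits(samples, probs.shape)
    n = theta.shape[0]
    r = rewards.effective
    if r.size != n:
        raise ValueError(f"{n} samples but {r.size} rewards")
    acc = _weighted_bit_sum(r, theta) - probs.values * r.sum()
    return acc / (n * probs.values * (1.0 - probs.values))


def fisher_diagonal(probs: ReleaseProbMatrix) -> NDArray[np.float64]:
    """Diagonal of the Fisher information matrix: ``1 / (rho (1 - rho))``.

    Independent synapses make the Fisher matrix diagonal, so the natural
    gradient is an elementwise rescaling of the plain gradient.
    """
    rho = np.asarray(probs.values, dtype=np.float64)
    denom = rho * (1.0 - rho)
    if np.any(denom == 0.0):
        raise ValueError("Fisher information diverges at rho in {0, 1}")
    return 1.0 / denom


def bernoulli_entropy(
    probs: ReleaseProbMatrix,
) -> tuple[float, NDArray[np.float64]]:
    """Shannon entropy (nats) of each synapse and the layer total.

    ``H(rho) = -rho ln rho - (1-rho) ln(1-rho)``; the total over synapses
    quantifies how much uncertainty the layer still carries.  Training that
    commits synapses toward 0 or 1 drives the total down.
    """
    rho = np.asarray(probs.values, dtype=np.float64)
    h = -rho * np.log(rho) - (1.0 - rho) * np.log(1.0 - rho)
    return float(h.sum()), h


@dataclasses.dataclass(frozen=True)
class HedonisticParams:
    """Sigmoid-parameterized release probabilities ``p = sigma(q)``.

    The classic hedonistic synapse adjusts an unconstrained pre-sigmoid
    parameter ``q`` with a plain (non-natural) gradient; the sigmoid keeps
    ``p`` inside (0, 1) without clipping.
    """

    q: NDArray[np.float64]

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=np.float64)
        if q.ndim != 2 or q.size == 0:
            raise ValueError(f"q must be a non-empty 2-D matrix, got shape {q.shape}")
        object.__setattr__(self, "q", _readonly(q))

    @property
    def p(self) -> NDArray[np.float64]:
        """Release probabilities derived from q."""
        from scipy.special import expit

        return expit(self.q)

    @property
    def shape(self) -> tuple[int, int]:
        return self.q.shape  # type: ignore[return-value]


def hedonistic_update(
    params: HedonisticParams,
    samples: SampleStack,
    rewards: RewardVector,
    learning_rate: float,
) -> HedonisticParams:
    """Plain-gradient update of the hedonistic synapse baseline.

        delta_q = (eta / N) * sum_i (theta_i - p) * R_i,   p = sigma(q)

    The eligibility ``theta - p`` is accumulated over release samples (each
    sample one trial); the sigmoid re-derives ``p`` after the step.
    """
    if learning_rate <= 0:
        raise ValueError(f"learning_rate must be > 0, got {learning_rate}")
    theta = _stack_bits(samples, params.shape)
    n = theta.shape[0]
    r = rewards.effective
    if r.size != n:
        raise ValueError(f"{n} samples but {r.size} rewards")
    p = params.p
    acc = _weighted_bit_sum(r, theta) - p * r.sum()
    return HedonisticParams(params.q + (learning_rate / n) * acc)
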