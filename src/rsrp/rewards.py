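"""Reward construction and shaping.

Population-based gradient estimation is notoriously sensitive to the scale
and sign structure of the raw rewards.  This module provides the shaping
transforms applied before the plasticity update — the centered-rank
transform (the default), a running zero-mean baseline, and a pass-through —
plus the three scalar reward signals used for sparse-reward classification
(accuracy, soft recall, negative cross-entropy).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.typing import NDArray
from scipy.special import log_softmax
from scipy.stats import rankdata

from .core import RewardVector

__all__ = [
    "RewardTransformState",
    "centered_rank",
    "zero_mean_transform",
    "identity_transform",
    "apply_transform",
    "accuracy_reward",
    "topk_hit_reward",
    "soft_recall_reward",
    "cross_entropy_reward",
    "TRANSFORMS",
]

TRANSFORMS = ("centered_rank", "zero_mean", "identity")


@dataclasses.dataclass(frozen=True)
class RewardTransformState:
    """Running state of a reward transform.

    Only the ``zero_mean`` transform is stateful: it subtracts the running
    mean of all rewards seen in *previous* batches.  ``centered_rank`` and
    ``identity`` carry the state through unchanged.
    """

    kind: str = "centered_rank"
    history_mean: float = 0.0
    history_count: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORMS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.history_count < 0:
            raise ValueError("history_count must be >= 0")
        if not np.isfinite(self.history_mean):
            raise ValueError("history_mean must be finite")


def _as_reward_vector(rewards: RewardVector | np.ndarray) -> RewardVector:
    if isinstance(rewards, RewardVector):
        return rewards
    return RewardVector(np.asarray(rewards, dtype=np.float64))


def centered_rank(rewards: RewardVector | np.ndarray) -> RewardVector:
    """Replace rewards by their centered ordinal ranks.

        R'_i = -1/2 + (1/N) * #{ j : R_i > R_j }

    Strict comparisons mean tied rewards receive identical transformed
    values (all-tie batches map to a constant -1/2, a neutral signal).  The
    transform depends only on the ordering of the rewards, which makes the
    update invariant to any monotone rescaling of the task's reward units.
    """
    rv = _as_reward_vector(rewards)
    raw = rv.raw
    n = raw.size
    # rankdata(method="min") - 1 counts strictly smaller elements
    dominated = rankdata(raw, method="min") - 1.0
    return RewardVector(raw, dominated / n - 0.5)


def zero_mean_transform(
    rewards: RewardVector | np.ndarray,
    state: RewardTransformState,
) -> tuple[RewardVector, RewardTransformState]:
    """Subtract the running mean of previously seen rewards.

    The first batch passes through unchanged (empty-history baseline 0);
    afterwards the state absorbs the current batch so a constant reward
    stream is driven to zero in the limit.  Returns the shaped rewards and
    the updated state; the input state is not mutated.
    """
    rv = _as_reward_vector(rewards)
    raw = rv.raw
    baseline = state.history_mean if state.history_count > 0 else 0.0
    total = state.history_mean * state.history_count + raw.sum()
    count = state.history_count + raw.size
    new_state = RewardTransformState(state.kind, float(total / count), count)
    return RewardVector(raw, raw - baseline), new_state


def identity_transform(rewards: RewardVector | np.ndarray) -> RewardVector:
    """Pass raw rewards through unchanged (ablation mode)."""
    rv = _as_reward_vector(rewards)
    return RewardVector(rv.raw, rv.raw.copy())


def apply_transform(
    rewards: RewardVector | np.ndarray,
    state: RewardTransformState,
) -> tuple[RewardVector, RewardTransformState]:
    """Dispatch on ``state.kind``; stateless kinds return the state as-is."""
    if state.kind == "centered_rank":
        return centered_rank(rewards), state
    if state.kind == "zero_mean":
        return zero_mean_transform(rewards, state)
    return identity_transform(rewards), state


def accuracy_reward(predicted_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Fraction of matching labels, in [0, 1]."""
    pred = np.asarray(predicted_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"label shape mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(pred == true))


def _true_label_ranks(scores: np.ndarray, true_labels: np.ndarray) -> NDArray[np.int64]:
    """1-based rank of each true label's score in its row, sorted descending.

    Ties are broken toward the smaller class index (stable descending sort):
    the rank is one plus the number of strictly greater scores plus the
    number of equal scores at smaller indices.
    """
    s = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(true_labels)
    if s.ndim != 2 or s.shape[1] < 2:
        raise ValueError(f"scores must be (instances, classes>=2), got {s.shape}")
    if labels.shape != (s.shape[0],):
        raise ValueError(f"labels shape {labels.shape} != ({s.shape[0]},)")
    if labels.min() < 0 or labels.max() >= s.shape[1]:
        raise ValueError("label out of range for the score matrix")
    rows = np.arange(s.shape[0])
    s_true = s[rows, labels]
    greater = (s > s_true[:, None]).sum(axis=1)
    idx = np.arange(s.shape[1])
    equal_before = ((s == s_true[:, None]) & (idx[None, :] < labels[:, None])).sum(axis=1)
    return (1 + greater + equal_before).astype(np.int64)


def soft_recall_reward(scores: np.ndarray, true_labels: np.ndarray) -> float:
    """Mean reciprocal rank of the true class — a smoothed recall.

    Each instance contributes ``1 / rank_i`` where ``rank_i`` is the true
    label's position in the descending ordering of that instance's class
    scores; the sum is normalized by the batch size (every instance emits
    exactly one prediction, so predicted positives equal the batch size).
    The reward lies in (0, 1] and, unlike plain accuracy, still rewards
    near-misses, which smooths the learning signal early in training.
    """
    ranks = _true_label_ranks(scores, true_labels)
    return float(np.mean(1.0 / ranks))


def topk_hit_reward(scores: np.ndarray, true_labels: np.ndarray, k: int = 1) -> float:
    """Fraction of instances whose true label ranks within the top ``k``.

    ``k=1`` is ordinary argmax accuracy computed from raw class scores.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranks = _true_label_ranks(scores, true_labels)
    return float(np.mean(ranks <= k))


def cross_entropy_reward(scores: np.ndarray, true_labels: np.ndarray) -> float:
    """Negative mean categorical cross-entropy of softmax scores.

    Higher is better (it is a reward, bounded above by 0).  The softmax uses
    max-subtraction internally for numerical stability.
    """
    s = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(true_labels)
    _ = _true_label_ranks(s, labels)  # shared shape/range validation
    logp = log_softmax(s, axis=1)
    return float(np.mean(logp[np.arange(s.shape[0]), labels]))
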