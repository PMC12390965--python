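"""Synthetic datasets and tabulated reward functions.

Everything the supervised-learning and gradient-oracle tests need is
generated here programmatically, so no download is required:

* Gaussian cluster classification with a separation dial (simplex centers);
* 8x8 binary digit glyphs with independent pixel-flip noise — a desk-scale
  stand-in for handwritten-digit data that trains in seconds;
* small tabulated reward functions ``R : {0,1}^K -> reals`` whose expected
  reward and exact gradient can be enumerated over all 2^K release
  patterns, serving as the brute-force oracle for the Monte-Carlo
  estimators.

An optional reader for the big-endian IDX image/label format lets real
digit data be plugged in when a file is available.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import struct
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

__all__ = [
    "SyntheticDataset",
    "TabularRewardFunction",
    "make_cluster_classification",
    "make_digit_patterns",
    "make_target_pattern_reward",
    "make_random_table_reward",
    "enumerate_reward_moments",
    "read_idx",
    "read_idx_images",
    "read_idx_labels",
    "DIGIT_GLYPHS",
]

MAX_TABLE_SYNAPSES = 12


@dataclasses.dataclass(frozen=True)
class SyntheticDataset:
    """Feature matrix (n, d), integer labels (n,) in [0, C), and provenance."""

    features: NDArray[np.float64]
    labels: NDArray[np.int64]
    metadata: dict

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=np.float64)
        y = np.asarray(self.labels, dtype=np.int64)
        if f.ndim != 2 or y.shape != (f.shape[0],):
            raise ValueError(f"inconsistent shapes: {f.shape} vs {y.shape}")
        if not np.isfinite(f).all():
            raise ValueError("features must be finite")
        if np.unique(y).size < 1 or y.min() < 0:
            raise ValueError("labels must be nonnegative integers")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "labels", y)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:
        return self.features.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Write a headered CSV (feature columns f0..fD-1 plus ``label``)."""
        df = pd.DataFrame(
            self.features, columns=[f"f{i}" for i in range(self.n_features)]
        )
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SyntheticDataset":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=np.int64)
        return cls(df.to_numpy(dtype=np.float64), labels, {"source": str(path)})


def make_cluster_classification(
    n_classes: int,
    dim: int,
    n_per_class: int,
    separation: float,
    noise_sd: float,
    seed: int,
    nonnegative: bool = False,
) -> SyntheticDataset:
    """Gaussian clusters around simplex vertices scaled by ``separation``.

    Class ``c``'s center is ``separation * (e_c - 1/C)`` (a regular simplex
    centered at the origin; requires ``dim >= n_classes``).  Instances are
    center plus isotropic Gaussian noise.  ``separation = 0`` collapses all
    classes onto one distribution (chance-level Bayes accuracy);
    ``separation >> noise_sd`` is trivially separable.  ``nonnegative``
    shifts features into the nonnegative orthant for spike-like inputs.
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    if separation < 0:
        raise ValueError(f"separation must be >= 0, got {separation}")
    if dim < n_classes:
        raise ValueError(f"dim ({dim}) must be >= n_classes ({n_classes})")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_classes, dim))
    centers[np.arange(n_classes), np.arange(n_classes)] = 1.0
    centers -= 1.0 / n_classes
    centers *= separation
    labels = np.repeat(np.arange(n_classes), n_per_class)
    feats = centers[labels] + rng.normal(0.0, noise_sd, size=(labels.size, dim))
    if nonnegative:
        feats = feats - feats.min()
    perm = rng.permutation(labels.size)
    meta = {
        "generator": "cluster",
        "n_classes": n_classes,
        "dim": dim,
        "n_per_class": n_per_class,
        "separation": separation,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return SyntheticDataset(feats[perm], labels[perm], meta)


# 8x8 glyphs for the ten digits; '#' = on pixel.
_GLYPH_ROWS = {
    0: ("..####..", ".##..##.", ".##..##.", ".##..##.",
        ".##..##.", ".##..##.", "..####..", "........"),
    1: ("...##...", "..###...", "...##...", "...##...",
        "...##...", "...##...", "..####..", "........"),
    2: ("..####..", ".##..##.", ".....##.", "....##..",
        "...##...", "..##....", ".######.", "........"),
    3: ("..####..", ".##..##.", ".....##.", "...###..",
        ".....##.", ".##..##.", "..####..", "........"),
    4: ("....##..", "...###..", "..#.##..", ".#..##..",
        ".######.", "....##..", "....##..", "........"),
    5: (".######.", ".##.....", ".#####..", ".....##.",
        ".....##.", ".##..##.", "..####..", "........"),
    6: ("..####..", ".##.....", ".#####..", ".##..##.",
        ".##..##.", ".##..##.", "..####..", "........"),
    7: (".######.", ".....##.", "....##..", "...##...",
        "..##....", "..##....", "..##....", "........"),
    8: ("..####..", ".##..##.", ".##..##.", "..####..",
        ".##..##.", ".##..##.", "..####..", "........"),
    9: ("..####..", ".##..##.", ".##..##.", "..#####.",
        ".....##.", ".....##.", "..####..", "........"),
}

DIGIT_GLYPHS: NDArray[np.float64] = np.stack(
    [
        np.array(
            [[1.0 if ch == "#" else 0.0 for ch in row] for row in _GLYPH_ROWS[d]]
        ).ravel()
        for d in range(10)
    ]
)
DIGIT_GLYPHS.setflags(write=False)


def make_digit_patterns(
    n_per_class: int,
    pixel_noise: float,
    seed: int,
) -> SyntheticDataset:
    """Noise-corrupted 8x8 binary digit glyphs, labels 0-9.

    Each of the 64 pixels is flipped independently with probability
    ``pixel_noise`` (< 0.5; at 0.5 the image carries no label information).
    """
    if not (0.0 <= pixel_noise < 0.5):
        raise ValueError(f"pixel_noise must be in [0, 0.5), got {pixel_noise}")
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(10), n_per_class)
    feats = DIGIT_GLYPHS[labels].copy()
    flips = rng.random(feats.shape) < pixel_noise
    feats = np.abs(feats - flips.astype(np.float64))
    perm = rng.permutation(labels.size)
    meta = {
        "generator": "digit_patterns",
        "n_per_class": n_per_class,
        "pixel_noise": pixel_noise,
        "seed": seed,
    }
    return SyntheticDataset(feats[perm], labels[perm], meta)


@dataclasses.dataclass(frozen=True)
class TabularRewardFunction:
    """A reward function on K synapses given by its full table of 2^K values."""

    n_synapses: int
    table: NDArray[np.float64]

    def __post_init__(self) -> None:
        if self.n_synapses < 1 or self.n_synapses > MAX_TABLE_SYNAPSES:
            raise ValueError(
                f"n_synapses must be in [1, {MAX_TABLE_SYNAPSES}], got {self.n_synapses}"
            )
        t = np.asarray(self.table, dtype=np.float64)
        if t.shape != (2**self.n_synapses,):
            raise ValueError(
                f"table must have length {2 ** self.n_synapses}, got {t.shape}"
            )
        object.__setattr__(self, "table", t)

    def evaluate(self, bits: np.ndarray) -> np.ndarray:
        """Reward of release pattern(s); ``bits`` has the synapse axis last."""
        b = np.asarray(bits)
        if b.shape[-1] != self.n_synapses:
            raise ValueError(
                f"patterns have {b.shape[-1]} bits, expected {self.n_synapses}"
            )
        idx = b.astype(np.int64) @ (1 << np.arange(self.n_synapses, dtype=np.int64))
        return self.table[idx]


def make_target_pattern_reward(
    n_synapses: int, target: np.ndarray, seed: int = 0
) -> TabularRewardFunction:
    """Bandit reward ``R(theta) = 1 - Hamming(theta, target) / K``.

    Maximized (R = 1) exactly at the target pattern, 0 at its complement;
    every synapse contributes independently, making the optimum trivially
    known for parameter-recovery tests.  ``seed`` is accepted for interface
    uniformity with the stochastic generators; the table is deterministic.
    """
    target = np.asarray(target).astype(np.int64)
    if target.shape != (n_synapses,) or not np.isin(target, (0, 1)).all():
        raise ValueError(f"target must be {n_synapses} bits")
    patterns = _all_patterns(n_synapses)
    hamming = np.abs(patterns - target).sum(axis=1)
    return TabularRewardFunction(n_synapses, 1.0 - hamming / n_synapses)


def make_random_table_reward(n_synapses: int, seed: int) -> TabularRewardFunction:
    """Uniform(-1, 1) rewards for every release pattern (oracle test fodder)."""
    rng = np.random.default_rng(seed)
    return TabularRewardFunction(n_synapses, rng.uniform(-1.0, 1.0, 2**n_synapses))


def _all_patterns(k: int) -> np.ndarray:
    """All 2^k bit patterns, row ``i`` holding the bits of integer ``i``
    (least-significant bit first, matching ``TabularRewardFunction.evaluate``)."""
    ints = np.arange(2**k, dtype=np.int64)
    return (ints[:, None] >> np.arange(k)) & 1


def enumerate_reward_moments(
    rho: np.ndarray, reward: TabularRewardFunction
) -> tuple[float, np.ndarray]:
    """Exact expected reward J(rho) and its gradient by full enumeration.

        J(rho)    = sum_theta P(theta | rho) R(theta)
        dJ/drho_k = sum_theta P(theta | rho) R(theta)
                    (theta_k - rho_k) / (rho_k (1 - rho_k))

    Feasible for K <= 12; this is the independent oracle the Monte-Carlo
    score-function estimator is tested against.
    """
    rho = np.asarray(rho, dtype=np.float64).ravel()
    k = rho.size
    if k != reward.n_synapses:
        raise ValueError(f"rho has {k} entries, reward expects {reward.n_synapses}")
    if np.any(rho <= 0) or np.any(rho >= 1):
        raise ValueError("rho entries must lie strictly inside (0, 1)")
    patterns = _all_patterns(k)
    probs = np.where(patterns == 1, rho, 1.0 - rho).prod(axis=1)
    r = reward.evaluate(patterns)
    j = float(probs @ r)
    score = (patterns - rho) / (rho * (1.0 - rho))
    grad = (probs * r) @ score
    return j, grad


def read_idx(path: str | Path) -> np.ndarray:
    """Read one array in the big-endian IDX format (magic 0x00 0x00 type dims)."""
    data = Path(path).read_bytes()
    if len(data) < 4 or data[0] != 0 or data[1] != 0:
        raise ValueError(f"{path}: not an IDX file")
    type_code, ndim = data[2], data[3]
    dtypes = {
        0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2",
        0x0C: ">i4", 0x0D: ">f4", 0x0E: ">f8",
    }
    if type_code not in dtypes:
        raise ValueError(f"{path}: unsupported IDX type code {type_code:#x}")
    dims = struct.unpack(f">{ndim}I", data[4 : 4 + 4 * ndim])
    arr = np.frombuffer(data, dtype=dtypes[type_code], offset=4 + 4 * ndim)
    return arr.reshape(dims).astype(arr.dtype.newbyteorder("="))


def read_idx_images(path: str | Path) -> np.ndarray:
    """Images file (magic 2051): returns (n, rows*cols) floats scaled to [0, 1]."""
    arr = read_idx(path)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image array, got {arr.ndim}-D")
    return arr.reshape(arr.shape[0], -1).astype(np.float64) / 255.0


def read_idx_labels(path: str | Path) -> np.ndarray:
    """Labels file (magic 2049): returns (n,) int64 labels."""
    arr = read_idx(path)
    if arr.ndim != 1:
        raise ValueError(f"{path}: expected a 1-D label array, got {arr.ndim}-D")
    return arr.astype(np.int64)
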