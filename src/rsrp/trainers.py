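"""Training loops: population evaluation followed by plasticity optimization.

Each training iteration has two stages.  In the interaction stage, N
release-sample sets are drawn from the current probabilities (each set held
fixed for one whole evaluation — a full episode in reinforcement learning,
one batch of stimuli in classification) and a scalar reward is collected
per sample.  In the optimization stage the rewards are shaped (centered
rank by default) and every trainable layer takes one natural-gradient step.

Three tasks share this loop:

* ``rl`` — the bundled cart-pole task driven by the recurrent spiking
  network, with the whole population of realized networks stepped in
  lockstep through vectorized physics;
* ``classification`` — sparse-reward training of the EI-balanced MLP on a
  labeled dataset;
* ``bandit`` — a tabulated reward over a small set of synapses, used for
  parameter-recovery studies (its exact expected reward is computable by
  enumeration, so evaluation is noise-free).

Reported learning curves use a deterministic evaluation pass with expected
weights ``gain * rho`` (in reservoir mode the frozen recurrent realization
is kept as-is), separate from the stochastic training rollouts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ReleaseProbMatrix,
    RewardVector,
    UpdateConfig,
    bernoulli_entropy,
    init_release_probs,
    sample_release_array,
)
from .environments import MAX_STEPS, THETA_LIMIT, CartPoleVector, RESET_RANGE
from .models import (
    LIFParams,
    RSNNPopulation,
    RSNNSpec,
    build_mlp,
    build_rsnn,
    ei_signs,
)
from .rewards import (
    RewardTransformState,
    TRANSFORMS,
    apply_transform,
    cross_entropy_reward,
    soft_recall_reward,
    topk_hit_reward,
)
from .synthetic_data import (
    SyntheticDataset,
    TabularRewardFunction,
    enumerate_reward_moments,
)

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "TrainResult",
    "preset",
    "train",
    "evaluate_population_rl",
    "evaluate_population_classification",
    "evaluate_rl_deterministic",
    "sampling_size_sweep",
    "save_checkpoint",
    "load_checkpoint",
]

# Seed-stream tags: every random draw comes from a SeedSequence keyed by
# (master seed, tag, iteration, index), so population batches are
# reproducible and independent of evaluation order.
_TAG_THETA = 1
_TAG_ENV = 2
_TAG_EVAL = 3
_TAG_DATA = 4
_TAG_SPLIT = 5

TASKS = ("rl", "classification", "bandit")
REWARD_KINDS = ("soft_recall", "accuracy", "cross_entropy")
SAMPLING_MODES = ("shared_batch", "per_trial_random")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Everything one training run needs.

    The reinforcement-learning defaults mirror the reference operating
    point (learning rate 0.15, clip 0.001, centered-rank shaping); sample
    count and network width are set by preset: ``paper`` uses N = 10,240
    and 256 hidden units, ``desk`` N = 512 and 64 hidden units so a full
    run finishes in minutes on one CPU.
    """

    task: str = "rl"
    n_samples: int = 512
    learning_rate: float = 0.15
    clip_eps: float = 1e-3
    iterations: int = 100
    reward_transform: str = "centered_rank"
    seed: int = 0
    eval_interval: int = 1
    n_eval_seeds: int = 8
    early_stop_score: float | None = None
    init_value: float = 0.5
    init_jitter: float = 0.0
    # reinforcement learning
    hidden_dim: int = 64
    reservoir: bool = False
    gain_scale: float = 2.0
    gain_scales: tuple[float, float, float] = (48.0, 0.5, 2.0)
    lif: LIFParams = LIFParams()
    readout_decay: float = 0.5
    obs_scale: tuple[float, ...] | None = (
        1.0 / 2.4, 1.0 / 3.0, 1.0 / THETA_LIMIT, 1.0 / 3.0,
    )
    shared_scenarios: bool = True
    max_steps: int = MAX_STEPS
    # classification
    data_batch_size: int = 64
    data_sampling: str = "shared_batch"
    reward_kind: str = "soft_recall"
    topk: int = 1
    mlp_hidden: tuple[int, ...] = (32,)
    balanced_input: bool = True
    holdout_frac: float = 0.25
    # optimizer hooks (plain stochastic updates are the supported mode)
    momentum: float = 0.0
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.reward_transform not in TRANSFORMS:
            raise ValueError(f"unknown reward_transform {self.reward_transform!r}")
        if self.reward_kind not in REWARD_KINDS:
            raise ValueError(f"unknown reward_kind {self.reward_kind!r}")
        if self.data_sampling not in SAMPLING_MODES:
            raise ValueError(f"unknown data_sampling {self.data_sampling!r}")
        for field in ("n_samples", "iterations", "eval_interval", "n_eval_seeds",
                      "data_batch_size", "max_steps", "topk"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be a positive count")
        if self.momentum != 0.0 or self.weight_decay != 0.0:
            raise NotImplementedError(
                "momentum/weight_decay are config hooks; plain updates only"
            )
        # delegate range checks for the core hyperparameters
        UpdateConfig(self.learning_rate, self.n_samples, self.clip_eps, self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mlp_hidden"] = list(self.mlp_hidden)
        d["gain_scales"] = list(self.gain_scales)
        d["obs_scale"] = None if self.obs_scale is None else list(self.obs_scale)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def preset(name: str, task: str = "rl", **overrides) -> TrainConfig:
    """Named configurations: ``paper`` (full scale) and ``desk`` (minutes-scale)."""
    presets = {
        ("paper", "rl"): dict(
            task="rl", n_samples=10240, hidden_dim=256, iterations=100,
            learning_rate=0.15, eval_interval=5, init_jitter=0.499,
        ),
        ("desk", "rl"): dict(
            task="rl", n_samples=512, hidden_dim=64, iterations=100,
            learning_rate=0.15, eval_interval=1, n_eval_seeds=8,
            early_stop_score=500.0, init_jitter=0.499,
        ),
        ("paper", "classification"): dict(
            task="classification", n_samples=20000, data_batch_size=64,
            iterations=3000, mlp_hidden=(64,), learning_rate=0.15,
            eval_interval=50,
        ),
        ("desk", "classification"): dict(
            task="classification", n_samples=128, data_batch_size=16,
            iterations=300, mlp_hidden=(32,), learning_rate=3.0,
            eval_interval=25,
        ),
    }
    key = (name, task)
    if key not in presets:
        raise ValueError(f"no preset {name!r} for task {task!r}")
    return TrainConfig(**{**presets[key], **overrides})


class TrainingLog:
    """One record per iteration: reward statistics, evaluation score,
    per-layer release entropy, and a wall-clock stamp."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def append(self, **record) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")

    def column(self, key: str) -> np.ndarray:
        return np.array([rec[key] for rec in self.records])


@dataclasses.dataclass
class TrainResult:
    """Final probabilities, the per-iteration log, and run metadata."""

    config: TrainConfig
    log: TrainingLog
    probs: dict[str, ReleaseProbMatrix]
    spec: object = None

    @property
    def final_score(self) -> float:
        for rec in reversed(self.log.records):
            if rec.get("eval_score") is not None:
                return float(rec["eval_score"])
        raise ValueError("no evaluation was recorded")

    @property
    def initial_entropy(self) -> float:
        return float(self.log.records[0]["entropy_total"])

    @property
    def final_entropy(self) -> float:
        return float(self.log.records[-1]["entropy_total"])


def _seed_rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(key))


def _check_finite(rewards: np.ndarray, context: str) -> None:
    if not np.isfinite(rewards).all():
        bad = np.flatnonzero(~np.isfinite(rewards))
        raise RuntimeError(
            f"non-finite rewards in {context}: samples {bad[:5].tolist()} "
            f"(and {max(0, bad.size - 5)} more)"
        )


# ---------------------------------------------------------------------------
# reinforcement learning
# ---------------------------------------------------------------------------


def _sample_layer_thetas(
    spec: RSNNSpec,
    probs: Mapping[str, ReleaseProbMatrix],
    n: int,
    seed: int,
    iteration: int,
) -> dict[str, np.ndarray]:
    """One release-sample set per layer per population member.

    In reservoir mode the recurrent layer keeps its single frozen
    realization (broadcast over the population) instead of being resampled.
    """
    thetas: dict[str, np.ndarray] = {}
    for li, name in enumerate(spec.layer_names):
        if spec.reservoir and name == "recurrent":
            thetas[name] = np.asarray(spec.reservoir_bits)[None]
        else:
            rng = _seed_rng(seed, _TAG_THETA, iteration, li)
            thetas[name] = sample_release_array(probs[name], n, rng)
    return thetas


def _thetas_to_weights(
    spec: RSNNSpec, thetas: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    return {
        name: spec.layers[name].gain * thetas[name].astype(np.float64)
        for name in spec.layer_names
    }


def _rollout_cartpole_population(
    spec: RSNNSpec,
    weights: Mapping[str, np.ndarray],
    init_states: np.ndarray,
    max_steps: int,
    obs_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Step N realized networks through N independent episodes in lockstep.

    ``obs_scale`` rescales each observation component (typically by the
    reciprocal of its characteristic range) before it reaches the network.
    Finished episodes are compacted out of the batch once they make up a
    sizable fraction, so late iterations (when a few stragglers survive
    long) do not pay for the whole population.
    """
    n = init_states.shape[0]
    env = CartPoleVector(init_states)
    pop = RSNNPopulation(spec, weights, n)
    returns = np.zeros(n)
    idx = np.arange(n)
    finished = np.zeros(n, dtype=bool)
    for _ in range(max_steps):
        obs = env.observations
        if obs_scale is not None:
            obs = obs * obs_scale
        readout = pop.step(obs)
        actions = readout.argmax(axis=1)
        done_now = env.step(actions)
        live = ~finished
        returns[idx[live]] += 1.0
        finished |= done_now  # sticky: a fallen pole stays fallen
        n_live = int((~finished).sum())
        if n_live == 0:
            break
        if n_live < 0.7 * finished.size:
            keep = ~finished
            idx = idx[keep]
            env.select(keep)
            pop.select(keep)
            finished = np.zeros(n_live, dtype=bool)
    return returns


def _initial_states(
    seed: int, tag: int, iteration: int, n: int, shared: bool = False
) -> np.ndarray:
    """Episode initializations for one population batch.

    With ``shared=True`` the whole population faces a single scenario drawn
    fresh each iteration (common random numbers): return differences are
    then caused only by the release samples, which sharpens the rank
    signal.  Otherwise each member gets its own independent initialization.
    """
    count = 1 if shared else n
    children = np.random.SeedSequence((seed, tag, iteration)).spawn(count)
    states = np.stack(
        [
            np.random.default_rng(c).uniform(-RESET_RANGE, RESET_RANGE, 4)
            for c in children
        ]
    )
    if shared:
        states = np.repeat(states, n, axis=0)
    return states


def _obs_scale(config: TrainConfig) -> np.ndarray | None:
    return None if config.obs_scale is None else np.asarray(config.obs_scale)


def evaluate_population_rl(
    spec: RSNNSpec,
    probs: Mapping[str, ReleaseProbMatrix],
    env_factory: Callable[[], object] | None,
    config: TrainConfig,
    iteration: int = 0,
) -> tuple[dict[str, np.ndarray], RewardVector]:
    """Draw N release-sample sets and collect one episodic return each.

    With ``env_factory=None`` the bundled cart-pole is rolled out with the
    vectorized population path; otherwise each sample runs its own
    environment instance through the generic reset/step contract (episode
    seeds are derived per sample either way, so results do not depend on
    evaluation order).
    """
    n = config.n_samples
    thetas = _sample_layer_thetas(spec, probs, n, config.seed, iteration)
    if env_factory is None:
        init = _initial_states(
            config.seed, _TAG_ENV, iteration, n, shared=config.shared_scenarios
        )
        # stream the population through in chunks so the float weight
        # stacks stay bounded at large N and hidden sizes
        chunk = max(1, 2048 * 64 * 64 // max(1, spec.hidden_dim**2))
        returns = np.empty(n)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            weights = {
                name: spec.layers[name].gain
                * thetas[name][sl if thetas[name].shape[0] > 1 else slice(0, 1)]
                .astype(np.float64)
                for name in spec.layer_names
            }
            returns[sl] = _rollout_cartpole_population(
                spec, weights, init[sl], config.max_steps, _obs_scale(config)
            )
    else:
        returns = np.zeros(n)
        seeds = np.random.SeedSequence((config.seed, _TAG_ENV, iteration)).spawn(n)
        scale = _obs_scale(config)
        for i in range(n):
            w_i = {
                name: (spec.layers[name].gain
                       * thetas[name][i if thetas[name].shape[0] > 1 else 0]
                       .astype(np.float64))[None]
                for name in spec.layer_names
            }
            try:
                env = env_factory()
                obs = env.reset(np.random.default_rng(seeds[i]))
                single = RSNNPopulation(spec, w_i, 1)
                total = 0.0
                for _ in range(config.max_steps):
                    o = np.asarray(obs, dtype=np.float64)
                    if scale is not None:
                        o = o * scale
                    action = int(single.step(o[None]).argmax())
                    obs, reward, done, _ = env.step(action)
                    total += reward
                    if done:
                        break
                returns[i] = total
            except Exception as exc:  # surface which population member failed
                raise RuntimeError(f"environment failure at sample {i}") from exc
    _check_finite(returns, f"population evaluation (iteration {iteration})")
    return thetas, RewardVector(returns)


def evaluate_rl_deterministic(
    spec: RSNNSpec,
    probs: Mapping[str, ReleaseProbMatrix],
    n_eval_seeds: int,
    seed: int,
    iteration: int = 0,
    max_steps: int = MAX_STEPS,
    obs_scale: np.ndarray | None = None,
    sample_seed: int | None = None,
) -> float:
    """Mean return of the expected-weight network over fresh episodes.

    Trainable layers use analog weights ``gain * rho``; a frozen reservoir
    keeps its fixed binary realization.  The policy is deterministic, so
    the only randomness is the episode initialization.  With
    ``sample_seed`` the evaluation instead realizes one binary release
    sample per layer (sampled-weight evaluation); as probabilities commit
    toward 0 or 1 the two modes converge.
    """
    weights = {}
    sample_rng = (
        np.random.default_rng(sample_seed) if sample_seed is not None else None
    )
    for name in spec.layer_names:
        if spec.reservoir and name == "recurrent":
            w = spec.layers[name].gain * np.asarray(
                spec.reservoir_bits, dtype=np.float64
            )
        elif sample_rng is not None:
            bits = sample_release_array(probs[name], 1, sample_rng)[0]
            w = spec.layers[name].gain * bits.astype(np.float64)
        else:
            w = spec.layers[name].gain * probs[name].values
        weights[name] = w[None]
    init = _initial_states(seed, _TAG_EVAL, iteration, n_eval_seeds)
    returns = _rollout_cartpole_population(spec, weights, init, max_steps, obs_scale)
    return float(returns.mean())


def _train_rl(config: TrainConfig) -> TrainResult:
    spec = build_rsnn(
        input_dim=4,
        output_dim=2,
        hidden_dim=config.hidden_dim,
        reservoir=config.reservoir,
        clip_eps=config.clip_eps,
        init_value=config.init_value,
        gain_scales=dict(
            zip(("input", "recurrent", "readout"), config.gain_scales)
        ),
        lif=config.lif,
        readout_decay=config.readout_decay,
        seed=config.seed,
    )
    probs = {}
    for li, name in enumerate(spec.layer_names):
        probs[name] = init_release_probs(
            spec.layers[name].probs.shape,
            config.init_value,
            config.clip_eps,
            jitter=config.init_jitter,
            seed=int(np.random.SeedSequence((config.seed, 7, li)).generate_state(1)[0]),
        )
    return _run_loop(
        config,
        probs,
        trainable=spec.trainable_names,
        evaluate_fn=lambda it: evaluate_population_rl(spec, probs, None, config, it),
        score_fn=lambda it: evaluate_rl_deterministic(
            spec, probs, config.n_eval_seeds, config.seed, it,
            config.max_steps, _obs_scale(config),
        ),
        spec=spec,
        probs_ref=probs,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


_REWARD_FNS = {
    "soft_recall": lambda s, y, cfg: soft_recall_reward(s, y),
    "accuracy": lambda s, y, cfg: topk_hit_reward(s, y, cfg.topk),
    "cross_entropy": lambda s, y, cfg: cross_entropy_reward(s, y),
}


class _EpochStream:
    """Without-replacement index stream: reshuffles when an epoch runs out."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self.queue = rng.permutation(n)
        self.pos = 0

    def draw(self, count: int) -> np.ndarray:
        out = np.empty(count, dtype=np.int64)
        filled = 0
        while filled < count:
            take = min(count - filled, self.n - self.pos)
            out[filled : filled + take] = self.queue[self.pos : self.pos + take]
            self.pos += take
            filled += take
            if self.pos == self.n:
                self.queue = self.rng.permutation(self.n)
                self.pos = 0
        return out


class _MLPTask:
    """Vectorized population evaluation of the EI MLP on a dataset.

    Holds the train/holdout split, the sign-expanded inputs, and the layer
    gains; all N realized networks score their batch with two stacked
    matrix products per layer.
    """

    def __init__(self, config: TrainConfig, dataset: SyntheticDataset):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.config = config
        self.n_classes = dataset.n_classes
        self.layers = build_mlp(
            dataset.n_features,
            config.mlp_hidden,
            self.n_classes,
            clip_eps=config.clip_eps,
            init_value=config.init_value,
            gain_scale=config.gain_scale,
            balanced=config.balanced_input,
        )
        if len(self.layers) != 2:
            raise NotImplementedError(
                "the vectorized classification path supports one hidden layer"
            )
        x = dataset.features
        if config.balanced_input:
            x = np.concatenate([x, x], axis=1)
        # fold the EI sign flip of the input population into the data once
        x = x * ei_signs(self.layers[0].fan_in)
        y = dataset.labels
        rng = _seed_rng(config.seed, _TAG_SPLIT)
        perm = rng.permutation(len(dataset))
        n_hold = max(1, int(round(config.holdout_frac * len(dataset))))
        hold, tr = perm[:n_hold], perm[n_hold:]
        if tr.size == 0:
            raise ValueError("holdout fraction leaves no training data")
        self.x_train, self.y_train = x[tr], y[tr]
        self.x_hold, self.y_hold = x[hold], y[hold]
        self.signs_h = ei_signs(self.layers[1].fan_in)
        self.stream = _EpochStream(tr.size, _seed_rng(config.seed, _TAG_DATA))

    def probs(self) -> dict[str, ReleaseProbMatrix]:
        return {layer.name: layer.probs for layer in self.layers}

    def _forward(self, w1: np.ndarray, w2: np.ndarray, xb: np.ndarray) -> np.ndarray:
        """Scores for stacked weights; xb is (..., batch, features)."""
        h = np.matmul(w1, np.swapaxes(xb, -1, -2))
        np.maximum(h, 0.0, out=h)
        h *= self.signs_h[:, None]
        return np.matmul(w2, h)  # (..., classes, batch)

    def evaluate_population(
        self,
        probs: Mapping[str, ReleaseProbMatrix],
        iteration: int,
    ) -> tuple[dict[str, np.ndarray], RewardVector]:
        cfg = self.config
        n, ds = cfg.n_samples, cfg.data_batch_size
        ds = min(ds, self.y_train.size)
        thetas = {
            layer.name: sample_release_array(
                probs[layer.name], n, _seed_rng(cfg.seed, _TAG_THETA, iteration, li)
            )
            for li, layer in enumerate(self.layers)
        }
        w1 = self.layers[0].gain * thetas[self.layers[0].name].astype(np.float64)
        w2 = self.layers[1].gain * thetas[self.layers[1].name].astype(np.float64)
        reward_fn = _REWARD_FNS[cfg.reward_kind]
        if cfg.data_sampling == "shared_batch":
            idx = self.stream.draw(ds)
            scores = self._forward(w1, w2, self.x_train[idx])  # (n, C, ds)
            yb = self.y_train[idx]
            rewards = np.array(
                [reward_fn(scores[i].T, yb, cfg) for i in range(n)]
            )
        else:  # per_trial_random: a fresh batch for every release sample
            idx = self.stream.draw(n * ds).reshape(n, ds)
            scores = self._forward(w1, w2, self.x_train[idx])  # (n, C, ds)
            rewards = np.array(
                [
                    reward_fn(scores[i].T, self.y_train[idx[i]], cfg)
                    for i in range(n)
                ]
            )
        _check_finite(rewards, f"classification rewards (iteration {iteration})")
        return thetas, RewardVector(rewards)

    def holdout_accuracy(self, probs: Mapping[str, ReleaseProbMatrix]) -> float:
        w1 = self.layers[0].gain * probs[self.layers[0].name].values
        w2 = self.layers[1].gain * probs[self.layers[1].name].values
        scores = self._forward(w1, w2, self.x_hold)  # (C, n_hold)
        return float(np.mean(scores.argmax(axis=0) == self.y_hold))


def evaluate_population_classification(
    config: TrainConfig,
    probs: Mapping[str, ReleaseProbMatrix] | None,
    dataset: SyntheticDataset,
    iteration: int = 0,
) -> tuple[dict[str, np.ndarray], RewardVector]:
    """Standalone population evaluation on a dataset (fresh task state)."""
    task = _MLPTask(config, dataset)
    return task.evaluate_population(probs or task.probs(), iteration)


def _train_classification(config: TrainConfig, dataset: SyntheticDataset) -> TrainResult:
    task = _MLPTask(config, dataset)
    probs = task.probs()
    return _run_loop(
        config,
        probs,
        trainable=tuple(probs),
        evaluate_fn=lambda it: task.evaluate_population(probs, it),
        score_fn=lambda it: task.holdout_accuracy(probs),
        spec=task.layers,
        probs_ref=probs,
    )


# ---------------------------------------------------------------------------
# bandit
# ---------------------------------------------------------------------------


def _train_bandit(config: TrainConfig, reward_table: TabularRewardFunction) -> TrainResult:
    k = reward_table.n_synapses
    probs = {"synapses": init_release_probs((1, k), config.init_value, config.clip_eps)}

    def evaluate(it: int):
        rng = _seed_rng(config.seed, _TAG_THETA, it, 0)
        thetas = sample_release_array(probs["synapses"], config.n_samples, rng)
        rewards = reward_table.evaluate(thetas[:, 0, :])
        return {"synapses": thetas}, RewardVector(rewards)

    def score(it: int) -> float:
        j, _ = enumerate_reward_moments(probs["synapses"].values[0], reward_table)
        return j

    return _run_loop(
        config,
        probs,
        trainable=("synapses",),
        evaluate_fn=evaluate,
        score_fn=score,
        spec=reward_table,
        probs_ref=probs,
    )


# ---------------------------------------------------------------------------
# the shared two-stage loop
# ---------------------------------------------------------------------------


def _run_loop(
    config: TrainConfig,
    probs: dict[str, ReleaseProbMatrix],
    trainable: Sequence[str],
    evaluate_fn: Callable[[int], tuple[dict[str, np.ndarray], RewardVector]],
    score_fn: Callable[[int], float],
    spec: object,
    probs_ref: dict[str, ReleaseProbMatrix],
) -> TrainResult:
    ucfg = UpdateConfig(
        config.learning_rate, config.n_samples, config.clip_eps, config.seed
    )
    from .core import rsrp_update  # local import avoids a cycle in docs builds

    state = RewardTransformState(config.reward_transform)
    log = TrainingLog()
    t0 = time.perf_counter()
    for it in range(config.iterations):
        thetas, raw = evaluate_fn(it)
        shaped, state = apply_transform(raw, state)
        for name in trainable:
            probs_ref[name] = rsrp_update(probs_ref[name], thetas[name], shaped, ucfg)
        record: dict = {
            "iteration": it,
            "reward_mean": float(raw.raw.mean()),
            "reward_min": float(raw.raw.min()),
            "reward_max": float(raw.raw.max()),
            "transformed_sum": float(shaped.effective.sum()),
            "elapsed": time.perf_counter() - t0,
        }
        total = 0.0
        for name in trainable:
            h, _ = bernoulli_entropy(probs_ref[name])
            record[f"entropy_{name}"] = h
            total += h
        record["entropy_total"] = total
        is_last = it == config.iterations - 1
        if it % config.eval_interval == 0 or is_last:
            record["eval_score"] = float(score_fn(it))
        else:
            record["eval_score"] = None
        log.append(**record)
        if (
            config.early_stop_score is not None
            and record["eval_score"] is not None
            and record["eval_score"] >= config.early_stop_score
        ):
            break
    return TrainResult(config, log, dict(probs_ref), spec)


def train(
    config: TrainConfig,
    dataset: SyntheticDataset | None = None,
    reward_table: TabularRewardFunction | None = None,
) -> TrainResult:
    """Run one training job described by ``config``.

    ``classification`` requires ``dataset``; ``bandit`` requires
    ``reward_table``; ``rl`` uses the bundled cart-pole.
    """
    if config.task == "rl":
        return _train_rl(config)
    if config.task == "classification":
        if dataset is None:
            raise ValueError("classification training requires a dataset")
        return _train_classification(config, dataset)
    if reward_table is None:
        raise ValueError("bandit training requires a reward_table")
    return _train_bandit(config, reward_table)


def sampling_size_sweep(
    grid: Sequence[tuple[int, int]],
    base_config: TrainConfig,
    dataset: SyntheticDataset,
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Train once per (synaptic sampling size, data sampling size, seed).

    Returns a tidy frame with one row per run and the final holdout
    accuracy, for studying how performance depends on the product
    ``ss * ds`` (the total number of forward trials per update).
    """
    rows = []
    for ss, ds in grid:
        for seed in seeds:
            cfg = dataclasses.replace(
                base_config, n_samples=ss, data_batch_size=ds, seed=seed
            )
            result = train(cfg, dataset=dataset)
            rows.append(
                {
                    "synaptic_samples": ss,
                    "data_samples": ds,
                    "product": ss * ds,
                    "seed": seed,
                    "final_accuracy": result.final_score,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path: str | Path, result: TrainResult) -> None:
    """Write final probabilities plus run metadata; round-trips bit-exactly."""
    arrays = {}
    meta = {
        "config": result.config.to_dict(),
        "config_digest": result.config.digest(),
        "layers": [],
    }
    for name, p in result.probs.items():
        arrays[f"probs_{name}"] = p.values
        meta["layers"].append({"name": name, "clip_eps": p.clip_eps})
    np.savez(path, meta_json=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict[str, ReleaseProbMatrix], dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        probs = {
            layer["name"]: ReleaseProbMatrix(
                data[f"probs_{layer['name']}"], layer["clip_eps"]
            )
            for layer in meta["layers"]
        }
    return probs, meta
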