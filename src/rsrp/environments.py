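"""A self-contained cart-pole balancing task and the episode contract.

The classic control problem: a pole hinged on a cart must be kept upright
by pushing the cart left or right with a fixed-magnitude force.  The
dynamics use the standard constants (gravity 9.8 m/s^2, cart mass 1.0 kg,
pole mass 0.1 kg, pole half-length 0.5 m, force +/-10 N) integrated with
semi-implicit Euler at dt = 0.02 s, position updated with the old velocity.
An episode terminates when |x| > 2.4 m, |theta| > 12 degrees, or after 500
steps; the agent earns +1 per step, so return equals survival length.

Bundling the simulator keeps reinforcement-learning experiments free of
external dependencies.  Any simulator exposing the same
``reset(seed) -> obs`` / ``step(action) -> (obs, reward, done, info)``
contract plugs into :func:`run_episode` and the trainers unchanged.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np

__all__ = [
    "PUSH_LEFT",
    "PUSH_RIGHT",
    "CartPoleState",
    "EpisodeResult",
    "CartPole",
    "CartPoleVector",
    "cartpole_reset",
    "cartpole_step",
    "run_episode",
]

PUSH_LEFT = 0
PUSH_RIGHT = 1

GRAVITY = 9.8
MASS_CART = 1.0
MASS_POLE = 0.1
TOTAL_MASS = MASS_CART + MASS_POLE
HALF_LENGTH = 0.5
POLEMASS_LENGTH = MASS_POLE * HALF_LENGTH
FORCE_MAG = 10.0
DT = 0.02
X_LIMIT = 2.4
THETA_LIMIT = 12.0 * math.pi / 180.0
MAX_STEPS = 500
RESET_RANGE = 0.05


@dataclasses.dataclass
class CartPoleState:
    """Cart position/velocity, pole angle/angular velocity, and step count."""

    x: float
    x_dot: float
    theta: float
    theta_dot: float
    steps: int = 0

    @property
    def terminated(self) -> bool:
        return (
            abs(self.x) > X_LIMIT
            or abs(self.theta) > THETA_LIMIT
            or self.steps >= MAX_STEPS
        )

    def observation(self) -> np.ndarray:
        return np.array([self.x, self.x_dot, self.theta, self.theta_dot])


@dataclasses.dataclass(frozen=True)
class EpisodeResult:
    """Episode summary: total return and number of steps survived."""

    total_return: float
    length: int


def cartpole_reset(seed: int | np.random.Generator) -> CartPoleState:
    """Draw the four state variables uniformly from [-0.05, 0.05]."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, x_dot, theta, theta_dot = rng.uniform(-RESET_RANGE, RESET_RANGE, size=4)
    return CartPoleState(float(x), float(x_dot), float(theta), float(theta_dot), 0)


def cartpole_step(
    state: CartPoleState, action: int
) -> tuple[CartPoleState, float, bool]:
    """Advance the dynamics one Euler step; +1 reward per step taken.

    Raises if the episode has already terminated.
    """
    if state.terminated:
        raise RuntimeError("cannot step a terminated cart-pole episode")
    if action not in (PUSH_LEFT, PUSH_RIGHT):
        raise ValueError(f"action must be {PUSH_LEFT} or {PUSH_RIGHT}, got {action}")
    force = FORCE_MAG if action == PUSH_RIGHT else -FORCE_MAG
    cos_t = math.cos(state.theta)
    sin_t = math.sin(state.theta)
    temp = (force + POLEMASS_LENGTH * state.theta_dot**2 * sin_t) / TOTAL_MASS
    theta_acc = (GRAVITY * sin_t - cos_t * temp) / (
        HALF_LENGTH * (4.0 / 3.0 - MASS_POLE * cos_t**2 / TOTAL_MASS)
    )
    x_acc = temp - POLEMASS_LENGTH * theta_acc * cos_t / TOTAL_MASS
    new = CartPoleState(
        x=state.x + DT * state.x_dot,
        x_dot=state.x_dot + DT * x_acc,
        theta=state.theta + DT * state.theta_dot,
        theta_dot=state.theta_dot + DT * theta_acc,
        steps=state.steps + 1,
    )
    return new, 1.0, new.terminated


class CartPole:
    """Episode-contract wrapper: reset(seed) -> obs; step(a) -> (obs, r, done, info)."""

    def __init__(self) -> None:
        self._state: CartPoleState | None = None

    def reset(self, seed: int | np.random.Generator) -> np.ndarray:
        self._state = cartpole_reset(seed)
        return self._state.observation()

    def step(self, action: int) -> tuple[np.ndarray, float, bool, dict]:
        if self._state is None:
            raise RuntimeError("reset() must be called before step()")
        self._state, reward, done = cartpole_step(self._state, action)
        return self._state.observation(), reward, done, {}

    @property
    def state(self) -> CartPoleState | None:
        return self._state


class CartPoleVector:
    """N independent cart-pole episodes stepped in lockstep (numpy arrays).

    Used for population evaluation: each population member owns its own
    episode.  ``step`` advances every live episode; finished episodes report
    ``done`` and must be masked out by the caller.
    """

    def __init__(self, init_states: np.ndarray):
        s = np.asarray(init_states, dtype=np.float64)
        if s.ndim != 2 or s.shape[1] != 4:
            raise ValueError(f"init_states must be (n, 4), got {s.shape}")
        self.s = s.copy()
        self.steps = np.zeros(s.shape[0], dtype=np.int64)

    @classmethod
    def from_seeds(cls, seed_seqs) -> "CartPoleVector":
        states = np.stack(
            [
                np.random.default_rng(ss).uniform(-RESET_RANGE, RESET_RANGE, 4)
                for ss in seed_seqs
            ]
        )
        return cls(states)

    @property
    def observations(self) -> np.ndarray:
        return self.s

    def select(self, keep: np.ndarray) -> None:
        self.s = self.s[keep]
        self.steps = self.steps[keep]

    def step(self, actions: np.ndarray) -> np.ndarray:
        """Advance all episodes with per-episode actions; returns done mask."""
        x, x_dot, theta, theta_dot = self.s.T
        force = np.where(actions == PUSH_RIGHT, FORCE_MAG, -FORCE_MAG)
        cos_t = np.cos(theta)
        sin_t = np.sin(theta)
        temp = (force + POLEMASS_LENGTH * theta_dot**2 * sin_t) / TOTAL_MASS
        theta_acc = (GRAVITY * sin_t - cos_t * temp) / (
            HALF_LENGTH * (4.0 / 3.0 - MASS_POLE * cos_t**2 / TOTAL_MASS)
        )
        x_acc = temp - POLEMASS_LENGTH * theta_acc * cos_t / TOTAL_MASS
        self.s = np.stack(
            [
                x + DT * x_dot,
                x_dot + DT * x_acc,
                theta + DT * theta_dot,
                theta_dot + DT * theta_acc,
            ],
            axis=1,
        )
        self.steps += 1
        return (
            (np.abs(self.s[:, 0]) > X_LIMIT)
            | (np.abs(self.s[:, 2]) > THETA_LIMIT)
            | (self.steps >= MAX_STEPS)
        )


def run_episode(
    env,
    policy: Callable[[np.ndarray], int],
    max_steps: int = MAX_STEPS,
    seed: int | np.random.Generator = 0,
) -> EpisodeResult:
    """Roll out ``policy`` in any environment satisfying the episode contract."""
    obs = env.reset(seed)
    total = 0.0
    for t in range(max_steps):
        obs, reward, done, _ = env.step(policy(obs))
        total += reward
        if done:
            return EpisodeResult(total, t + 1)
    return EpisodeResult(total, max_steps)
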