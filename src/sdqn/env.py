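"""Self-contained pixel RL environment (catch) and synthetic fixtures.

The catch game: a ball drops straight down from a random column of a
square logical grid while the agent slides a paddle along the bottom row
(actions left / stay / right, one cell per step, clamped at the walls).
The episode ends when the ball reaches the bottom row; reward is +1 if the
ball column lies within the paddle span, else -1.  Observations are binary
sprite frames rendered to a square pixel canvas by nearest-neighbour block
upsampling, so the same convolutional pipeline used for 84x84 game screens
runs unchanged.  The game is fully solvable: a greedy column-matching
policy always catches, which gives training smoke tests a known ceiling.

Also here: i.i.d. Bernoulli spike-train fixtures for the theory oracle and
random sprite frames for depth-profile diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .lif import SpikeTrain

__all__ = [
    "CatchEnvConfig",
    "CatchEnv",
    "StepResult",
    "optimal_action",
    "random_policy_expected_reward",
    "make_spike_fixtures",
    "random_sprite_frames",
]


@dataclass(frozen=True)
class CatchEnvConfig:
    """Geometry and reward scheme of the catch game."""

    grid: int = 21
    paddle_width: int = 5
    render_size: int = 84
    reward_catch: float = 1.0
    reward_miss: float = -1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.paddle_width >= self.grid:
            raise ValueError("paddle width must be smaller than the grid")
        if self.paddle_width % 2 != 1:
            raise ValueError("paddle width must be odd (centered paddle)")
        if self.render_size % self.grid != 0:
            raise ValueError("render_size must be a multiple of the grid size")


@dataclass
class StepResult:
    """One transition: rendered frame, reward, terminal flag, diagnostics."""

    observation: np.ndarray
    reward: float
    terminal: bool
    info: dict[str, Any] = field(default_factory=dict)


class CatchEnv:
    """Seeded catch environment with the reset/step contract."""

    n_actions = 3  # 0: left, 1: stay, 2: right

    def __init__(self, config: CatchEnvConfig = CatchEnvConfig()):
        self.config = config
        self._rng = np.random.default_rng(config.seed)
        self._active = False
        self.ball_row = 0
        self.ball_col = 0
        self.paddle = 0  # paddle center column

    @property
    def observation_shape(self) -> tuple[int, int]:
        return (self.config.render_size, self.config.render_size)

    @property
    def episode_length(self) -> int:
        """Steps per episode: the ball falls grid-1 rows."""
        return self.config.grid - 1

    def reset(self, seed: int | None = None) -> np.ndarray:
        """Start an episode: ball at the top in a random column, paddle centered."""
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        g = self.config.grid
        self.ball_row = 0
        self.ball_col = int(self._rng.integers(g))
        self.paddle = g // 2
        self._active = True
        return self._render()

    def step(self, action: int) -> StepResult:
        if not self._active:
            raise RuntimeError("step() after terminal; call reset() first")
        if action not in (0, 1, 2):
            raise ValueError(f"action must be in {{0,1,2}}, got {action}")
        g, hw = self.config.grid, self.config.paddle_width // 2
        self.paddle = int(np.clip(self.paddle + (action - 1), hw, g - 1 - hw))
        self.ball_row += 1
        terminal = self.ball_row == g - 1
        reward = 0.0
        if terminal:
            caught = abs(self.ball_col - self.paddle) <= hw
            reward = self.config.reward_catch if caught else self.config.reward_miss
            self._active = False
        return StepResult(
            observation=self._render(),
            reward=reward,
            terminal=terminal,
            info={"ball": (self.ball_row, self.ball_col), "paddle": self.paddle},
        )

    def _render(self) -> np.ndarray:
        g, hw = self.config.grid, self.config.paddle_width // 2
        cells = np.zeros((g, g))
        cells[self.ball_row, self.ball_col] = 1.0
        cells[g - 1, self.paddle - hw : self.paddle + hw + 1] = 1.0
        block = self.config.render_size // g
        if block == 1:
            return cells
        return np.kron(cells, np.ones((block, block)))


def optimal_action(env: CatchEnv) -> int:
    """Greedy column matching: always catches (the reward ceiling is 1.0)."""
    if env.ball_col < env.paddle:
        return 0
    if env.ball_col > env.paddle:
        return 2
    return 1


def random_policy_expected_reward(config: CatchEnvConfig = CatchEnvConfig()) -> float:
    """Exact expected episode reward of the uniform-random policy.

    The paddle center performs a lazy random walk (steps -1/0/+1 each with
    probability 1/3, clamped); the ball column is uniform.  Propagating the
    paddle distribution over the grid-1 steps and integrating the catch
    indicator gives the closed-form expectation that simulations are
    checked against.
    """
    g, hw = config.grid, config.paddle_width // 2
    lo, hi = hw, g - 1 - hw
    dist = np.zeros(g)
    dist[g // 2] = 1.0
    for _ in range(g - 1):
        nxt = np.zeros(g)
        for c in np.nonzero(dist)[0]:
            for d in (-1, 0, 1):
                nxt[int(np.clip(c + d, lo, hi))] += dist[c] / 3.0
        dist = nxt
    catch = 0.0
    for col in range(g):
        for c in range(g):
            if dist[c] and abs(col - c) <= hw:
                catch += dist[c] / g
    return catch * config.reward_catch + (1.0 - catch) * config.reward_miss


def make_spike_fixtures(
    n_neurons: int, T: int, means, seed: int | None = None
) -> SpikeTrain:
    """I.i.d. Bernoulli spike train with the requested per-step means.

    ``means`` is a scalar or per-step sequence of length T, each in [0, 1].
    """
    rng = np.random.default_rng(seed)
    p = np.broadcast_to(np.asarray(means, dtype=float), (T,)).copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("spike means must lie in [0, 1]")
    o = (rng.random((T, n_neurons)) < p[:, None]).astype(float)
    return SpikeTrain(o=o)


def random_sprite_frames(
    rng: np.random.Generator,
    shape: tuple[int, int, int] = (4, 84, 84),
    n_sprites: int = 6,
    sprite_hw: tuple[int, int] = (4, 10),
    intensity: float = 1.0,
) -> np.ndarray:
    """Sparse binary sprite frames emulating preprocessed game screens.

    Drops ``n_sprites`` random rectangles of value ``intensity`` on a zero
    background of every channel; sprite size is drawn within
    ``sprite_hw``.  Pixel sparsity (a few percent) matches the regime of
    rendered game objects on a dark background.
    """
    c, h, w = shape
    frames = np.zeros(shape)
    lo, hi = sprite_hw
    for ch in range(c):
        for _ in range(n_sprites):
            sh = int(rng.integers(lo, hi + 1))
            sw = int(rng.integers(lo, hi + 1))
            r = int(rng.integers(0, h - sh + 1))
            col = int(rng.integers(0, w - sw + 1))
            frames[ch, r : r + sh, col : col + sw] = intensity
    return frames
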