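"""Deep Q-learning loop around the spiking network.

Standard DQN machinery: a ring replay buffer, epsilon-greedy behaviour
policy, a frozen target network synchronised periodically, and Adam on the
surrogate-BPTT gradients of the squared TD error.  Observations are
grayscale frames stacked along channels; rewards are already in [-1, 1]
for the catch environment (clipping is applied anyway and can be turned
off).  Everything is driven by one seeded generator, so two runs with the
same config produce bitwise-identical logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .learning import Adam, clip_grad_norm
from .network import SpikingQNetwork

__all__ = [
    "Transition",
    "ReplayBuffer",
    "TrainConfig",
    "TrainLog",
    "select_action",
    "epsilon_at",
    "train",
    "evaluate",
    "random_policy_rewards",
]


@dataclass
class Transition:
    """One (state, action, reward, next state, terminal) replay record."""

    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    terminal: bool


class ReplayBuffer:
    """Fixed-capacity ring of transitions, oldest evicted first."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._storage: list[Transition | None] = []
        self._next = 0

    def __len__(self) -> int:
        return len(self._storage)

    def add(self, tr: Transition) -> None:
        if len(self._storage) < self.capacity:
            self._storage.append(tr)
        else:
            self._storage[self._next] = tr
        self._next = (self._next + 1) % self.capacity

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        if len(self._storage) < batch_size:
            raise ValueError("not enough transitions to sample a batch")
        idx = rng.integers(len(self._storage), size=batch_size)
        return [self._storage[i] for i in idx]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults follow DQN convention (gamma 0.99, batch 32, target sync every
    1000 steps, epsilon 1.0 -> 0.05 over 1e4 steps, Adam 1e-4) with the
    full 16-step simulation window; desk-scale runs override T, the
    learning rate and the buffer size (see configs/catch_small.yaml).
    """

    T: int = 16
    gamma: float = 0.99
    lr: float = 1e-4
    batch_size: int = 32
    target_sync: int = 1000
    eps_start: float = 1.0
    eps_end: float = 0.05
    eps_decay_steps: int = 10_000
    total_steps: int = 20_000
    buffer_capacity: int = 100_000
    update_every: int = 4
    learn_start: int = 500
    frame_stack: int = 4
    grad_clip: float = 10.0
    clip_rewards: bool = True
    diag_every: int = 200  # episodes between firing-rate diagnostics
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        for e in (self.eps_start, self.eps_end):
            if not 0.0 <= e <= 1.0:
                raise ValueError("epsilon schedule must stay within [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")


@dataclass
class TrainLog:
    """Per-episode records plus run-level metadata."""

    episodes: list[dict] = field(default_factory=list)
    aborted: bool = False
    final_params: dict | None = None
    optimizer_state: dict | None = None

    def episode_rewards(self) -> np.ndarray:
        return np.array([e["reward"] for e in self.episodes])

    def final_mean_reward(self, n: int = 20) -> float:
        r = self.episode_rewards()
        if r.size == 0:
            return float("nan")
        return float(r[-n:].mean())


def select_action(q: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy with lowest-index argmax tie-break."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("empty Q-value vector")
    if not np.isfinite(q).all():
        raise ValueError("non-finite Q-values")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    if rng.random() < epsilon:
        return int(rng.integers(q.size))
    return int(np.argmax(q))  # np.argmax returns the first maximum


def epsilon_at(step: int, cfg: TrainConfig) -> float:
    """Linear decay from eps_start to eps_end over eps_decay_steps."""
    frac = min(step / max(cfg.eps_decay_steps, 1), 1.0)
    return cfg.eps_start + frac * (cfg.eps_end - cfg.eps_start)


class _FrameStack:
    def __init__(self, k: int):
        self.k = k
        self.frames: list[np.ndarray] = []

    def reset(self, frame: np.ndarray) -> np.ndarray:
        self.frames = [frame] * self.k
        return self.state()

    def push(self, frame: np.ndarray) -> np.ndarray:
        self.frames = self.frames[1:] + [frame]
        return self.state()

    def state(self) -> np.ndarray:
        return np.stack(self.frames)


def train(env, net: SpikingQNetwork, cfg: TrainConfig) -> TrainLog:
    """Run the DQN loop and return the episode log.

    The caller supplies a network whose ``T`` and input shape match the
    config/environment; its current weights are the starting point.  A
    non-finite loss aborts the run, keeping the last finite parameters in
    the returned log.
    """
    if net.T != cfg.T:
        raise ValueError(f"network window T={net.T} != config T={cfg.T}")
    rng = np.random.default_rng(cfg.seed)
    env.reset(seed=int(rng.integers(2 ** 31)))
    target = net.clone()
    buf = ReplayBuffer(cfg.buffer_capacity)
    opt = Adam(net.params, lr=cfg.lr)
    stack = _FrameStack(cfg.frame_stack)

    log = TrainLog()
    obs = env.reset(seed=int(rng.integers(2 ** 31)))
    state = stack.reset(obs)
    ep_reward, ep_len, ep_losses = 0.0, 0, []
    episode = 0
    last_finite = {k: v.copy() for k, v in net.params.items()}

    for step in range(cfg.total_steps):
        eps = epsilon_at(step, cfg)
        q = net.forward(state, collect=False).q
        a = select_action(q, eps, rng)
        res = env.step(a)
        r = float(np.clip(res.reward, -1, 1)) if cfg.clip_rewards else res.reward
        next_state = stack.push(res.observation)
        buf.add(Transition(state.astype(np.float32), a, r, next_state.astype(np.float32), res.terminal))
        ep_reward += res.reward
        ep_len += 1
        state = next_state

        if res.terminal:
            rec = {
                "episode": episode, "step": step, "reward": ep_reward,
                "length": ep_len, "epsilon": eps,
                "loss": float(np.mean(ep_losses)) if ep_losses else None,
            }
            if cfg.diag_every and episode % cfg.diag_every == 0:
                from .diagnostics import firing_fraction

                fr = net.forward(state)
                rec["firing_fractions"] = [
                    firing_fraction(spikes[:, 0]) for spikes in fr.layer_spikes
                ]
            log.episodes.append(rec)
            episode += 1
            obs = env.reset(seed=int(rng.integers(2 ** 31)))
            state = stack.reset(obs)
            ep_reward, ep_len, ep_losses = 0.0, 0, []

        if step >= cfg.learn_start and step % cfg.update_every == 0 and len(buf) >= cfg.batch_size:
            batch = buf.sample(cfg.batch_size, rng)
            states = np.stack([t.state for t in batch]).astype(float)
            nexts = np.stack([t.next_state for t in batch]).astype(float)
            acts = np.array([t.action for t in batch])
            rews = np.array([t.reward for t in batch])
            terms = np.array([t.terminal for t in batch], dtype=float)

            q_next = target.forward(nexts, collect=False).q.max(axis=1)
            res_fwd = net.forward(states, record=True, collect=False)
            q_sa = res_fwd.q[np.arange(cfg.batch_size), acts]
            delta = 0.5 * (rews + cfg.gamma * q_next * (1.0 - terms) - q_sa)
            loss = float((delta ** 2).mean())
            if not np.isfinite(loss):
                log.aborted = True
                log.final_params = last_finite
                return log
            gq = np.zeros((cfg.batch_size, net.n_actions))
            gq[np.arange(cfg.batch_size), acts] = -delta / cfg.batch_size
            grads = net.backward(res_fwd, gq)
            if cfg.grad_clip:
                clip_grad_norm(grads, cfg.grad_clip)
            opt.step(net.params, grads)
            last_finite = {k: v.copy() for k, v in net.params.items()}
            ep_losses.append(loss)

        if step % cfg.target_sync == 0:
            target.set_params(net.params)

    log.final_params = {k: v.copy() for k, v in net.params.items()}
    log.optimizer_state = opt.state_dict()
    return log


def evaluate(
    net: SpikingQNetwork, env, n_episodes: int, seed: int = 0,
    epsilon: float = 0.0, frame_stack: int | None = None,
) -> tuple[float, float, list[float]]:
    """Greedy (optionally eps-soft) rollouts; returns (mean, std, rewards)."""
    if n_episodes < 1:
        raise ValueError("need at least one evaluation episode")
    k = frame_stack if frame_stack is not None else net.input_shape[0]
    rng = np.random.default_rng(seed)
    stack = _FrameStack(k)
    rewards = []
    for ep in range(n_episodes):
        obs = env.reset(seed=int(rng.integers(2 ** 31)))
        state = stack.reset(obs)
        total = 0.0
        while True:
            a = select_action(net.forward(state, collect=False).q, epsilon, rng)
            res = env.step(a)
            total += res.reward
            state = stack.push(res.observation)
            if res.terminal:
                break
        rewards.append(total)
    arr = np.array(rewards)
    return float(arr.mean()), float(arr.std()), rewards


def random_policy_rewards(env, n_episodes: int, seed: int = 0) -> list[float]:
    """Uniform-random rollouts, the empirical baseline for smoke tests."""
    rng = np.random.default_rng(seed)
    rewards = []
    for ep in range(n_episodes):
        env.reset(seed=int(rng.integers(2 ** 31)))
        total = 0.0
        while True:
            res = env.step(int(rng.integers(env.n_actions)))
            total += res.reward
            if res.terminal:
                break
        rewards.append(total)
    return rewards
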