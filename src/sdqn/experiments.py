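"""Reproducible headline experiments, packaged as library calls.

These are the study conditions the package's claims are checked under:

* ``theory_grid`` — Monte-Carlo verification of the potential-variance
  prediction and the firing bound over a seeded (alpha, D(W), rate) grid;
* ``vanishing_profile`` — the depth-wise firing-fraction protocol on the
  full conv stack (10 randomised runs, pbLN off vs on under paired seeds);
* ``gradient_check_trials`` — finite-difference verification of the
  surrogate-relaxed BPTT gradients on randomly drawn small networks;
* ``catch_training_comparison`` — paired pbLN on/off DQN training runs on
  the catch environment against the seeded random-policy baseline.

Problem sizes here are the package's desk-scale defaults (see
docs/methods.md); everything is driven by explicit seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import random_policy_rewards, train
from .config import RunConfig, build_env, build_network, load_config
from .diagnostics import FiringReport, depth_profile
from .env import random_sprite_frames
from .network import ConvSpec, SpikingQNetwork
from .theory import verify_grid

__all__ = [
    "theory_grid",
    "vanishing_profile",
    "gradient_check_trials",
    "finite_difference_error",
    "catch_training_comparison",
    "TrainingComparison",
]


def theory_grid(n_trials: int = 100_000, seed: int = 0, T: int = 9) -> pd.DataFrame:
    """The standard verification grid: alpha x D(W) x rate, t <= T-1."""
    return verify_grid(n_trials=n_trials, seed=seed, T=T)


def vanishing_profile(
    n_runs: int = 10, seed: int = 0, T: int = 16,
    input_shape: tuple[int, int, int] = (4, 84, 84),
) -> dict[bool, FiringReport]:
    """Firing fractions of the three-conv stack on synthetic frames.

    Fresh fan-in-scaled random weights and fresh sprite frames per run;
    pbLN off and on evaluated on identical weights/frames.
    """
    net = SpikingQNetwork(
        input_shape=input_shape, conv="c32k8s4-c64k4s2-c64k3s1",
        fc_hidden=512, n_actions=4, T=T, pbln=True,
    )
    return depth_profile(
        net, lambda rng: random_sprite_frames(rng, shape=input_shape),
        n_runs=n_runs, seed=seed, init="kaiming",
    )


def finite_difference_error(
    net: SpikingQNetwork, frames: np.ndarray, gq: np.ndarray, h: float = 1e-6,
    noise_floor: float = 1e-4,
) -> float:
    """Worst relative error between analytic relaxed-mode gradients and
    central finite differences of the relaxed forward.

    Central differences at unit loss scale carry ~1e-10 absolute roundoff,
    so entries whose magnitude is below ``noise_floor`` are assessed
    against that floor rather than their own (noise-dominated) magnitude;
    a reported error of 1e-4 therefore means a genuine 1e-8 absolute
    discrepancy even on the smallest gradients.
    """
    res = net.forward(frames, record=True, relaxed=True)
    grads = net.backward(res, gq)

    def loss() -> float:
        out = net.forward(frames, relaxed=True, collect=False)
        return float((np.atleast_2d(gq) * np.atleast_2d(out.q)).sum())

    worst = 0.0
    for k, p in net.params.items():
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = p[i]
            p[i] = old + h
            lp = loss()
            p[i] = old - h
            lm = loss()
            p[i] = old
            fd = (lp - lm) / (2 * h)
            denom = max(abs(fd), abs(grads[k][i]), noise_floor)
            worst = max(worst, abs(fd - grads[k][i]) / denom)
    return worst


def gradient_check_trials(n_trials: int = 100, seed: int = 0) -> float:
    """Max finite-difference error over randomly drawn small networks.

    Networks stay within three spiking layers, eight neurons per layer and
    a four-step window; pbLN placement, geometry, weights and the loss
    seed vary per trial.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        in_ch = int(rng.integers(1, 3))
        size = int(rng.integers(4, 7))
        k = int(rng.integers(2, 4))
        convs = [ConvSpec(int(rng.integers(1, 3)), k, int(rng.integers(1, 3)))]
        if rng.random() < 0.5:
            h1 = (size - k) // convs[0].stride + 1
            k2 = 2
            if h1 > k2:
                convs.append(ConvSpec(int(rng.integers(1, 3)), k2, 1))
        net = SpikingQNetwork(
            input_shape=(in_ch, size, size),
            conv=convs,
            fc_hidden=int(rng.integers(2, 9)),
            n_actions=int(rng.integers(2, 4)),
            T=int(rng.integers(1, 5)),
            pbln=bool(rng.random() < 0.7),
            pbln_fc=bool(rng.random() < 0.3),
        )
        net.init_weights(rng, scheme="gaussian", weight_var=float(rng.uniform(0.2, 0.6)))
        frames = rng.random((in_ch, size, size))
        gq = rng.normal(size=net.n_actions)
        worst = max(worst, finite_difference_error(net, frames, gq))
    return worst


@dataclass
class TrainingComparison:
    """One paired pbLN on/off training outcome for a single seed."""

    seed: int
    reward_on: float          # final 20-episode mean, pbLN on
    reward_off: float         # final 20-episode mean, pbLN off
    random_baseline: float    # empirical random-policy mean, same seed set


def catch_training_comparison(
    seeds: tuple[int, ...] = (1, 2, 3),
    config_path: str = "configs/catch_small.yaml",
    config: RunConfig | None = None,
    total_steps: int | None = None,
    baseline_episodes: int = 200,
) -> list[TrainingComparison]:
    """Paired pbLN on/off DQN runs on catch, one pair per seed.

    Both runs of a pair start from identical weights and see identically
    seeded environments; the random baseline uses the same seed.  Returns
    the final 20-episode training means.
    """
    if config is not None:
        cfg = config
    else:
        from pathlib import Path

        p = Path(config_path)
        if not p.exists():
            # fall back to the repository root relative to this file
            p = Path(__file__).resolve().parents[2] / config_path
        cfg = load_config(p)
    out = []
    for seed in seeds:
        results = {}
        for pbln_on in (True, False):
            env = build_env(cfg)
            net = build_network(cfg, seed=seed)
            net.pbln = pbln_on
            tc = dataclasses.replace(cfg.train, seed=seed)
            if total_steps is not None:
                tc = dataclasses.replace(tc, total_steps=total_steps)
            log = train(env, net, tc)
            results[pbln_on] = log.final_mean_reward()
        baseline = float(np.mean(
            random_policy_rewards(build_env(cfg), baseline_episodes, seed=seed)
        ))
        out.append(TrainingComparison(
            seed=seed, reward_on=results[True], reward_off=results[False],
            random_baseline=baseline,
        ))
    return out
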