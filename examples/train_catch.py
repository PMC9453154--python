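"""A short DQN training run of the spiking network on the catch game.

Uses the desk-scale configuration (21x21 frames, two conv layers, T=4) and
a reduced step budget so the script finishes in about half a minute; the
full comparison protocol lives in scripts/acceptance.py.
"""

import dataclasses

import numpy as np

from sdqn import build_env, build_network, load_config, random_policy_rewards, train

cfg = load_config("configs/catch_small.yaml")
env = build_env(cfg)
net = build_network(cfg, seed=1)
tc = dataclasses.replace(cfg.train, total_steps=4000, seed=1)

print(f"training {tc.total_steps} steps on catch "
      f"(grid {cfg.env.grid}, T={tc.T}, pbLN on)...")
log = train(env, net, tc)
rewards = log.episode_rewards()
for i in range(0, len(rewards), 50):
    chunk = rewards[i:i + 50]
    print(f"  episodes {i:>3}-{i + len(chunk) - 1:<3} mean reward {chunk.mean():+.2f}")

baseline = float(np.mean(random_policy_rewards(build_env(cfg), 200, seed=1)))
print(f"\nrandom-policy baseline: {baseline:+.2f}")
print(f"final 20-episode mean:  {log.final_mean_reward():+.2f}")
print("(reward +1 = ball caught, -1 = missed; longer runs reach the +1 ceiling)")
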