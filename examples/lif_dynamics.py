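"""Leaky integrate-and-fire basics: integration, spiking, reset, leak.

Runs a single neuron on a hand-built input schedule and checks the
closed-form leak behaviour the rest of the package builds on.
"""

import numpy as np

from sdqn import LIFParams, run_trace

params = LIFParams(tau=2.0, v_th=0.5, v_reset=0.0)
print(f"tau={params.tau} -> decay factor alpha={params.alpha}")

# constant sub-threshold drive: u_t converges to c geometrically
c = 0.4
schedule = np.full((8, 1), c)
train, trace = run_trace(schedule, params)
print("\nconstant sub-threshold input c=0.4 (never reaches v_th=0.5):")
for t, u in enumerate(trace[:, 0], 1):
    closed = c * (1 - params.alpha ** t)
    print(f"  t={t}: u={u:.6f}  closed form c(1-alpha^t)={closed:.6f}")
print(f"  spikes emitted: {int(train.o.sum())} (drive below threshold)")

# a supra-threshold pulse spikes once, resets, then the potential leaks
schedule = np.zeros((6, 1))
schedule[0, 0] = 1.2
train, trace = run_trace(schedule, params)
print("\nsingle 1.2 pulse then silence:")
print(f"  spike at t=1: {train.o[0, 0] == 1.0}, potential after reset: {trace[0, 0]}")
print("  -> the membrane hard-resets to v_reset and stays there without input")
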