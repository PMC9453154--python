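"""Spike-feature vanishing with depth, and its rescue by pbLN.

Randomly initialised three-conv spiking stacks are run on synthetic sprite
frames; we count the fraction of neurons per conv layer that fire at least
once in the 16-step window, with normalisation off and on under identical
weights and inputs.
"""

from sdqn.experiments import vanishing_profile

reports = vanishing_profile(n_runs=3, seed=5)
off, on = reports[False], reports[True]

print("firing fraction per conv layer (mean +- SD over 3 runs):")
print(f"  {'layer':>6} {'no norm':>16} {'pbLN':>16}")
for i, name in enumerate(off.layers):
    print(f"  {name:>6} {off.mean[i]:>8.3f} +- {off.sd[i]:<5.3f} "
          f"{on.mean[i]:>8.3f} +- {on.sd[i]:<5.3f}")
print("\nwithout normalisation activity decays with depth (conv3 nearly"
      "\nsilent); pbLN re-standardises each layer's drive, so deeper layers"
      "\nfire more and features survive to the readout.")
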