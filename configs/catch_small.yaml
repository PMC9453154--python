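# Desk-scale training configuration for the catch environment.
# The full 84x84 / T=16 stack is a GPU-scale workload; this configuration
# keeps the whole pipeline (pixel conv stack, pbLN, surrogate BPTT, replay,
# target network) intact at CPU-minutes cost: 21x21 render, 2-frame stack,
# two conv layers, 64 hidden units, reduced simulation window T=4.
net:
  architecture: c8k5s2-c16k3s1
  fc_hidden: 64
  n_actions: 3
  pbln: true
train:
  T: 4
  lr: 1.0e-3
  total_steps: 20000
  buffer_capacity: 20000
  frame_stack: 2
  eps_decay_steps: 10000
  learn_start: 500
  update_every: 4
  target_sync: 1000
  diag_every: 200
env:
  grid: 21
  paddle_width: 5
  render_size: 21
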