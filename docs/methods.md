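# Methods

## Neuron model and conventions

Discrete-time LIF dynamics: `u_{t+1} = α u_t + (1−α) x_t` with
`α = 1 − 1/τ` (always recomputed from τ, never stored separately), Heaviside
spiking at `V_th`, hard reset to `V_reset`.  Conventions fixed by this
package, chosen where the model description leaves the boundary open:

* **Threshold equality fires**, `H(0) = 1`: the zero-measure boundary case
  is made deterministic and testable rather than left to floating point.
* **Input scaling** follows the explicit recurrence `u_{t+1} = αu_t +
  (1−α)x_t`: the drive carries the `1/τ` coefficient.  Some SNN frameworks
  inject un-scaled input; weight scales are not directly comparable across
  those conventions.
* **Per-inference reset**: membrane state starts at `V_reset` for every
  forward pass (each action selection is a fresh `T`-step simulation);
  potentials do not carry over between environment steps, matching the
  time-window readout semantics.
* Defaults `τ = 2` (α = 0.5), `V_th = 0.5`, `V_reset = 0` — exposed in
  config, never hard-coded in operations.
* Reset is reset-to-value, not reset-by-subtraction.

## Network

Conv stack `c32k8-c64k4-c64k3` (strides 4/2/1, the canonical values for
84×84 inputs; the architecture string accepts explicit `sN` tokens), FC
hidden layer of 512, non-spiking readout `q_i = (1/T) Σ_t W_i·O_t`, `T=16`
by default.  Frames are injected as **constant current** at every step —
no Poisson/rate encoding — which keeps the first layer's drive
deterministic in the input.  The readout's action count is
environment-driven (the catch game has 3).

## pbLN

At each time step the PSP of a conv layer is standardised over all
`H = C×H'×W'` elements jointly (population variance, divide by `H`;
`x̂ = (x − mean)/(std + ε)` with `ε = 1e−5`), then rescaled per channel:
`λ_c x̂ + β_c`, initialised at `λ = V_th − V_reset`, `β = V_reset`.  At
initialisation a +1σ input therefore drives a resting neuron exactly to
threshold ("one sigma drives threshold").  Choices where the formulation
is ambiguous:

* `λ, β` are **one scalar pair per channel, shared across time steps**
  (only a single initialisation pair is specified; per-channel matches
  layer-norm practice).  The normalisation statistics themselves are
  recomputed independently at every time step and for every sample —
  nothing is batched, which is what makes the scheme applicable to RL
  where observations arrive one at a time.
* pbLN is applied to conv layers only by default; an `pbln_fc` flag
  enables FC-layer normalisation for ablations (each feature treated as
  its own channel).
* An all-constant PSP has `std = 0` and normalises to zero, leaving the
  baseline drive `β` — this is also what produces the potential-maintenance
  effect: between sparse inputs the membrane settles toward the learned
  `β` rather than leaking to `V_reset`.

## Learning

Squared-TD-error Q-learning with a frozen target network.  With
`δ = ½(r + γ max Q' − Q)` (bootstrap dropped on terminal transitions) the
implementation minimises `δ²`, seeding the backward pass with
`dL/dq_a = −δ`; the readout-weight form `(1/T) Σ_t δ O_t` is the ascent
direction on the chosen action's row.  The overall loss scale (a factor
vs. the plain squared error) is absorbed by the learning rate.

Backpropagation runs over layers and time.  At the spike the surrogate
`g(v) = 2τ_s/(4 + (πτ_s v)²)` stands in for `dH/du`, evaluated at
`v = u − V_th`: an uncentered bump would peak at `u = 0` instead of at the
firing discontinuity, contradicting its role as `∂H(u − V_th)/∂u`; a
config flag preserves the literal uncentered form for comparison.  `τ_s`
defaults to 2.0 and is a sharpness constant independent of the membrane τ
(the two constants play unrelated roles).  The temporal recurrence
contributes factor `α` on non-spiking steps; the **reset path is detached**
(no gradient flows through the reset assignment).  pbLN's `λ, β` receive
gradients through the normalisation statistics (mean and std treated as
differentiable), as in standard layer-norm training.  Gradient clipping at
global norm 10 stabilises TD training and is off in all gradient-accuracy
tests.  The printed index bounds of the temporal chain are typographically
unclear in places; the implementation uses the standard full-horizon BPTT
recursion.

**Verification strategy.**  The spiking backward pass is not the gradient
of any differentiable function, so correctness is established on the
*surrogate-relaxed model*: every Heaviside replaced by the smooth primitive
`S(v) = arctan(πτ_s v/2)/π + ½` (whose derivative is exactly `g`) and the
reset replaced by the differentiable mix `u = u'(1−o) + V_reset·o`.  The
same backward code path, in relaxed mode, must be the exact gradient of
that model — checked against central finite differences on 100 random
networks (≤ 3 spiking layers, ≤ 8 neurons, T ≤ 4, pbLN placement varied)
to 1e-4 relative.  Entries below 1e-4 magnitude are assessed against the
finite-difference roundoff floor (~1e-8 absolute at unit loss scale)
rather than their own noise-dominated magnitude.  A two-step scalar chain
is additionally checked against a symbolic (sympy) expansion.

## Variance propagation and the vanishing bound

For zero-mean weights with variance `D(W)` and Bernoulli presynaptic
spikes, `D(u_{t+1}) = D(W) Σ_{i=0}^t ψ(i,t) E[o_i]` with
`ψ(i,j) = (1−α)²α^{2(j−i)}`.  The derivation treats the accumulated
potential and each step's fresh synaptic drive as uncorrelated, i.e. the
recursion `D(u_{t+1}) = α²D(u_t) + (1−α)²D(W)E(o_t)`.  Two consequences
for the Monte-Carlo oracle:

* **Weights are redrawn independently per step** (default).  A single
  weight shared across the window adds positive cross-time covariance
  (`E[W²]E[o_i]E[o_j]` terms) and empirically exceeds the prediction by
  ~50–100% at long lags; the `fixed` redraw mode exposes this surplus.
* **The variance trace is recorded from the free, un-thresholded
  accumulation** — the ensemble the closed form describes ("first spike
  after t steps").  Conditioning on threshold non-crossing truncates the
  distribution and biases the variance low; the conditioned estimate is
  still reported alongside its exclusion rate, but is not the comparator.

The firing bound `E(o_{t+1}) ≤ ε Σ_{i=1}^t E[o_i]`, `ε = D(W)/(2V_th²)`,
is checked on the thresholded dynamics for `t ≥ 1`: the literal sum starts
at `i = 1`, so the `t = 0` bound is vacuously zero while a freshly driven
neuron can fire.  The printed form of ε is typographically ambiguous; the
dimensionally consistent variance-to-threshold ratio is used, with the
alternative `D(W)²/V_th²` reading available behind a flag.  Verification
uses the `n_pre`-summed layer form with 32 presynaptic neurons for the
variance (independent contributions add, and averaging suppresses
Monte-Carlo noise; `n_pre = 1` reproduces the literal per-synapse
equation) and the single-synapse form for the bound, where it is not
vacuous.  Grid: `α ∈ {0.25, 0.5, 0.75} × D(W) ∈ {0.1, 0.5, 1.0} × rate ∈
{0.1, 0.3, 0.5}`, 1e5 trials, steps `t ≤ 8`; agreement within 2% relative
and zero bound violations beyond 3 standard errors.

## Depth firing profile

The vanishing demonstration initialises the full conv stack with the
fan-in-scaled training init (uniform Kaiming-style, per-layer
`D(W^l) ≈ 2/fan_in`, hence per-synapse ε ≪ 1) and measures, over 10 runs
with fresh weights and fresh synthetic sprite frames, the fraction of each
conv layer's neurons that fire at least once in the window ("firing
fraction"; mean spike count is reported as a secondary column).  pbLN
off/on are evaluated on identical weights and frames, so differences are
attributable to normalisation alone.  Note the regime matters: a
*depth-constant* `D(W)` with large fan-in amplifies activity with depth
instead — the constant-variance Gaussian init is available in
`depth_profile` to show that counter-regime.

## Synthetic environment and what it does not show

The catch game (21×21 logical grid, odd paddle width 5, ball falling
straight from a uniformly random column, ±1 terminal reward) renders to a
square pixel canvas by nearest-neighbour block upsampling so the full
conv pipeline runs unchanged.  It is fully solvable (a greedy
column-matching policy always catches) and its uniform-random-policy
expected reward has a closed form via the clamped-random-walk paddle
distribution — both used as test anchors.  Synthetic sprite frames
emulate the sparsity and value range of preprocessed game screens
(binary foreground on dark background, a few percent fill).  What passing
these tests does **not** show: performance on real game suites, robustness
to dense/natural image statistics, or long-horizon credit assignment —
catch episodes are 20 steps with terminal-only reward.

## Desk-scale training configuration

The full 84×84 / T=16 stack is a GPU-scale workload; the training
comparison instead uses `configs/catch_small.yaml`: 21×21 render, 2-frame
stack, `c8k5s2-c16k3s1` + FC 64, `T = 4`, Adam 1e-3, batch 32, replay
2e4, target sync 1000 steps, ε-greedy 1.0 → 0.05 over 1e4 steps, 2e4
environment steps (~1000 episodes).  The default `TrainConfig` keeps the
conventional large-scale values (T=16, lr 1e-4, buffer 1e5); the small
configuration overrides them because ~5000 Adam updates on a small network
need the larger step size.  The comparison protocol runs pbLN-on and
pbLN-off agents from identical initial weights and identically seeded
environments for each of three seeds, against the empirical random-policy
baseline on the same seeds.

## Numerical notes

* Everything is float64; determinism is bitwise under a fixed seed
  (single-threaded; all randomness flows from per-run `numpy` generators).
* Convolution is valid (no padding) cross-correlation via an index-table
  im2col; its backward pass is a single scatter-add (bincount).
* `pbln_normalize` of an all-constant array returns zeros (the ε in the
  denominator keeps division defined) and flags the case via `std = 0`;
  the backward pass guards the `1/σ` term the same way.
* Replay stores frames as float32 to halve memory; arithmetic is float64.
* A non-finite training loss aborts the run and keeps the last finite
  parameters in the returned log.

## Known limitations

* The spiking-mode gradients are surrogate approximations; only the
  relaxed-mode gradients are exact, and the loss-decrease smoke test is
  the only direct check of spiking-mode optimisation quality.
* λ, β shared across time steps is a modelling choice; per-time-step
  parameters would change the parameter count and are not implemented.
* The environment interface is the minimal reset/step contract; no
  general gym compatibility layer is provided.
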