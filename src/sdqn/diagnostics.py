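"""Layer-wise firing statistics and membrane-potential trace capture.

The headline statistic is the *firing fraction*: the proportion of a
layer's neurons that emit at least one spike within the ``T``-step window.
Profiling it across depth on randomly initialised networks exposes the
spike-feature vanishing phenomenon (deep conv layers fall silent when the
signal-loss ratio is below 1) and its rescue by pbLN.  On/off comparisons
always share weights and inputs (paired seeds), so differences are
attributable to the normalisation alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .layers import PbLNState, pbln_affine, pbln_normalize
from .lif import LIFParams, NeuronState, SpikeTrain, lif_step, run_trace
from .network import SpikingQNetwork

__all__ = [
    "FiringReport",
    "firing_fraction",
    "mean_spike_count",
    "depth_profile",
    "potential_trace_report",
    "sparse_spike_records",
]


def sparse_spike_records(result, sample: int = 0) -> pd.DataFrame:
    """Compressed sparse export of a forward pass's spikes.

    One row per emitted spike: columns (step, layer, neuron), with neurons
    flattened within each layer.  Dense binary trains of mostly-silent
    deep layers compress to a few rows.
    """
    rows = []
    for li, spikes in enumerate(result.layer_spikes):
        o = spikes[:, sample].reshape(spikes.shape[0], -1)
        t_idx, n_idx = np.nonzero(o)
        for t, n in zip(t_idx, n_idx):
            rows.append({"step": int(t), "layer": li, "neuron": int(n)})
    return pd.DataFrame(rows, columns=["step", "layer", "neuron"])


def _as_time_neuron(train) -> np.ndarray:
    o = train.o if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    return o.reshape(o.shape[0], -1)


def firing_fraction(spike_train) -> float:
    """Fraction of neurons with >= 1 spike in the window.

    Depends only on the per-neuron any-spike indicator, so it is invariant
    to permuting spike times.
    """
    o = _as_time_neuron(spike_train)
    if o.size == 0:
        raise ValueError("empty spike train")
    return float((o.max(axis=0) > 0).mean())


def mean_spike_count(spike_train) -> float:
    """Mean spikes per neuron over the window (secondary statistic)."""
    o = _as_time_neuron(spike_train)
    return float(o.sum(axis=0).mean())


@dataclass
class FiringReport:
    """Per-layer firing fractions across repeated randomised runs."""

    layers: list[str]
    pbln: bool
    fractions: np.ndarray       # (n_runs, n_layers)
    spike_counts: np.ndarray    # (n_runs, n_layers)

    @property
    def n_runs(self) -> int:
        return self.fractions.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.fractions.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.fractions.std(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for run in range(self.n_runs):
            for li, name in enumerate(self.layers):
                rows.append({
                    "layer": name, "pbln": self.pbln, "run": run,
                    "firing_fraction": self.fractions[run, li],
                    "mean_spike_count": self.spike_counts[run, li],
                })
        return pd.DataFrame(rows)


def depth_profile(
    net: SpikingQNetwork,
    frame_source: Callable[[np.random.Generator], np.ndarray],
    n_runs: int = 10,
    seed: int = 0,
    init: str | None = "kaiming",
    init_weight_var: float | None = None,
    settings: tuple[bool, ...] = (False, True),
) -> dict[bool, FiringReport]:
    """Firing fractions per conv layer over ``n_runs`` randomised runs.

    Each run draws fresh weights and a fresh input frame stack, then runs
    one forward pass per requested pbLN setting on the *same* weights and
    frames.  Ten runs with mean and SD is the standard protocol.

    ``init="kaiming"`` (default) uses the fan-in-scaled training
    initialisation — the regime in which deep conv layers fall silent,
    since the per-synapse weight variance (and hence the signal-loss ratio
    epsilon) shrinks with fan-in.  ``init="gaussian"`` draws every weight
    with the constant variance ``init_weight_var``; note a depth-constant
    D(W) with large fan-in *amplifies* activity with depth rather than
    vanishing.  ``init=None`` keeps the network's current weights.
    """
    rng = np.random.default_rng(seed)
    n_conv = len(net.conv_specs)
    names = [f"conv{i + 1}" for i in range(n_conv)]
    frac = {s: np.empty((n_runs, n_conv)) for s in settings}
    cnt = {s: np.empty((n_runs, n_conv)) for s in settings}
    for run in range(n_runs):
        if init == "kaiming":
            net.init_weights(rng, scheme="kaiming")
        elif init == "gaussian":
            net.init_weights(rng, scheme="gaussian", weight_var=init_weight_var)
        elif init is not None:
            raise ValueError(f"unknown init {init!r}")
        frames = frame_source(rng)
        for s in settings:
            res = net.forward(frames, pbln=s)
            for li in range(n_conv):
                train = res.layer_spikes[li][:, 0]
                frac[s][run, li] = firing_fraction(train)
                cnt[s][run, li] = mean_spike_count(train)
    return {
        s: FiringReport(layers=names, pbln=s, fractions=frac[s], spike_counts=cnt[s])
        for s in settings
    }


def potential_trace_report(
    schedule: np.ndarray,
    params: LIFParams = LIFParams(),
    pbln: PbLNState | None = None,
    target: int = 0,
) -> pd.DataFrame:
    """Paired potential traces of one neuron population, pbLN off vs on.

    ``schedule`` is a (time, neuron) PSP pulse schedule; pulses to the
    target neuron should be separated by gaps of at least ~3*tau to show
    the maintenance effect.  Without normalisation the potential leaks
    geometrically (factor alpha per step) toward ``v_reset``; with pbLN the
    inter-pulse drive is the learned baseline ``beta``, so the potential
    settles toward ``beta`` instead and stays higher whenever
    ``beta > v_reset`` — the neuron is held in an easy-to-fire state.

    Returns a long-format table with matching time indices:
    columns (step, neuron, pbln, potential, spike).
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.ndim != 2:
        raise ValueError("schedule must be (time, neuron)")
    T, n = schedule.shape
    off_train, off_trace = run_trace(schedule, params)

    if pbln is None:
        pbln = PbLNState.initialize(n, params)
    state = NeuronState.resting((n,), params)
    on_trace = np.empty_like(schedule)
    on_spikes = np.empty_like(schedule)
    for t in range(T):
        # constant (e.g. silent) steps normalise to zero, leaving the
        # baseline drive beta
        x_hat, _ = pbln_normalize(schedule[t], pbln.eps)
        drive = pbln_affine(x_hat, pbln)
        state, s = lif_step(state, drive, params)
        on_trace[t] = state.u
        on_spikes[t] = s

    rows = []
    for label, trace, spikes in (
        (False, off_trace, off_train.o),
        (True, on_trace, on_spikes),
    ):
        for t in range(T):
            for j in range(n):
                rows.append({
                    "step": t, "neuron": j, "pbln": label,
                    "potential": trace[t, j], "spike": spikes[t, j],
                })
    df = pd.DataFrame(rows)
    df.attrs["target"] = target
    return df
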