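"""Spiking layer primitives: PSP computation, pbLN, and the Q readout.

A spiking layer first computes a post-synaptic potential (PSP) from the
previous layer's binary spikes — a valid (no padding) 2-d cross-correlation
for convolutional layers, a plain matrix-vector product for fully-connected
layers — and then feeds that PSP to LIF neurons.

Potential-based layer normalization (pbLN) standardises the PSP of one
layer at one time step over all of its ``C x H x W`` elements jointly,

    x_hat = (x - mean(x)) / (std(x) + eps),

and re-scales it with learnable per-channel parameters ``lam`` and ``beta``
initialised at ``(v_th - v_reset, v_reset)``, so that at initialisation a
+1-sigma normalized input drives a resting neuron exactly to threshold.
Statistics are per-sample and per-time-step (nothing is batched and there
is no sum over time), which is what makes the scheme usable in RL where
observations arrive one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lif import LIFParams, NeuronState, SpikeTrain, lif_step

__all__ = [
    "ConvLayerSpec",
    "FCLayerSpec",
    "PbLNState",
    "ReadoutSpec",
    "conv_psp",
    "fc_psp",
    "pbln_normalize",
    "pbln_affine",
    "pbln_lif_step",
    "readout_q",
    "im2col_indices",
    "conv_output_shape",
]


# ---------------------------------------------------------------------------
# layer specs
# ---------------------------------------------------------------------------


@dataclass
class ConvLayerSpec:
    """Valid (unpadded) 2-d convolutional layer weights and geometry."""

    out_channels: int
    kernel_size: int
    stride: int
    weight: np.ndarray  # (out_ch, in_ch, k, k)

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        w = np.asarray(self.weight, dtype=float)
        if w.ndim != 4 or w.shape[0] != self.out_channels or w.shape[2:] != (
            self.kernel_size,
            self.kernel_size,
        ):
            raise ValueError(f"weight shape {w.shape} inconsistent with spec")
        if not np.isfinite(w).all():
            raise ValueError("conv weights must be finite")
        self.weight = w


@dataclass
class FCLayerSpec:
    """Fully-connected layer weights, shape (out, in)."""

    weight: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weight, dtype=float)
        if w.ndim != 2:
            raise ValueError("FC weight must be 2-d (out, in)")
        if not np.isfinite(w).all():
            raise ValueError("FC weights must be finite")
        self.weight = w


@dataclass
class PbLNState:
    """Learnable pbLN scale/shift (one value per channel) plus eps.

    ``norm_size`` records the number of elements normalised together
    (``C*H*W`` for a conv layer, the feature count for an FC layer).
    """

    lam: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5
    norm_size: int | None = None

    def __post_init__(self) -> None:
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.lam.shape != self.beta.shape:
            raise ValueError("lam and beta must have the same length")
        if not self.eps > 0:
            raise ValueError("eps must be > 0")

    @classmethod
    def initialize(
        cls, n_channels: int, params: LIFParams, eps: float = 1e-5,
        norm_size: int | None = None,
    ) -> "PbLNState":
        """Initialise ``lam = v_th - v_reset`` and ``beta = v_reset``."""
        return cls(
            lam=np.full(n_channels, params.v_th - params.v_reset, dtype=float),
            beta=np.full(n_channels, params.v_reset, dtype=float),
            eps=eps,
            norm_size=norm_size,
        )


@dataclass
class ReadoutSpec:
    """Non-spiking readout head: weights (n_actions, n_hidden) and window T."""

    weight: np.ndarray
    T: int

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("time window T must be >= 1")
        w = np.asarray(self.weight, dtype=float)
        if w.ndim != 2:
            raise ValueError("readout weight must be 2-d (n_actions, n_hidden)")
        self.weight = w


# ---------------------------------------------------------------------------
# PSP computation
# ---------------------------------------------------------------------------


def conv_output_shape(in_hw: tuple[int, int], k: int, s: int) -> tuple[int, int]:
    h, w = in_hw
    if h < k or w < k:
        raise ValueError(f"input {in_hw} smaller than kernel {k}")
    return ((h - k) // s + 1, (w - k) // s + 1)


def im2col_indices(
    in_shape: tuple[int, int, int], k: int, s: int
) -> tuple[np.ndarray, tuple[int, int]]:
    """Flat gather indices turning (C,H,W) into (C*k*k, P) patch columns.

    ``P`` enumerates output positions row-major.  The same index table turns
    the backward pass into a single scatter-add (bincount).
    """
    c, h, w = in_shape
    oh, ow = conv_output_shape((h, w), k, s)
    i0 = np.repeat(np.arange(c) * h * w, k * k)
    kr = np.repeat(np.arange(k), k)  # kernel row
    kc = np.tile(np.arange(k), k)  # kernel col
    patch = (i0.reshape(c, k * k) + (kr * w + kc)[None, :]).reshape(-1)  # (C*k*k,)
    pr = np.repeat(np.arange(oh) * s, ow)  # output row origin
    pc = np.tile(np.arange(ow) * s, oh)
    pos = (pr * w + pc)  # (P,)
    idx = patch[:, None] + pos[None, :]
    return idx, (oh, ow)


def conv_psp(prev_spikes: np.ndarray, spec: ConvLayerSpec) -> np.ndarray:
    """Valid cross-correlation of a (C,H,W) spike map with the layer kernel.

    Linear in its input; returns a real (out_ch, H', W') PSP map.
    """
    x = np.asarray(prev_spikes, dtype=float)
    if x.ndim != 3:
        raise ValueError("prev_spikes must be (in_ch, H, W)")
    if x.shape[0] != spec.weight.shape[1]:
        raise ValueError(
            f"input channels {x.shape[0]} != kernel in-channels {spec.weight.shape[1]}"
        )
    idx, (oh, ow) = im2col_indices(x.shape, spec.kernel_size, spec.stride)
    cols = x.reshape(-1)[idx]  # (C*k*k, P)
    w2 = spec.weight.reshape(spec.out_channels, -1)
    return (w2 @ cols).reshape(spec.out_channels, oh, ow)


def fc_psp(prev_spikes: np.ndarray, spec: FCLayerSpec) -> np.ndarray:
    """Weighted sum of the previous layer's spikes: ``w @ o``."""
    o = np.asarray(prev_spikes, dtype=float)
    if o.ndim != 1 or o.shape[0] != spec.weight.shape[1]:
        raise ValueError(
            f"spike vector length {o.shape} incompatible with weight {spec.weight.shape}"
        )
    return spec.weight @ o


# ---------------------------------------------------------------------------
# pbLN
# ---------------------------------------------------------------------------


def pbln_normalize(x: np.ndarray, eps: float) -> tuple[np.ndarray, tuple[float, float]]:
    """Standardise ``x`` over all of its elements at this single time step.

    Uses the population variance (divide by ``H = C*H*W``).  Returns
    ``(x_hat, (mean, std))``; an all-constant input has ``std == 0`` and
    maps to an all-zero output (the eps in the denominator keeps the
    division defined), which callers can detect from the returned std.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("pbLN needs at least 2 elements to normalise")
    mean = float(x.mean())
    std = float(x.std())  # population (1/H) variance
    x_hat = (x - mean) / (std + eps)
    return x_hat, (mean, std)


def pbln_affine(x_hat: np.ndarray, state: PbLNState) -> np.ndarray:
    """Per-channel rescale ``lam_c * x_hat + beta_c`` broadcast over space."""
    x_hat = np.asarray(x_hat, dtype=float)
    n_ch = x_hat.shape[0] if x_hat.ndim >= 1 else 1
    if state.lam.shape[0] not in (n_ch,):
        raise ValueError(
            f"channel count {n_ch} does not match pbLN parameters {state.lam.shape[0]}"
        )
    bshape = (n_ch,) + (1,) * (x_hat.ndim - 1)
    return state.lam.reshape(bshape) * x_hat + state.beta.reshape(bshape)


def pbln_lif_step(
    state: NeuronState,
    raw_psp: np.ndarray,
    pbln: PbLNState,
    params: LIFParams,
) -> tuple[NeuronState, np.ndarray]:
    """LIF update driven by the normalised-and-rescaled PSP.

    Exactly ``lif_step(state, pbln_affine(pbln_normalize(raw_psp)), params)``;
    spiking and reset semantics are unchanged.
    """
    x_hat, _ = pbln_normalize(raw_psp, pbln.eps)
    drive = pbln_affine(x_hat, pbln)
    return lif_step(state, drive, params)


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------


def readout_q(fc_spikes: SpikeTrain, spec: ReadoutSpec) -> np.ndarray:
    """Q-values as the time-window mean of weighted hidden spikes.

    ``q_i = (1/T) * sum_t W_i . O_t`` — linear in per-neuron spike counts,
    so permuting spike times leaves q unchanged.  No spiking in this head.
    """
    if fc_spikes.T != spec.T:
        raise ValueError(
            f"spike train window {fc_spikes.T} != readout window {spec.T}"
        )
    o = fc_spikes.o.reshape(fc_spikes.T, -1)
    if o.shape[1] != spec.weight.shape[1]:
        raise ValueError("hidden size mismatch between spikes and readout weights")
    return spec.weight @ o.mean(axis=0)
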