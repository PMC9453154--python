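"""Discrete-time leaky integrate-and-fire (LIF) neuron dynamics.

The membrane potential of every spiking unit in this package follows the
leaky integrator

    u_{t+1} = alpha * u_t + (1 - alpha) * x_t,        alpha = 1 - 1/tau,

where ``x_t`` is the post-synaptic potential (PSP) delivered at step ``t``.
A spike is emitted through a Heaviside threshold, ``o_{t+1} = H(u_{t+1} -
v_th)``, and a spiking neuron is hard-reset to ``v_reset``.  Two conventions
are fixed here and relied on everywhere else:

* threshold equality fires: ``H(0) = 1`` (the zero-measure boundary is made
  deterministic rather than left to floating-point luck);
* the reset is a hard reset-to-value, not reset-by-subtraction.

Membrane state is re-initialised to ``v_reset`` at the start of every
forward inference; potentials never carry over between network inferences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LIFParams",
    "NeuronState",
    "SpikeTrain",
    "decay_factor",
    "heaviside",
    "lif_step",
    "run_trace",
]


def decay_factor(tau: float) -> float:
    """Potential decay factor ``alpha = 1 - 1/tau``.

    ``tau`` is the membrane time constant in units of simulation steps.
    ``tau = 1`` is the memoryless limit (``alpha = 0``); ``tau < 1`` would
    make the decay factor negative and is rejected.
    """
    if not np.isfinite(tau) or tau < 1.0:
        raise ValueError(f"membrane time constant must satisfy tau >= 1, got {tau!r}")
    return 1.0 - 1.0 / tau


@dataclass(frozen=True)
class LIFParams:
    """Neuron constants shared by a population.

    Attributes
    ----------
    tau:
        Membrane time constant (dimensionless steps, >= 1).
    v_th:
        Firing threshold potential.
    v_reset:
        Post-spike reset potential (also the resting/initial potential).
    """

    tau: float = 2.0
    v_th: float = 0.5
    v_reset: float = 0.0

    def __post_init__(self) -> None:
        decay_factor(self.tau)  # validates tau
        if not self.v_th > self.v_reset:
            raise ValueError(
                f"v_th ({self.v_th}) must exceed v_reset ({self.v_reset})"
            )

    @property
    def alpha(self) -> float:
        """Derived decay factor ``1 - 1/tau`` (always recomputed)."""
        return decay_factor(self.tau)


@dataclass
class NeuronState:
    """Membrane potential array plus the current simulation step index."""

    u: np.ndarray
    t: int = 0

    @classmethod
    def resting(cls, shape, params: LIFParams) -> "NeuronState":
        """Fresh state at ``t = 0`` with every potential at ``v_reset``."""
        return cls(u=np.full(shape, params.v_reset, dtype=float), t=0)


@dataclass
class SpikeTrain:
    """Binary spike record indexed ``(time step, neuron...)``."""

    o: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.o, dtype=float)
        if o.ndim < 2:
            raise ValueError("SpikeTrain needs a (time, neuron...) array")
        if not np.isin(o, (0.0, 1.0)).all():
            raise ValueError("spike train elements must be exactly 0 or 1")
        self.o = o

    @property
    def T(self) -> int:
        """Time-window length (number of simulation steps)."""
        return self.o.shape[0]

    @property
    def n_neurons(self) -> int:
        return int(np.prod(self.o.shape[1:]))


def heaviside(v) -> np.ndarray:
    """Spike indicator ``H(v)``: 1 where ``v >= 0``, else 0.

    NaN input is rejected rather than silently mapped to 0.
    """
    v = np.asarray(v, dtype=float)
    if np.isnan(v).any():
        raise ValueError("heaviside received NaN input")
    return (v >= 0.0).astype(float)


def lif_step(
    state: NeuronState, psp: np.ndarray, params: LIFParams
) -> tuple[NeuronState, np.ndarray]:
    """Advance one simulation step: integrate, threshold, reset.

    Returns the new state (post-reset potentials, step index incremented)
    and the binary spike array.  The pre-spike potential is
    ``u' = alpha*u + (1-alpha)*psp``; spiking neurons are reset to
    ``v_reset``, non-spiking neurons keep ``u'``.
    """
    psp = np.asarray(psp, dtype=float)
    if psp.shape != np.shape(state.u):
        raise ValueError(
            f"psp shape {psp.shape} does not match state shape {np.shape(state.u)}"
        )
    if not np.isfinite(psp).all():
        raise ValueError("psp contains non-finite values")
    alpha = params.alpha
    u_pre = alpha * state.u + (1.0 - alpha) * psp
    spikes = heaviside(u_pre - params.v_th)
    u_post = np.where(spikes == 1.0, params.v_reset, u_pre)
    return NeuronState(u=u_post, t=state.t + 1), spikes


def run_trace(
    psp_sequence: np.ndarray,
    params: LIFParams,
    initial: NeuronState | None = None,
) -> tuple[SpikeTrain, np.ndarray]:
    """Iterate :func:`lif_step` over a ``(time, neuron...)`` PSP sequence.

    Returns the emitted :class:`SpikeTrain` and the post-reset potential
    trace with the same ``(time, neuron...)`` shape.  Deterministic given
    its inputs; used by the diagnostics module for potential-maintenance
    traces.
    """
    psp_sequence = np.asarray(psp_sequence, dtype=float)
    if psp_sequence.ndim < 2 or psp_sequence.shape[0] == 0:
        raise ValueError("psp_sequence must be a non-empty (time, neuron...) array")
    state = initial or NeuronState.resting(psp_sequence.shape[1:], params)
    spikes = np.empty_like(psp_sequence)
    trace = np.empty_like(psp_sequence)
    for t in range(psp_sequence.shape[0]):
        state, s = lif_step(state, psp_sequence[t], params)
        spikes[t] = s
        trace[t] = state.u
    return SpikeTrain(o=spikes), trace
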