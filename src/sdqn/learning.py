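"""TD-error loss and surrogate-gradient machinery for spiking BPTT.

The network is trained on the squared temporal-difference error.  With

    delta = 1/2 * (r + gamma * max_a' Q(s', a') - Q(s, a))

(the gamma term dropped on terminal transitions) the training loss is
``delta**2`` and the gradient seeded at the chosen action's Q-value is
``-delta``; everything upstream is obtained by backpropagating through the
spiking forward pass over both layers and time (STBP).

At the spike discontinuity the Heaviside derivative is replaced by the
normalised bump

    g(v) = 2*tau_s / (4 + (pi * tau_s * v)**2),      v = u - v_th,

whose antiderivative ``S(v) = arctan(pi*tau_s*v/2)/pi + 1/2`` is a smooth
sigmoid ("relaxed spike").  Replacing every Heaviside by ``S`` gives a
fully differentiable surrogate-relaxed network; the analytic backward pass
in relaxed mode is the exact gradient of that model, which is how the
implementation is verified against finite differences.  ``tau_s`` is a
surrogate sharpness constant independent of the membrane time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lif import SpikeTrain

__all__ = [
    "SurrogateParams",
    "TDLossTerms",
    "td_error",
    "td_loss_terms",
    "surrogate_grad",
    "spike_primitive",
    "output_weight_grad",
    "backward_through_time",
    "Adam",
    "clip_grad_norm",
]


@dataclass(frozen=True)
class SurrogateParams:
    """Surrogate sharpness ``tau_s`` and the centering convention.

    ``centered=True`` evaluates the bump at ``u - v_th`` so it peaks at the
    firing discontinuity; ``centered=False`` keeps the literal uncentered
    form (peak at ``u = 0``) for comparison experiments.
    """

    tau_s: float = 2.0
    centered: bool = True

    def __post_init__(self) -> None:
        if not self.tau_s > 0:
            raise ValueError("tau_s must be > 0")


@dataclass
class TDLossTerms:
    """One TD update's ingredients: reward, bootstrap target, error, loss."""

    r: float
    gamma: float
    q_sa: float
    q_next_max: float
    terminal: bool
    delta: float
    loss: float


def td_error(
    r: float, gamma: float, q_next_max: float, q_sa: float, terminal: bool | float = False
) -> float:
    """Q-learning TD error ``1/2 (r + gamma * max Q' - Q)``.

    The bootstrap term is dropped for terminal transitions.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    cont = 1.0 - float(np.asarray(terminal, dtype=float))
    return 0.5 * (r + gamma * q_next_max * cont - q_sa)


def td_loss_terms(
    r: float, gamma: float, q_next_max: float, q_sa: float, terminal: bool = False
) -> TDLossTerms:
    delta = td_error(r, gamma, q_next_max, q_sa, terminal)
    return TDLossTerms(
        r=r, gamma=gamma, q_sa=q_sa, q_next_max=q_next_max,
        terminal=bool(terminal), delta=delta, loss=delta ** 2,
    )


def surrogate_grad(
    u, v_th: float, s: SurrogateParams | float = SurrogateParams()
) -> np.ndarray:
    """Surrogate derivative of the spike w.r.t. the membrane potential.

    ``g(v) = 2 tau_s / (4 + (pi tau_s v)^2)`` evaluated at ``v = u - v_th``
    (or at ``v = u`` in the uncentered variant).  Strictly positive, even
    about its peak, and integrates to 1 over the real line.
    """
    if not isinstance(s, SurrogateParams):
        s = SurrogateParams(tau_s=float(s))
    u = np.asarray(u, dtype=float)
    if np.isnan(u).any():
        raise ValueError("surrogate_grad received NaN potentials")
    v = u - v_th if s.centered else u
    return 2.0 * s.tau_s / (4.0 + (np.pi * s.tau_s * v) ** 2)


def spike_primitive(
    u, v_th: float, s: SurrogateParams | float = SurrogateParams()
) -> np.ndarray:
    """Smooth antiderivative of :func:`surrogate_grad` — the relaxed spike.

    ``S(v) = arctan(pi tau_s v / 2)/pi + 1/2`` with ``v = u - v_th``; maps
    potentials to (0, 1) and tends to the Heaviside as ``tau_s -> inf``.
    """
    if not isinstance(s, SurrogateParams):
        s = SurrogateParams(tau_s=float(s))
    u = np.asarray(u, dtype=float)
    v = u - v_th if s.centered else u
    return np.arctan(np.pi * s.tau_s * v / 2.0) / np.pi + 0.5


def output_weight_grad(
    delta: float, fc_spike_train: SpikeTrain, action: int, n_actions: int
) -> np.ndarray:
    """Readout-weight update direction ``(1/T) sum_t delta * O_t``.

    Only the selected action's weight row is driven; all other rows get
    zero.  Equal to ``delta`` times the per-neuron mean spike count.  This
    is the ascent direction that moves ``Q(s, a)`` toward its TD target.
    """
    if not 0 <= action < n_actions:
        raise IndexError(f"action {action} out of range [0, {n_actions})")
    o = fc_spike_train.o.reshape(fc_spike_train.T, -1)
    g = np.zeros((n_actions, o.shape[1]))
    g[action] = delta * o.mean(axis=0)
    return g


def backward_through_time(network, record, gq: np.ndarray) -> dict[str, np.ndarray]:
    """Backpropagate ``dL/dq`` through a stored forward record.

    Thin named entry point over :meth:`SpikingQNetwork.backward`: applies
    the chain rule backwards over layers and simulation time, inserting the
    surrogate derivative wherever the spike nonlinearity appears and the
    decay factor ``alpha`` for the potential recurrence, and differentiates
    through the pbLN statistics.  Returns one gradient per learnable
    parameter, keyed by parameter path.
    """
    return network.backward(record, gq)


class Adam:
    """Minimal Adam optimiser over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}


def clip_grad_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so the global L2 norm is <= max_norm."""
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total
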