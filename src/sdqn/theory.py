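"""Variance propagation of spike-driven potentials and the vanishing bound.

For a LIF neuron receiving Bernoulli presynaptic spikes through zero-mean
random weights with variance ``D(W)``, the sub-threshold potential
accumulation satisfies

    D(u_{t+1}) = D(W) * sum_{i=0}^{t} psi(i, t) * E[o_i],
    psi(i, j) = (1 - alpha)^2 * alpha^{2(j-i)},

i.e. each past presynaptic step contributes its spike mean, discounted by
the squared leak.  The derivation treats the potential and the fresh
synaptic drive as uncorrelated at every step, so the Monte-Carlo oracle
redraws weights independently per step by default (a ``fixed``-weight mode
exposes the cross-time covariance surplus of a shared weight).  The stated
variance is that of the free sub-threshold accumulation ("first spike after
t steps"); the oracle therefore records the un-thresholded potential for
the variance trace, and separately reports the threshold-conditioned
estimate with its exclusion rate, which is truncation-biased.

With ``epsilon = D(W) / (2 * v_th^2)`` the firing expectation obeys

    E(o_{t+1}^l) <= epsilon * E[ sum_{i=1}^{t} o_i^{l-1} ],

so when ``epsilon < 1`` the admissible spike mass contracts geometrically
with depth — the spike-feature vanishing phenomenon.  The literal sum
starts at i=1, which makes the t=0 bound vacuous (zero while a freshly
driven neuron can fire); the bound is checked for t >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LayerEnsembleConfig",
    "TheoryPrediction",
    "MonteCarloTraces",
    "psi",
    "predicted_potential_variance",
    "epsilon_ratio",
    "spike_mean_bound",
    "layer_bound_sequence",
    "monte_carlo_layer",
    "verify_grid",
]


def psi(i: int, j: int, alpha: float) -> float:
    """Leak-discount coefficient ``(1-alpha)^2 * alpha^{2(j-i)}``.

    Strictly decreasing in the lag ``j - i``; lies in (0, 1] for
    ``0 < alpha < 1``.
    """
    if j < i or i < 0:
        raise ValueError(f"need j >= i >= 0, got i={i}, j={j}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"need 0 < alpha < 1, got {alpha}")
    return (1.0 - alpha) ** 2 * alpha ** (2 * (j - i))


@dataclass
class LayerEnsembleConfig:
    """Monte-Carlo ensemble for one layer/synapse chain.

    ``spike_means`` may be a scalar (constant presynaptic rate) or a
    per-step sequence of length >= T.  ``n_pre`` presynaptic neurons
    contribute independently, so predicted variances scale with ``n_pre``
    (``n_pre=1`` reproduces the literal per-synapse equation).
    """

    weight_var: float
    spike_means: float | np.ndarray = 0.5
    alpha: float = 0.5
    v_th: float = 0.5
    T: int = 9
    n_pre: int = 1
    n_trials: int = 100_000
    seed: int = 0
    weight_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.weight_mean != 0.0:
            raise ValueError("the analysis premise requires E(W) = 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        p = np.atleast_1d(np.asarray(self.spike_means, dtype=float))
        if ((p < 0) | (p > 1)).any():
            raise ValueError("spike means must lie in [0, 1]")

    def means_per_step(self) -> np.ndarray:
        p = np.atleast_1d(np.asarray(self.spike_means, dtype=float))
        if p.size == 1:
            return np.full(self.T, float(p[0]))
        if p.size < self.T:
            raise ValueError("spike_means shorter than time window")
        return p[: self.T].astype(float)


@dataclass
class TheoryPrediction:
    """Closed-form predictions for one (layer, time) index."""

    predicted_var_u: float
    spike_mean_bound: float
    epsilon_ratio: float
    psi_weights: np.ndarray


def predicted_potential_variance(cfg: LayerEnsembleConfig, t: int) -> float:
    """Predicted ``D(u_{t+1})`` after integrating steps 0..t.

    ``D(W) * n_pre * sum_{i=0}^t psi(i,t) * E[o_i]``; the large-t limit for
    constant rate p is ``n_pre * D(W) * p * (1-alpha)^2 / (1-alpha^2)``.
    """
    p = cfg.means_per_step()
    if t >= p.size:
        raise ValueError(f"no spike mean available for step {t}")
    coeffs = np.array([psi(i, t, cfg.alpha) for i in range(t + 1)])
    return float(cfg.weight_var * cfg.n_pre * (coeffs * p[: t + 1]).sum())


def epsilon_ratio(weight_var: float, v_th: float, squared_reading: bool = False) -> float:
    """Signal-loss ratio ``epsilon = D(W) / (2 * v_th^2)``.

    ``squared_reading=True`` evaluates the alternative typographic reading
    ``D(W)^2 / v_th^2`` (not the default; exposed for comparison only).
    """
    if weight_var < 0:
        raise ValueError("weight variance must be >= 0")
    if v_th == 0:
        raise ValueError("v_th must be nonzero")
    if squared_reading:
        return weight_var ** 2 / v_th ** 2
    return weight_var / (2.0 * v_th ** 2)


def spike_mean_bound(cfg: LayerEnsembleConfig, t: int) -> float:
    """Upper bound on ``E(o_{t+1}^l)``: ``epsilon * sum_{i=1}^t n_pre*E[o_i]``.

    Empty (zero) at ``t = 0`` per the literal starting index.
    """
    p = cfg.means_per_step()
    eps = epsilon_ratio(cfg.weight_var, cfg.v_th)
    return float(eps * cfg.n_pre * p[1 : t + 1].sum())


def layer_bound_sequence(
    weight_var: float, v_th: float, initial_mass: float, n_layers: int
) -> np.ndarray:
    """Admissible window spike mass per layer under the recursive bound.

    Applying the firing bound layer after layer contracts the admissible
    spike mass by the factor ``epsilon`` each time; with ``epsilon = 0.5``
    each layer can carry at most half of its predecessor's mass.  A
    geometrically decaying sequence (``epsilon < 1``) is the vanishing
    statement.
    """
    eps = epsilon_ratio(weight_var, v_th)
    masses = [float(initial_mass)]
    for _ in range(n_layers):
        masses.append(eps * masses[-1])
    return np.array(masses)


def prediction(cfg: LayerEnsembleConfig, t: int) -> TheoryPrediction:
    return TheoryPrediction(
        predicted_var_u=predicted_potential_variance(cfg, t),
        spike_mean_bound=spike_mean_bound(cfg, t),
        epsilon_ratio=epsilon_ratio(cfg.weight_var, cfg.v_th),
        psi_weights=np.array([psi(i, t, cfg.alpha) for i in range(t + 1)]),
    )


@dataclass
class MonteCarloTraces:
    """Empirical ensemble traces; index t holds quantities after step t
    (i.e. ``u_{t+1}`` / ``o_{t+1}``)."""

    var_u: np.ndarray            # free sub-threshold accumulation variance
    var_u_se: np.ndarray
    spike_mean: np.ndarray       # thresholded-dynamics firing expectation
    spike_mean_se: np.ndarray
    var_u_conditioned: np.ndarray  # pre-spike potentials, early-spike trials excluded
    exclusion_rate: np.ndarray
    n_trials: int
    warning: str | None = None


def monte_carlo_layer(
    cfg: LayerEnsembleConfig, weight_redraw: str = "per_step"
) -> MonteCarloTraces:
    """Simulate the layer ensemble and return empirical variance/rate traces.

    Each trial drives ``n_pre`` Bernoulli spike trains through zero-mean
    Gaussian weights with variance ``D(W)`` into one LIF accumulator.  Two
    parallel recordings are made from the same synaptic drive: the free
    (un-thresholded) accumulation, whose ensemble variance the closed-form
    prediction describes, and the thresholded/reset dynamics, whose spike
    rate the firing bound constrains.  ``weight_redraw="fixed"`` keeps one
    weight draw per trial across time instead of the default per-step
    redraw.
    """
    if weight_redraw not in ("per_step", "fixed"):
        raise ValueError("weight_redraw must be 'per_step' or 'fixed'")
    rng = np.random.default_rng(cfg.seed)
    p = cfg.means_per_step()
    n, m = cfg.n_trials, cfg.n_pre
    sigma_w = np.sqrt(cfg.weight_var)
    u_free = np.zeros(n)
    u_thr = np.zeros(n)
    never_spiked = np.ones(n, dtype=bool)
    var_u = np.empty(cfg.T)
    var_se = np.empty(cfg.T)
    rate = np.empty(cfg.T)
    rate_se = np.empty(cfg.T)
    var_cond = np.empty(cfg.T)
    excl = np.empty(cfg.T)
    a = cfg.alpha
    w_fixed = rng.normal(0.0, sigma_w, size=(n, m)) if weight_redraw == "fixed" else None
    for t in range(cfg.T):
        o = rng.random((n, m)) < p[t]
        w = w_fixed if w_fixed is not None else rng.normal(0.0, sigma_w, size=(n, m))
        x = (w * o).sum(axis=1)
        u_free = a * u_free + (1 - a) * x
        # variance of the mean-zero accumulation; SE via the 4th moment
        m2 = float((u_free ** 2).mean())
        m4 = float((u_free ** 4).mean())
        var_u[t] = m2
        var_se[t] = np.sqrt(max(m4 - m2 ** 2, 0.0) / n)
        # thresholded dynamics (pre-spike potential, hard reset to 0)
        u_pre = a * u_thr + (1 - a) * x
        spikes = u_pre >= cfg.v_th
        rate[t] = spikes.mean()
        rate_se[t] = np.sqrt(rate[t] * (1 - rate[t]) / n)
        if never_spiked.any():
            var_cond[t] = float((u_pre[never_spiked] ** 2).mean())
        else:
            var_cond[t] = np.nan
        excl[t] = 1.0 - never_spiked.mean()
        never_spiked &= ~spikes
        u_thr = np.where(spikes, 0.0, u_pre)
    warning = None
    if n < 1000:
        warning = f"n_trials={n} is small for variance estimation (want >= 1e3)"
    return MonteCarloTraces(
        var_u=var_u, var_u_se=var_se, spike_mean=rate, spike_mean_se=rate_se,
        var_u_conditioned=var_cond, exclusion_rate=excl, n_trials=n,
        warning=warning,
    )


def verify_grid(
    alphas=(0.25, 0.5, 0.75),
    weight_vars=(0.1, 0.5, 1.0),
    spike_means=(0.1, 0.3, 0.5),
    n_trials: int = 100_000,
    seed: int = 0,
    T: int = 9,
    v_th: float = 0.5,
    n_pre_variance: int = 32,
    n_pre_bound: int = 1,
) -> pd.DataFrame:
    """Predicted-vs-empirical sweep over the (alpha, D(W), rate) grid.

    The variance comparison uses the ``n_pre``-summed layer form (default
    32 presynaptic neurons, which also averages down Monte-Carlo noise);
    the firing bound uses the literal single-synapse form where the bound
    is not vacuous.  Returns one row per (grid point, step) with relative
    errors, bound slack in Monte-Carlo standard errors, and pass flags.
    """
    rows = []
    point = 0
    for a in alphas:
        for dw in weight_vars:
            for p in spike_means:
                cfg_v = LayerEnsembleConfig(
                    weight_var=dw, spike_means=p, alpha=a, v_th=v_th, T=T,
                    n_pre=n_pre_variance, n_trials=n_trials,
                    seed=seed + 7919 * point,
                )
                cfg_b = LayerEnsembleConfig(
                    weight_var=dw, spike_means=p, alpha=a, v_th=v_th, T=T,
                    n_pre=n_pre_bound, n_trials=n_trials,
                    seed=seed + 7919 * point + 31,
                )
                mc_v = monte_carlo_layer(cfg_v)
                mc_b = monte_carlo_layer(cfg_b)
                eps = epsilon_ratio(dw, v_th)
                for t in range(T):
                    pred = predicted_potential_variance(cfg_v, t)
                    bound = spike_mean_bound(cfg_b, t)
                    emp_rate = mc_b.spike_mean[t]
                    slack = bound + 3.0 * mc_b.spike_mean_se[t] - emp_rate
                    rows.append({
                        "alpha": a, "weight_var": dw, "spike_mean": p, "t": t,
                        "epsilon": eps,
                        "predicted_var": pred,
                        "empirical_var": mc_v.var_u[t],
                        "var_rel_err": abs(mc_v.var_u[t] - pred) / pred,
                        "var_se": mc_v.var_u_se[t],
                        "bound": bound,
                        "empirical_rate": emp_rate,
                        "rate_se": mc_b.spike_mean_se[t],
                        "bound_ok": bool(t == 0 or slack >= 0.0),
                        "exclusion_rate": mc_v.exclusion_rate[t],
                    })
                point += 1
    return pd.DataFrame(rows)
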