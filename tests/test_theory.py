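"""Closed-form variance/bound predictions against the Monte-Carlo oracle."""

import numpy as np
import pytest

from sdqn.theory import (
    LayerEnsembleConfig,
    epsilon_ratio,
    layer_bound_sequence,
    monte_carlo_layer,
    predicted_potential_variance,
    psi,
    spike_mean_bound,
)


# ---------------------------------------------------------------------------
# psi
# ---------------------------------------------------------------------------


def test_psi_values_and_monotonicity():
    assert psi(3, 3, 0.3) == pytest.approx((1 - 0.3) ** 2)
    assert psi(0, 1, 0.5) == pytest.approx(0.0625)  # 0.25 * 0.25
    lags = [psi(0, j, 0.5) for j in range(6)]
    assert all(a > b for a, b in zip(lags, lags[1:]))
    assert all(0 < v <= 1 for v in lags)


def test_psi_rejects_bad_arguments():
    with pytest.raises(ValueError):
        psi(2, 1, 0.5)
    with pytest.raises(ValueError):
        psi(0, 1, 1.0)


# ---------------------------------------------------------------------------
# predicted variance
# ---------------------------------------------------------------------------


def test_predicted_variance_silent_input_is_zero():
    cfg = LayerEnsembleConfig(weight_var=1.0, spike_means=0.0, alpha=0.5, T=5)
    assert predicted_potential_variance(cfg, 4) == 0.0


def test_predicted_variance_single_term():
    cfg = LayerEnsembleConfig(weight_var=1.0, spike_means=0.5, alpha=0.5, T=5)
    assert predicted_potential_variance(cfg, 0) == pytest.approx(0.125)  # 0.25*0.5


def test_predicted_variance_large_t_geometric_limit():
    alpha, dw, p = 0.6, 0.8, 0.3
    cfg = LayerEnsembleConfig(weight_var=dw, spike_means=p, alpha=alpha, T=400)
    limit = dw * p * (1 - alpha) ** 2 / (1 - alpha ** 2)
    assert predicted_potential_variance(cfg, 399) == pytest.approx(limit, abs=1e-12)


def test_predicted_variance_scales_with_n_pre():
    cfg1 = LayerEnsembleConfig(weight_var=0.5, spike_means=0.3, alpha=0.5, T=4, n_pre=1)
    cfg8 = LayerEnsembleConfig(weight_var=0.5, spike_means=0.3, alpha=0.5, T=4, n_pre=8)
    assert predicted_potential_variance(cfg8, 3) == pytest.approx(
        8 * predicted_potential_variance(cfg1, 3)
    )


# ---------------------------------------------------------------------------
# epsilon and bound
# ---------------------------------------------------------------------------


def test_epsilon_ratio_values():
    assert epsilon_ratio(0.0, 0.5) == 0.0
    assert epsilon_ratio(0.5, 0.5) == pytest.approx(1.0)  # the regime boundary
    # epsilon < 1 iff D(W) < 2 v_th^2
    assert epsilon_ratio(0.49, 0.5) < 1.0 < epsilon_ratio(0.51, 0.5)
    with pytest.raises(ValueError):
        epsilon_ratio(1.0, 0.0)
    assert epsilon_ratio(0.5, 0.5, squared_reading=True) == pytest.approx(1.0)


def test_spike_mean_bound_values():
    silent = LayerEnsembleConfig(weight_var=0.3, spike_means=0.0, alpha=0.5, T=6)
    assert spike_mean_bound(silent, 5) == 0.0
    # epsilon = 0.1 needs D(W) = 0.05 at v_th = 0.5; constant rate 0.2 over t=5
    cfg = LayerEnsembleConfig(weight_var=0.05, spike_means=0.2, alpha=0.5, T=6)
    assert spike_mean_bound(cfg, 5) == pytest.approx(0.1 * 5 * 0.2)
    assert spike_mean_bound(cfg, 0) == 0.0  # literal i=1 start: empty sum


def test_layer_bound_sequence_halves_with_epsilon_half():
    seq = layer_bound_sequence(weight_var=0.25, v_th=0.5, initial_mass=4.0, n_layers=5)
    assert epsilon_ratio(0.25, 0.5) == pytest.approx(0.5)
    assert np.allclose(seq, 4.0 * 0.5 ** np.arange(6))
    assert all(seq[i + 1] <= 0.5 * seq[i] for i in range(5))


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------


def test_monte_carlo_zero_weight_variance_gives_zero_potential_variance():
    cfg = LayerEnsembleConfig(weight_var=0.0, spike_means=0.5, alpha=0.5, T=4,
                              n_trials=2000, seed=0)
    mc = monte_carlo_layer(cfg)
    assert np.all(mc.var_u == 0.0)
    assert np.all(mc.spike_mean == 0.0)


def test_monte_carlo_first_step_matches_prediction():
    cfg = LayerEnsembleConfig(weight_var=1.0, spike_means=0.5, alpha=0.5, T=1,
                              n_pre=1, n_trials=100_000, seed=42)
    mc = monte_carlo_layer(cfg)
    pred = predicted_potential_variance(cfg, 0)  # 0.125
    assert abs(mc.var_u[0] - pred) < 3 * mc.var_u_se[0]


def test_monte_carlo_bound_respected_and_exclusions_reported():
    cfg = LayerEnsembleConfig(weight_var=0.1, spike_means=0.3, alpha=0.5, T=6,
                              n_pre=1, n_trials=50_000, seed=7)
    mc = monte_carlo_layer(cfg)
    for t in range(1, 6):
        bound = spike_mean_bound(cfg, t)
        assert mc.spike_mean[t] <= bound + 3 * mc.spike_mean_se[t]
    assert np.all((mc.exclusion_rate >= 0) & (mc.exclusion_rate <= 1))
    assert np.all(np.diff(mc.exclusion_rate) >= 0)  # exclusions accumulate


def test_fixed_weight_mode_shows_cross_time_covariance_surplus():
    """With one shared weight per trial the time sum is positively
    correlated, so the empirical variance exceeds the independence-based
    prediction — the reason the oracle redraws weights per step."""
    cfg = LayerEnsembleConfig(weight_var=1.0, spike_means=0.5, alpha=0.5, T=8,
                              n_pre=1, n_trials=100_000, seed=3)
    mc_fixed = monte_carlo_layer(cfg, weight_redraw="fixed")
    pred = predicted_potential_variance(cfg, 7)
    assert mc_fixed.var_u[7] > 1.5 * pred
    mc_iid = monte_carlo_layer(cfg)
    assert abs(mc_iid.var_u[7] - pred) / pred < 0.05


def test_monte_carlo_small_trials_warns():
    cfg = LayerEnsembleConfig(weight_var=0.5, spike_means=0.5, T=2, n_trials=100)
    assert monte_carlo_layer(cfg).warning is not None


def test_config_validation():
    with pytest.raises(ValueError):
        LayerEnsembleConfig(weight_var=0.5, weight_mean=0.1)
    with pytest.raises(ValueError):
        LayerEnsembleConfig(weight_var=0.5, spike_means=1.5)
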