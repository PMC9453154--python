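"""TD error, surrogate properties, and gradient correctness of the BPTT."""

import numpy as np
import pytest

from sdqn.learning import (
    Adam,
    SurrogateParams,
    clip_grad_norm,
    output_weight_grad,
    spike_primitive,
    surrogate_grad,
    td_error,
    td_loss_terms,
)
from sdqn.lif import LIFParams, SpikeTrain
from sdqn.network import ConvSpec, SpikingQNetwork


# ---------------------------------------------------------------------------
# TD error
# ---------------------------------------------------------------------------


def test_td_error_hand_example():
    # 0.5 * (1 + 0.99*2 - 1) = 0.99
    assert td_error(1.0, 0.99, 2.0, 1.0) == pytest.approx(0.99)


def test_td_error_self_consistent_value_is_zero():
    assert td_error(0.0, 0.9, 2.0 / 0.9, 2.0) == pytest.approx(0.0)


def test_td_error_terminal_drops_bootstrap():
    assert td_error(1.0, 0.99, 5.0, 0.0, terminal=True) == pytest.approx(0.5)


def test_td_error_rejects_bad_gamma():
    with pytest.raises(ValueError):
        td_error(0.0, 1.5, 0.0, 0.0)


def test_td_loss_terms_nonnegative():
    terms = td_loss_terms(1.0, 0.99, 2.0, 4.0)
    assert terms.loss >= 0 and terms.loss == pytest.approx(terms.delta ** 2)


# ---------------------------------------------------------------------------
# surrogate
# ---------------------------------------------------------------------------


def test_surrogate_peak_value_at_threshold():
    s = SurrogateParams(tau_s=2.0)
    assert surrogate_grad(0.5, 0.5, s) == pytest.approx(s.tau_s / 2.0)


def test_surrogate_is_even_about_threshold():
    s = SurrogateParams(tau_s=3.0)
    for d in (0.01, 0.3, 2.0):
        assert surrogate_grad(0.5 + d, 0.5, s) == pytest.approx(
            surrogate_grad(0.5 - d, 0.5, s)
        )


def test_surrogate_total_mass_is_one():
    from scipy.integrate import quad

    s = SurrogateParams(tau_s=2.0)
    mass, _ = quad(lambda v: surrogate_grad(v, 0.0, s), -np.inf, np.inf)
    assert mass == pytest.approx(1.0, abs=1e-8)


def test_uncentered_variant_peaks_at_zero_potential():
    s = SurrogateParams(tau_s=2.0, centered=False)
    assert surrogate_grad(0.0, 0.5, s) == pytest.approx(s.tau_s / 2.0)
    assert surrogate_grad(0.5, 0.5, s) < surrogate_grad(0.0, 0.5, s)


def test_spike_primitive_derivative_matches_surrogate():
    s = SurrogateParams(tau_s=2.0)
    h = 1e-6
    for u in (-0.5, 0.2, 0.5, 1.3):
        fd = (spike_primitive(u + h, 0.5, s) - spike_primitive(u - h, 0.5, s)) / (2 * h)
        assert fd == pytest.approx(float(surrogate_grad(u, 0.5, s)), rel=1e-6)


# ---------------------------------------------------------------------------
# output weight gradient
# ---------------------------------------------------------------------------


def test_output_weight_grad_identities(rng):
    silent = SpikeTrain(o=np.zeros((4, 6)))
    assert np.all(output_weight_grad(1.3, silent, 1, 3) == 0.0)
    ones = SpikeTrain(o=np.ones((4, 6)))
    g = output_weight_grad(1.0, ones, 2, 3)
    assert np.all(g[2] == 1.0) and np.all(g[[0, 1]] == 0.0)
    o = (rng.random((4, 6)) < 0.5).astype(float)
    g = output_weight_grad(0.7, SpikeTrain(o=o), 0, 2)
    assert np.allclose(g[0], 0.7 * o.mean(axis=0))
    with pytest.raises(IndexError):
        output_weight_grad(1.0, ones, 5, 3)


# ---------------------------------------------------------------------------
# BPTT gradient correctness
# ---------------------------------------------------------------------------


def test_two_step_scalar_chain_matches_symbolic_expansion():
    """T=2, one conv 'pixel' and one hidden neuron: the analytic backward
    equals a sympy expansion of the relaxed temporal chain."""
    import sympy as sp

    lif = LIFParams(tau=2.0, v_th=0.5, v_reset=0.0)
    net = SpikingQNetwork(
        input_shape=(1, 1, 1), conv=[ConvSpec(1, 1, 1)], fc_hidden=1,
        n_actions=1, T=2, lif=lif, pbln=False,
    )
    rng = np.random.default_rng(3)
    net.init_weights(rng, scheme="gaussian", weight_var=1.0)
    x_val = 0.8
    gq_val = 1.0

    w1, w2, wr, x = sp.symbols("w1 w2 wr x", real=True)
    a = sp.Rational(1, 2)
    vth = sp.Rational(1, 2)
    ts = 2

    def S(v):
        return sp.atan(sp.pi * ts * v / 2) / sp.pi + sp.Rational(1, 2)

    # layer 1 (conv 1x1): psp = w1*x at both steps
    u1 = (1 - a) * w1 * x
    o1 = S(u1 - vth)
    u1p = u1 * (1 - o1)
    u2 = a * u1p + (1 - a) * w1 * x
    o2 = S(u2 - vth)
    # layer 2 (fc): psp = w2*o_t
    v1 = (1 - a) * w2 * o1
    p1 = S(v1 - vth)
    v1p = v1 * (1 - p1)
    v2 = a * v1p + (1 - a) * w2 * o2
    p2 = S(v2 - vth)
    q = wr * (p1 + p2) / 2
    subs = {
        w1: float(net.params["conv0.w"][0, 0, 0, 0]),
        w2: float(net.params["fc.w"][0, 0]),
        wr: float(net.params["readout.w"][0, 0]),
        x: x_val,
    }
    expected = {
        "conv0.w": float(sp.diff(q, w1).evalf(subs=subs)),
        "fc.w": float(sp.diff(q, w2).evalf(subs=subs)),
        "readout.w": float(sp.diff(q, wr).evalf(subs=subs)),
    }

    frames = np.full((1, 1, 1), x_val)
    res = net.forward(frames, record=True, relaxed=True)
    grads = net.backward(res, np.array([gq_val]))
    for key, want in expected.items():
        assert float(np.ravel(grads[key])[0]) == pytest.approx(want, rel=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_relaxed_gradients_match_finite_differences(seed):
    from sdqn.experiments import finite_difference_error

    rng = np.random.default_rng(seed)
    pbln = bool(seed % 2)
    net = SpikingQNetwork(
        input_shape=(1, 5, 5), conv=[ConvSpec(2, 3, 2)], fc_hidden=4,
        n_actions=2, T=3, pbln=pbln, pbln_fc=not pbln,
    )
    net.init_weights(rng, scheme="gaussian", weight_var=0.4)
    frames = rng.random((1, 5, 5))
    gq = rng.normal(size=2)
    assert finite_difference_error(net, frames, gq) < 1e-4


def test_zero_loss_gradient_gives_zero_parameter_gradients(tiny_net, rng):
    res = tiny_net.forward(rng.random((2, 8, 8)), record=True)
    grads = tiny_net.backward(res, np.zeros(3))
    for g in grads.values():
        assert np.all(g == 0.0)


def test_training_step_reduces_loss_on_fixed_batch():
    """200 Adam steps on one fixed synthetic batch cut the TD loss by >= 50%."""
    rng = np.random.default_rng(11)
    lif = LIFParams()
    net = SpikingQNetwork(
        input_shape=(1, 8, 8), conv=[ConvSpec(4, 3, 2)], fc_hidden=8,
        n_actions=3, T=4, lif=lif, pbln=True,
    )
    net.init_weights(rng, scheme="kaiming")
    B = 8
    states = rng.random((B, 1, 8, 8))
    actions = rng.integers(3, size=B)
    targets = rng.uniform(-1, 1, size=B)  # fixed TD targets
    opt = Adam(net.params, lr=2e-3)

    def batch_loss_and_grads():
        res = net.forward(states, record=True, collect=False)
        q_sa = res.q[np.arange(B), actions]
        delta = 0.5 * (targets - q_sa)
        gq = np.zeros((B, 3))
        gq[np.arange(B), actions] = -delta / B
        return float((delta ** 2).mean()), net.backward(res, gq)

    first, _ = batch_loss_and_grads()
    for _ in range(200):
        loss, grads = batch_loss_and_grads()
        opt.step(net.params, grads)
    final, _ = batch_loss_and_grads()
    assert final <= 0.5 * first


def test_clip_grad_norm_scales_to_bound():
    grads = {"a": np.array([3.0, 4.0]), "b": np.array([12.0])}
    total = clip_grad_norm(grads, max_norm=1.0)
    assert total == pytest.approx(13.0)
    new_norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    assert new_norm == pytest.approx(1.0)
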