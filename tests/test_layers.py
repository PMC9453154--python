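"""Layer primitives: PSP linearity, pbLN contracts, readout identities."""

import numpy as np
import pytest

from sdqn.layers import (
    ConvLayerSpec,
    FCLayerSpec,
    PbLNState,
    ReadoutSpec,
    conv_psp,
    fc_psp,
    pbln_affine,
    pbln_lif_step,
    pbln_normalize,
    readout_q,
)
from sdqn.lif import NeuronState, SpikeTrain, lif_step
from sdqn.network import parse_architecture


def _loop_conv(x, w, stride):
    """Brute-force nested-loop cross-correlation oracle."""
    oc, ic, k, _ = w.shape
    c, h, wd = x.shape
    oh = (h - k) // stride + 1
    ow = (wd - k) // stride + 1
    out = np.zeros((oc, oh, ow))
    for o in range(oc):
        for i in range(oh):
            for j in range(ow):
                acc = 0.0
                for ci in range(ic):
                    for a in range(k):
                        for b in range(k):
                            acc += w[o, ci, a, b] * x[ci, i * stride + a, j * stride + b]
                out[o, i, j] = acc
    return out


@pytest.mark.parametrize("k,stride,in_ch,out_ch", [(3, 1, 1, 1), (3, 2, 2, 3), (2, 2, 3, 2)])
def test_conv_psp_matches_loop_oracle(rng, k, stride, in_ch, out_ch):
    x = (rng.random((in_ch, 8, 8)) < 0.4).astype(float)
    w = rng.normal(size=(out_ch, in_ch, k, k))
    spec = ConvLayerSpec(out_channels=out_ch, kernel_size=k, stride=stride, weight=w)
    got = conv_psp(x, spec)
    want = _loop_conv(x, w, stride)
    assert np.allclose(got, want, rtol=1e-10, atol=1e-12)


def test_conv_psp_identity_structure(rng):
    # 1x1 kernel, stride 1: psp == w * o elementwise
    x = (rng.random((1, 5, 5)) < 0.5).astype(float)
    w = np.full((1, 1, 1, 1), 0.7)
    spec = ConvLayerSpec(1, 1, 1, w)
    assert np.allclose(conv_psp(x, spec), 0.7 * x)
    assert np.all(conv_psp(np.zeros((1, 5, 5)), spec) == 0.0)


def test_conv_psp_linearity(rng):
    w = rng.normal(size=(2, 1, 3, 3))
    spec = ConvLayerSpec(2, 3, 1, w)
    a = (rng.random((1, 6, 6)) < 0.5).astype(float)
    b = (rng.random((1, 6, 6)) < 0.5).astype(float)
    assert np.allclose(conv_psp(a + b, spec), conv_psp(a, spec) + conv_psp(b, spec))
    assert np.allclose(conv_psp(3.0 * a, spec), 3.0 * conv_psp(a, spec))


def test_conv_psp_shape_errors(rng):
    spec = ConvLayerSpec(1, 3, 1, rng.normal(size=(1, 2, 3, 3)))
    with pytest.raises(ValueError):
        conv_psp(np.zeros((1, 6, 6)), spec)  # channel mismatch
    with pytest.raises(ValueError):
        conv_psp(np.zeros((2, 2, 2)), spec)  # smaller than kernel


def test_fc_psp_identities(rng):
    w = rng.normal(size=(4, 7))
    spec = FCLayerSpec(weight=w)
    assert np.all(fc_psp(np.zeros(7), spec) == 0.0)
    one_hot = np.zeros(7)
    one_hot[3] = 1.0
    assert np.allclose(fc_psp(one_hot, spec), w[:, 3])
    o = (rng.random(7) < 0.5).astype(float)
    explicit = np.array([sum(w[i, j] * o[j] for j in range(7)) for i in range(4)])
    assert np.allclose(fc_psp(o, spec), explicit)
    with pytest.raises(ValueError):
        fc_psp(np.zeros(6), spec)


def test_pbln_normalize_hand_example():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    x_hat, (mean, std) = pbln_normalize(x, eps=0.0)
    assert mean == pytest.approx(2.5)
    assert std == pytest.approx(np.sqrt(1.25))  # population variance
    assert np.allclose(x_hat, (x - 2.5) / np.sqrt(1.25))


def test_pbln_normalize_degenerate_and_errors():
    x_hat, (mean, std) = pbln_normalize(np.full((2, 3), 7.0), eps=1e-5)
    assert np.all(x_hat == 0.0) and std == 0.0
    with pytest.raises(ValueError):
        pbln_normalize(np.array([1.0]), eps=1e-5)


def test_pbln_normalize_idempotent_on_standardized(rng):
    x = rng.normal(size=1000)
    x = (x - x.mean()) / x.std()
    x_hat, _ = pbln_normalize(x, eps=1e-12)
    assert np.allclose(x_hat, x, atol=1e-9)


def test_pbln_affine_cases(lif):
    x_hat = np.zeros((2, 3, 3))
    st = PbLNState(lam=np.array([2.0, 2.0]), beta=np.array([-1.0, -1.0]))
    assert np.all(pbln_affine(x_hat, st) == -1.0)
    ident = PbLNState(lam=np.ones(2), beta=np.zeros(2))
    y = np.ones((2, 3, 3))
    assert np.allclose(pbln_affine(y, ident), y)
    init = PbLNState.initialize(2, lif)
    assert np.allclose(pbln_affine(y, init), lif.v_th * y)  # 0.5*x_hat + 0
    with pytest.raises(ValueError):
        pbln_affine(np.zeros((3, 2, 2)), st)


def test_pbln_initialization_is_threshold_calibrated(lif):
    st = PbLNState.initialize(4, lif)
    assert np.all(st.lam == lif.v_th - lif.v_reset)
    assert np.all(st.beta == lif.v_reset)


def test_pbln_lif_step_is_the_composition(rng, lif):
    raw = rng.normal(size=(3, 4, 4))
    st = PbLNState.initialize(3, lif)
    state = NeuronState.resting((3, 4, 4), lif)
    got_state, got_spikes = pbln_lif_step(state, raw, st, lif)
    x_hat, _ = pbln_normalize(raw, st.eps)
    want_state, want_spikes = lif_step(
        NeuronState.resting((3, 4, 4), lif), pbln_affine(x_hat, st), lif
    )
    assert np.array_equal(got_spikes, want_spikes)
    assert np.allclose(got_state.u, want_state.u)


def test_pbln_lif_step_constant_input_behaves_as_beta_drive(lif):
    # constant raw psp normalises to zero, so the drive is beta everywhere
    st = PbLNState(lam=np.ones(2), beta=np.full(2, 0.2))
    state = NeuronState.resting((2, 3, 3), lif)
    new, spikes = pbln_lif_step(state, np.full((2, 3, 3), 5.0), st, lif)
    # u' = alpha*0 + (1-alpha)*0.2 = 0.1, sub-threshold
    assert np.allclose(new.u, (1 - lif.alpha) * 0.2)
    assert np.all(spikes == 0.0)


def test_readout_identities(rng):
    w = rng.normal(size=(3, 5))
    spec = ReadoutSpec(weight=w, T=4)
    silent = SpikeTrain(o=np.zeros((4, 5)))
    assert np.all(readout_q(silent, spec) == 0.0)
    # neuron j fires every step -> q = W[:, j]
    o = np.zeros((4, 5))
    o[:, 2] = 1.0
    assert np.allclose(readout_q(SpikeTrain(o=o), spec), w[:, 2])


def test_readout_depends_only_on_spike_counts(rng):
    w = rng.normal(size=(2, 6))
    spec = ReadoutSpec(weight=w, T=5)
    o = (rng.random((5, 6)) < 0.5).astype(float)
    q = readout_q(SpikeTrain(o=o), spec)
    # algebraic identity: q = (1/T) W @ column sums
    assert np.allclose(q, w @ o.sum(axis=0) / 5.0)
    # permuting spike times per neuron leaves q unchanged
    perm = np.stack([o[np.random.default_rng(i).permutation(5), j] for j, i in
                     enumerate(range(6))], axis=1)
    assert np.allclose(readout_q(SpikeTrain(o=perm), spec), q)


def test_readout_window_mismatch(rng):
    spec = ReadoutSpec(weight=rng.normal(size=(2, 3)), T=4)
    with pytest.raises(ValueError):
        readout_q(SpikeTrain(o=np.zeros((3, 3))), spec)


def test_parse_architecture_default_strides():
    specs = parse_architecture("c32k8-c64k4-c64k3")
    assert [(s.out_channels, s.kernel_size, s.stride) for s in specs] == [
        (32, 8, 4), (64, 4, 2), (64, 3, 1),
    ]
    explicit = parse_architecture("c8k5s2-c16k3s1")
    assert [(s.out_channels, s.kernel_size, s.stride) for s in explicit] == [
        (8, 5, 2), (16, 3, 1),
    ]
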