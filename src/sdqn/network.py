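"""The spiking Q-network: batched multi-layer forward pass and exact BPTT.

Architecture (configurable; defaults follow the DQN convention): a stack of
spiking convolutional layers with pbLN on their PSPs, one spiking
fully-connected hidden layer, and a non-spiking readout that averages
weighted hidden spikes over the ``T``-step window.

Input encoding is constant-current: the same real-valued frame stack is
injected as the PSP of the first conv layer at every simulation step (no
Poisson/rate coding).  Membrane state is re-initialised at the start of
every inference.

Two forward modes share one code path:

* ``relaxed=False`` (default): binary Heaviside spikes, hard reset.  The
  backward pass uses the surrogate derivative at the spike and detaches
  the reset (no gradient flows through the reset assignment).
* ``relaxed=True``: every Heaviside is replaced by the smooth surrogate
  primitive and the reset is the differentiable convex mix
  ``u = u'*(1-o) + v_reset*o``.  The backward pass in this mode is the
  exact analytic gradient of the relaxed model, which finite differences
  can verify.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import PbLNState, conv_output_shape, im2col_indices
from .learning import SurrogateParams, spike_primitive, surrogate_grad
from .lif import LIFParams, SpikeTrain

__all__ = ["ConvSpec", "SpikingQNetwork", "ForwardResult", "parse_architecture"]


@dataclass(frozen=True)
class ConvSpec:
    """Geometry of one conv layer: (out_channels, kernel_size, stride)."""

    out_channels: int
    kernel_size: int
    stride: int


#: canonical DQN strides for the three-conv stack when an architecture
#: string omits them
_DEFAULT_STRIDES = (4, 2, 1)


def parse_architecture(arch: str) -> list[ConvSpec]:
    """Parse an architecture string like ``"c32k8s4-c64k4s2-c64k3s1"``.

    The stride token may be omitted (``"c32k8-c64k4-c64k3"``), in which
    case the canonical DQN strides (4, 2, 1) are assigned positionally.
    """
    specs = []
    tokens = arch.split("-")
    for i, tok in enumerate(tokens):
        if not tok.startswith("c") or "k" not in tok:
            raise ValueError(f"bad architecture token {tok!r}")
        body = tok[1:]
        cpart, kpart = body.split("k", 1)
        if "s" in kpart:
            kpart, spart = kpart.split("s", 1)
            stride = int(spart)
        elif i < len(_DEFAULT_STRIDES):
            stride = _DEFAULT_STRIDES[i]
        else:
            stride = 1
        specs.append(ConvSpec(int(cpart), int(kpart), stride))
    return specs


@dataclass
class _LayerCache:
    """Per-layer forward record needed by the backward pass."""

    cols: list = field(default_factory=list)      # conv: (B,CK,P); fc: input (B,n_in)
    x_hat: list = field(default_factory=list)     # pbLN normalised psp
    sd: list = field(default_factory=list)        # pbLN std per sample (B,)
    u_pre: list = field(default_factory=list)     # pre-spike potential
    spikes: list = field(default_factory=list)    # emitted spikes (binary or relaxed)


@dataclass
class ForwardResult:
    """Output of one network inference.

    ``q`` has shape (n_actions,) for a single sample, (B, n_actions) for a
    batch.  ``layer_spikes``/``layer_potentials`` list one array per
    spiking layer, shaped (T, B, C, H, W) for conv layers and (T, B, n)
    for the FC layer; potentials are post-reset.  ``record`` holds the
    caches required by :meth:`SpikingQNetwork.backward` when requested.
    """

    q: np.ndarray
    layer_spikes: list
    layer_potentials: list
    record: list | None = None
    relaxed: bool = False
    single: bool = False

    def spike_train(self, layer: int, sample: int = 0) -> SpikeTrain:
        """Binary spike record of one layer for one sample, (T, neurons...)."""
        if self.relaxed:
            raise ValueError("relaxed forward does not emit binary spike trains")
        return SpikeTrain(o=self.layer_spikes[layer][:, sample])


class SpikingQNetwork:
    """LIF conv stack + FC hidden layer + time-averaged Q readout."""

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        conv: list[ConvSpec] | str = "c32k8s4-c64k4s2-c64k3s1",
        fc_hidden: int = 512,
        n_actions: int = 4,
        T: int = 16,
        lif: LIFParams = LIFParams(),
        surrogate: SurrogateParams = SurrogateParams(),
        pbln: bool = True,
        pbln_fc: bool = False,
        eps: float = 1e-5,
    ):
        if T < 1:
            raise ValueError("T must be >= 1")
        if isinstance(conv, str):
            conv = parse_architecture(conv)
        self.input_shape = tuple(input_shape)
        self.conv_specs = list(conv)
        self.fc_hidden = fc_hidden
        self.n_actions = n_actions
        self.T = T
        self.lif = lif
        self.surrogate = surrogate
        self.pbln = pbln
        self.pbln_fc = pbln_fc
        self.eps = eps

        # geometry
        shapes = [self.input_shape]
        for cs in self.conv_specs:
            h, w = conv_output_shape(shapes[-1][1:], cs.kernel_size, cs.stride)
            shapes.append((cs.out_channels, h, w))
        self.layer_shapes = shapes  # input + conv outputs
        self.flat_conv_out = int(np.prod(shapes[-1]))
        self._im2col = []
        for cs, shp in zip(self.conv_specs, shapes[:-1]):
            idx, ohw = im2col_indices(shp, cs.kernel_size, cs.stride)
            self._im2col.append((idx, ohw, int(np.prod(shp))))

        self.params: dict[str, np.ndarray] = {}
        self.init_weights(np.random.default_rng(0))

    # -- parameters --------------------------------------------------------

    def init_weights(self, rng: np.random.Generator, scheme: str = "kaiming",
                     weight_var: float | None = None) -> None:
        """(Re-)draw all weights and reset pbLN parameters to (v_th-v_reset, v_reset).

        ``scheme="kaiming"``: uniform fan-in scaling, U(-sqrt(6/fan_in),
        +sqrt(6/fan_in)) — the training default.  ``scheme="gaussian"``:
        i.i.d. zero-mean normals with variance ``weight_var`` (D(W)), the
        regime of the variance-propagation analysis.
        """
        p: dict[str, np.ndarray] = {}

        def draw(shape, fan_in):
            if scheme == "kaiming":
                b = np.sqrt(6.0 / fan_in)
                return rng.uniform(-b, b, size=shape)
            if scheme == "gaussian":
                if weight_var is None:
                    raise ValueError("gaussian init needs weight_var (D(W))")
                return rng.normal(0.0, np.sqrt(weight_var), size=shape)
            raise ValueError(f"unknown init scheme {scheme!r}")

        in_ch = self.input_shape[0]
        for i, cs in enumerate(self.conv_specs):
            fan_in = in_ch * cs.kernel_size ** 2
            p[f"conv{i}.w"] = draw(
                (cs.out_channels, in_ch, cs.kernel_size, cs.kernel_size), fan_in
            )
            st = PbLNState.initialize(cs.out_channels, self.lif, self.eps)
            p[f"conv{i}.lam"] = st.lam
            p[f"conv{i}.beta"] = st.beta
            in_ch = cs.out_channels
        p["fc.w"] = draw((self.fc_hidden, self.flat_conv_out), self.flat_conv_out)
        if self.pbln_fc:
            st = PbLNState.initialize(self.fc_hidden, self.lif, self.eps)
            p["fc.lam"], p["fc.beta"] = st.lam, st.beta
        p["readout.w"] = draw((self.n_actions, self.fc_hidden), self.fc_hidden)
        self.params = p

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    def clone(self) -> "SpikingQNetwork":
        other = copy.copy(self)
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        frames: np.ndarray,
        record: bool = False,
        relaxed: bool = False,
        pbln: bool | None = None,
        collect: bool = True,
    ) -> ForwardResult:
        """Run the T-step simulation on a frame stack (or batch of stacks).

        ``pbln`` overrides the network's conv-layer normalisation toggle
        (used for paired on/off diagnostics on identical weights).
        ``collect=False`` skips assembling the per-layer spike/potential
        traces (Q-values only — the fast path for action selection).
        """
        frames = np.asarray(frames, dtype=float)
        single = frames.ndim == 3
        if single:
            frames = frames[None]
        if frames.shape[1:] != self.input_shape:
            raise ValueError(
                f"frames shape {frames.shape[1:]} != expected {self.input_shape}"
            )
        if not np.isfinite(frames).all():
            raise ValueError("frames contain non-finite values")
        B = frames.shape[0]
        alpha, v_th, v_reset = self.lif.alpha, self.lif.v_th, self.lif.v_reset
        conv_pbln = self.pbln if pbln is None else pbln

        n_layers = len(self.conv_specs) + 1  # convs + fc
        caches = [_LayerCache() for _ in range(n_layers)]
        # membrane potentials, flat spatial layout (B, C, P) for convs
        u = [
            np.full((B, shp[0], shp[1] * shp[2]), v_reset)
            for shp in self.layer_shapes[1:]
        ] + [np.full((B, self.fc_hidden), v_reset)]

        # constant-current encoding: first-layer patch columns are the same
        # at every step, extract once
        idx0 = self._im2col[0][0]
        cols0 = frames.reshape(B, -1)[:, idx0]

        fc_spikes_sum = np.zeros((B, self.fc_hidden))
        layer_spikes = [[] for _ in range(n_layers)]
        layer_pots = [[] for _ in range(n_layers)]

        for t in range(self.T):
            prev = None  # spikes of previous layer, (B, C, P)
            for li, cs in enumerate(self.conv_specs):
                if li == 0:
                    cols = cols0
                else:
                    idx, _, in_size = self._im2col[li]
                    cols = prev.reshape(B, -1)[:, idx]
                w2 = self.params[f"conv{li}.w"].reshape(cs.out_channels, -1)
                psp = np.matmul(w2, cols)  # (B, O, P)
                if conv_pbln:
                    y, xh, sd = self._pbln_forward(
                        psp, self.params[f"conv{li}.lam"], self.params[f"conv{li}.beta"]
                    )
                else:
                    y, xh, sd = psp, None, None
                u_pre = alpha * u[li] + (1.0 - alpha) * y
                o, u[li] = self._fire(u_pre, relaxed)
                prev = o
                if record:
                    c = caches[li]
                    c.cols.append(cols)
                    c.x_hat.append(xh)
                    c.sd.append(sd)
                    c.u_pre.append(u_pre)
                    c.spikes.append(o)
                if collect:
                    layer_spikes[li].append(o)
                    layer_pots[li].append(u[li])
            # fc layer
            fin = prev.reshape(B, -1)
            psp = fin @ self.params["fc.w"].T
            if self.pbln_fc:
                # each feature is its own channel: (B, n, 1)
                y, xh, sd = self._pbln_forward(
                    psp[:, :, None], self.params["fc.lam"], self.params["fc.beta"]
                )
                y = y[:, :, 0]
            else:
                y, xh, sd = psp, None, None
            u_pre = alpha * u[-1] + (1.0 - alpha) * y
            o, u[-1] = self._fire(u_pre, relaxed)
            fc_spikes_sum += o
            if record:
                c = caches[-1]
                c.cols.append(fin)
                c.x_hat.append(xh)
                c.sd.append(sd)
                c.u_pre.append(u_pre)
                c.spikes.append(o)
            if collect:
                layer_spikes[-1].append(o)
                layer_pots[-1].append(u[-1])

        q = (fc_spikes_sum / self.T) @ self.params["readout.w"].T

        def stack(lst, li):
            arr = np.stack(lst)  # (T, B, ...)
            if li < len(self.conv_specs):
                shp = self.layer_shapes[li + 1]
                return arr.reshape(self.T, B, *shp)
            return arr

        result = ForwardResult(
            q=q[0] if single else q,
            layer_spikes=[stack(s, i) for i, s in enumerate(layer_spikes)] if collect else [],
            layer_potentials=[stack(s, i) for i, s in enumerate(layer_pots)] if collect else [],
            record=caches if record else None,
            relaxed=relaxed,
            single=single,
        )
        if record:
            result._conv_pbln = conv_pbln  # remember the toggle used
        return result

    def _fire(self, u_pre: np.ndarray, relaxed: bool):
        v_reset = self.lif.v_reset
        if relaxed:
            o = spike_primitive(u_pre, self.lif.v_th, self.surrogate)
            u_post = u_pre * (1.0 - o) + v_reset * o
        else:
            o = (u_pre >= self.lif.v_th).astype(float)
            u_post = np.where(o == 1.0, v_reset, u_pre)
        return o, u_post

    def _pbln_forward(self, psp, lam, beta):
        """Normalise (B, C, P) over all C*P elements per sample, then apply
        the per-channel affine.  Population variance; eps in denominator."""
        B = psp.shape[0]
        flat = psp.reshape(B, -1)
        mu = flat.mean(axis=1)
        # population variance via E[x^2] - mu^2 (single BLAS pass)
        ex2 = np.einsum("bi,bi->b", flat, flat) / flat.shape[1]
        sd = np.sqrt(np.maximum(ex2 - mu * mu, 0.0))
        xh = (psp - mu[:, None, None]) / (sd + self.eps)[:, None, None]
        y = lam.reshape(1, -1, 1) * xh + beta.reshape(1, -1, 1)
        return y, xh, sd

    # -- backward ----------------------------------------------------------

    def backward(self, record_or_result, gq: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every learnable parameter.

        ``gq`` is dL/dq with shape (B, n_actions) (or (n_actions,) for a
        single-sample record).  In relaxed mode this is the exact gradient
        of the relaxed forward; in spiking mode the surrogate derivative
        stands in for dH/du and the reset path is detached.
        """
        result = record_or_result
        if result.record is None:
            raise ValueError("forward must be called with record=True")
        caches = result.record
        relaxed = result.relaxed
        conv_pbln = getattr(result, "_conv_pbln", self.pbln)
        gq = np.asarray(gq, dtype=float)
        if gq.ndim == 1:
            gq = gq[None]
        B = caches[0].u_pre[0].shape[0]
        if gq.shape != (B, self.n_actions):
            raise ValueError(f"gq shape {gq.shape} != {(B, self.n_actions)}")
        alpha, v_th, v_reset = self.lif.alpha, self.lif.v_th, self.lif.v_reset
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        # readout: q = (1/T) sum_t O_t @ Wr^T
        fc_o = caches[-1].spikes
        gWr = np.zeros_like(self.params["readout.w"])
        for t in range(self.T):
            gWr += gq.T @ fc_o[t]
        grads["readout.w"] = gWr / self.T
        go_const = (gq @ self.params["readout.w"]) / self.T  # dL/dO_t, same all t
        go = [go_const] * self.T

        # fc layer
        go_prev = self._layer_backward(
            kind="fc", li=None, cache=caches[-1], go=go, grads=grads,
            relaxed=relaxed, use_pbln=self.pbln_fc,
        )
        # conv layers, deepest first
        for li in reversed(range(len(self.conv_specs))):
            shp = self.layer_shapes[li + 1]
            go_li = [g.reshape(B, shp[0], shp[1] * shp[2]) for g in go_prev]
            go_prev = self._layer_backward(
                kind="conv", li=li, cache=caches[li], go=go_li, grads=grads,
                relaxed=relaxed, use_pbln=conv_pbln,
            )
        return grads

    def _layer_backward(self, kind, li, cache, go, grads, relaxed, use_pbln):
        alpha, v_th, v_reset = self.lif.alpha, self.lif.v_th, self.lif.v_reset
        T = self.T
        name = "fc" if kind == "fc" else f"conv{li}"
        w_key = f"{name}.w"
        B = cache.u_pre[0].shape[0]
        go_prev = [None] * T
        gu_next = 0.0
        first_conv = kind == "conv" and li == 0
        for t in reversed(range(T)):
            o = cache.spikes[t]
            u_pre = cache.u_pre[t]
            g_s = surrogate_grad(u_pre, v_th, self.surrogate)
            if relaxed:
                gu_pre = go[t] * g_s + gu_next * ((1.0 - o) + (v_reset - u_pre) * g_s)
            else:
                gu_pre = go[t] * g_s + gu_next * (1.0 - o)
            gy = (1.0 - alpha) * gu_pre
            gu_next = alpha * gu_pre
            if use_pbln:
                gpsp = self._pbln_backward(name, cache, t, gy, grads, kind)
            else:
                gpsp = gy
            if kind == "fc":
                fin = cache.cols[t]  # (B, n_in)
                grads[w_key] += gpsp.T @ fin
                go_prev[t] = gpsp @ self.params[w_key]
            else:
                cs = self.conv_specs[li]
                cols = cache.cols[t]  # (B, CK, P)
                w2 = self.params[w_key].reshape(cs.out_channels, -1)
                o_ch = cs.out_channels
                gw2 = gpsp.transpose(1, 0, 2).reshape(o_ch, -1) @ \
                    cols.transpose(1, 0, 2).reshape(cols.shape[1], -1).T
                grads[w_key] += gw2.reshape(self.params[w_key].shape)
                if not first_conv:
                    gcols = np.matmul(w2.T, gpsp)
                    go_prev[t] = self._col2im(li, gcols)
        return go_prev

    def _pbln_backward(self, name, cache, t, gy, grads, kind):
        lam = self.params[f"{name}.lam"]
        xh = cache.x_hat[t]
        sd = cache.sd[t]  # (B,)
        if kind == "fc":
            gy3 = gy[:, :, None]  # (B, C, 1): per-feature channels
            xh3 = xh
        else:
            gy3 = gy
            xh3 = xh
        grads[f"{name}.lam"] += (gy3 * xh3).sum(axis=(0, 2))
        grads[f"{name}.beta"] += gy3.sum(axis=(0, 2))
        gxh = lam.reshape(1, -1, 1) * gy3  # (B, C, P)
        B = gxh.shape[0]
        g = gxh.reshape(B, -1)
        fx = xh3.reshape(B, -1)
        d = sd + self.eps
        m1 = g.mean(axis=1)
        m2 = (g * fx).mean(axis=1)
        safe_sd = np.where(sd > 0, sd, 1.0)
        gflat = (g - m1[:, None]) / d[:, None] - fx * np.where(
            sd > 0, m2 / safe_sd, 0.0
        )[:, None]
        gpsp = gflat.reshape(gxh.shape)
        if kind == "fc":
            gpsp = gpsp[:, :, 0]
        return gpsp

    def _col2im(self, li, gcols):
        """Scatter-add patch-column gradients back to the input map."""
        idx, _, in_size = self._im2col[li]
        B = gcols.shape[0]
        offs = (np.arange(B) * in_size)[:, None, None]
        flat_idx = (idx[None] + offs).ravel()
        out = np.bincount(flat_idx, weights=gcols.ravel(), minlength=B * in_size)
        shp = self.layer_shapes[li]
        return out.reshape(B, shp[0], shp[1] * shp[2])
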