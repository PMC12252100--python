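"""MAK-Net: multi-scale attentive Kolmogorov-Arnold network for ECG beats.

The model classifies fixed-length single-lead beat segments into the five
AAMI classes (N, S, V, F, Q).  Stages, in forward order:

1. a stem of four ConvBlocks (Conv1d -> BatchNorm -> ReLU -> MaxPool with
   kernel 2, stride 1, padding 1 -- the stated pooling grows the length by
   one sample per block);
2. a multi-scale fusion block: four parallel convolutions with kernel sizes
   3/11/21/31 combined by a learnable softmax-weighted average, plus a
   parallel ConvBlock branch and a 1x1-convolution residual skip, all fused
   by element-wise addition;
3. an attention stack alternating two MLPBlocks (dual-branch: full
   convolutional main path + partial convolution on a quarter of the
   channels) with two ECA layers (global average pooling and a single
   1-D convolution across channels, adaptive kernel size);
4. a bidirectional GRU whose per-step forward/backward states are
   concatenated, followed by a temporal mean-pool;
5. a two-layer KAN head whose edges carry learnable B-spline activations
   (nodes only sum), ending in a softmax over the 5 classes.

Channel widths, GRU size and the KAN hidden width are not dictated by the
architecture itself; the defaults below total 6.11 million trainable
parameters (`kan_hidden` is the calibration knob, see `ModelConfig`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, no_grad

logger = logging.getLogger(__name__)

VARIANTS = (
    "full",
    "single_scale_3",
    "single_scale_11",
    "single_scale_21",
    "single_scale_31",
    "no_attention",
    "no_bigru",
    "no_kan",
)

N_CLASSES = 5


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Architectural hyper-parameters; the network builds deterministically
    from this record and a seed.

    ``kan_hidden`` is the designated width knob: with all other defaults
    fixed, 570 makes the full model's trainable-parameter count round to
    6.11 million.
    """

    input_len: int = 300
    stem_channels: tuple[int, ...] = (16, 32, 64, 128)
    stem_kernel: int = 3
    ms_kernels: tuple[int, ...] = (3, 11, 21, 31)
    ms_out_channels: int = 128
    dropout: float = 0.3
    partial_ratio: float = 0.25
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    gru_hidden: int = 256
    gru_layers: int = 2
    kan_hidden: int = 570
    kan_grid: int = 5
    kan_order: int = 3
    kan_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if any(k % 2 == 0 for k in self.ms_kernels):
            raise ValueError(f"multi-scale kernels must all be odd, got {self.ms_kernels}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if not (0.0 < self.partial_ratio <= 1.0):
            raise ValueError(f"partial_ratio must be in (0, 1], got {self.partial_ratio}")
        if self.kan_grid < 1 or self.kan_order < 0:
            raise ValueError("kan_grid must be >= 1 and kan_order >= 0")
        if self.kan_range[0] >= self.kan_range[1]:
            raise ValueError(f"kan_range must be increasing, got {self.kan_range}")

    @property
    def kan_widths(self) -> tuple[int, int, int]:
        return (2 * self.gru_hidden, self.kan_hidden, N_CLASSES)


# --------------------------------------------------------------------------
# basic layers
# --------------------------------------------------------------------------


class Module:
    """Minimal layer base: named parameters + named buffers, recursively."""

    def named_parameters(self) -> list[tuple[str, Parameter]]:
        out = []
        for name, obj in vars(self).items():
            if isinstance(obj, Parameter):
                out.append((name, obj))
            elif isinstance(obj, Module):
                out.extend((f"{name}.{n}", p) for n, p in obj.named_parameters())
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{n}", p) for n, p in item.named_parameters())
                    elif isinstance(item, Parameter):
                        out.append((f"{name}.{i}", item))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for name, obj in vars(self).items():
            if isinstance(obj, np.ndarray):
                out.append((name, obj))
            elif isinstance(obj, Module):
                out.extend((f"{name}.{n}", b) for n, b in obj.named_buffers())
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{n}", b) for n, b in item.named_buffers())
        return out


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True, padding: int | None = None):
        self.padding = (kernel - 1) // 2 if padding is None else padding
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.weight = Parameter(rng.normal(0.0, scale, (out_ch, in_ch, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, padding=self.padding)

    def named_parameters(self):
        out = [("weight", self.weight)]
        if self.bias is not None:
            out.append(("bias", self.bias))
        return out


class BatchNorm1d(Module):
    def __init__(self, channels: int, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return x.batch_norm(self.gamma, self.beta, self.running_mean,
                            self.running_var, training, self.momentum)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Parameter(rng.normal(0.0, scale, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvBlock(Module):
    """Conv1d -> BatchNorm1d -> ReLU -> MaxPool1d(kernel=2, stride=1, padding=1).

    The pooling parameters grow the sequence length by exactly one sample
    (L -> L + 2 - 2 + 1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv1d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm1d(out_ch)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return self.bn(self.conv(x), training).relu().max_pool1d(2, 1, 1)


# --------------------------------------------------------------------------
# multi-scale fusion block
# --------------------------------------------------------------------------


class MultiScaleBlock(Module):
    """Inception-style four-kernel fusion with a ConvBlock branch and a
    residual 1x1 skip, all merged by element-wise addition.

    The four parallel convolutions use "same" padding; their outputs are
    averaged with learnable softmax-normalized weights (initialized uniform,
    so the block starts as a plain average), then BN -> ReLU -> dropout ->
    max-pool.  The skip is also max-pooled so all three summands share the
    (length + 1) output length that the stride-1/padding-1 pooling forces.
    """

    def __init__(self, in_ch: int, out_ch: int, kernels: tuple[int, ...],
                 dropout: float, rng: np.random.Generator):
        self.branches = [Conv1d(in_ch, out_ch, k, rng) for k in kernels]
        self.fusion_logits = Parameter(np.zeros(len(kernels)))
        self.bn = BatchNorm1d(out_ch)
        self.dropout_p = dropout
        self.convblock2 = ConvBlock(in_ch, out_ch, 3, rng)
        self.skip = Conv1d(in_ch, out_ch, 1, rng, padding=0)

    def fusion_weights(self) -> Tensor:
        return self.fusion_logits.softmax(axis=0)

    def __call__(self, x: Tensor, training: bool, drop_rng: np.random.Generator) -> Tensor:
        w = self.fusion_weights()
        fused = None
        for i, branch in enumerate(self.branches):
            term = branch(x) * w[i]
            fused = term if fused is None else fused + term
        fused = self.bn(fused, training).relu()
        fused = fused.dropout(self.dropout_p, drop_rng, training).max_pool1d(2, 1, 1)
        side = self.convblock2(x, training)
        res = self.skip(x).max_pool1d(2, 1, 1)
        return fused + side + res


# --------------------------------------------------------------------------
# attention: MLPBlock (partial convolution) + ECA
# --------------------------------------------------------------------------


class MLPBlock(Module):
    """Dual-branch block: a full Conv->BN->ReLU->Conv main path plus a
    partial-convolution path touching only the first ceil(ratio*C) channels
    (identity on the rest), fused by addition. Length-preserving."""

    def __init__(self, channels: int, partial_ratio: float, rng: np.random.Generator):
        self.conv1 = Conv1d(channels, channels, 3, rng)
        self.bn = BatchNorm1d(channels)
        self.conv2 = Conv1d(channels, channels, 3, rng)
        self.n_partial = int(np.ceil(partial_ratio * channels))
        if self.n_partial < 1:
            raise ValueError("partial_ratio too small: no channel would be convolved")
        self.partial_conv = Conv1d(self.n_partial, self.n_partial, 3, rng)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        main = self.conv2(self.bn(self.conv1(x), training).relu())
        head = self.partial_conv(x[:, : self.n_partial])
        if self.n_partial < x.shape[1]:
            partial = Tensor.concat([head, x[:, self.n_partial :]], axis=1)
        else:
            partial = head
        return main + partial


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive ECA kernel: nearest odd integer to |log2(C)/gamma + b/gamma|,
    ties resolved toward the smaller odd value, floored at 1."""
    if channels < 1:
        raise ValueError("channel count must be >= 1")
    t = abs(np.log2(channels) / gamma + b / gamma)
    lower = 2 * int(np.floor((t + 1) / 2)) - 1  # largest odd <= t (or t-1 at odd t+eps)
    lower = max(lower, 1)
    upper = lower + 2
    k = lower if (t - lower) <= (upper - t) else upper
    return max(k, 1)


class ECALayer(Module):
    """Efficient channel attention: global average pool per channel, one
    small convolution across the channel axis, logistic squashing, and
    multiplicative reweighting. No dimensionality reduction."""

    def __init__(self, channels: int, gamma: float, b: float, rng: np.random.Generator):
        self.kernel = eca_kernel_size(channels, gamma, b)
        scale = np.sqrt(1.0 / self.kernel)
        self.weight = Parameter(rng.normal(0.0, scale, (1, 1, self.kernel)))

    def __call__(self, x: Tensor) -> Tensor:
        n, c, _ = x.shape
        s = x.mean(axis=2).reshape(n, 1, c)
        w = s.conv1d(self.weight, None, padding=self.kernel // 2).sigmoid()
        return x * w.reshape(n, c, 1)


# --------------------------------------------------------------------------
# bidirectional GRU
# --------------------------------------------------------------------------


def _gru_direction(x: Tensor, wih: Parameter, whh: Parameter,
                   bih: Parameter, bhh: Parameter, reverse: bool) -> Tensor:
    """One GRU direction as a fused autodiff op with manual BPTT.

    x: (N, T, I); weights use the [reset | update | candidate] gate layout.
    Returns the hidden-state sequence (N, T, H) in original time order.
    """
    xd = x.data if not reverse else x.data[:, ::-1]
    n, t_len, _ = xd.shape
    h_dim = whh.data.shape[0]
    gi_all = xd @ wih.data + bih.data  # (N, T, 3H)
    h = np.zeros((n, h_dim))
    hs = np.empty((n, t_len, h_dim))
    cache = []
    for t in range(t_len):
        gh = h @ whh.data + bhh.data
        a_r = gi_all[:, t, :h_dim] + gh[:, :h_dim]
        a_z = gi_all[:, t, h_dim : 2 * h_dim] + gh[:, h_dim : 2 * h_dim]
        r = 1.0 / (1.0 + np.exp(-a_r))
        z = 1.0 / (1.0 + np.exp(-a_z))
        ghn = gh[:, 2 * h_dim :]
        nstate = np.tanh(gi_all[:, t, 2 * h_dim :] + r * ghn)
        h_prev = h
        h = (1.0 - z) * nstate + z * h_prev
        hs[:, t] = h
        cache.append((r, z, nstate, ghn, h_prev))

    out_data = hs if not reverse else hs[:, ::-1]

    def backward(grad):
        g_hs = grad if not reverse else grad[:, ::-1]
        d_gi = np.zeros_like(gi_all)
        d_whh = np.zeros_like(whh.data)
        d_bhh = np.zeros_like(bhh.data)
        dh_next = np.zeros((n, h_dim))
        for t in range(t_len - 1, -1, -1):
            r, z, nstate, ghn, h_prev = cache[t]
            dh = g_hs[:, t] + dh_next
            dz = dh * (h_prev - nstate)
            da_z = dz * z * (1.0 - z)
            dn = dh * (1.0 - z)
            da_n = dn * (1.0 - nstate * nstate)
            dr = da_n * ghn
            da_r = dr * r * (1.0 - r)
            d_gi[:, t, :h_dim] = da_r
            d_gi[:, t, h_dim : 2 * h_dim] = da_z
            d_gi[:, t, 2 * h_dim :] = da_n
            dgh = np.concatenate([da_r, da_z, da_n * r], axis=1)
            d_whh += h_prev.T @ dgh
            d_bhh += dgh.sum(axis=0)
            dh_next = dh * z + dgh @ whh.data.T
        if whh.requires_grad:
            whh._accum(d_whh)
        if bhh.requires_grad:
            bhh._accum(d_bhh)
        flat = d_gi.reshape(n * t_len, -1)
        if wih.requires_grad:
            wih._accum(xd.reshape(n * t_len, -1).T @ flat)
        if bih.requires_grad:
            bih._accum(flat.sum(axis=0))
        if x.requires_grad:
            dx = d_gi @ wih.data.T
            x._accum(dx if not reverse else dx[:, ::-1])

    return Tensor.make(out_data, (x, wih, whh, bih, bhh), backward)


class GRUDirection(Module):
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, reverse: bool):
        s_in = np.sqrt(1.0 / in_dim)
        s_h = np.sqrt(1.0 / hidden)
        self.wih = Parameter(rng.uniform(-s_in, s_in, (in_dim, 3 * hidden)))
        self.whh = Parameter(rng.uniform(-s_h, s_h, (hidden, 3 * hidden)))
        self.bih = Parameter(np.zeros(3 * hidden))
        self.bhh = Parameter(np.zeros(3 * hidden))
        self.reverse = reverse

    def __call__(self, x: Tensor) -> Tensor:
        return _gru_direction(x, self.wih, self.whh, self.bih, self.bhh, self.reverse)


class BiGRU(Module):
    """Stacked bidirectional GRU; per step the forward and backward hidden
    states are concatenated, so each layer outputs width 2*hidden."""

    def __init__(self, in_dim: int, hidden: int, layers: int, rng: np.random.Generator):
        self.layers = []
        d = in_dim
        for _ in range(layers):
            fwd = GRUDirection(d, hidden, rng, reverse=False)
            bwd = GRUDirection(d, hidden, rng, reverse=True)
            self.layers.append(fwd)
            self.layers.append(bwd)
            d = 2 * hidden
        self.out_dim = d

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(0, len(self.layers), 2):
            x = Tensor.concat([self.layers[i](x), self.layers[i + 1](x)], axis=2)
        return x


# --------------------------------------------------------------------------
# KAN head: B-spline edge activations
# --------------------------------------------------------------------------


def make_grid(lo: float, hi: float, grid: int, order: int) -> np.ndarray:
    """Uniform knot vector with `grid` intervals on [lo, hi], extended by
    `order` knots on each side; length grid + 2*order + 1."""
    step = (hi - lo) / grid
    return lo + step * np.arange(-order, grid + order + 1)


def bspline_basis(u: np.ndarray, knots: np.ndarray, order: int) -> np.ndarray:
    """Cox-de Boor B-spline basis values.

    u: any shape; returns shape u.shape + (n_basis,) with
    n_basis = len(knots) - order - 1 (= grid + order for `make_grid`).
    Inputs are clamped to the interior interval [knots[order], knots[-order-1]].
    """
    u = np.asarray(u, dtype=np.float64)
    lo, hi = knots[order], knots[-order - 1]
    uc = np.clip(u, lo, hi)
    flat = uc.reshape(-1, 1)
    # degree 0: half-open interval indicators, last interior interval closed
    left = knots[:-1]
    right = knots[1:]
    b = ((flat >= left) & (flat < right)).astype(np.float64)
    last = np.searchsorted(knots, hi, side="left") - 1  # interval owning u == hi
    b[(flat[:, 0] == hi), :] = 0.0
    b[(flat[:, 0] == hi), last] = 1.0
    for k in range(1, order + 1):
        nb = len(knots) - k - 1
        new = np.zeros((flat.shape[0], nb))
        for i in range(nb):
            d1 = knots[i + k] - knots[i]
            d2 = knots[i + k + 1] - knots[i + 1]
            if d1 > 0:
                new[:, i] += (flat[:, 0] - knots[i]) / d1 * b[:, i]
            if d2 > 0:
                new[:, i] += (knots[i + k + 1] - flat[:, 0]) / d2 * b[:, i + 1]
        b = new
    return b.reshape(u.shape + (b.shape[1],))


def bspline_basis_deriv(u: np.ndarray, knots: np.ndarray, order: int) -> np.ndarray:
    """First derivative of the basis functions of `bspline_basis`."""
    u = np.asarray(u, dtype=np.float64)
    n_basis = len(knots) - order - 1
    if order == 0:
        return np.zeros(u.shape + (n_basis,))
    lower = bspline_basis(u, knots, order - 1)  # n_basis + 1 functions
    out = np.zeros(u.shape + (n_basis,))
    for i in range(n_basis):
        d1 = knots[i + order] - knots[i]
        d2 = knots[i + order + 1] - knots[i + 1]
        if d1 > 0:
            out[..., i] += order / d1 * lower[..., i]
        if d2 > 0:
            out[..., i] -= order / d2 * lower[..., i + 1]
    return out


class KanLayer(Module):
    """One Kolmogorov-Arnold layer: every edge (i -> j) carries
    phi_ji(u) = w_b[j,i]*silu(u) + w_s[j,i]*sum_g c[j,i,g]*B_g(u); each
    output node sums its incoming edges plus a bias.  Inputs are expected
    inside `kan_range` (the model squashes with tanh beforehand; stray
    values are clamped by the basis)."""

    def __init__(self, in_dim: int, out_dim: int, grid: int, order: int,
                 rng_range: tuple[float, float], rng: np.random.Generator):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.grid, self.order = grid, order
        self.range = tuple(float(v) for v in rng_range)
        self.knots = make_grid(self.range[0], self.range[1], grid, order)
        n_basis = grid + order
        s = np.sqrt(1.0 / in_dim)
        self.coeffs = Parameter(rng.normal(0.0, 0.1, (out_dim, in_dim, n_basis)))
        self.w_base = Parameter(rng.uniform(-s, s, (out_dim, in_dim)))
        self.w_spline = Parameter(rng.uniform(-s, s, (out_dim, in_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        xd = x.data
        basis = bspline_basis(xd, self.knots, self.order)  # (N, in, B)
        spline = np.einsum("nib,oib->noi", basis, self.coeffs.data)
        sig = 1.0 / (1.0 + np.exp(-xd))
        silu_x = xd * sig
        edge = (self.w_base.data[None] * silu_x[:, None, :]
                + self.w_spline.data[None] * spline)
        out = edge.sum(axis=2) + self.bias.data

        coeffs, w_base, w_spline, bias = self.coeffs, self.w_base, self.w_spline, self.bias

        def backward(grad):  # grad: (N, out)
            dedge = grad[:, :, None]  # broadcast over inputs
            if bias.requires_grad:
                bias._accum(grad.sum(axis=0))
            if w_base.requires_grad:
                w_base._accum(np.einsum("no,ni->oi", grad, silu_x))
            if w_spline.requires_grad:
                w_spline._accum((dedge * spline).sum(axis=0))
            dspline = dedge * w_spline.data[None]  # (N, out, in)
            if coeffs.requires_grad:
                coeffs._accum(np.einsum("noi,nib->oib", dspline, basis))
            if x.requires_grad:
                dbasis = bspline_basis_deriv(xd, self.knots, self.order)
                sprime = np.einsum("nib,oib->noi", dbasis, coeffs.data)
                dsilu = sig + xd * sig * (1.0 - sig)
                dx = (np.einsum("no,oi->ni", grad, w_base.data) * dsilu
                      + (dspline * sprime).sum(axis=1))
                x._accum(dx)

        return Tensor.make(out, (x, coeffs, w_base, w_spline, bias), backward)

    # -- export / rebuild ---------------------------------------------------

    def export(self, n_samples: int = 101) -> dict:
        """Serializable record: knots, per-edge coefficients and weights, and
        each edge activation sampled at `n_samples` points across the range."""
        u = np.linspace(self.range[0], self.range[1], n_samples)
        basis = bspline_basis(u, self.knots, self.order)  # (S, B)
        spline = np.einsum("sb,oib->ois", basis, self.coeffs.data)
        silu_u = u / (1.0 + np.exp(-u))
        curves = (self.w_base.data[:, :, None] * silu_u[None, None, :]
                  + self.w_spline.data[:, :, None] * spline)
        return {
            "in_dim": self.in_dim,
            "out_dim": self.out_dim,
            "grid": self.grid,
            "order": self.order,
            "range": list(self.range),
            "knots": self.knots.tolist(),
            "coeffs": self.coeffs.data.tolist(),
            "w_base": self.w_base.data.tolist(),
            "w_spline": self.w_spline.data.tolist(),
            "bias": self.bias.data.tolist(),
            "sample_u": u.tolist(),
            "curves": curves.tolist(),
        }

    @classmethod
    def from_export(cls, rec: dict) -> "KanLayer":
        layer = cls(rec["in_dim"], rec["out_dim"], rec["grid"], rec["order"],
                    tuple(rec["range"]), np.random.default_rng(0))
        layer.coeffs.data[...] = np.asarray(rec["coeffs"])
        layer.w_base.data[...] = np.asarray(rec["w_base"])
        layer.w_spline.data[...] = np.asarray(rec["w_spline"])
        layer.bias.data[...] = np.asarray(rec["bias"])
        return layer


def kan_spline_export(model: "MakNet", n_samples: int = 101) -> list[dict]:
    """Export every KAN layer's grid, coefficients and sampled edge curves."""
    return [layer.export(n_samples) for layer in model.kan_layers]


# --------------------------------------------------------------------------
# the full model
# --------------------------------------------------------------------------


class MakNet(Module):
    def __init__(self, cfg: ModelConfig, variant: str = "full"):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; valid names: {', '.join(VARIANTS)}")
        self.cfg = cfg
        self.variant = variant
        rng = np.random.default_rng(cfg.seed)
        self._drop_rng = np.random.default_rng(cfg.seed + 1)

        self.stem = []
        c_in = 1
        for c_out in cfg.stem_channels:
            self.stem.append(ConvBlock(c_in, c_out, cfg.stem_kernel, rng))
            c_in = c_out

        if variant.startswith("single_scale_"):
            kernels = (int(variant.rsplit("_", 1)[1]),)
        else:
            kernels = cfg.ms_kernels
        self.multiscale = MultiScaleBlock(c_in, cfg.ms_out_channels, kernels,
                                          cfg.dropout, rng)
        c = cfg.ms_out_channels

        self.attention = []
        if variant != "no_attention":
            for _ in range(2):
                self.attention.append(MLPBlock(c, cfg.partial_ratio, rng))
                self.attention.append(ECALayer(c, cfg.eca_gamma, cfg.eca_b, rng))

        if variant != "no_bigru":
            self.bigru = BiGRU(c, cfg.gru_hidden, cfg.gru_layers, rng)
            feat_dim = self.bigru.out_dim
        else:
            self.bigru = None
            feat_dim = c

        widths = (feat_dim, cfg.kan_hidden, N_CLASSES)
        self.kan_layers: list[KanLayer] = []
        self.head_linear: list[Linear] = []
        if variant != "no_kan":
            for a, b in zip(widths[:-1], widths[1:]):
                self.kan_layers.append(
                    KanLayer(a, b, cfg.kan_grid, cfg.kan_order, cfg.kan_range, rng)
                )
        else:
            for a, b in zip(widths[:-1], widths[1:]):
                self.head_linear.append(Linear(a, b, rng))

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray | Tensor, training: bool = False) -> Tensor:
        """x: (N, L) or (N, 1, L) beat segments; returns (N, 5) class
        probabilities (softmax)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim == 2:
            x = x.reshape(x.shape[0], 1, x.shape[1])
        h = x
        for block in self.stem:
            h = block(h, training)
        h = self.multiscale(h, training, self._drop_rng)
        for layer in self.attention:
            h = layer(h, training) if isinstance(layer, MLPBlock) else layer(h)
        if self.bigru is not None:
            h = h.transpose(0, 2, 1)  # (N, T, C)
            h = self.bigru(h)
            h = h.mean(axis=1)
        else:
            h = h.mean(axis=2)
        if self.kan_layers:
            for layer in self.kan_layers:
                h = h.tanh()  # squash into the spline range
                h = layer(h)
        else:
            h = self.head_linear[0](h.tanh()).relu()
            h = self.head_linear[1](h)
        return h.softmax(axis=1)

    __call__ = forward

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Argmax class indices, evaluation mode, batched (ties -> lowest)."""
        preds = []
        with no_grad():
            for i in range(0, len(x), batch_size):
                p = self.forward(x[i : i + batch_size], training=False)
                preds.append(np.argmax(p.data, axis=1))
        return np.concatenate(preds) if preds else np.empty(0, dtype=int)

    def reset_dropout_rng(self, seed: int) -> None:
        self._drop_rng = np.random.default_rng(seed)

    # -- (de)serialization ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{n}": p.data for n, p in self.named_parameters()}
        state.update({f"buffer.{n}": b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data[...] = state[f"param.{n}"]
        for n, b in self.named_buffers():
            b[...] = state[f"buffer.{n}"]


def build_model(cfg: ModelConfig, variant: str = "full") -> MakNet:
    """Construct a MAK-Net (or one of its ablation variants) deterministically
    from the config's seed. Valid variants: full, single_scale_{3,11,21,31},
    no_attention, no_bigru, no_kan."""
    return MakNet(cfg, variant)


def count_parameters(model: MakNet) -> int:
    """Number of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))
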