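"""Neural-network building blocks on top of the autodiff tensor.

Layers follow the NCHW layout.  Every layer takes an explicit
``numpy.random.Generator`` at construction so that model initialization
is a pure function of the seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, from_op, _acc

__all__ = [
    "Module",
    "Sequential",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "MaxPool2d",
    "MultiHeadAttention",
    "upsample_nearest2x",
    "pad2d",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for m in self.modules():
            for v in m.__dict__.values():
                items = v if isinstance(v, (list, tuple)) else [v]
                for item in items:
                    if isinstance(item, Tensor) and item.requires_grad and id(item) not in seen:
                        seen.add(id(item))
                        yield item

    def named_parameters(self, prefix=""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{prefix}{name}.{i}", item

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # state includes non-trainable buffers (running BN stats) via _buffers
    def state_dict(self):
        state = {}
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for i, m in enumerate(self.modules()):
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[f"__buf{i}__{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name]).copy()
        for i, m in enumerate(self.modules()):
            for bname in getattr(m, "_buffers", {}):
                key = f"__buf{i}__{bname}"
                if key in state:
                    m._buffers[bname] = np.asarray(state[key]).copy()
                    setattr(m, bname, m._buffers[bname])


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(np.float32), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(in_features)
        self.weight = _param(rng, (out_features, in_features), scale)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.swapaxes(-1, -2)
        if self.bias is not None:
            y = y + self.bias
        return y


def pad2d(x: Tensor, pad: tuple[int, int, int, int], value: float = 0.0) -> Tensor:
    """Pad the last two axes by (top, bottom, left, right)."""
    t, b, l, r = pad
    if t == b == l == r == 0:
        return x
    widths = [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)]
    out = from_op(np.pad(x.data, widths, constant_values=value), (x,), None)
    if out.requires_grad:
        H, W = x.shape[-2], x.shape[-1]

        def bw(g):
            sl = (Ellipsis, slice(t, t + H), slice(l, l + W))
            _acc(x, g[sl])
        out._backward = bw
    return out


def _im2col(xp: np.ndarray, k: int, stride: int, Ho: int, Wo: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> contiguous (B, Ho, Wo, C, k, k) view-copy."""
    B, C, Hp, Wp = xp.shape
    sB, sC, sH, sW = xp.strides
    win = as_strided(
        xp,
        shape=(B, C, Ho, Wo, k, k),
        strides=(sB, sC, sH * stride, sW * stride, sH, sW),
        writeable=False,
    )
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


class Conv2d(Module):
    """2-D convolution via im2col + GEMM; supports depthwise via groups."""

    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 stride=1, padding=None, groups=1, bias=True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        k = kernel_size
        self.k, self.stride, self.groups = k, stride, groups
        self.padding = (k - 1) // 2 if padding is None else padding
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels // groups * k * k
        scale = 1.0 / np.sqrt(fan_in)
        self.weight = _param(rng, (out_channels, in_channels // groups, k, k), scale)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k, s, p, G = self.k, self.stride, self.padding, self.groups
        xd = x.data
        B, C, H, W = xd.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        if k == 1 and s == 1 and p == 0 and G == 1:
            return self._forward_1x1(x)
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd

        Co = self.out_channels
        Cg, Og = C // G, Co // G
        cols = _im2col(xp, k, s, Ho, Wo)                      # (B,Ho,Wo,C,k,k)
        if G == 1:
            mat = cols.reshape(B * Ho * Wo, C * k * k)
            out = mat @ w.data.reshape(Co, -1).T              # (BHoWo, Co)
            out = out.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)
        else:
            colsg = cols.reshape(B, Ho, Wo, G, Cg, k, k)
            wg = w.data.reshape(G, Og, Cg * k * k)
            out = np.einsum("bhwgi,goi->bhwgo",
                            colsg.reshape(B, Ho, Wo, G, Cg * k * k), wg)
            out = out.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)
        if b is not None:
            out = out + b.data[None, :, None, None]

        parents = (x, w) if b is None else (x, w, b)
        res = from_op(out, parents, None)
        if res.requires_grad:
            def bw(g):
                gmat = g.transpose(0, 2, 3, 1)                 # (B,Ho,Wo,Co)
                if b is not None and b.requires_grad:
                    _acc(b, gmat.sum(axis=(0, 1, 2)))
                if G == 1:
                    gm = gmat.reshape(B * Ho * Wo, Co)
                    if w.requires_grad:
                        gw = gm.T @ cols.reshape(B * Ho * Wo, C * k * k)
                        _acc(w, gw.reshape(w.data.shape))
                    if x.requires_grad:
                        gcols = (gm @ w.data.reshape(Co, -1)).reshape(B, Ho, Wo, C, k, k)
                        _acc(x, _col2im(gcols, xp.shape, k, s, p, H, W))
                else:
                    gg = gmat.reshape(B, Ho, Wo, G, Og)
                    colsg = cols.reshape(B, Ho, Wo, G, Cg * k * k)
                    if w.requires_grad:
                        gw = np.einsum("bhwgo,bhwgi->goi", gg, colsg)
                        _acc(w, gw.reshape(w.data.shape))
                    if x.requires_grad:
                        wg = w.data.reshape(G, Og, Cg * k * k)
                        gcols = np.einsum("bhwgo,goi->bhwgi", gg, wg)
                        gcols = gcols.reshape(B, Ho, Wo, C, k, k)
                        _acc(x, _col2im(gcols, xp.shape, k, s, p, H, W))
            res._backward = bw
        return res

    def _forward_1x1(self, x: Tensor) -> Tensor:
        """Pointwise convolution as a plain channel GEMM (no im2col)."""
        w, b = self.weight, self.bias
        xd = x.data
        B, C, H, W = xd.shape
        Co = self.out_channels
        wm = w.data.reshape(Co, C)
        out = np.matmul(wm, xd.reshape(B, C, H * W)).reshape(B, Co, H, W)
        if b is not None:
            out += b.data[None, :, None, None]
        parents = (x, w) if b is None else (x, w, b)
        res = from_op(out, parents, None)
        if res.requires_grad:
            def bw(g):
                gm = g.reshape(B, Co, H * W)
                if b is not None and b.requires_grad:
                    _acc(b, g.sum(axis=(0, 2, 3)))
                if w.requires_grad:
                    gw = np.einsum("bon,bcn->oc", gm, xd.reshape(B, C, H * W))
                    _acc(w, gw.reshape(w.data.shape))
                if x.requires_grad:
                    gx = np.matmul(wm.T, gm).reshape(B, C, H, W)
                    _acc(x, gx)
            res._backward = bw
        return res


def _col2im(gcols: np.ndarray, xp_shape, k: int, s: int, p: int, H: int, W: int) -> np.ndarray:
    B, C = xp_shape[0], xp_shape[1]
    Ho, Wo = gcols.shape[1], gcols.shape[2]
    gxp = np.zeros(xp_shape, dtype=gcols.dtype)
    gt = gcols.transpose(0, 3, 1, 2, 4, 5)                     # (B,C,Ho,Wo,k,k)
    for ki in range(k):
        for kj in range(k):
            gxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += gt[:, :, :, :, ki, kj]
    if p:
        return gxp[:, :, p:p + H, p:p + W]
    return gxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers = {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        xd = x.data
        if self.training:
            mean = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            n = xd.shape[0] * xd.shape[2] * xd.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mean[None, :, None, None]) * invstd[None, :, None, None]
        out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        res = from_op(out_data, (x, gamma, beta), None)
        if res.requires_grad:
            training = self.training

            def bw(g):
                if gamma.requires_grad:
                    _acc(gamma, (g * xhat).sum(axis=(0, 2, 3)))
                if beta.requires_grad:
                    _acc(beta, g.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    gs = g * gamma.data[None, :, None, None]
                    if training:
                        n = g.shape[0] * g.shape[2] * g.shape[3]
                        sum_gs = gs.sum(axis=(0, 2, 3), keepdims=True)
                        sum_gs_xhat = (gs * xhat).sum(axis=(0, 2, 3), keepdims=True)
                        gx = (gs - sum_gs / n - xhat * sum_gs_xhat / n) * invstd[None, :, None, None]
                    else:
                        gx = gs * invstd[None, :, None, None]
                    _acc(x, gx)
            res._backward = bw
        return res


class LayerNorm(Module):
    """Normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        xd = x.data
        mean = xd.mean(axis=-1, keepdims=True)
        var = xd.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mean) * invstd
        out_data = gamma.data * xhat + beta.data
        res = from_op(out_data, (x, gamma, beta), None)
        if res.requires_grad:
            def bw(g):
                if gamma.requires_grad:
                    _acc(gamma, (g * xhat).reshape(-1, xd.shape[-1]).sum(axis=0))
                if beta.requires_grad:
                    _acc(beta, g.reshape(-1, xd.shape[-1]).sum(axis=0))
                if x.requires_grad:
                    n = xd.shape[-1]
                    gs = g * gamma.data
                    gx = (gs - gs.mean(axis=-1, keepdims=True)
                          - xhat * (gs * xhat).mean(axis=-1, keepdims=True)) * invstd
                    _acc(x, gx)
            res._backward = bw
        return res


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.k = kernel_size
        self.stride = stride if stride is not None else kernel_size
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.k, self.stride, self.padding
        xd = x.data
        B, C, H, W = xd.shape
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else xd
        Hp, Wp = xp.shape[-2:]
        Ho = (Hp - k) // s + 1
        Wo = (Wp - k) // s + 1
        sB, sC, sH, sW = xp.strides
        win = as_strided(xp, shape=(B, C, Ho, Wo, k, k),
                         strides=(sB, sC, sH * s, sW * s, sH, sW), writeable=False)
        flat = win.reshape(B, C, Ho, Wo, k * k)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        res = from_op(out_data, (x,), None)
        if res.requires_grad:
            def bw(g):
                gxp = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
                ki, kj = np.divmod(arg, k)
                bi, ci, oi, oj = np.indices(arg.shape)
                np.add.at(gxp, (bi, ci, oi * s + ki, oj * s + kj), g)
                _acc(x, gxp[:, :, p:p + H, p:p + W] if p else gxp)
            res._backward = bw
        return res


def upsample_nearest2x(x: Tensor) -> Tensor:
    xd = x.data
    out = from_op(np.repeat(np.repeat(xd, 2, axis=-2), 2, axis=-1), (x,), None)
    if out.requires_grad:
        B, C, H, W = xd.shape

        def bw(g):
            _acc(x, g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))
        out._backward = bw
    return out


class MultiHeadAttention(Module):
    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % num_heads:
            raise ValueError("dim must be divisible by num_heads")
        self.dim, self.num_heads = dim, num_heads
        self.head_dim = dim // num_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def forward(self, query: Tensor, key: Tensor | None = None, value: Tensor | None = None,
                attn_bias: np.ndarray | None = None) -> Tensor:
        """``attn_bias``: optional additive bias on the attention logits,
        broadcastable to (B, heads, Nq, Nk); e.g. a spatial locality prior."""
        from .tensor import softmax

        key = query if key is None else key
        value = key if value is None else value
        B, Nq, D = query.shape
        Nk = key.shape[1]
        H, Dh = self.num_heads, self.head_dim

        q = self.q_proj(query).reshape(B, Nq, H, Dh).transpose(0, 2, 1, 3)
        k = self.k_proj(key).reshape(B, Nk, H, Dh).transpose(0, 2, 1, 3)
        v = self.v_proj(value).reshape(B, Nk, H, Dh).transpose(0, 2, 1, 3)
        logits = (q @ k.swapaxes(-1, -2)) * float(1.0 / np.sqrt(Dh))
        if attn_bias is not None:
            logits = logits + Tensor(np.asarray(attn_bias, dtype=logits.dtype))
        attn = softmax(logits, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Nq, D)
        return self.out_proj(out)
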