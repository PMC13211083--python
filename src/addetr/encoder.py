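"""Spatial-spectral attentive feature fusion (SSAFF) encoder neck.

Three ideas live here:

* **FTD** (Fourier-transform downsampling): a 2x downsampler that maps a
  feature map to the frequency domain, keeps the centered low-frequency
  quarter of the spectrum, multiplies by a learnable complex filter, and
  inverse-transforms.  Truncation removes all energy above the new
  Nyquist rate, so the operation is anti-aliasing by construction.
* **HA** (hierarchical-aware patch weighting): non-overlapping p x p
  patches are scored by the cosine similarity between their channel
  descriptor and a learned task embedding; each patch is scaled by the
  score (clamped to [0, 1]) and channel-transformed by a learned matrix.
* **MFI** (multi-scale focus integration): attention-based fusion of two
  same-resolution inputs: 1x1 reductions, a 3x3 preliminary fusion, HA
  branches at patch sizes 4 (global) and 2 (local), and a 1x1 ->
  reparameterized-3x3 -> 1x1 integration stage.

The analysis utilities :func:`dft2` / :func:`idft2` use the convention
with the 1/(H W) factor on the forward transform, so the DC coefficient
of a constant image equals that constant.  :func:`freq_conv_oracle`
realizes the convolution theorem (spectral product == circular
convolution) and serves as the module's independent test oracle.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn.tensor import _acc, from_op

__all__ = [
    "dft2",
    "idft2",
    "rdft2_half",
    "complete_half_spectrum",
    "freq_conv_oracle",
    "FTD",
    "ftd_downsample",
    "ha_block",
    "HABlock",
    "RepConv",
    "MFIBlock",
    "AIFI",
    "SSAFFNeck",
    "BaselineNeck",
    "IdentityNeck",
    "build_neck",
]


# ---------------------------------------------------------------------------
# DFT analysis utilities (plain numpy; these are measurement tools, not layers)
# ---------------------------------------------------------------------------

def dft2(x: np.ndarray) -> np.ndarray:
    """2-D DFT with the 1/(H W) forward normalization.

    X[k1,k2] = (1/(H W)) sum_{n,m} x[n,m] exp(-2 pi j (n k1 / H + m k2 / W)).
    A constant input c therefore has X[0,0] == c.
    """
    x = np.asarray(x)
    H, W = x.shape[-2:]
    return np.fft.fft2(x) / (H * W)


def idft2(X: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dft2`; returns the real part."""
    X = np.asarray(X)
    H, W = X.shape[-2:]
    return np.fft.ifft2(X * (H * W)).real


def rdft2_half(x: np.ndarray) -> np.ndarray:
    """Non-redundant half spectrum of a real input (conjugate symmetry
    makes the remaining coefficients redundant)."""
    x = np.asarray(x)
    H, W = x.shape[-2:]
    return np.fft.rfft2(x) / (H * W)


def complete_half_spectrum(Xh: np.ndarray, width: int) -> np.ndarray:
    """Rebuild the full spectrum from the half representation."""
    H = Xh.shape[-2]
    full = np.zeros(Xh.shape[:-2] + (H, width), dtype=complex)
    full[..., : Xh.shape[-1]] = Xh
    # mirror: X[-k1, -k2] = conj(X[k1, k2])
    k1 = (-np.arange(H)) % H
    k2 = (-np.arange(width)) % width
    mirrored = np.conj(full[..., k1[:, None], k2[None, :]])
    missing = np.zeros(full.shape[-1], dtype=bool)
    missing[Xh.shape[-1]:] = True
    full[..., missing] = mirrored[..., missing]
    return full


def freq_conv_oracle(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Convolution theorem: IDFT{ DFT(x) .* FFT(w) } == circular x * w.

    ``x`` carries the normalized transform, ``w`` the unnormalized one, so
    the product inverse-transforms to the plain circular convolution.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {w.shape}")
    return idft2(dft2(x) * np.fft.fft2(w))


# ---------------------------------------------------------------------------
# FTD: spectral 2x downsampling with a learnable complex filter
# ---------------------------------------------------------------------------

def _ftd_apply(x: Tensor, wr: Tensor, wi: Tensor) -> Tensor:
    """Custom autodiff op: fft2 -> centered truncation -> complex filter
    -> ifft2 (real part), scaled so a constant input with the identity
    filter stays that constant (DC preservation).

    The map is linear in x (fixed filter) and linear in the filter (fixed
    x); the backward pass applies the adjoints analytically.
    """
    xd = x.data
    B, C, H, W = xd.shape
    if H % 2 or W % 2:
        raise ValueError(f"FTD needs even spatial dims, got {H}x{W}")
    H2, W2 = H // 2, W // 2
    r0, c0 = (H - H2) // 2, (W - W2) // 2
    scale = (H2 * W2) / (H * W)

    cdtype = np.complex64 if xd.dtype == np.float32 else np.complex128
    Wc = (wr.data + 1j * wi.data).astype(cdtype)      # (C, H2, W2)
    X = np.fft.fft2(xd)
    Xs = np.fft.fftshift(X, axes=(-2, -1))
    T = Xs[..., r0:r0 + H2, c0:c0 + W2]
    Y = Wc[None] * T
    y = scale * np.fft.ifft2(np.fft.ifftshift(Y, axes=(-2, -1))).real

    out = from_op(y, (x, wr, wi), None)
    if out.requires_grad:
        def bw(g):
            # adjoint of scale * Re(ifft2(ifftshift(.)))
            gZ = (scale / (H2 * W2)) * np.fft.fft2(g)
            gY = np.fft.fftshift(gZ, axes=(-2, -1))
            if wr.requires_grad or wi.requires_grad:
                gW = (np.conj(T) * gY).sum(axis=0)
                if wr.requires_grad:
                    _acc(wr, gW.real)
                if wi.requires_grad:
                    _acc(wi, gW.imag)
            if x.requires_grad:
                gT = np.conj(Wc)[None] * gY
                gXs = np.zeros((B, C, H, W), dtype=cdtype)
                gXs[..., r0:r0 + H2, c0:c0 + W2] = gT
                gX = np.fft.ifftshift(gXs, axes=(-2, -1))
                _acc(x, (H * W) * np.fft.ifft2(gX).real)
        out._backward = bw
    return out


class FTD(nn.Module):
    """Fourier-transform downsampling block (2x).

    One learnable complex filter per channel, sized to the truncated
    H/2 x W/2 grid and initialized to the identity (real part 1,
    imaginary part 0) so training starts as a pure anti-aliased
    downsampler.  Filters are created on first use for each spatial size
    encountered (initialization is deterministic, no randomness).
    """

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.filters_real: list[Tensor] = []
        self.filters_imag: list[Tensor] = []
        self._size_index: dict[tuple[int, int], int] = {}

    def _get_filter(self, H: int, W: int) -> tuple[Tensor, Tensor]:
        key = (H // 2, W // 2)
        if key not in self._size_index:
            wr = Tensor(np.ones((self.channels,) + key, dtype=np.float32), requires_grad=True)
            wi = Tensor(np.zeros((self.channels,) + key, dtype=np.float32), requires_grad=True)
            self._size_index[key] = len(self.filters_real)
            self.filters_real.append(wr)
            self.filters_imag.append(wi)
        i = self._size_index[key]
        return self.filters_real[i], self.filters_imag[i]

    def forward(self, x: Tensor) -> Tensor:
        x = nn.as_tensor(x)
        _, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        wr, wi = self._get_filter(H, W)
        return _ftd_apply(x, wr, wi)


def ftd_downsample(x, filt: np.ndarray | None = None) -> np.ndarray:
    """Functional FTD on a numpy feature map (H, W, C) or (B, C, H, W).

    ``filt`` is the complex filter over the truncated grid (broadcastable
    to (C, H/2, W/2)); the default is the identity filter.
    """
    arr = np.asarray(x, dtype=float)
    squeeze = False
    if arr.ndim == 3:                                  # (H, W, C) convention
        arr = arr.transpose(2, 0, 1)[None]
        squeeze = True
    B, C, H, W = arr.shape
    wr = np.ones((C, H // 2, W // 2)) if filt is None else np.real(filt) * np.ones((C, H // 2, W // 2))
    wi = np.zeros((C, H // 2, W // 2)) if filt is None else np.imag(filt) * np.ones((C, H // 2, W // 2))
    out = _ftd_apply(Tensor(arr), Tensor(wr), Tensor(wi)).data
    if squeeze:
        return out[0].transpose(1, 2, 0)
    return out


# ---------------------------------------------------------------------------
# HA: hierarchical-aware patch weighting
# ---------------------------------------------------------------------------

def ha_block(f, xi, p: int, P, sim_override=None, eps: float = 1e-8) -> Tensor:
    """Score p x p patches against a task embedding and reweight them.

    The patch descriptor t_i is the channel-wise mean over the tile (a
    C-vector), scored by cosine similarity against ``xi`` and clamped to
    [0, 1]; every pixel of the patch is scaled by the score and the
    channels are transformed by ``P``.  Patches tile the map exactly, so
    recombination is lossless; with score 1 and P = I the block is the
    identity map.

    ``sim_override`` replaces the computed scores by a constant (used by
    ablation and identity tests).
    """
    f = nn.as_tensor(f)
    xi = nn.as_tensor(xi)
    P = nn.as_tensor(P)
    B, C, H, W = f.shape
    if H % p or W % p:
        raise ValueError(f"spatial dims {H}x{W} not divisible by patch size {p}")
    Hp, Wp = H // p, W // p

    if sim_override is None:
        t = f.reshape(B, C, Hp, p, Wp, p).mean(axis=(3, 5))       # (B,C,Hp,Wp)
        num = (t * xi.reshape(1, C, 1, 1)).sum(axis=1)            # (B,Hp,Wp)
        t_norm = ((t * t).sum(axis=1) + eps).sqrt()
        xi_norm = ((xi * xi).sum() + eps).sqrt()
        sim = nn.minimum(nn.maximum(num / (t_norm * xi_norm), 0.0), 1.0)
    else:
        sim = nn.as_tensor(np.full((B, Hp, Wp), float(sim_override)))

    # broadcast each patch score over its p x p tile
    sim_up = (sim.reshape(B, 1, Hp, 1, Wp, 1)
              * nn.as_tensor(np.ones((1, 1, 1, p, 1, p), dtype=sim.dtype))).reshape(B, 1, H, W)
    scaled = f * sim_up
    # channel transform: out[c'] = sum_c P[c', c] scaled[c]
    out = (scaled.transpose(0, 2, 3, 1) @ P.swapaxes(-1, -2)).transpose(0, 3, 1, 2)
    return out


class HABlock(nn.Module):
    """Module wrapper holding the task embedding xi and channel matrix P."""

    def __init__(self, channels: int, patch_size: int, rng: np.random.Generator):
        super().__init__()
        self.patch_size = patch_size
        self.xi = Tensor(rng.normal(0.0, 1.0 / np.sqrt(channels), size=channels).astype(np.float32),
                         requires_grad=True)
        self.P = Tensor((np.eye(channels) + rng.normal(0.0, 0.01, size=(channels, channels))).astype(np.float32),
                        requires_grad=True)

    def forward(self, f: Tensor, sim_override=None) -> Tensor:
        return ha_block(f, self.xi, self.patch_size, self.P, sim_override=sim_override)


# ---------------------------------------------------------------------------
# Building blocks shared with the backbone
# ---------------------------------------------------------------------------

class ConvBNAct(nn.Module):
    """3x3/1x1 convolution + batch norm + SiLU (the block convention)."""

    def __init__(self, cin, cout, k, rng, stride=1, groups=1, padding=None, act=True):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, rng, stride=stride, padding=padding,
                              groups=groups, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


class RepConv(nn.Module):
    """Reparameterizable 3x3 convolution (RepVGG style).

    Training runs three parallel branches (3x3+BN, 1x1+BN, identity BN
    when shapes permit) summed before the activation; :meth:`fuse` merges
    them algebraically into a single 3x3 convolution for deployment.
    Branch-merge equivalence (eval mode) is unit-tested.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.conv3 = nn.Conv2d(cin, cout, 3, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(cout)
        self.conv1 = nn.Conv2d(cin, cout, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.bnid = nn.BatchNorm2d(cout) if cin == cout else None
        self.deploy_conv: nn.Conv2d | None = None

    def forward(self, x):
        if self.deploy_conv is not None:
            return self.deploy_conv(x).silu()
        y = self.bn3(self.conv3(x)) + self.bn1(self.conv1(x))
        if self.bnid is not None:
            y = y + self.bnid(x)
        return y.silu()

    @staticmethod
    def _fold(kernel: np.ndarray, bn: nn.BatchNorm2d) -> tuple[np.ndarray, np.ndarray]:
        std = np.sqrt(bn.running_var + bn.eps)
        scale = bn.gamma.data / std
        return kernel * scale[:, None, None, None], bn.beta.data - bn.running_mean * scale

    def fuse(self) -> None:
        """Merge the branches into one 3x3 conv (idempotent)."""
        if self.deploy_conv is not None:
            return
        k3, b3 = self._fold(self.conv3.weight.data, self.bn3)
        k1, b1 = self._fold(self.conv1.weight.data, self.bn1)
        k1pad = np.zeros_like(k3)
        k1pad[:, :, 1:2, 1:2] = k1
        kernel, bias = k3 + k1pad, b3 + b1
        if self.bnid is not None:
            kid = np.zeros_like(k3)
            kid[np.arange(self.cout), np.arange(self.cin), 1, 1] = 1.0
            kf, bf = self._fold(kid, self.bnid)
            kernel, bias = kernel + kf, bias + bf
        conv = nn.Conv2d(self.cin, self.cout, 3, np.random.default_rng(0), bias=True)
        conv.weight.data = kernel
        conv.bias.data = bias
        self.deploy_conv = conv


class MFIBlock(nn.Module):
    """Multi-scale focus integration: attention fusion of two inputs.

    1x1 reductions -> concat -> 3x3 preliminary fusion (baseline) -> HA
    branches at the configured patch sizes -> 1x1 / reparameterized 3x3 /
    1x1 integration.
    """

    def __init__(self, c1: int, c2: int, c_out: int, rng: np.random.Generator,
                 c_mid: int | None = None, p_sizes=(4, 2)):
        super().__init__()
        c_mid = c_mid or c_out
        self.red1 = ConvBNAct(c1, c_mid, 1, rng)
        self.red2 = ConvBNAct(c2, c_mid, 1, rng)
        self.fuse = ConvBNAct(2 * c_mid, c_mid, 3, rng)
        self.ha_branches = [HABlock(c_mid, p, rng) for p in p_sizes]
        self.integrate_in = ConvBNAct((1 + len(self.ha_branches)) * c_mid, c_mid, 1, rng)
        self.rep = RepConv(c_mid, c_mid, rng)
        self.integrate_out = ConvBNAct(c_mid, c_out, 1, rng)

    def forward(self, f1: Tensor, f2: Tensor) -> Tensor:
        if f1.shape[-2:] != f2.shape[-2:]:
            raise ValueError(f"spatial mismatch {f1.shape} vs {f2.shape}")
        base = self.fuse(nn.concat([self.red1(f1), self.red2(f2)], axis=1))
        feats = [base] + [ha(base) for ha in self.ha_branches]
        x = self.integrate_in(nn.concat(feats, axis=1))
        return self.integrate_out(self.rep(x))


def sincos_position_embedding(H: int, W: int, dim: int, temperature: float = 10000.0) -> np.ndarray:
    """2-D sine/cosine positional embedding, (H*W, dim)."""
    if dim % 4:
        raise ValueError("embedding dim must be divisible by 4")
    gy, gx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    d4 = dim // 4
    omega = 1.0 / temperature ** (np.arange(d4) / d4)
    out = np.concatenate([
        np.sin(gx.reshape(-1, 1) * omega),
        np.cos(gx.reshape(-1, 1) * omega),
        np.sin(gy.reshape(-1, 1) * omega),
        np.cos(gy.reshape(-1, 1) * omega),
    ], axis=1)
    return out.astype(np.float32)


class AIFI(nn.Module):
    """Intra-scale self-attention on the deepest level (hybrid-encoder
    convention): one post-norm transformer layer over the S5 tokens."""

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator, ffn_mult: int = 2):
        super().__init__()
        self.dim = dim
        self.attn = nn.MultiHeadAttention(dim, num_heads, rng)
        self.norm1 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, ffn_mult * dim, rng)
        self.fc2 = nn.Linear(ffn_mult * dim, dim, rng)
        self.norm2 = nn.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        tokens = x.reshape(B, C, H * W).transpose(0, 2, 1)
        pos = nn.as_tensor(sincos_position_embedding(H, W, self.dim))
        t = tokens + pos
        t = self.norm1(t + self.attn(t))
        t = self.norm2(t + self.fc2(self.fc1(t).silu()))
        return t.transpose(0, 2, 1).reshape(B, C, H, W)


# ---------------------------------------------------------------------------
# Neck assemblies
# ---------------------------------------------------------------------------

class SSAFFNeck(nn.Module):
    """Hybrid-encoder feature-fusion path with MFI fusion and FTD
    downsampling.

    Top-down: P5 = AIFI(lat(S5)); P4 = MFI(lat(S4), up(P5));
              P3 = MFI(lat(S3), up(P4)).
    Bottom-up: N4 = MFI(P4, FTD(P3)); N5 = MFI(P5, FTD(N4)).
    Emits (P3, N4, N5) at strides 8/16/32 with a common channel width.
    """

    def __init__(self, in_channels: tuple[int, int, int], dim: int,
                 rng: np.random.Generator, p_sizes=(4, 2), num_heads: int = 4):
        super().__init__()
        c3, c4, c5 = in_channels
        self.lat3 = ConvBNAct(c3, dim, 1, rng)
        self.lat4 = ConvBNAct(c4, dim, 1, rng)
        self.lat5 = ConvBNAct(c5, dim, 1, rng)
        self.aifi = AIFI(dim, num_heads, rng)
        # patch sizes per level: a stride-8 map of a 32k input is 4k x 4k
        # (all configured sizes divide), stride 16 is 2k x 2k (p <= 2),
        # stride 32 is k x k (no patching guarantee -> baseline path only)
        p_hi = tuple(p_sizes)
        p_mid = tuple(p for p in p_sizes if p <= 2)
        self.td4 = MFIBlock(dim, dim, dim, rng, p_sizes=p_mid)
        self.td3 = MFIBlock(dim, dim, dim, rng, p_sizes=p_hi)
        self.ftd3 = FTD(dim)
        self.bu4 = MFIBlock(dim, dim, dim, rng, p_sizes=p_mid)
        self.ftd4 = FTD(dim)
        self.bu5 = MFIBlock(dim, dim, dim, rng, p_sizes=())

    def forward(self, pyramid: dict[int, Tensor]) -> dict[int, Tensor]:
        s3, s4, s5 = pyramid[8], pyramid[16], pyramid[32]
        p5 = self.aifi(self.lat5(s5))
        p4 = self.td4(self.lat4(s4), nn.upsample_nearest2x(p5))
        p3 = self.td3(self.lat3(s3), nn.upsample_nearest2x(p4))
        n4 = self.bu4(p4, self.ftd3(p3))
        n5 = self.bu5(p5, self.ftd4(n4))
        return {8: p3, 16: n4, 32: n5}


class BaselineNeck(nn.Module):
    """Plain hybrid-encoder path: concat+conv fusion and strided-conv
    downsampling (the configuration the SSAFF blocks replace)."""

    def __init__(self, in_channels: tuple[int, int, int], dim: int,
                 rng: np.random.Generator, num_heads: int = 4):
        super().__init__()
        c3, c4, c5 = in_channels
        self.lat3 = ConvBNAct(c3, dim, 1, rng)
        self.lat4 = ConvBNAct(c4, dim, 1, rng)
        self.lat5 = ConvBNAct(c5, dim, 1, rng)
        self.aifi = AIFI(dim, num_heads, rng)
        self.td4 = ConvBNAct(2 * dim, dim, 3, rng)
        self.td3 = ConvBNAct(2 * dim, dim, 3, rng)
        self.down3 = ConvBNAct(dim, dim, 3, rng, stride=2)
        self.bu4 = ConvBNAct(2 * dim, dim, 3, rng)
        self.down4 = ConvBNAct(dim, dim, 3, rng, stride=2)
        self.bu5 = ConvBNAct(2 * dim, dim, 3, rng)

    def forward(self, pyramid: dict[int, Tensor]) -> dict[int, Tensor]:
        s3, s4, s5 = pyramid[8], pyramid[16], pyramid[32]
        p5 = self.aifi(self.lat5(s5))
        p4 = self.td4(nn.concat([self.lat4(s4), nn.upsample_nearest2x(p5)], axis=1))
        p3 = self.td3(nn.concat([self.lat3(s3), nn.upsample_nearest2x(p4)], axis=1))
        n4 = self.bu4(nn.concat([p4, self.down3(p3)], axis=1))
        n5 = self.bu5(nn.concat([p5, self.down4(n4)], axis=1))
        return {8: p3, 16: n4, 32: n5}


class IdentityNeck(nn.Module):
    """Lateral projections only (ablation switch: no cross-scale fusion)."""

    def __init__(self, in_channels: tuple[int, int, int], dim: int,
                 rng: np.random.Generator):
        super().__init__()
        c3, c4, c5 = in_channels
        self.lat3 = ConvBNAct(c3, dim, 1, rng)
        self.lat4 = ConvBNAct(c4, dim, 1, rng)
        self.lat5 = ConvBNAct(c5, dim, 1, rng)

    def forward(self, pyramid: dict[int, Tensor]) -> dict[int, Tensor]:
        return {8: self.lat3(pyramid[8]), 16: self.lat4(pyramid[16]),
                32: self.lat5(pyramid[32])}


def build_neck(kind: str, in_channels, dim, rng, p_sizes=(4, 2)):
    if kind == "ssaff":
        return SSAFFNeck(tuple(in_channels), dim, rng, p_sizes=tuple(p_sizes))
    if kind == "baseline":
        return BaselineNeck(tuple(in_channels), dim, rng)
    if kind == "identity":
        return IdentityNeck(tuple(in_channels), dim, rng)
    raise ValueError(f"unknown neck kind {kind!r}")
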