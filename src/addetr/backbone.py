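"""MSANet feature extractor.

A stride-4 HGStem, three DWConv+C2f stages (strides 8/16/32), and AFA
(adapt-fusion-align) blocks joining adjacent stages.  AFA projects two
feature maps into a common channel space (1x1 convs), derives
spatially-varying gates from their concatenation (3x3 conv + sigmoid,
split channel-wise), and mixes the gated branches with two learnable
coefficients constrained to the simplex: lambda_1 + lambda_2 = 1 with
both in [0, 1], enforced by construction through a softmax over two
logits and initialized at 0.5 / 0.5.

Stage widths and depths are configuration-driven; the defaults are a
small profile suitable for CPU training at modest resolutions.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .encoder import ConvBNAct
from .nn import Tensor

__all__ = ["AFA", "HGStem", "C2f", "DWSepConv", "MSANet", "BaselineBackbone", "build_backbone"]


class HGStem(nn.Module):
    """Low-level stem: two stride-2 steps with a parallel max-pool branch
    (PPHGNet convention); output stride 4."""

    def __init__(self, cin: int, cm: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.stem1 = ConvBNAct(cin, cm, 3, rng, stride=2)
        self.stem2a = ConvBNAct(cm, cm // 2, 2, rng, padding=0)
        self.stem2b = ConvBNAct(cm // 2, cm, 2, rng, padding=0)
        self.stem3 = ConvBNAct(2 * cm, cm, 3, rng, stride=2)
        self.stem4 = ConvBNAct(cm, cout, 1, rng)
        self.pool = nn.MaxPool2d(2, stride=1)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem1(x)
        xp = nn.pad2d(x, (0, 1, 0, 1))
        x2 = self.stem2b(nn.pad2d(self.stem2a(xp), (0, 1, 0, 1)))
        x1 = self.pool(xp)
        return self.stem4(self.stem3(nn.concat([x1, x2], axis=1)))


class Bottleneck(nn.Module):
    def __init__(self, c: int, rng: np.random.Generator, shortcut: bool = True):
        super().__init__()
        self.cv1 = ConvBNAct(c, c, 3, rng)
        self.cv2 = ConvBNAct(c, c, 3, rng)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(nn.Module):
    """Cross-stage partial block with n bottlenecks; all intermediate
    outputs are concatenated before the final 1x1 projection."""

    def __init__(self, cin: int, cout: int, n: int, rng: np.random.Generator,
                 shortcut: bool = True):
        super().__init__()
        self.c = cout // 2
        self.cv1 = ConvBNAct(cin, 2 * self.c, 1, rng)
        self.blocks = [Bottleneck(self.c, rng, shortcut) for _ in range(n)]
        self.cv2 = ConvBNAct((2 + n) * self.c, cout, 1, rng)

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, : self.c], y[:, self.c:]
        outs = [a, b]
        for blk in self.blocks:
            outs.append(blk(outs[-1]))
        return self.cv2(nn.concat(outs, axis=1))


class DWSepConv(nn.Module):
    """Depthwise-separable convolution: depthwise 3x3 + pointwise 1x1."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, stride: int = 1):
        super().__init__()
        self.dw = ConvBNAct(cin, cin, 3, rng, stride=stride, groups=cin)
        self.pw = ConvBNAct(cin, cout, 1, rng)

    def forward(self, x):
        return self.pw(self.dw(x))


class AFA(nn.Module):
    """Adapt-fusion-align block.

    forward(x1, x2) with equal spatial dims (the caller upsamples the
    lower-resolution input beforehand):

    1. 1x1 channel projections into a common width;
    2. concat -> 3x3 gate conv -> sigmoid -> channel split into w1, w2;
    3. output = lambda_1 (w1 . x1_hat) + lambda_2 (w2 . x2_hat), with
       (lambda_1, lambda_2) = softmax(branch_logits); a final 1x1
       projection matches the downstream channel count.
    """

    def __init__(self, c1: int, c2: int, c_common: int, c_out: int,
                 rng: np.random.Generator):
        super().__init__()
        self.proj1 = nn.Conv2d(c1, c_common, 1, rng)
        self.proj2 = nn.Conv2d(c2, c_common, 1, rng)
        self.gate = nn.Conv2d(2 * c_common, 2 * c_common, 3, rng)
        self.branch_logits = Tensor(np.zeros(2, dtype=np.float32), requires_grad=True)  # lambdas start at 0.5/0.5
        self.out_proj = ConvBNAct(c_common, c_out, 1, rng)
        self.c_common = c_common

    @property
    def lambdas(self) -> np.ndarray:
        z = self.branch_logits.data.astype(np.float64)
        e = np.exp(z - z.max())
        return e / e.sum()

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        if x1.shape[-2:] != x2.shape[-2:]:
            raise ValueError(f"spatial mismatch {x1.shape} vs {x2.shape}")
        if x1.shape[0] != x2.shape[0]:
            raise ValueError("batch mismatch")
        h1, h2 = self.proj1(x1), self.proj2(x2)
        w_align = self.gate(nn.concat([h1, h2], axis=1)).sigmoid()
        w1, w2 = w_align[:, : self.c_common], w_align[:, self.c_common:]
        lam = nn.softmax(self.branch_logits, axis=0)
        fused = lam[0] * (w1 * h1) + lam[1] * (w2 * h2)
        return self.out_proj(fused)


class MSANet(nn.Module):
    """Backbone emitting a stride 8/16/32 pyramid with AFA fusion between
    adjacent stages (S3 <- AFA(C3, up C4); S4 <- AFA(C4, up C5))."""

    def __init__(self, rng: np.random.Generator,
                 widths: tuple[int, int, int, int, int] = (16, 24, 32, 48, 64),
                 depths: tuple[int, int, int] = (1, 1, 1),
                 afa_common: int | None = None):
        super().__init__()
        cm, c2, c3, c4, c5 = widths
        self.stem = HGStem(3, cm, c2, rng)
        self.down3 = DWSepConv(c2, c3, rng, stride=2)
        self.stage3 = C2f(c3, c3, depths[0], rng)
        self.down4 = DWSepConv(c3, c4, rng, stride=2)
        self.stage4 = C2f(c4, c4, depths[1], rng)
        self.down5 = DWSepConv(c4, c5, rng, stride=2)
        self.stage5 = C2f(c5, c5, depths[2], rng)
        common34 = afa_common or c3
        common45 = afa_common or c4
        self.afa34 = AFA(c3, c4, common34, c3, rng)
        self.afa45 = AFA(c4, c5, common45, c4, rng)
        self.out_channels = (c3, c4, c5)

    def forward(self, x: Tensor) -> dict[int, Tensor]:
        H, W = x.shape[-2:]
        if H % 32 or W % 32:
            raise ValueError(f"input dims must be divisible by 32, got {H}x{W}")
        s = self.stem(x)
        c3 = self.stage3(self.down3(s))
        c4 = self.stage4(self.down4(c3))
        c5 = self.stage5(self.down5(c4))
        s3 = self.afa34(c3, nn.upsample_nearest2x(c4))
        s4 = self.afa45(c4, nn.upsample_nearest2x(c5))
        return {8: s3, 16: s4, 32: c5}


class BasicBlock(nn.Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, stride: int = 1):
        super().__init__()
        self.cv1 = ConvBNAct(cin, cout, 3, rng, stride=stride)
        self.cv2 = ConvBNAct(cout, cout, 3, rng, act=False)
        self.short = (None if stride == 1 and cin == cout
                      else ConvBNAct(cin, cout, 1, rng, stride=stride, act=False))

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        sc = x if self.short is None else self.short(x)
        return (y + sc).silu()


class BaselineBackbone(nn.Module):
    """Plain residual CNN (ResNet-style) used as the non-MSANet baseline;
    its default widths are deliberately heavier, mirroring the parameter
    reduction the aligned backbone provides."""

    def __init__(self, rng: np.random.Generator,
                 widths: tuple[int, int, int, int] = (32, 48, 72, 104),
                 blocks_per_stage: int = 2):
        super().__init__()
        c2, c3, c4, c5 = widths
        self.stem = nn.Sequential(ConvBNAct(3, c2 // 2, 3, rng, stride=2),
                                  ConvBNAct(c2 // 2, c2, 3, rng, stride=2))
        def stage(cin, cout):
            layers = [BasicBlock(cin, cout, rng, stride=2)]
            layers += [BasicBlock(cout, cout, rng) for _ in range(blocks_per_stage - 1)]
            return nn.Sequential(*layers)
        self.stage3 = stage(c2, c3)
        self.stage4 = stage(c3, c4)
        self.stage5 = stage(c4, c5)
        self.out_channels = (c3, c4, c5)

    def forward(self, x: Tensor) -> dict[int, Tensor]:
        H, W = x.shape[-2:]
        if H % 32 or W % 32:
            raise ValueError(f"input dims must be divisible by 32, got {H}x{W}")
        s = self.stem(x)
        c3 = self.stage3(s)
        c4 = self.stage4(c3)
        c5 = self.stage5(c4)
        return {8: c3, 16: c4, 32: c5}


def build_backbone(kind: str, rng: np.random.Generator, **kwargs):
    if kind == "msanet":
        return MSANet(rng, **kwargs)
    if kind == "baseline":
        return BaselineBackbone(rng, **kwargs)
    raise ValueError(f"unknown backbone kind {kind!r}")
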