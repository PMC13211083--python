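"""IoU-family bounding-box regression losses.

The package's core regression loss is IPIoUv2, built from three pieces:

* an edge-distance penalty ``p`` normalized by the ground-truth width and
  height, which is zero iff the two boxes coincide;
* a non-monotonic focal weight ``u(lambda * q)`` with ``q = exp(-p)`` and
  ``u(x) = 3 x exp(-x^2)``, which down-weights both very easy and very
  hard pairs;
* an inner IoU computed on auxiliary boxes that share the originals'
  centers with widths and heights scaled by ``gamma`` (< 1 makes the
  overlap criterion stricter).

The combined loss is ``u(lambda q) * (2 - exp(-p^2) - IoU_inner)``.

All operations accept a single box pair (``BoxCWH`` or a 4-sequence,
returning a float) or aligned arrays of shape (..., 4).  Loss operations
take a ``reduction`` parameter for batched use.  The functions also run
on :class:`addetr.nn.Tensor` inputs, in which case gradients flow to the
predicted boxes; degenerate widths/heights are epsilon-clamped on that
path instead of raising, to keep training robust.

The GIoU/DIoU/CIoU/EIoU/SIoU/WIoU baselines at the bottom implement
external formulas from their original publications; they exist only so
the loss-comparison harness can benchmark against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _ops as ops
from .boxes import BoxCWH, InvalidBoxError, as_box_array

__all__ = [
    "LossConfig",
    "iou",
    "piou_penalty",
    "piou_loss",
    "piouv2_loss",
    "inner_iou",
    "ipiouv2_loss",
    "regression_loss",
    "REGRESSION_LOSSES",
]


@dataclass
class LossConfig:
    """Hyperparameters of the IPIoUv2 family.

    lambda_ : focal penalty-strength scalar (default 1.3).
    gamma   : inner-box scale factor (default 0.7).
    eps     : numerical floor for divisions and width/height clamping.
    """

    lambda_: float = 1.3
    gamma: float = 0.7
    eps: float = 1e-7

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _prepare(pred, gt, clamp: bool):
    """Coerce inputs; returns (pred, gt, scalar_pair) with validation."""
    scalar = isinstance(pred, BoxCWH) or (not ops.is_tensor(pred) and np.asarray(pred).ndim == 1)
    if ops.is_tensor(pred) or ops.is_tensor(gt):
        if not ops.is_tensor(pred):
            pred = np.asarray(pred, dtype=float)
        if not ops.is_tensor(gt):
            gt = np.asarray(gt, dtype=float)
        return pred, gt, False
    pred = as_box_array(pred, validate=not clamp)
    gt = as_box_array(gt, validate=not clamp)
    return pred, gt, scalar


def _wh(b, eps: float):
    w = ops.maximum(b[..., 2], eps)
    h = ops.maximum(b[..., 3], eps)
    return w, h


def _edges(b, eps: float):
    xc, yc = b[..., 0], b[..., 1]
    w, h = _wh(b, eps)
    return xc - w * 0.5, xc + w * 0.5, yc - h * 0.5, yc + h * 0.5, w, h


def _iou_core(a, b, eps: float):
    al, ar, at, ab, aw, ah = _edges(a, eps)
    bl, br, bt, bb, bw, bh = _edges(b, eps)
    iw = ops.maximum(ops.minimum(ar, br) - ops.maximum(al, bl), 0.0)
    ih = ops.maximum(ops.minimum(ab, bb) - ops.maximum(at, bt), 0.0)
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    return inter / ops.maximum(union, eps)


def _reduce(x, reduction: str):
    if reduction == "none":
        return x
    if reduction == "mean":
        return ops.mean(x)
    if reduction == "sum":
        return ops.sum_(x)
    raise ValueError(f"unknown reduction {reduction!r}")


def _finish(x, scalar: bool, reduction: str = "none"):
    if scalar and not ops.is_tensor(x):
        return float(x)
    return _reduce(x, reduction)


def iou(a, b, eps: float = 1e-12, clamp: bool = False):
    """Intersection over union; symmetric, in [0, 1]."""
    a, b, scalar = _prepare(a, b, clamp)
    return _finish(_iou_core(a, b, eps), scalar)


def piou_penalty(pred, gt, eps: float = 1e-7, clamp: bool = False):
    """Edge-distance penalty p >= 0; zero iff the boxes coincide.

    p = 1/4 (dw1/wgt + dw2/wgt + dh1/hgt + dh2/hgt) where dw1/dw2 are
    the absolute left/right edge distances between predicted and
    ground-truth boxes and dh1/dh2 the top/bottom ones.
    """
    pred, gt, scalar = _prepare(pred, gt, clamp)
    pl, pr, pt, pb, _, _ = _edges(pred, eps)
    gl, gr, gt_, gb, gw, gh = _edges(gt, eps)
    p = 0.25 * (
        ops.abs_(pl - gl) / gw + ops.abs_(pr - gr) / gw
        + ops.abs_(pt - gt_) / gh + ops.abs_(pb - gb) / gh
    )
    return _finish(p, scalar)


def piou_loss(pred, gt, eps: float = 1e-7, clamp: bool = False, reduction: str = "none"):
    """L_PIoU = (1 - IoU) + 1 - exp(-p^2); bounded in [0, 2]."""
    pred, gt, scalar = _prepare(pred, gt, clamp)
    p = piou_penalty(pred, gt, eps=eps, clamp=True)
    loss = (1.0 - _iou_core(pred, gt, eps)) + 1.0 - ops.exp(-(p * p))
    return _finish(loss, scalar, reduction)


def _focal_weight(p, lambda_: float):
    """u(lambda q) with q = exp(-p) in (0, 1] and u(x) = 3 x exp(-x^2)."""
    q = ops.exp(-p)
    x = lambda_ * q
    return 3.0 * x * ops.exp(-(x * x))


def piouv2_loss(pred, gt, cfg: LossConfig | None = None, clamp: bool = False,
                reduction: str = "none"):
    """Focal-reweighted PIoU: u(lambda q) * L_PIoU."""
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    p = piou_penalty(pred, gt, eps=cfg.eps, clamp=True)
    lp = (1.0 - _iou_core(pred, gt, cfg.eps)) + 1.0 - ops.exp(-(p * p))
    loss = _focal_weight(p, cfg.lambda_) * lp
    return _finish(loss, scalar, reduction)


def inner_iou(pred, gt, gamma: float = 0.7, eps: float = 1e-12, clamp: bool = False):
    """IoU of auxiliary boxes: same centers, widths/heights scaled by gamma.

    The auxiliary intersection is clamped at zero when the scaled boxes
    are disjoint; the union uses the scaled areas gamma^2 (w h).
    With gamma = 1 this is exactly the plain IoU.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    pred, gt, scalar = _prepare(pred, gt, clamp)
    pw, ph = _wh(pred, eps)
    gw, gh = _wh(gt, eps)
    pxc, pyc = pred[..., 0], pred[..., 1]
    gxc, gyc = gt[..., 0], gt[..., 1]

    bl, br = pxc - pw * (gamma / 2), pxc + pw * (gamma / 2)
    bt, bb = pyc - ph * (gamma / 2), pyc + ph * (gamma / 2)
    blg, brg = gxc - gw * (gamma / 2), gxc + gw * (gamma / 2)
    btg, bbg = gyc - gh * (gamma / 2), gyc + gh * (gamma / 2)

    iw = ops.maximum(ops.minimum(brg, br) - ops.maximum(blg, bl), 0.0)
    ih = ops.maximum(ops.minimum(bbg, bb) - ops.maximum(btg, bt), 0.0)
    inter = iw * ih
    union = (gw * gh) * gamma ** 2 + (pw * ph) * gamma ** 2 - inter
    return _finish(inter / ops.maximum(union, eps), scalar)


def ipiouv2_loss(pred, gt, cfg: LossConfig | None = None, clamp: bool = False,
                 reduction: str = "none"):
    """IPIoUv2: u(lambda q) * (2 - exp(-p^2) - IoU_inner).

    Zero iff pred == gt; differentiable in pred's four fields wherever
    the boxes are non-degenerate.
    """
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    p = piou_penalty(pred, gt, eps=cfg.eps, clamp=True)
    inner = inner_iou(pred, gt, gamma=cfg.gamma, eps=cfg.eps, clamp=True)
    loss = _focal_weight(p, cfg.lambda_) * (2.0 - ops.exp(-(p * p)) - inner)
    return _finish(loss, scalar, reduction)


# ---------------------------------------------------------------------------
# Baseline losses (external formulas, benchmarking plumbing only).
# Implemented from the original publications: GIoU (Rezatofighi et al. 2019),
# DIoU/CIoU (Zheng et al. 2020), EIoU (Zhang et al. 2022), SIoU (Gevorgyan
# 2022), WIoU v1 (Tong et al. 2023).
# ---------------------------------------------------------------------------


def _enclose(pred, gt, eps):
    pl, pr, pt, pb, pw, ph = _edges(pred, eps)
    gl, gr, gt_, gb, gw, gh = _edges(gt, eps)
    cw = ops.maximum(pr, gr) - ops.minimum(pl, gl)
    ch = ops.maximum(pb, gb) - ops.minimum(pt, gt_)
    return cw, ch


def giou_loss(pred, gt, cfg=None, clamp=False, reduction="none"):
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    i = _iou_core(pred, gt, cfg.eps)
    pw, ph = _wh(pred, cfg.eps)
    gw, gh = _wh(gt, cfg.eps)
    cw, ch = _enclose(pred, gt, cfg.eps)
    # enclosing area minus union, over enclosing area
    pl, pr, pt, pb, _, _ = _edges(pred, cfg.eps)
    gl, gr, gt_, gb, _, _ = _edges(gt, cfg.eps)
    iw = ops.maximum(ops.minimum(pr, gr) - ops.maximum(pl, gl), 0.0)
    ih = ops.maximum(ops.minimum(pb, gb) - ops.maximum(pt, gt_), 0.0)
    union = pw * ph + gw * gh - iw * ih
    area_c = ops.maximum(cw * ch, cfg.eps)
    loss = 1.0 - i + (area_c - union) / area_c
    return _finish(loss, scalar, reduction)


def _center_dist2(pred, gt):
    dx = pred[..., 0] - gt[..., 0]
    dy = pred[..., 1] - gt[..., 1]
    return dx * dx + dy * dy


def diou_loss(pred, gt, cfg=None, clamp=False, reduction="none"):
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    i = _iou_core(pred, gt, cfg.eps)
    cw, ch = _enclose(pred, gt, cfg.eps)
    c2 = ops.maximum(cw * cw + ch * ch, cfg.eps)
    loss = 1.0 - i + _center_dist2(pred, gt) / c2
    return _finish(loss, scalar, reduction)


def ciou_loss(pred, gt, cfg=None, clamp=False, reduction="none"):
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    i = _iou_core(pred, gt, cfg.eps)
    cw, ch = _enclose(pred, gt, cfg.eps)
    c2 = ops.maximum(cw * cw + ch * ch, cfg.eps)
    pw, ph = _wh(pred, cfg.eps)
    gw, gh = _wh(gt, cfg.eps)
    v = (4.0 / np.pi ** 2) * (ops.arctan(gw / gh) - ops.arctan(pw / ph)) ** 2
    alpha = ops.detach(v / ops.maximum(1.0 - i + v, cfg.eps))
    loss = 1.0 - i + _center_dist2(pred, gt) / c2 + alpha * v
    return _finish(loss, scalar, reduction)


def eiou_loss(pred, gt, cfg=None, clamp=False, reduction="none"):
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    i = _iou_core(pred, gt, cfg.eps)
    cw, ch = _enclose(pred, gt, cfg.eps)
    c2 = ops.maximum(cw * cw + ch * ch, cfg.eps)
    pw, ph = _wh(pred, cfg.eps)
    gw, gh = _wh(gt, cfg.eps)
    loss = (1.0 - i + _center_dist2(pred, gt) / c2
            + (pw - gw) ** 2 / ops.maximum(cw * cw, cfg.eps)
            + (ph - gh) ** 2 / ops.maximum(ch * ch, cfg.eps))
    return _finish(loss, scalar, reduction)


def siou_loss(pred, gt, cfg=None, clamp=False, reduction="none"):
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    i = _iou_core(pred, gt, cfg.eps)
    dx = gt[..., 0] - pred[..., 0]
    dy = gt[..., 1] - pred[..., 1]
    sigma = ops.sqrt(dx * dx + dy * dy + cfg.eps)
    sin_alpha = ops.clip(ops.abs_(dy) / sigma, -1.0 + 1e-9, 1.0 - 1e-9)
    # angle cost peaks at 45 degrees: Lambda = sin(2 * arcsin(sin_alpha))
    angle = ops.sin(2.0 * ops.arcsin(sin_alpha))
    cw, ch = _enclose(pred, gt, cfg.eps)
    rho_x = (dx / ops.maximum(cw, cfg.eps)) ** 2
    rho_y = (dy / ops.maximum(ch, cfg.eps)) ** 2
    gamma_s = 2.0 - angle
    dist = (1.0 - ops.exp(-gamma_s * rho_x)) + (1.0 - ops.exp(-gamma_s * rho_y))
    pw, ph = _wh(pred, cfg.eps)
    gw, gh = _wh(gt, cfg.eps)
    ww = ops.abs_(pw - gw) / ops.maximum(pw, gw)
    wh = ops.abs_(ph - gh) / ops.maximum(ph, gh)
    shape = (1.0 - ops.exp(-ww)) ** 4 + (1.0 - ops.exp(-wh)) ** 4
    loss = 1.0 - i + 0.5 * (dist + shape)
    return _finish(loss, scalar, reduction)


def wiou_loss(pred, gt, cfg=None, clamp=False, reduction="none"):
    """WIoU v1: distance-attention-weighted IoU loss (enclosing-box term
    detached from the gradient, per the original formulation)."""
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    i = _iou_core(pred, gt, cfg.eps)
    cw, ch = _enclose(pred, gt, cfg.eps)
    denom = ops.detach(ops.maximum(cw * cw + ch * ch, cfg.eps))
    attn = ops.exp(_center_dist2(pred, gt) / denom)
    loss = attn * (1.0 - i)
    return _finish(loss, scalar, reduction)


def iou_loss(pred, gt, cfg=None, clamp=False, reduction="none"):
    """Plain 1 - IoU baseline."""
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    return _finish(1.0 - _iou_core(pred, gt, cfg.eps), scalar, reduction)


def inner_iou_loss(pred, gt, cfg=None, clamp=False, reduction="none"):
    """1 - IoU_inner used as a standalone regression loss."""
    cfg = cfg or LossConfig()
    pred, gt, scalar = _prepare(pred, gt, clamp)
    return _finish(1.0 - inner_iou(pred, gt, gamma=cfg.gamma, eps=cfg.eps, clamp=True),
                   scalar, reduction)


def sample_random_box_pairs(n: int, rng: np.random.Generator,
                            size_range: tuple[float, float] = (1.0, 1000.0),
                            field: float = 2000.0) -> tuple[np.ndarray, np.ndarray]:
    """Randomized stress sampler for loss sweeps.

    Draws ``n`` (pred, gt) pairs with log-uniform widths/heights in
    ``size_range`` (covering extreme aspect ratios) and centers uniform
    in a ``field`` x ``field`` region, which includes near-disjoint and
    fully disjoint configurations.
    """
    lo, hi = np.log(size_range[0]), np.log(size_range[1])

    def draw():
        centers = rng.uniform(0.0, field, size=(n, 2))
        sides = np.exp(rng.uniform(lo, hi, size=(n, 2)))
        return np.concatenate([centers, sides], axis=1)

    return draw(), draw()


REGRESSION_LOSSES = {
    "iou": iou_loss,
    "giou": giou_loss,
    "diou": diou_loss,
    "ciou": ciou_loss,
    "eiou": eiou_loss,
    "siou": siou_loss,
    "wiou": wiou_loss,
    "piou": piou_loss,
    "piouv2": piouv2_loss,
    "inner_iou": inner_iou_loss,
    "ipiouv2": ipiouv2_loss,
}


def regression_loss(name: str, pred, gt, cfg: LossConfig | None = None,
                    reduction: str = "mean"):
    """Look up a registered loss by name and evaluate it (clamped path)."""
    try:
        fn = REGRESSION_LOSSES[name]
    except KeyError:
        raise KeyError(
            f"unknown regression loss {name!r}; known: {sorted(REGRESSION_LOSSES)}"
        ) from None
    if name == "piou":
        return fn(pred, gt, clamp=True, reduction=reduction)
    return fn(pred, gt, cfg=cfg, clamp=True, reduction=reduction)
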