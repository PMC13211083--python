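"""DETR-style detector assembly: backbone -> neck -> query decoder.

The decoder follows the real-time detection-transformer convention: a
fixed set of learned queries with reference boxes (initialized on a
grid), self-attention among queries, cross-attention over the flattened
multi-scale memory, and per-query class/box heads.  Boxes are predicted
in normalized center/width/height coordinates through a sigmoid around
the reference logits.

Training uses Hungarian one-to-one matching (classification + L1 +
IoU costs), focal binary cross-entropy for classification, and a
configurable IoU-family regression loss (IPIoUv2 by default).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nn
from .backbone import BaselineBackbone, MSANet
from .boxes import BoxCWH, Detection
from .config import RunConfig
from .encoder import build_neck, sincos_position_embedding
from .losses import LossConfig, iou, regression_loss
from .nn import Tensor

__all__ = ["DiseaseDetector", "build_model", "hungarian_match", "training_step",
           "detect", "TrainingError"]


class TrainingError(RuntimeError):
    """Raised when training produces a non-finite loss."""


def _inverse_sigmoid(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    x = np.clip(x, eps, 1 - eps)
    return np.log(x / (1 - x))


class MLP(nn.Module):
    def __init__(self, dim_in, dim_hidden, dim_out, rng):
        super().__init__()
        self.fc1 = nn.Linear(dim_in, dim_hidden, rng)
        self.fc2 = nn.Linear(dim_hidden, dim_out, rng)

    def forward(self, x):
        return self.fc2(self.fc1(x).relu())


class DecoderLayer(nn.Module):
    def __init__(self, dim, heads, ffn_mult, rng):
        super().__init__()
        self.self_attn = nn.MultiHeadAttention(dim, heads, rng)
        self.norm1 = nn.LayerNorm(dim)
        self.cross_attn = nn.MultiHeadAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, ffn_mult * dim, rng)
        self.fc2 = nn.Linear(ffn_mult * dim, dim, rng)
        self.norm3 = nn.LayerNorm(dim)

    def forward(self, q, memory, cross_bias=None):
        q = self.norm1(q + self.self_attn(q))
        q = self.norm2(q + self.cross_attn(q, memory, attn_bias=cross_bias))
        return self.norm3(q + self.fc2(self.fc1(q).silu()))


class QueryDecoder(nn.Module):
    """Learned queries with grid-initialized reference boxes, iterative
    per-layer box refinement, and a Gaussian spatial locality prior on
    cross-attention centered at each query's current reference box.

    ``forward`` returns one (logits, boxes) pair per decoder layer; the
    last pair is the prediction, the earlier ones serve as auxiliary
    (deep-supervision) outputs during training.
    """

    def __init__(self, dim, num_queries, num_classes, num_layers, heads,
                 ffn_mult, rng):
        super().__init__()
        self.num_queries = num_queries
        self.query_embed = Tensor(rng.normal(0, 0.5, size=(num_queries, dim)).astype(np.float32),
                                  requires_grad=True)
        side = int(np.ceil(np.sqrt(num_queries)))
        gy, gx = np.meshgrid((np.arange(side) + 0.5) / side,
                             (np.arange(side) + 0.5) / side, indexing="ij")
        refs = np.stack([gx.ravel(), gy.ravel(),
                         np.full(side * side, 0.15), np.full(side * side, 0.15)],
                        axis=1)[:num_queries]
        self.ref_logits = Tensor(_inverse_sigmoid(refs).astype(np.float32), requires_grad=True)
        self.layers = [DecoderLayer(dim, heads, ffn_mult, rng) for _ in range(num_layers)]
        self.class_head = nn.Linear(dim, num_classes, rng)
        self.box_head = MLP(dim, dim, 4, rng)
        # start box deltas near zero so initial boxes sit on the reference grid
        self.box_head.fc2.weight.data *= 0.01

    @staticmethod
    def _locality_bias(ref_boxes: np.ndarray, token_xy: np.ndarray) -> np.ndarray:
        """-d^2 / (2 sigma^2) between query reference centers and token
        positions (normalized coords); sigma follows the box size."""
        centers = ref_boxes[..., :2]                              # (B, nq, 2)
        sigma = np.clip(0.5 * ref_boxes[..., 2:].max(axis=-1), 0.08, 0.5)
        d2 = ((centers[:, :, None, :] - token_xy[None, None, :, :]) ** 2).sum(-1)
        bias = -d2 / (2.0 * sigma[:, :, None] ** 2)
        return np.clip(bias, -30.0, 0.0)[:, None].astype(np.float32)  # (B,1,nq,Nk)

    def forward(self, memory: Tensor, token_xy: np.ndarray):
        B = memory.shape[0]
        q = self.query_embed.reshape(1, self.num_queries, -1) \
            * nn.as_tensor(np.ones((B, 1, 1), dtype=self.query_embed.dtype))
        ref_logits = np.broadcast_to(self.ref_logits.data, (B,) + self.ref_logits.shape)
        outputs = []
        for li, layer in enumerate(self.layers):
            refs_np = 1.0 / (1.0 + np.exp(-ref_logits))
            bias = self._locality_bias(refs_np, token_xy)
            q = layer(q, memory, cross_bias=bias)
            delta = self.box_head(q)
            if li == 0:
                # the learned reference grid receives gradient at layer 0
                boxes = (delta + self.ref_logits).sigmoid()
            else:
                boxes = (delta + nn.as_tensor(ref_logits)).sigmoid()
            logits = self.class_head(q)
            outputs.append((logits, boxes))
            # refined references for the next layer (detached, stabilizes
            # matching like standard iterative refinement)
            ref_logits = _inverse_sigmoid(boxes.data)
        return outputs


class DiseaseDetector(nn.Module):
    """Full detector; ``forward`` maps a normalized image batch to
    per-query class logits and normalized boxes."""

    def __init__(self, config: RunConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        mc = config.model
        if mc.backbone.kind == "msanet":
            self.backbone = MSANet(rng, widths=mc.backbone.widths,
                                   depths=mc.backbone.depths,
                                   afa_common=mc.backbone.afa_common)
        else:
            self.backbone = BaselineBackbone(rng, widths=mc.backbone.baseline_widths,
                                             blocks_per_stage=mc.backbone.baseline_blocks)
        dim = mc.neck.channels
        self.neck = build_neck(mc.neck.kind, self.backbone.out_channels, dim, rng,
                               p_sizes=mc.neck.p_sizes)
        self.level_embed = Tensor(rng.normal(0, 0.1, size=(3, dim)).astype(np.float32), requires_grad=True)
        self.decoder = QueryDecoder(dim, mc.head.num_queries, mc.num_classes,
                                    mc.head.num_layers, mc.head.num_heads,
                                    mc.head.ffn_mult, rng)

    def forward(self, images: Tensor) -> tuple[Tensor, Tensor]:
        """Final-layer (logits, boxes); use :meth:`forward_all` for the
        per-layer auxiliary outputs."""
        return self.forward_all(images)[-1]

    def forward_all(self, images: Tensor) -> list[tuple[Tensor, Tensor]]:
        pyramid = self.backbone(nn.as_tensor(images))
        feats = self.neck(pyramid)
        tokens = []
        centers = []
        for lvl, stride in enumerate((8, 16, 32)):
            f = feats[stride]
            B, C, H, W = f.shape
            t = f.reshape(B, C, H * W).transpose(0, 2, 1)
            pos = nn.as_tensor(sincos_position_embedding(H, W, C))
            t = t + pos + self.level_embed[lvl]
            tokens.append(t)
            gy, gx = np.meshgrid((np.arange(H) + 0.5) / H, (np.arange(W) + 0.5) / W,
                                 indexing="ij")
            centers.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        memory = nn.concat(tokens, axis=1)
        token_xy = np.concatenate(centers, axis=0).astype(np.float32)
        return self.decoder(memory, token_xy)


def build_model(config: RunConfig) -> DiseaseDetector:
    """Instantiate the detector; same config (incl. seed) -> identical
    initial weights."""
    if config.model.head.num_queries < 1:
        raise ValueError("num_queries must be >= 1")
    return DiseaseDetector(config)


# ---------------------------------------------------------------------------
# Matching and training
# ---------------------------------------------------------------------------

def hungarian_match(pred_boxes: np.ndarray, pred_scores: np.ndarray,
                    gt_boxes: np.ndarray, gt_labels: np.ndarray,
                    cost_weights: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-cost one-to-one assignment of queries to ground truths.

    Costs: classification (negative predicted probability of the true
    class), L1 box distance, and 1 - IoU.  Returns (query_idx, gt_idx).
    """
    m = len(gt_boxes)
    nq = len(pred_boxes)
    if m > nq:
        raise ValueError(f"{m} ground truths exceed {nq} queries")
    if m == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    w = {"cls": 1.0, "l1": 5.0, "iou": 2.0}
    if cost_weights:
        w.update(cost_weights)
    if not (np.all(np.isfinite(pred_boxes)) and np.all(np.isfinite(pred_scores))):
        raise ValueError("non-finite predictions in matching")
    cost_cls = -pred_scores[:, gt_labels]                          # (nq, m)
    cost_l1 = np.abs(pred_boxes[:, None, :] - gt_boxes[None, :, :]).sum(-1)
    cost_iou = 1.0 - iou(pred_boxes[:, None, :], gt_boxes[None, :, :], clamp=True)
    cost = w["cls"] * cost_cls + w["l1"] * cost_l1 + w["iou"] * cost_iou
    qi, gi = linear_sum_assignment(cost)
    return qi, gi


def _softplus(x: Tensor) -> Tensor:
    return x.relu() + ((-x.abs()).exp() + 1.0).log()


def focal_bce(logits: Tensor, targets: np.ndarray, alpha: float = 0.25,
              gamma: float = 2.0) -> Tensor:
    """Focal binary cross-entropy, summed; stable log-sigmoid form."""
    p = logits.sigmoid()
    log_p = -_softplus(-logits)
    log_1p = -_softplus(logits)
    t = nn.as_tensor(targets)
    pos = (((1.0 - p) ** gamma) * log_p) * t * (-alpha)
    neg = ((p ** gamma) * log_1p) * (1.0 - t) * (-(1.0 - alpha))
    return (pos + neg).sum()


def training_step(model: DiseaseDetector, batch, cfg: RunConfig):
    """One forward/loss computation over a matched batch.

    ``batch`` is (images, targets) with images (B, 3, H, W) float in
    [0, 1]-ish normalized units and targets a list of (labels, boxes)
    with normalized cwh boxes.  Returns (total_loss Tensor, parts dict).
    """
    images, targets = batch
    layer_outputs = model.forward_all(nn.as_tensor(images))
    loss_cfg = LossConfig(lambda_=cfg.loss.lambda_, gamma=cfg.loss.gamma,
                          eps=cfg.loss.eps)
    w = cfg.train.weights

    total = nn.as_tensor(0.0)
    parts = {}
    n_layers = len(layer_outputs)
    for li, (logits, boxes) in enumerate(layer_outputs):
        B, nq, K = logits.shape
        scores_np = 1.0 / (1.0 + np.exp(-logits.data))
        boxes_np = boxes.data

        tgt = np.zeros((B, nq, K), dtype=np.float32)
        b_idx, q_idx = [], []
        gt_box_list = []
        for b, (labels, gt_boxes) in enumerate(targets):
            labels = np.asarray(labels, dtype=int)
            gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
            if len(labels) == 0:
                continue
            qi, gi = hungarian_match(boxes_np[b], scores_np[b], gt_boxes, labels,
                                     cost_weights={"cls": w.cls, "l1": w.l1,
                                                   "iou": w.iou})
            tgt[b, qi, labels[gi]] = 1.0
            b_idx.extend([b] * len(qi))
            q_idx.extend(qi)
            gt_box_list.append(gt_boxes[gi])

        n_matched = max(len(b_idx), 1)
        cls_loss = focal_bce(logits, tgt, alpha=cfg.train.focal_alpha,
                             gamma=cfg.train.focal_gamma) * (1.0 / n_matched)
        if b_idx:
            matched = boxes[np.asarray(b_idx), np.asarray(q_idx)]
            gt_all = np.concatenate(gt_box_list, axis=0)
            l1_loss = (matched - nn.as_tensor(gt_all)).abs().sum() * (1.0 / n_matched)
            iou_loss = regression_loss(cfg.train.regression_loss, matched, gt_all,
                                       cfg=loss_cfg, reduction="sum") * (1.0 / n_matched)
        else:
            l1_loss = nn.as_tensor(0.0)
            iou_loss = nn.as_tensor(0.0)

        total = total + (w.cls * cls_loss + w.l1 * l1_loss + w.iou * iou_loss) \
            * (1.0 / n_layers)
        if li == n_layers - 1:      # report the prediction layer's terms
            parts = {"cls": float(cls_loss.data), "l1": float(l1_loss.data),
                     "iou": float(iou_loss.data), "n_matched": n_matched}

    parts["total"] = float(total.data)
    if not np.isfinite(parts["total"]):
        raise TrainingError(f"non-finite loss: {parts}")
    return total, parts


def preprocess_image(image: np.ndarray) -> np.ndarray:
    """uint8 HWC -> float CHW, centered to roughly [-0.5, 0.5]."""
    arr = np.asarray(image, dtype=np.float32) / np.float32(255.0) - np.float32(0.5)
    return arr.transpose(2, 0, 1)


def detect(model: DiseaseDetector, image: np.ndarray,
           score_threshold: float = 0.25, max_detections: int = 50) -> list[Detection]:
    """Run the detector on one image (H, W, 3 uint8 or preprocessed CHW);
    returns scored detections in pixel space, clamped to image bounds."""
    if image.ndim == 3 and image.shape[-1] == 3:
        size_hw = image.shape[:2]
        arr = preprocess_image(image)
    else:
        size_hw = image.shape[-2:]
        arr = np.asarray(image, dtype=float)
    H, W = size_hw
    if H % 32 or W % 32:
        raise ValueError(f"image dims must be divisible by 32, got {H}x{W}")
    was_training = model.training
    model.eval()
    logits, boxes = model(Tensor(arr[None]))
    if was_training:
        model.train()
    scores = 1.0 / (1.0 + np.exp(-logits.data[0]))
    boxes = boxes.data[0]
    labels = scores.argmax(axis=1)
    best = scores[np.arange(len(labels)), labels]
    order = np.argsort(-best)[:max_detections]
    out = []
    for i in order:
        if best[i] < score_threshold:
            continue
        cx, cy, w, h = boxes[i]
        x1 = np.clip((cx - w / 2) * W, 0, W)
        x2 = np.clip((cx + w / 2) * W, 0, W)
        y1 = np.clip((cy - h / 2) * H, 0, H)
        y2 = np.clip((cy + h / 2) * H, 0, H)
        if x2 - x1 <= 0 or y2 - y1 <= 0:
            continue
        out.append(Detection(BoxCWH((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1),
                             float(best[i]), int(labels[i])))
    return out
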