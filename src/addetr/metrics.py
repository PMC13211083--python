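"""Detection metrics: per-class / macro precision and recall, average
precision (101-point interpolation), mAP@50 and mAP@50-95, and a
row-normalized confusion matrix with a background category.

Matching convention: detections are processed in descending score
order; a detection is a true positive iff its label matches and its IoU
with a not-yet-matched ground truth of that class reaches the
threshold.  Each ground truth yields at most one true positive;
unmatched ground truths are false negatives.

The confusion matrix deliberately matches class-agnostically (best IoU
regardless of label) so that inter-class confusion and confusion with
the background are both visible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxes import Detection, GroundTruth, as_box_array
from .losses import iou

__all__ = [
    "MatchResult",
    "UndefinedMetricError",
    "match_detections",
    "macro_pr",
    "average_precision",
    "evaluate_detections",
    "confusion_matrix",
    "load_yolo_ground_truth",
    "detections_to_json",
    "detections_from_json",
]

IOU_THRESHOLDS_50_95 = np.arange(0.50, 0.96, 0.05)


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. no ground truth)."""


@dataclass
class MatchResult:
    """Per-class (score, is_true_positive) pairs plus false-negative
    counts, accumulated over one or more images at a fixed IoU
    threshold."""

    scored: dict[int, list[tuple[float, bool]]] = field(default_factory=dict)
    fn_counts: dict[int, int] = field(default_factory=dict)
    n_gt: dict[int, int] = field(default_factory=dict)

    def merge(self, other: "MatchResult") -> "MatchResult":
        for c, pairs in other.scored.items():
            self.scored.setdefault(c, []).extend(pairs)
        for c, n in other.fn_counts.items():
            self.fn_counts[c] = self.fn_counts.get(c, 0) + n
        for c, n in other.n_gt.items():
            self.n_gt[c] = self.n_gt.get(c, 0) + n
        return self

    def counts_at(self, c: int, score_thr: float) -> tuple[int, int, int]:
        """(TP, FP, FN) for class c at a score threshold."""
        pairs = [p for p in self.scored.get(c, []) if p[0] >= score_thr]
        tp = sum(1 for _, is_tp in pairs if is_tp)
        fp = len(pairs) - tp
        fn = self.n_gt.get(c, 0) - tp
        return tp, fp, fn


def _iou_matrix(dets: list[Detection], gts: list[GroundTruth]) -> np.ndarray:
    if not dets or not gts:
        return np.zeros((len(dets), len(gts)))
    d = np.stack([det.box.as_array() for det in dets])
    g = np.stack([gt.box.as_array() for gt in gts])
    return iou(d[:, None, :], g[None, :, :])


def match_detections(dets: list[Detection], gts: list[GroundTruth],
                     iou_thr: float = 0.5) -> MatchResult:
    """Greedy per-class matching in descending score order."""
    result = MatchResult()
    for gt in gts:
        result.n_gt[gt.label] = result.n_gt.get(gt.label, 0) + 1
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    ious = _iou_matrix(dets, gts)
    gt_taken = [False] * len(gts)
    for i in order:
        det = dets[i]
        best_j, best_iou = -1, iou_thr
        for j, gt in enumerate(gts):
            if gt_taken[j] or gt.label != det.label:
                continue
            if ious[i, j] >= best_iou:
                best_j, best_iou = j, ious[i, j]
        is_tp = best_j >= 0
        if is_tp:
            gt_taken[best_j] = True
        result.scored.setdefault(det.label, []).append((det.score, is_tp))
    for j, gt in enumerate(gts):
        if not gt_taken[j]:
            result.fn_counts[gt.label] = result.fn_counts.get(gt.label, 0) + 1
    return result


def macro_pr(m: MatchResult, score_thr: float = 0.25) -> tuple[float, float]:
    """Unweighted class means of per-class precision and recall.

    Classes with ground truths but no predictions contribute P_c = 0;
    classes without any ground truth are excluded from the means.
    """
    classes = [c for c, n in m.n_gt.items() if n > 0]
    if not classes:
        raise UndefinedMetricError("no ground truths: precision/recall undefined")
    ps, rs = [], []
    for c in classes:
        tp, fp, fn = m.counts_at(c, score_thr)
        ps.append(tp / (tp + fp) if tp + fp > 0 else 0.0)
        rs.append(tp / (tp + fn) if tp + fn > 0 else 0.0)
    return float(np.mean(ps)), float(np.mean(rs))


def average_precision(scored: list[tuple[float, bool]], n_gt: int,
                      n_points: int = 101) -> float:
    """Average precision by the 101-point interpolation rule.

    Detections are sorted by descending score; the precision envelope
    max_{r' >= r} p(r') is sampled at recall levels 0, 0.01, ..., 1 and
    averaged.
    """
    if n_gt <= 0:
        raise UndefinedMetricError("average precision undefined without ground truth")
    if not scored:
        return 0.0
    order = sorted(scored, key=lambda p: -p[0])
    tp = np.cumsum([1.0 if is_tp else 0.0 for _, is_tp in order])
    fp = np.cumsum([0.0 if is_tp else 1.0 for _, is_tp in order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1e-12)
    # precision envelope, right to left
    env = np.maximum.accumulate(precision[::-1])[::-1]
    levels = np.linspace(0.0, 1.0, n_points)
    idx = np.searchsorted(recall, levels, side="left")
    sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(sampled.mean())


def evaluate_detections(dets_per_image: list[list[Detection]],
                        gts_per_image: list[list[GroundTruth]],
                        score_thr: float = 0.25) -> dict:
    """Full evaluation: macro P/R at ``score_thr`` (IoU 0.5 matching),
    mAP@50 and mAP@50-95, plus per-class AP@50.

    Classes with no ground truth anywhere are excluded from the means
    (with a warning if they received predictions).
    """
    if len(dets_per_image) != len(gts_per_image):
        raise ValueError("detections and ground truths must align per image")
    per_thr_maps = []
    ap50_per_class: dict[int, float] = {}
    merged50 = MatchResult()
    for thr in IOU_THRESHOLDS_50_95:
        merged = MatchResult()
        for dets, gts in zip(dets_per_image, gts_per_image):
            merged.merge(match_detections(dets, gts, iou_thr=float(thr)))
        classes = sorted(c for c, n in merged.n_gt.items() if n > 0)
        predicted_only = set(merged.scored) - set(classes)
        if predicted_only and abs(thr - 0.5) < 1e-9:
            warnings.warn(f"classes {sorted(predicted_only)} have predictions but no "
                          "ground truth; excluded from mAP")
        if not classes:
            raise UndefinedMetricError("no ground truths in the evaluation set")
        aps = {c: average_precision(merged.scored.get(c, []), merged.n_gt[c])
               for c in classes}
        per_thr_maps.append(float(np.mean(list(aps.values()))))
        if abs(thr - 0.5) < 1e-9:
            ap50_per_class = aps
            merged50 = merged
    precision, recall = macro_pr(merged50, score_thr=score_thr)
    return {
        "precision": precision,
        "recall": recall,
        "map50": per_thr_maps[0],
        "map50_95": float(np.mean(per_thr_maps)),
        "ap50_per_class": ap50_per_class,
        "score_threshold": score_thr,
    }


def confusion_matrix(dets_per_image, gts_per_image, num_classes: int,
                     iou_thr: float = 0.5, score_thr: float = 0.25) -> np.ndarray:
    """(num_classes+1)^2 row-normalized confusion matrix.

    Rows are true classes (last row background), columns predicted
    classes (last column background).  Matching is class-agnostic:
    detections above ``score_thr`` greedily claim the best-IoU unmatched
    ground truth regardless of label.
    """
    bg = num_classes
    mat = np.zeros((num_classes + 1, num_classes + 1))
    for dets, gts in zip(dets_per_image, gts_per_image):
        dets = [d for d in dets if d.score >= score_thr]
        order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
        ious = _iou_matrix(dets, gts)
        gt_taken = [False] * len(gts)
        det_matched = [False] * len(dets)
        for i in order:
            best_j, best_iou = -1, iou_thr
            for j in range(len(gts)):
                if gt_taken[j]:
                    continue
                if ious[i, j] >= best_iou:
                    best_j, best_iou = j, ious[i, j]
            if best_j >= 0:
                gt_taken[best_j] = True
                det_matched[i] = True
                mat[gts[best_j].label, dets[i].label] += 1
        for j, gt in enumerate(gts):
            if not gt_taken[j]:
                mat[gt.label, bg] += 1
        for i, det in enumerate(dets):
            if not det_matched[i]:
                mat[bg, det.label] += 1
    sums = mat.sum(axis=1, keepdims=True)
    return np.divide(mat, sums, out=np.zeros_like(mat), where=sums > 0)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_yolo_ground_truth(labels_dir: Path, image_size: int) -> dict[str, list[GroundTruth]]:
    """Read a directory of YOLO-TXT files into pixel-space ground truths."""
    from .synth import read_yolo_txt
    from .boxes import BoxCWH

    out = {}
    for path in sorted(Path(labels_dir).glob("*.txt")):
        gts = []
        for label, (cx, cy, w, h) in read_yolo_txt(path):
            gts.append(GroundTruth(BoxCWH(cx * image_size, cy * image_size,
                                          w * image_size, h * image_size), label))
        out[path.stem] = gts
    return out


def detections_to_json(dets_per_image: dict[str, list[Detection]], path: Path) -> None:
    """COCO-style flat detections list: [{image_id, category_id, bbox, score}]
    with bbox = [x, y, w, h] (top-left corner)."""
    rows = []
    for image_id, dets in dets_per_image.items():
        for d in dets:
            x1, y1, _, _ = d.box.to_xyxy()
            rows.append({"image_id": image_id, "category_id": d.label,
                         "bbox": [x1, y1, d.box.w, d.box.h], "score": d.score})
    Path(path).write_text(json.dumps(rows, indent=1))


def detections_from_json(path: Path) -> dict[str, list[Detection]]:
    from .boxes import BoxCWH

    out: dict[str, list[Detection]] = {}
    for row in json.loads(Path(path).read_text()):
        x, y, w, h = row["bbox"]
        det = Detection(BoxCWH(x + w / 2, y + h / 2, w, h), row["score"], row["category_id"])
        out.setdefault(str(row["image_id"]), []).append(det)
    return out
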