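"""Synthetic leaf/lesion scene generator with YOLO-TXT annotations.

Generates leaf-like RGB images: a textured green background with
vein-like streaks (hard negatives), and procedurally rendered lesions
drawn from per-class motifs (spots, blotches, rust pustule clusters,
elongated streaks, ring spots).  Every lesion's bounding box is recorded
exactly from the rendered mask, so ground truth is noise-free.

The generator's defaults define the study conditions used throughout
the test-suite: a handful of classes with a skewed class distribution,
lesion areas of a few percent of the image, moderate-to-high contrast,
occasional partial occlusion, and a fraction of healthy (lesion-free)
images.  Datasets are written as PNG images plus one YOLO-TXT label
file per image (``class cx cy w h``, normalized, 0-based classes, six
decimals) under train/test/val splits in 7:1:2 proportions, stratified
by primary class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .boxes import BoxCWH

__all__ = [
    "DatasetSpec",
    "SceneRecord",
    "AugmentPolicy",
    "render_scene",
    "generate_dataset",
    "augment",
    "write_yolo_txt",
    "read_yolo_txt",
    "load_split",
    "records_to_coco",
]


def default_class_weights(num_classes: int) -> np.ndarray:
    """Skewed class distribution (geometric decay), echoing the imbalance
    of real disease surveys where a few diseases dominate."""
    w = 0.8 ** np.arange(num_classes)
    return w / w.sum()


@dataclass
class DatasetSpec:
    """Generative recipe for a synthetic lesion-detection dataset.

    ``lesion_size_range`` is the box-area interval as a fraction of the
    image area; ``contrast_range`` controls how strongly lesions deviate
    from the leaf background; ``healthy_fraction`` is the probability of
    a lesion-free image.  Splits follow the train:test:val = 7:1:2
    convention (test is the single part, validation the double part).
    """

    num_classes: int = 5
    total_images: int = 200
    class_weights: list[float] | None = None
    lesion_size_range: tuple[float, float] = (0.02, 0.10)
    contrast_range: tuple[float, float] = (0.35, 0.9)
    occlusion_prob: float = 0.10
    healthy_fraction: float = 0.10
    max_lesions: int = 3
    image_size: int = 160
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.num_classes <= 41:
            raise ValueError("num_classes must be in [1, 41]")
        if not 0.0 <= self.healthy_fraction < 1.0:
            raise ValueError("healthy_fraction must be in [0, 1)")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if len(w) != self.num_classes or np.any(w < 0):
                raise ValueError("class_weights must be nonnegative, one per class")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("class_weights must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        if self.class_weights is not None:
            return np.asarray(self.class_weights, dtype=float)
        return default_class_weights(self.num_classes)

    @property
    def images_per_split(self) -> dict[str, int]:
        n = self.total_images
        n_test = round(n / 10)
        n_val = round(2 * n / 10)
        return {"train": n - n_test - n_val, "test": n_test, "val": n_val}


@dataclass
class SceneRecord:
    """One rendered scene: image, normalized annotations, provenance."""

    image: np.ndarray                                  # (H, W, 3) uint8
    annotations: list[tuple[int, tuple[float, float, float, float]]]
    provenance: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([
        55 + rng.uniform(-12, 12),
        105 + rng.uniform(-18, 18),
        50 + rng.uniform(-12, 12),
    ])
    img = np.ones((size, size, 3)) * base
    # smooth mottling
    noise = gaussian_filter(rng.normal(0, 1, size=(size, size)), sigma=size / 12)
    noise = noise / (np.abs(noise).max() + 1e-9)
    img += noise[..., None] * rng.uniform(8, 18)
    # vein-like streaks: lighter lines through a random point
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(rng.integers(2, 5)):
        angle = rng.uniform(0, np.pi)
        px, py = rng.uniform(0, size, 2)
        d = np.abs((xx - px) * np.sin(angle) - (yy - py) * np.cos(angle))
        width = rng.uniform(0.8, 1.8)
        vein = np.exp(-(d / width) ** 2)
        img += vein[..., None] * np.array([18, 26, 14]) * rng.uniform(0.5, 1.0)
    return img


_MOTIFS = ("spot", "blotch", "rust", "streak", "ring")


def _lesion_mask_and_color(motif: str, size: int, w: float, h: float,
                           cx: float, cy: float, rng: np.random.Generator):
    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - cx) / (w / 2)
    v = (yy - cy) / (h / 2)
    r = np.sqrt(u ** 2 + v ** 2)
    # every motif's mask stays above the 0.05 render threshold out to the
    # box edges along both axes, so the recorded box matches the sampled
    # size to pixel rounding
    if motif == "spot":
        mask = np.clip(1.2 - r, 0, 1) ** 0.7
        color = np.array([92, 58, 32]) + rng.uniform(-10, 10, 3)
    elif motif == "blotch":
        theta = np.arctan2(v, u)
        wobble = (1.0 + 0.20 * (np.sin(3 * theta + rng.uniform(0, 2 * np.pi)) + 1) / 2
                  + 0.12 * (np.sin(5 * theta + rng.uniform(0, 2 * np.pi)) + 1) / 2)
        mask = np.clip(1.15 * wobble - r, 0, 1) ** 0.6
        color = np.array([150, 120, 55]) + rng.uniform(-15, 15, 3)
    elif motif == "rust":
        mask = np.zeros((size, size))
        anchors = [(-0.75, 0.0), (0.75, 0.0), (0.0, -0.75), (0.0, 0.75)]
        dots = anchors + [tuple(rng.uniform(-0.7, 0.7, 2)) for _ in range(rng.integers(4, 10))]
        for du, dv in dots:
            dr = np.sqrt((u - du) ** 2 * 9 + (v - dv) ** 2 * 9)
            mask = np.maximum(mask, np.clip(1.4 - dr, 0, 1))
        color = np.array([170, 95, 30]) + rng.uniform(-15, 15, 3)
    elif motif == "streak":
        # elongation comes from the sampled aspect ratio (u, v are
        # box-normalized); darker, vein-following appearance
        mask = np.clip(1.2 - r, 0, 1) ** 0.9
        color = np.array([80, 62, 40]) + rng.uniform(-10, 10, 3)
    else:  # ring
        mask = np.clip(1.0 - np.abs(r - 0.75) * 2.2, 0, 1)
        mask = np.maximum(mask, np.clip(0.5 - r, 0, 1))      # faint center
        color = np.array([110, 70, 35]) + rng.uniform(-10, 10, 3)
    # clip support to the nominal box so ground truth stays exact
    support = (np.abs(u) <= 1.0) & (np.abs(v) <= 1.0)
    return mask * support, color


def render_scene(spec: DatasetSpec, rng: np.random.Generator) -> SceneRecord:
    """Draw one scene: textured background, 0..max_lesions lesions with
    class-specific motifs, optional partial occlusion; exact boxes."""
    size = spec.image_size
    img = _background(size, rng)
    annotations: list[tuple[int, tuple[float, float, float, float]]] = []
    provenance: list[dict] = []

    healthy = rng.random() < spec.healthy_fraction
    n_lesions = 0 if healthy else int(rng.integers(1, spec.max_lesions + 1))
    placed: list[tuple[float, float, float, float]] = []
    for _ in range(n_lesions):
        label = int(rng.choice(spec.num_classes, p=spec.weights))
        motif = _MOTIFS[label % len(_MOTIFS)]
        area = rng.uniform(*spec.lesion_size_range) * size * size
        aspect = rng.uniform(2.5, 4.5) if motif == "streak" else rng.uniform(0.6, 1.6)
        w = float(np.sqrt(area * aspect))
        h = float(area / w)
        w, h = min(w, 0.9 * size), min(h, 0.9 * size)
        for _attempt in range(20):
            cx = rng.uniform(w / 2 + 1, size - w / 2 - 1)
            cy = rng.uniform(h / 2 + 1, size - h / 2 - 1)
            if all(abs(cx - px) > (w + pw) / 2.5 or abs(cy - py) > (h + ph) / 2.5
                   for px, py, pw, ph in placed):
                break
        placed.append((cx, cy, w, h))
        contrast = rng.uniform(*spec.contrast_range)
        mask, color = _lesion_mask_and_color(motif, size, w, h, cx, cy, rng)
        img = img * (1 - contrast * mask[..., None]) + color * (contrast * mask[..., None])

        ys, xs = np.nonzero(mask > 0.05)
        if len(xs) == 0:
            placed.pop()
            continue
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        box = BoxCWH((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)
        occluded = False
        if rng.random() < spec.occlusion_prob:
            occluded = True
            ox = rng.uniform(x1, x2)
            ow = rng.uniform(0.15, 0.35) * (x2 - x1)
            sl = slice(int(max(ox - ow / 2, 0)), int(min(ox + ow / 2, size)))
            img[y1:y2, sl] = _background(size, rng)[y1:y2, sl]
        annotations.append((label, (box.xc / size, box.yc / size, box.w / size, box.h / size)))
        provenance.append({"label": label, "motif": motif, "area_frac": area / size ** 2,
                           "contrast": contrast, "occluded": occluded})

    return SceneRecord(np.clip(img, 0, 255).astype(np.uint8), annotations, provenance)


# ---------------------------------------------------------------------------
# Dataset writing / reading (YOLO-TXT dialect)
# ---------------------------------------------------------------------------

def write_yolo_txt(path: Path, annotations) -> None:
    lines = [f"{label} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
             for label, (cx, cy, w, h) in annotations]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path: Path) -> list[tuple[int, tuple[float, float, float, float]]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"malformed YOLO line in {path}: {line!r}")
        label = int(parts[0])
        cx, cy, w, h = (float(p) for p in parts[1:])
        out.append((label, (cx, cy, w, h)))
    return out


def _primary_class(rec: SceneRecord, num_classes: int) -> int:
    return rec.annotations[0][0] if rec.annotations else num_classes  # healthy marker


def generate_dataset(spec: DatasetSpec, out_dir: Path) -> dict:
    """Render the full dataset and write it under ``out_dir``.

    Layout: ``images/{split}/img_00000.png`` + ``labels/{split}/img_00000.txt``
    with splits train/test/val in 7:1:2 proportions, stratified by the
    primary class of each image.  Returns (and writes) a manifest with
    per-split, per-class counts.  The result is a pure function of the
    spec (including its seed).
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    records = [render_scene(spec, rng) for _ in range(spec.total_images)]

    targets = spec.images_per_split
    # stratified assignment: inside each primary-class group, deal the
    # images out in 7:1:2 proportion
    groups: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(_primary_class(rec, spec.num_classes), []).append(i)
    assignment: dict[int, str] = {}
    quota = dict(targets)
    for cls in sorted(groups):
        idxs = groups[cls]
        n = len(idxs)
        n_test = round(n / 10)
        n_val = round(2 * n / 10)
        for j, i in enumerate(idxs):
            if j < n_test:
                split = "test"
            elif j < n_test + n_val:
                split = "val"
            else:
                split = "train"
            # keep global counts close to target where rounding drifted
            if quota.get(split, 0) <= 0:
                split = max(quota, key=quota.get)
            quota[split] -= 1
            assignment[i] = split

    manifest = {
        "num_classes": spec.num_classes,
        "image_size": spec.image_size,
        "seed": spec.seed,
        "splits": {s: {"images": 0, "per_class_instances": [0] * spec.num_classes,
                       "healthy_images": 0} for s in targets},
    }
    counters = {s: 0 for s in targets}
    try:
        for split in targets:
            (out_dir / "images" / split).mkdir(parents=True, exist_ok=True)
            (out_dir / "labels" / split).mkdir(parents=True, exist_ok=True)
        for i, rec in enumerate(records):
            split = assignment[i]
            stem = f"img_{counters[split]:05d}"
            counters[split] += 1
            Image.fromarray(rec.image).save(out_dir / "images" / split / f"{stem}.png")
            write_yolo_txt(out_dir / "labels" / split / f"{stem}.txt", rec.annotations)
            m = manifest["splits"][split]
            m["images"] += 1
            if not rec.annotations:
                m["healthy_images"] += 1
            for label, _ in rec.annotations:
                m["per_class_instances"][label] += 1
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as e:
        raise OSError(f"failed writing dataset under {out_dir}: {e}") from e
    return manifest


def load_split(data_dir: Path, split: str) -> list[SceneRecord]:
    """Read a written split back into memory."""
    data_dir = Path(data_dir)
    records = []
    img_dir = data_dir / "images" / split
    for img_path in sorted(img_dir.glob("*.png")):
        label_path = data_dir / "labels" / split / f"{img_path.stem}.txt"
        image = np.asarray(Image.open(img_path).convert("RGB"))
        anns = read_yolo_txt(label_path) if label_path.exists() else []
        records.append(SceneRecord(image, anns))
    return records


def records_to_coco(records: list[SceneRecord], class_names=None) -> dict:
    """Optional COCO-JSON export of a list of scenes."""
    images, annotations = [], []
    ann_id = 1
    num_classes = 0
    for i, rec in enumerate(records):
        H, W = rec.image.shape[:2]
        images.append({"id": i, "width": W, "height": H, "file_name": f"img_{i:05d}.png"})
        for label, (cx, cy, w, h) in rec.annotations:
            num_classes = max(num_classes, label + 1)
            annotations.append({
                "id": ann_id, "image_id": i, "category_id": label,
                "bbox": [(cx - w / 2) * W, (cy - h / 2) * H, w * W, h * H],
                "area": w * W * h * H, "iscrowd": 0,
            })
            ann_id += 1
    names = class_names or [f"class_{c}" for c in range(num_classes)]
    return {"images": images, "annotations": annotations,
            "categories": [{"id": c, "name": n} for c, n in enumerate(names)]}


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentPolicy:
    """Batch augmentation policy (all off == identity)."""

    hflip: bool = False
    color_jitter: float = 0.0          # relative brightness/channel jitter
    scale_range: tuple[float, float] | None = None
    mosaic: bool = False
    oversample_rare: bool = False

    @property
    def is_identity(self) -> bool:
        return (not self.hflip and self.color_jitter == 0.0
                and self.scale_range is None and not self.mosaic
                and not self.oversample_rare)


def hflip_scene(rec: SceneRecord) -> SceneRecord:
    img = rec.image[:, ::-1].copy()
    anns = [(lbl, (1.0 - cx, cy, w, h)) for lbl, (cx, cy, w, h) in rec.annotations]
    return SceneRecord(img, anns, rec.provenance)


def _jitter_scene(rec: SceneRecord, strength: float, rng) -> SceneRecord:
    gains = 1.0 + rng.uniform(-strength, strength, size=3)
    img = np.clip(rec.image.astype(float) * gains, 0, 255).astype(np.uint8)
    return SceneRecord(img, list(rec.annotations), rec.provenance)


def _scale_scene(rec: SceneRecord, factor: float) -> SceneRecord:
    """Zoom by ``factor`` about the image center, keeping the canvas size
    (crop when zooming in, pad with edge color when zooming out)."""
    H, W = rec.image.shape[:2]
    newW, newH = max(int(round(W * factor)), 1), max(int(round(H * factor)), 1)
    resized = np.asarray(Image.fromarray(rec.image).resize((newW, newH), Image.BILINEAR))
    canvas = np.zeros_like(rec.image)
    canvas[:] = np.median(rec.image.reshape(-1, 3), axis=0).astype(np.uint8)
    ox, oy = (W - newW) // 2, (H - newH) // 2
    sx1, sy1 = max(-ox, 0), max(-oy, 0)
    dx1, dy1 = max(ox, 0), max(oy, 0)
    cw = min(newW - sx1, W - dx1)
    ch = min(newH - sy1, H - dy1)
    canvas[dy1:dy1 + ch, dx1:dx1 + cw] = resized[sy1:sy1 + ch, sx1:sx1 + cw]
    anns = []
    for lbl, (cx, cy, w, h) in rec.annotations:
        ncx = (cx * newW + ox) / W
        ncy = (cy * newH + oy) / H
        nw, nh = w * newW / W, h * newH / H
        x1, x2 = np.clip([ncx - nw / 2, ncx + nw / 2], 0, 1)
        y1, y2 = np.clip([ncy - nh / 2, ncy + nh / 2], 0, 1)
        if x2 - x1 > 1e-3 and y2 - y1 > 1e-3:
            anns.append((lbl, ((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)))
    return SceneRecord(canvas, anns, rec.provenance)


def mosaic_scenes(recs: list[SceneRecord]) -> SceneRecord:
    """2x2 mosaic of four scenes at the original canvas size; all source
    boxes are remapped into their quadrant and clipped to the canvas."""
    if len(recs) != 4:
        raise ValueError("mosaic needs exactly 4 scenes")
    H, W = recs[0].image.shape[:2]
    h2, w2 = H // 2, W // 2
    canvas = np.zeros((H, W, 3), dtype=np.uint8)
    anns = []
    for q, rec in enumerate(recs):
        qy, qx = divmod(q, 2)
        tile = np.asarray(Image.fromarray(rec.image).resize((w2, h2), Image.BILINEAR))
        canvas[qy * h2:(qy + 1) * h2, qx * w2:(qx + 1) * w2] = tile
        for lbl, (cx, cy, w, h) in rec.annotations:
            anns.append((lbl, ((cx + qx) / 2, (cy + qy) / 2, w / 2, h / 2)))
    return SceneRecord(canvas, anns)


def augment(batch: list[SceneRecord], policy: AugmentPolicy,
            rng: np.random.Generator | None = None) -> list[SceneRecord]:
    """Apply the policy to a batch of scenes; identity policy returns the
    batch unchanged."""
    if policy.is_identity:
        return batch
    rng = rng or np.random.default_rng(0)
    out = list(batch)
    if policy.oversample_rare and out:
        counts: dict[int, int] = {}
        for rec in out:
            for lbl, _ in rec.annotations:
                counts[lbl] = counts.get(lbl, 0) + 1
        if counts:
            rare = min(counts, key=counts.get)
            extras = [rec for rec in out if any(lbl == rare for lbl, _ in rec.annotations)]
            out.extend(extras[: max(1, len(out) // 4)])
    result = []
    for rec in out:
        if policy.scale_range is not None:
            rec = _scale_scene(rec, rng.uniform(*policy.scale_range))
        if policy.hflip and rng.random() < 0.5:
            rec = hflip_scene(rec)
        if policy.color_jitter > 0:
            rec = _jitter_scene(rec, policy.color_jitter, rng)
        result.append(rec)
    if policy.mosaic and len(result) >= 4:
        picks = rng.choice(len(result), size=4, replace=False)
        result.append(mosaic_scenes([result[i] for i in picks]))
    return result
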