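"""Model/Results facade over the detector.

Usage follows the fitted-model convention:

>>> from addetr.config import desk_profile
>>> from addetr.model import DetectionModel
>>> model = DetectionModel(desk_profile(seed=0))
>>> results = model.fit()
>>> print(results.summary())
>>> dets = results.predict(image)

``DetectionModel`` owns the configuration and the data source (an
inline synthetic-data spec or a directory of YOLO-TXT data);
``fit`` trains the detector and returns a ``DetectionResults`` carrying
the trained weights, the per-epoch loss history, held-out metrics and a
``summary()`` table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxes import BoxCWH, GroundTruth
from .config import RunConfig, config_hash
from .detector import DiseaseDetector, build_model, detect, preprocess_image, training_step
from .metrics import confusion_matrix, evaluate_detections
from .nn import AdamW, clip_grad_norm
from .synth import SceneRecord, generate_dataset, load_split, render_scene

__all__ = ["DetectionModel", "DetectionResults"]


def _scenes_to_batch(scenes: list[SceneRecord]):
    images = np.stack([preprocess_image(rec.image) for rec in scenes])
    targets = []
    for rec in scenes:
        labels = [lbl for lbl, _ in rec.annotations]
        boxes = [box for _, box in rec.annotations]
        targets.append((np.asarray(labels, dtype=int),
                        np.asarray(boxes, dtype=float).reshape(-1, 4)))
    return images, targets


def _scene_ground_truth(rec: SceneRecord) -> list[GroundTruth]:
    H, W = rec.image.shape[:2]
    return [GroundTruth(BoxCWH(cx * W, cy * H, w * W, h * H), lbl)
            for lbl, (cx, cy, w, h) in rec.annotations]


@dataclass
class DetectionResults:
    """Outcome of a training run: weights, history, metrics."""

    config: RunConfig
    model: DiseaseDetector
    history: list[dict]
    metrics: dict
    num_parameters: int
    train_images: int
    val_images: int
    wall_time_s: float
    confusion: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def predict(self, image: np.ndarray, score_threshold: float | None = None):
        thr = self.config.eval.score_threshold if score_threshold is None else score_threshold
        return detect(self.model, image, score_threshold=thr)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Detection model fit",
            "=" * 58,
            f"{'backbone':<22}{cfg.model.backbone.kind:>36}",
            f"{'neck':<22}{cfg.model.neck.kind:>36}",
            f"{'regression loss':<22}{cfg.train.regression_loss:>36}",
            f"{'parameters':<22}{self.num_parameters:>36,}",
            f"{'config hash':<22}{config_hash(cfg):>36}",
            f"{'train / val images':<22}{f'{self.train_images} / {self.val_images}':>36}",
            f"{'epochs':<22}{len(self.history):>36}",
            f"{'wall time [s]':<22}{self.wall_time_s:>36.1f}",
            "-" * 58,
        ]
        if self.history:
            h0, h1 = self.history[0], self.history[-1]
            span = "{:.4f} -> {:.4f}".format(h0["total"], h1["total"])
            lines.append(f"{'loss (first -> last)':<22}{span:>36}")
        for key in ("precision", "recall", "map50", "map50_95"):
            if key in self.metrics:
                lines.append(f"{key:<22}{self.metrics[key]:>36.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def save(self, path: Path) -> None:
        state = self.model.state_dict()
        np.savez_compressed(path, __config__=self.config.model_dump_json(),
                            **state)

    @staticmethod
    def load_weights(path: Path) -> DiseaseDetector:
        data = np.load(path, allow_pickle=False)
        cfg = RunConfig.model_validate_json(str(data["__config__"]))
        model = build_model(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model


class DetectionModel:
    """A detector specification bound to a data source, ready to fit."""

    def __init__(self, config: RunConfig, data_dir: Path | None = None):
        self.config = config
        self.data_dir = Path(data_dir) if data_dir else (
            Path(config.data.path) if config.data.path else None)
        self._train_scenes: list[SceneRecord] | None = None
        self._val_scenes: list[SceneRecord] | None = None

    # -- data ----------------------------------------------------------
    def _load_data(self):
        if self._train_scenes is not None:
            return
        if self.data_dir is not None:
            self._train_scenes = load_split(self.data_dir, "train")
            self._val_scenes = load_split(self.data_dir, "val")
        else:
            spec = self.config.data.to_spec(self.config.train.image_size,
                                            seed=self.config.seed)
            rng = np.random.default_rng(spec.seed)
            scenes = [render_scene(spec, rng) for _ in range(spec.total_images)]
            n = spec.images_per_split
            # deterministic order: train block, then test, then val
            self._train_scenes = scenes[: n["train"]]
            self._val_scenes = scenes[n["train"] + n["test"]:]
        if not self._train_scenes:
            raise ValueError("empty training split")

    def materialize_dataset(self, out_dir: Path) -> dict:
        """Write the configured synthetic dataset to disk (YOLO-TXT)."""
        spec = self.config.data.to_spec(self.config.train.image_size,
                                       seed=self.config.seed)
        return generate_dataset(spec, out_dir)

    # -- fitting -------------------------------------------------------
    def fit(self, epochs: int | None = None, verbose: bool = False,
            eval_on: str = "val") -> DetectionResults:
        cfg = self.config
        self._load_data()
        model = build_model(cfg)
        model.train()
        opt = AdamW(model.parameters(), lr=cfg.train.lr,
                    weight_decay=cfg.train.weight_decay)
        n_epochs = cfg.train.epochs if epochs is None else epochs
        order_rng = np.random.default_rng(cfg.seed + 1)
        history = []
        t0 = time.perf_counter()
        n_train = len(self._train_scenes)
        bs = cfg.train.batch_size
        steps_per_epoch = (n_train + bs - 1) // bs
        total_steps = max(n_epochs * steps_per_epoch, 1)
        base_lr = cfg.train.lr
        step = 0
        for epoch in range(n_epochs):
            perm = order_rng.permutation(n_train)
            sums: dict[str, float] = {}
            n_batches = 0
            for start in range(0, n_train, bs):
                # linear warmup then (optionally) cosine decay
                if step < cfg.train.warmup_steps:
                    opt.lr = base_lr * (step + 1) / cfg.train.warmup_steps
                elif cfg.train.lr_schedule == "cosine":
                    frac = (step - cfg.train.warmup_steps) / max(
                        total_steps - cfg.train.warmup_steps, 1)
                    opt.lr = base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))
                step += 1
                batch_scenes = [self._train_scenes[i] for i in perm[start:start + bs]]
                batch = _scenes_to_batch(batch_scenes)
                model.zero_grad()
                total, parts = training_step(model, batch, cfg)
                total.backward()
                clip_grad_norm(model.parameters(), cfg.train.grad_clip)
                opt.step()
                n_batches += 1
                for k, v in parts.items():
                    sums[k] = sums.get(k, 0.0) + float(v)
            epoch_log = {k: v / n_batches for k, v in sums.items()}
            epoch_log["epoch"] = epoch
            history.append(epoch_log)
            if verbose:
                print(f"epoch {epoch:3d}  total {epoch_log['total']:.4f}  "
                      f"cls {epoch_log['cls']:.4f}  l1 {epoch_log['l1']:.4f}  "
                      f"iou {epoch_log['iou']:.4f}")
        wall = time.perf_counter() - t0

        val = self._val_scenes if eval_on == "val" else self._train_scenes
        metrics, conf = self._evaluate(model, val)
        return DetectionResults(
            config=cfg, model=model, history=history, metrics=metrics,
            num_parameters=model.num_parameters(),
            train_images=n_train, val_images=len(val), wall_time_s=wall,
            confusion=conf,
        )

    def _evaluate(self, model: DiseaseDetector, scenes: list[SceneRecord]):
        dets_per_image, gts_per_image = [], []
        for rec in scenes:
            # rank with a low score floor so the full PR curve is
            # populated; macro P/R applies the operating threshold
            dets_per_image.append(detect(model, rec.image, score_threshold=0.01))
            gts_per_image.append(_scene_ground_truth(rec))
        metrics = evaluate_detections(dets_per_image, gts_per_image,
                                      score_thr=self.config.eval.score_threshold)
        conf = confusion_matrix(dets_per_image, gts_per_image,
                                num_classes=self.config.model.num_classes,
                                iou_thr=self.config.eval.iou_threshold,
                                score_thr=self.config.eval.score_threshold)
        return metrics, conf

    def evaluate(self, results_or_model, split: str = "val") -> dict:
        self._load_data()
        model = getattr(results_or_model, "model", results_or_model)
        scenes = self._val_scenes if split == "val" else self._train_scenes
        metrics, _ = self._evaluate(model, scenes)
        return metrics
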