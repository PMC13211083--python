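"""Tests for the detector assembly, Hungarian matching and training step."""

import itertools

import numpy as np
import pytest

from addetr.config import RunConfig, apply_ablation, desk_profile
from addetr.detector import (
    TrainingError,
    build_model,
    detect,
    hungarian_match,
    training_step,
)
from addetr.model import _scenes_to_batch
from addetr.synth import DatasetSpec, render_scene


def tiny_config(seed=0, **over):
    cfg = desk_profile(seed=seed)
    cfg.train.image_size = 64
    cfg.train.epochs = 1
    cfg.train.batch_size = 4
    cfg.model.backbone.widths = (4, 8, 8, 8, 12)
    cfg.model.backbone.baseline_widths = (8, 12, 16, 20)
    cfg.model.neck.channels = 8
    cfg.model.head.num_queries = 8
    cfg.model.head.num_layers = 1
    cfg.data.total_images = 15
    for k, v in over.items():
        obj = cfg
        *parents, leaf = k.split(".")
        for p in parents:
            obj = getattr(obj, p)
        setattr(obj, leaf, v)
    return cfg


def tiny_batch(cfg, n=3, seed=0):
    spec = cfg.data.to_spec(cfg.train.image_size, seed=seed)
    rng = np.random.default_rng(seed)
    return _scenes_to_batch([render_scene(spec, rng) for _ in range(n)])


class TestBuildModel:
    def test_forward_contract(self):
        cfg = tiny_config()
        model = build_model(cfg)
        logits, boxes = model(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert logits.shape == (1, 8, cfg.model.num_classes)
        assert boxes.shape == (1, 8, 4)
        assert np.all(boxes.data > 0) and np.all(boxes.data < 1)

    def test_same_seed_identical_weights(self):
        m1 = build_model(tiny_config(seed=3))
        m2 = build_model(tiny_config(seed=3))
        s1, s2 = m1.state_dict(), m2.state_dict()
        assert set(s1) == set(s2)
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_different_seed_different_weights(self):
        m1 = build_model(tiny_config(seed=3))
        m2 = build_model(tiny_config(seed=4))
        diffs = sum(not np.array_equal(a, b)
                    for a, b in zip(m1.state_dict().values(), m2.state_dict().values()))
        assert diffs > 0

    def test_ablation_baseline_runnable(self):
        cfg = apply_ablation(tiny_config(), msanet=False, ssaff=False, ipiouv2=False)
        model = build_model(cfg)
        logits, boxes = model(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert np.all(np.isfinite(logits.data))

    def test_msanet_reduces_parameters_under_default_config(self):
        base = RunConfig()
        with_msanet = build_model(apply_ablation(base, msanet=True))
        without = build_model(apply_ablation(base, msanet=False))
        assert with_msanet.num_parameters() < without.num_parameters()

    def test_invalid_config_rejected(self):
        cfg = tiny_config()
        cfg.model.head.num_queries = 0
        with pytest.raises(ValueError):
            build_model(cfg)


class TestHungarianMatch:
    def test_exact_query_matched(self):
        pred = np.array([[0.5, 0.5, 0.2, 0.2], [0.1, 0.1, 0.1, 0.1]])
        scores = np.array([[0.9, 0.1], [0.1, 0.1]])
        qi, gi = hungarian_match(pred, scores, np.array([[0.5, 0.5, 0.2, 0.2]]),
                                 np.array([0]))
        assert list(qi) == [0] and list(gi) == [0]

    def test_permutation_equivariance(self, rng):
        nq, m = 6, 3
        pred = rng.uniform(0.1, 0.9, size=(nq, 4))
        scores = rng.uniform(0.01, 0.99, size=(nq, 4))
        gt = rng.uniform(0.2, 0.8, size=(m, 4))
        labels = rng.integers(0, 4, size=m)
        qi, gi = hungarian_match(pred, scores, gt, labels)
        perm = rng.permutation(nq)
        qi2, gi2 = hungarian_match(pred[perm], scores[perm], gt, labels)
        mapping = {g: q for q, g in zip(qi2, gi2)}
        for q, g in zip(qi, gi):
            assert perm[mapping[g]] == q

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            nq, m = 6, int(rng.integers(1, 6))
            pred = rng.uniform(0.05, 0.95, size=(nq, 4))
            scores = rng.uniform(0.01, 0.99, size=(nq, 3))
            gt = rng.uniform(0.2, 0.8, size=(m, 4))
            labels = rng.integers(0, 3, size=m)
            qi, gi = hungarian_match(pred, scores, gt, labels)

            def cost_of(assign):
                from addetr import iou as iou_fn
                c = 0.0
                for g, q in enumerate(assign):
                    c += 1.0 * -scores[q, labels[g]]
                    c += 5.0 * np.abs(pred[q] - gt[g]).sum()
                    c += 2.0 * (1.0 - iou_fn(pred[q], gt[g], clamp=True))
                return c

            hung = cost_of([qi[list(gi).index(g)] for g in range(m)])
            best = min(cost_of(a) for a in itertools.permutations(range(nq), m))
            assert hung == pytest.approx(best, abs=1e-9)

    def test_too_many_ground_truths(self):
        with pytest.raises(ValueError):
            hungarian_match(np.zeros((2, 4)) + 0.5, np.zeros((2, 3)),
                            np.zeros((3, 4)) + 0.5, np.zeros(3, dtype=int))


class TestTrainingStep:
    def test_finite_grads_for_every_parameter(self):
        cfg = tiny_config()
        model = build_model(cfg)
        total, parts = training_step(model, tiny_batch(cfg), cfg)
        total.backward()
        n_params = n_grads = 0
        for p in model.parameters():
            n_params += 1
            if p.grad is not None:
                n_grads += 1
                assert np.all(np.isfinite(p.grad))
        assert n_grads == n_params

    def test_self_consistent_targets_zero_iou_term(self):
        """Feeding the model's own predictions back as ground truth makes
        the regression term vanish (the matcher pairs each target with
        the query that produced it)."""
        cfg = tiny_config()
        model = build_model(cfg)
        images, _ = tiny_batch(cfg, n=2)
        logits, boxes = model(np.asarray(images, dtype=np.float32))
        targets = []
        for b in range(2):
            targets.append((np.array([0, 1]), boxes.data[b, :2].astype(float)))
        _, parts = training_step(model, (images, targets), cfg)
        assert parts["iou"] == pytest.approx(0.0, abs=1e-5)
        assert parts["l1"] == pytest.approx(0.0, abs=1e-5)

    def test_loss_decreases_over_short_run(self):
        cfg = tiny_config()
        cfg.train.lr = 1e-3
        model = build_model(cfg)
        from addetr.nn import AdamW
        opt = AdamW(model.parameters(), lr=cfg.train.lr)
        batch = tiny_batch(cfg, n=4)
        first = last = None
        for i in range(25):
            model.zero_grad()
            total, parts = training_step(model, batch, cfg)
            total.backward()
            opt.step()
            if i == 0:
                first = parts["total"]
            last = parts["total"]
        assert last < first

    def test_regression_loss_swap_changes_only_iou_component(self):
        cfg_a = tiny_config()
        cfg_b = tiny_config()
        cfg_b.train.regression_loss = "iou"
        model_a = build_model(cfg_a)
        model_b = build_model(cfg_b)
        batch = tiny_batch(cfg_a)
        _, parts_a = training_step(model_a, batch, cfg_a)
        _, parts_b = training_step(model_b, batch, cfg_b)
        assert parts_a["cls"] == pytest.approx(parts_b["cls"], abs=1e-9)
        assert parts_a["l1"] == pytest.approx(parts_b["l1"], abs=1e-9)
        assert parts_a["iou"] != pytest.approx(parts_b["iou"], abs=1e-9)

    def test_nan_weights_raise_training_error(self):
        cfg = tiny_config()
        model = build_model(cfg)
        next(iter(model.parameters())).data[:] = np.nan
        with pytest.raises((TrainingError, ValueError)):
            training_step(model, tiny_batch(cfg), cfg)


class TestDetect:
    def test_threshold_one_yields_empty(self):
        cfg = tiny_config()
        model = build_model(cfg)
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        assert detect(model, img, score_threshold=1.0) == []

    def test_boxes_within_image_bounds(self):
        cfg = tiny_config()
        model = build_model(cfg)
        spec = cfg.data.to_spec(64, seed=0)
        rec = render_scene(spec, np.random.default_rng(0))
        for d in detect(model, rec.image, score_threshold=0.0):
            x1, y1, x2, y2 = d.box.to_xyxy()
            assert 0 <= x1 <= x2 <= 64 and 0 <= y1 <= y2 <= 64
            assert 0.0 <= d.score <= 1.0
            assert 0 <= d.label < cfg.model.num_classes

    def test_indivisible_dims_rejected(self):
        model = build_model(tiny_config())
        with pytest.raises(ValueError):
            detect(model, np.zeros((60, 64, 3), dtype=np.uint8))

    def test_detect_deterministic(self):
        cfg = tiny_config()
        model = build_model(cfg)
        img = (np.random.default_rng(0).uniform(0, 255, (64, 64, 3))).astype(np.uint8)
        d1 = detect(model, img, score_threshold=0.0)
        d2 = detect(model, img, score_threshold=0.0)
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            assert a.score == b.score and a.label == b.label
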