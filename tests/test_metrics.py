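"""Tests for the detection metrics: matching, macro P/R, AP, confusion
matrix.  The 101-point AP is checked against exact step-curve
integration of the precision envelope (independent oracle)."""

import itertools

import numpy as np
import pytest

from addetr.boxes import BoxCWH, Detection, GroundTruth
from addetr.metrics import (
    MatchResult,
    UndefinedMetricError,
    average_precision,
    confusion_matrix,
    detections_from_json,
    detections_to_json,
    evaluate_detections,
    macro_pr,
    match_detections,
)


def det(x, y, w, h, score, label):
    return Detection(BoxCWH(x, y, w, h), score, label)


def gt(x, y, w, h, label):
    return GroundTruth(BoxCWH(x, y, w, h), label)


def exact_envelope_area(scored, n_gt):
    """Independent AP oracle: exact area under the interpolated
    (envelope) precision-recall step curve."""
    order = sorted(scored, key=lambda p: -p[0])
    tp = fp = 0
    points = [(0.0, 1.0)]
    for _, is_tp in order:
        tp += is_tp
        fp += not is_tp
        points.append((tp / n_gt, tp / (tp + fp)))
    recalls = [r for r, _ in points]
    area = 0.0
    prev_r = 0.0
    for r in sorted(set(recalls[1:])):
        env = max(p for rr, p in points if rr >= r)
        area += (r - prev_r) * env
        prev_r = r
    return area


def random_problem(rng, n_classes=3, n_gt=4, n_det=6, size=100):
    gts = [gt(rng.uniform(10, size - 10), rng.uniform(10, size - 10),
              rng.uniform(5, 20), rng.uniform(5, 20), int(rng.integers(n_classes)))
           for _ in range(n_gt)]
    dets = []
    for _ in range(n_det):
        if rng.random() < 0.6 and gts:
            base = gts[rng.integers(len(gts))]
            b = base.box
            dets.append(det(b.xc + rng.normal(0, 3), b.yc + rng.normal(0, 3),
                            max(b.w + rng.normal(0, 3), 1), max(b.h + rng.normal(0, 3), 1),
                            float(rng.uniform(0.3, 1)),
                            base.label if rng.random() < 0.8 else int(rng.integers(n_classes))))
        else:
            dets.append(det(rng.uniform(10, size - 10), rng.uniform(10, size - 10),
                            rng.uniform(5, 20), rng.uniform(5, 20),
                            float(rng.uniform(0.3, 1)), int(rng.integers(n_classes))))
    return dets, gts


class TestMatching:
    def test_no_detections_one_gt(self):
        m = match_detections([], [gt(5, 5, 4, 4, 0)])
        assert m.counts_at(0, 0.0) == (0, 0, 1)

    def test_correct_detection_above_threshold(self):
        m = match_detections([det(6, 5, 4, 4, 0.9, 0)], [gt(5, 5, 4, 4, 0)], iou_thr=0.5)
        assert m.counts_at(0, 0.0) == (1, 0, 0)

    def test_wrong_class_is_fp_and_fn(self):
        m = match_detections([det(5, 5, 4, 4, 0.9, 1)], [gt(5, 5, 4, 4, 0)])
        assert m.counts_at(1, 0.0) == (0, 1, 0)
        assert m.counts_at(0, 0.0) == (0, 0, 1)

    def test_two_detections_one_gt_higher_score_wins(self):
        dets = [det(5, 5, 4, 4, 0.7, 0), det(5.2, 5, 4, 4, 0.9, 0)]
        m = match_detections(dets, [gt(5, 5, 4, 4, 0)])
        pairs = sorted(m.scored[0], key=lambda p: -p[0])
        assert pairs[0] == (0.9, True)
        assert pairs[1] == (0.7, False)

    def test_greedy_never_beats_exhaustive_optimum(self, rng):
        """Sanity bound: the greedy TP count can't exceed the maximum
        over all one-to-one assignments (exhaustive on small instances)."""
        for _ in range(20):
            dets, gts = random_problem(rng, n_gt=3, n_det=4)
            m = match_detections(dets, gts, iou_thr=0.5)
            greedy_tp = sum(m.counts_at(c, 0.0)[0] for c in m.n_gt)
            best = 0
            from addetr import iou as iou_fn
            for perm in itertools.permutations(range(len(dets)), min(len(gts), len(dets))):
                tp = sum(
                    1 for j, i in enumerate(perm)
                    if dets[i].label == gts[j].label
                    and iou_fn(dets[i].box, gts[j].box) >= 0.5
                )
                best = max(best, tp)
            assert greedy_tp <= best

    def test_conservation_tp_plus_fn(self, rng):
        """TP_c + FN_c equals the ground-truth count of class c at every
        IoU threshold, on fuzzed instances."""
        for k in range(30):
            dets, gts = random_problem(rng)
            for thr in (0.3, 0.5, 0.75, 0.9):
                m = match_detections(dets, gts, iou_thr=thr)
                for c, n in m.n_gt.items():
                    tp, fp, fn = m.counts_at(c, 0.0)
                    assert tp + fn == n


class TestMacroPR:
    def test_perfect_detector(self):
        gts = [gt(5, 5, 4, 4, 0), gt(20, 20, 6, 6, 1)]
        dets = [det(5, 5, 4, 4, 0.9, 0), det(20, 20, 6, 6, 0.8, 1)]
        m = match_detections(dets, gts)
        assert macro_pr(m) == (1.0, 1.0)

    def test_unweighted_class_mean(self):
        # class 0: P=1 (1 TP); class 1: P=0.5 (1 TP, 1 FP)
        gts = [gt(5, 5, 4, 4, 0), gt(20, 20, 6, 6, 1)]
        dets = [det(5, 5, 4, 4, 0.9, 0), det(20, 20, 6, 6, 0.9, 1),
                det(50, 50, 6, 6, 0.8, 1)]
        m = match_detections(dets, gts)
        p, r = macro_pr(m, score_thr=0.0)
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(1.0)

    def test_all_wrong_class_gives_zero_precision(self):
        gts = [gt(5, 5, 4, 4, 0)]
        dets = [det(5, 5, 4, 4, 0.9, 1)]
        m = match_detections(dets, gts)
        # class 0 has gts, no predictions -> P_0 = 0; class 1 has no gts -> excluded
        p, r = macro_pr(m, score_thr=0.0)
        assert p == 0.0 and r == 0.0

    def test_no_ground_truth_raises(self):
        with pytest.raises(UndefinedMetricError):
            macro_pr(match_detections([det(5, 5, 4, 4, 0.9, 0)], []))

    def test_matches_from_scratch_recount(self, rng):
        """Macro P/R equals an independent per-class recount."""
        from addetr import iou as iou_fn
        for _ in range(10):
            dets, gts = random_problem(rng)
            m = match_detections(dets, gts, iou_thr=0.5)
            p, r = macro_pr(m, score_thr=0.0)
            # independent recount: replay greedy matching per class
            ps, rs = [], []
            for c in sorted({g.label for g in gts}):
                cdets = sorted([d for d in dets if d.label == c], key=lambda d: -d.score)
                cgts = [g for g in gts if g.label == c]
                used = set()
                tp = 0
                for d in cdets:
                    cands = [(iou_fn(d.box, g.box), j) for j, g in enumerate(cgts)
                             if j not in used and iou_fn(d.box, g.box) >= 0.5]
                    if cands:
                        _, j = max(cands)
                        used.add(j)
                        tp += 1
                ps.append(tp / len(cdets) if cdets else 0.0)
                rs.append(tp / len(cgts))
            assert p == pytest.approx(np.mean(ps))
            assert r == pytest.approx(np.mean(rs))


class TestAveragePrecision:
    def test_all_found_no_fp(self):
        assert average_precision([(1.0, True), (1.0, True)], 2) == pytest.approx(1.0)

    def test_single_fp_only(self):
        assert average_precision([(0.9, False)], 1) == 0.0

    def test_empty_detections(self):
        assert average_precision([], 3) == 0.0

    def test_no_gt_raises(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([(0.9, True)], 0)

    def test_three_det_example_matches_envelope_integral(self):
        scored = [(0.9, True), (0.8, False), (0.7, True)]
        ap101 = average_precision(scored, 2)
        exact = exact_envelope_area(scored, 2)
        # 101-point quadrature of the exact envelope: agreement to the
        # sampling resolution (one recall step = 1/n_gt spans <= n_gt+1
        # sample points)
        assert ap101 == pytest.approx(exact, abs=(2 + 1) / 101)

    def test_fuzzed_against_envelope_integral(self, rng):
        for _ in range(50):
            n_gt = int(rng.integers(1, 6))
            n = int(rng.integers(1, 10))
            scored = [(float(rng.uniform()), bool(rng.random() < 0.5)) for _ in range(n)]
            # a valid detection set cannot contain more TPs than ground truths
            tp_idx = [i for i, (_, t) in enumerate(scored) if t]
            for i in tp_idx[n_gt:]:
                scored[i] = (scored[i][0], False)
            if not any(t for _, t in scored):
                continue
            ap101 = average_precision(scored, n_gt)
            exact = exact_envelope_area(scored, n_gt)
            assert ap101 == pytest.approx(exact, abs=(n_gt + 1) / 101)

    def test_invariant_under_monotone_score_rescaling(self, rng):
        scored = [(float(rng.uniform()), bool(rng.random() < 0.6)) for _ in range(12)]
        rescaled = [(0.1 + 0.8 * s ** 3, t) for s, t in scored]
        assert average_precision(scored, 5) == pytest.approx(average_precision(rescaled, 5))


class TestEvaluateDetections:
    def test_map50_at_least_map50_95(self, rng):
        for _ in range(5):
            dets, gts = random_problem(rng, n_gt=5, n_det=8)
            res = evaluate_detections([dets], [gts])
            assert res["map50"] >= res["map50_95"] - 1e-12

    def test_perfect_detector_full_marks(self):
        gts = [[gt(20, 20, 10, 10, 0), gt(60, 60, 14, 14, 1)]]
        dets = [[det(20, 20, 10, 10, 0.95, 0), det(60, 60, 14, 14, 0.9, 1)]]
        res = evaluate_detections(dets, gts)
        assert res["precision"] == 1.0 and res["recall"] == 1.0
        assert res["map50"] == pytest.approx(1.0)
        assert res["map50_95"] == pytest.approx(1.0)

    def test_misaligned_lists_raise(self):
        with pytest.raises(ValueError):
            evaluate_detections([[]], [[], []])


class TestConfusionMatrix:
    def test_perfect_detector_identity_block(self):
        gts = [[gt(20, 20, 10, 10, 0), gt(60, 60, 14, 14, 1)]]
        dets = [[det(20, 20, 10, 10, 0.95, 0), det(60, 60, 14, 14, 0.9, 1)]]
        mat = confusion_matrix(dets, gts, num_classes=2)
        np.testing.assert_allclose(mat[:2, :2], np.eye(2))

    def test_rows_normalized(self, rng):
        dets, gts = random_problem(rng, n_gt=6, n_det=8)
        mat = confusion_matrix([dets], [gts], num_classes=3, score_thr=0.0)
        sums = mat.sum(axis=1)
        for s in sums:
            assert s == pytest.approx(1.0) or s == 0.0

    def test_cross_class_confusion_recorded(self):
        # class-A ground truth detected as class B at IoU ~0.7
        gts = [[gt(20, 20, 10, 10, 0)]]
        dets = [[det(21, 20, 10, 10, 0.9, 1)]]
        mat = confusion_matrix(dets, gts, num_classes=2)
        assert mat[0, 1] == 1.0

    def test_unmatched_go_to_background(self):
        gts = [[gt(20, 20, 10, 10, 0)]]
        dets = [[det(80, 80, 10, 10, 0.9, 1)]]
        mat = confusion_matrix(dets, gts, num_classes=2)
        assert mat[0, 2] == 1.0      # missed gt -> background column
        assert mat[2, 1] == 1.0      # spurious det -> background row


class TestDetectionIO:
    def test_json_roundtrip(self, tmp_path, rng):
        dets, _ = random_problem(rng)
        per_image = {"img_0": dets[:3], "img_1": dets[3:]}
        path = tmp_path / "dets.json"
        detections_to_json(per_image, path)
        back = detections_from_json(path)
        assert set(back) == {"img_0", "img_1"}
        for key in back:
            for a, b in zip(per_image[key], back[key]):
                np.testing.assert_allclose(a.box.as_array(), b.box.as_array(), atol=1e-9)
                assert a.score == pytest.approx(b.score)
                assert a.label == b.label
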