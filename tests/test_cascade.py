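"""Cascade detector: integral images, Haar features, boosting, detection."""

import numpy as np
import pytest

from spineseg import cascade as cc
from spineseg import pipeline
from spineseg.imgio import BoundingBox, GrayImage, iou
from spineseg.synthetic import PhantomSpec, generate_phantom


class TestIntegral:
    def test_all_ones(self):
        ii = cc.integral(np.ones((4, 4)))
        assert ii.ii[-1, -1] == 16

    def test_single_pixel(self):
        ii = cc.integral(np.array([[7.5]]))
        assert ii.ii[-1, -1] == 7.5

    def test_exhaustive_rectangles(self):
        rng = np.random.default_rng(1)
        px = rng.random((8, 8))
        ii = cc.integral(px)
        for y in range(8):
            for x in range(8):
                for h in range(1, 8 - y + 1):
                    for w in range(1, 8 - x + 1):
                        expect = px[y : y + h, x : x + w].sum()
                        got = cc._rect_sum(ii.ii, x, y, w, h)
                        assert got == pytest.approx(expect, abs=1e-9)


class TestFeatures:
    @pytest.fixture(scope="class")
    def pool(self):
        return cc.generate_feature_pool((24, 24), feature_stride=4, include_tilted=True)

    def test_zero_on_constant_window(self, pool):
        integ = cc.integral(np.full((24, 24), 42.0))
        win = BoundingBox(0, 0, 24, 24)
        for f in pool[::7]:
            assert cc.eval_feature(f, integ, win) == 0.0

    def test_edge_feature_hand_value(self):
        # left half 0, right half 1: an edge_v spanning the window
        px = np.zeros((24, 24))
        px[:, 12:] = 1.0
        feat = cc.HaarFeature("edge_v", [((0, 0, 12, 24), 1.0), ((12, 0, 12, 24), -1.0)])
        integ = cc.integral(px)
        raw = 0.0 - 12 * 24  # brute-force rect sums: left 0, right 288
        std = px.std()
        got = cc.eval_feature(feat, integ, BoundingBox(0, 0, 24, 24))
        assert got == pytest.approx(raw / std)

    def test_affine_intensity_invariance(self, pool):
        rng = np.random.default_rng(3)
        px = rng.random((24, 24)) * 50
        win = BoundingBox(0, 0, 24, 24)
        v1 = [cc.eval_feature(f, cc.integral(px), win) for f in pool[::11]]
        v2 = [cc.eval_feature(f, cc.integral(3.0 * px + 17.0), win) for f in pool[::11]]
        np.testing.assert_allclose(v1, v2, atol=1e-8)

    def test_out_of_bounds_window(self, pool):
        integ = cc.integral(np.zeros((24, 24)))
        with pytest.raises(ValueError):
            cc.eval_feature(pool[0], integ, BoundingBox(10, 10, 24, 24))

    def test_weighted_areas_sum_to_zero(self):
        with pytest.raises(ValueError):
            cc.HaarFeature("edge_v", [((0, 0, 4, 4), 1.0), ((4, 0, 2, 4), -1.0)])

    def test_mask_equals_integral_route(self, pool):
        rng = np.random.default_rng(5)
        win_px = rng.random((24, 24)) * 100
        flat_vals = cc.compute_feature_values(pool[:80], win_px[None])
        integ = cc.integral(win_px)
        direct = [cc.eval_feature(f, integ, BoundingBox(0, 0, 24, 24)) for f in pool[:80]]
        np.testing.assert_allclose(flat_vals[0], direct, atol=1e-9)


def _adaboost_oracle(values, labels, n_rounds):
    """Discrete AdaBoost with exhaustive threshold search, explicit loops.

    ``values`` is (n_samples, n_features); returns the list of
    (feature, threshold, polarity, alpha) and the final weights.
    """
    n, m = values.shape
    w = np.full(n, 1.0 / n)
    chosen = []
    for _ in range(n_rounds):
        best = (None, None, None, np.inf)
        for j in range(m):
            vs = np.sort(np.unique(values[:, j]))
            cands = [vs[0] - 1.0] + [(a + b) / 2 for a, b in zip(vs[:-1], vs[1:])] + [vs[-1] + 1.0]
            for thr in cands:
                for pol in (1, -1):
                    pred = np.where(pol * (values[:, j] - thr) >= 0, 1.0, -1.0)
                    err = w[pred != labels].sum()
                    if err < best[3] - 1e-15:
                        best = (j, thr, pol, err)
        j, thr, pol, err = best
        err = max(err, 1e-10)
        alpha = np.log((1 - err) / err)
        pred = np.where(pol * (values[:, j] - thr) >= 0, 1.0, -1.0)
        w = w * np.exp(alpha * (pred != labels))
        w = w / w.sum()
        chosen.append((j, thr, pol, alpha))
    return chosen, w


class TestTrainStage:
    def _samples_from_values(self, values):
        """Wrap precomputed 1-feature values as dummy windows via identity."""
        return values

    def test_separable_toy_single_stump(self):
        # one feature: positives > 0, negatives < 0
        F = np.array([[2.0], [1.0], [-1.0], [-2.0]])
        labels = np.array([1.0, 1.0, -1.0, -1.0])
        w = np.full(4, 0.25)
        stage = cc.train_stage(None, None, labels, w, {"max_stumps": 5}, feature_values=F)
        assert len(stage.stumps) == 1
        scores = stage.scores(F)
        assert ((scores >= stage.stage_threshold) == (labels > 0)).all()
        assert stage.hit_rate == 1.0 and stage.false_alarm == 0.0

    def test_matches_bruteforce_adaboost(self):
        # 2-feature toy with one inseparable point
        F = np.array(
            [[3.0, 0.1], [2.0, -0.2], [-1.0, 0.3], [-2.0, -0.4], [1.5, -0.6], [-0.5, 0.5]]
        )
        labels = np.array([1.0, 1.0, -1.0, -1.0, -1.0, 1.0])
        w = np.full(6, 1 / 6)
        oracle, w_final = _adaboost_oracle(F, labels, n_rounds=3)
        stage = cc.train_stage(
            None, None, labels, w,
            {"max_stumps": 3, "min_hit_rate": 1.0, "max_false_alarm": 0.0},
            feature_values=F,
        )
        for stump, (j, thr, pol, alpha) in zip(stage.stumps, oracle):
            assert stump.feature_index == j
            assert stump.polarity == pol
            assert stump.threshold == pytest.approx(thr)
            assert abs(stump.right) == pytest.approx(alpha)
        assert w_final.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unlearnable_stage(self):
        F = np.array([[1.0], [1.0]])
        labels = np.array([1.0, -1.0])
        with pytest.raises(cc.TrainingError):
            cc.train_stage(None, None, labels, np.array([0.5, 0.5]), feature_values=F)

    def test_requires_both_classes(self):
        F = np.zeros((3, 1))
        with pytest.raises(ValueError):
            cc.train_stage(None, None, np.ones(3), np.full(3, 1 / 3), feature_values=F)


@pytest.fixture(scope="module")
def tiny_cascade():
    """Small cascade trained on a 10-image phantom set (fast, module scope)."""
    from spineseg.synthetic import generate_dataset
    from spineseg import augment as ag
    from spineseg.imgio import BinaryMask

    man = generate_dataset(10, seed=31)
    pos, neg = [], []
    for it in man["items"]:
        img = it["image"]
        body = np.zeros(img.shape, bool)
        for box, _lms, mask in it["truths"]:
            x0, y0 = int(max(0, box.x)), int(max(0, box.y))
            x1 = int(min(img.shape[1], box.x + box.width))
            y1 = int(min(img.shape[0], box.y + box.height))
            pos.append(img.pixels[y0:y1, x0:x1])
            body |= mask.pixels
        neg.append(ag.inpaint(img, BinaryMask(body, img.spacing)))
    params = {"n_stages": 3, "seed": 7, "n_neg_per_stage": 150, "feature_stride": 4}
    return cc.train_cascade(pos, neg, params), neg, params


class TestTrainCascade:
    def test_stage_log_meets_hit_rate(self, tiny_cascade):
        model, _neg, params = tiny_cascade
        for entry in model.metadata["training_log"]:
            assert entry["hit_rate"] >= 0.995

    def test_same_seed_byte_identical(self, tiny_cascade, tmp_path):
        from spineseg.synthetic import generate_dataset
        from spineseg import augment as ag
        from spineseg.imgio import BinaryMask

        model, neg, params = tiny_cascade
        man = generate_dataset(10, seed=31)
        pos = []
        for it in man["items"]:
            img = it["image"]
            for box, _lms, _mask in it["truths"]:
                x0, y0 = int(max(0, box.x)), int(max(0, box.y))
                x1 = int(min(img.shape[1], box.x + box.width))
                y1 = int(min(img.shape[0], box.y + box.height))
                pos.append(img.pixels[y0:y1, x0:x1])
        model2 = cc.train_cascade(pos, neg, params)
        model.save(tmp_path / "a.json")
        model2.save(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_cumulative_false_alarm_bound(self, tiny_cascade):
        model, neg, params = tiny_cascade
        rng = np.random.default_rng(123)
        wins = cc._mine_negatives([n.pixels for n in neg], [], model.features,
                                  model.window, 400, rng)
        k = len(model.stages)
        acc = cc._accept_windows(wins, model.stages, model.features)
        assert acc.mean() <= 0.5**k + 1e-9

    def test_acceptance_is_stage_conjunction(self, tiny_cascade):
        model, neg, _params = tiny_cascade
        rng = np.random.default_rng(5)
        wins = cc._mine_negatives([n.pixels for n in neg], [], model.features,
                                  model.window, 50, rng)
        F = cc.compute_feature_values(model.features, wins)
        per_stage = np.ones(len(wins), bool)
        for stage in model.stages:
            per_stage &= stage.passes(F)
        np.testing.assert_array_equal(model.accept(F), per_stage)

    def test_serialization_round_trip(self, tiny_cascade, tmp_path):
        model, _neg, _params = tiny_cascade
        model.save(tmp_path / "m.json")
        back = cc.CascadeModel.load(tmp_path / "m.json")
        rng = np.random.default_rng(9)
        wins = rng.random((20, model.window[1], model.window[0])) * 100
        F1 = cc.compute_feature_values(model.features, wins)
        F2 = cc.compute_feature_values(back.features, wins)
        np.testing.assert_array_equal(model.accept(F1), back.accept(F2))


class TestDetect:
    def test_blank_image_no_detections(self, tiny_cascade):
        model, _neg, _params = tiny_cascade
        blank = GrayImage(np.full((128, 128), 10.0))
        assert cc.detect(blank, model) == []

    def test_phantom_vertebrae_recovered(self, tiny_cascade):
        model, _neg, _params = tiny_cascade
        image, truths = generate_phantom(PhantomSpec(seed=555))
        dets = cc.filter_by_size(cc.detect(image, model))
        found = sum(
            1 for box, _l, _m in truths if max((iou(d, box) for d in dets), default=0) >= 0.5
        )
        assert found >= 4

    def test_min_neighbors_monotone(self, tiny_cascade):
        model, _neg, _params = tiny_cascade
        image, _ = generate_phantom(PhantomSpec(seed=555))
        d1 = cc.detect(image, model, min_neighbors=1)
        d3 = cc.detect(image, model, min_neighbors=3)
        keys3 = {(b.x, b.y, b.width, b.height) for b in d3}
        keys1 = {(b.x, b.y, b.width, b.height) for b in d1}
        assert keys3 <= keys1

    def test_translation_covariance(self, tiny_cascade):
        model, _neg, _params = tiny_cascade
        image, truths = generate_phantom(PhantomSpec(seed=556))
        step = 2
        shifted = GrayImage(np.roll(image.pixels, step, axis=1), image.spacing)
        d0 = cc.filter_by_size(cc.detect(image, model, step_px=step))
        d1 = cc.filter_by_size(cc.detect(shifted, model, step_px=step))
        assert d0 and d1
        # every original detection has a shifted counterpart nearby
        matched = 0
        for b in d0:
            moved = BoundingBox(b.x + step, b.y, b.width, b.height)
            if max((iou(moved, c) for c in d1), default=0) >= 0.6:
                matched += 1
        assert matched >= max(1, int(0.8 * len(d0)))


class TestFilterBySize:
    def test_empty(self):
        assert cc.filter_by_size([]) == []

    def test_outlier_removed(self):
        boxes = [
            BoundingBox(0, 0, 10, 10),
            BoundingBox(0, 0, 10, 11),
            BoundingBox(0, 0, 10, 9),
            BoundingBox(0, 0, 20, 20),
        ]
        kept = cc.filter_by_size(boxes)
        assert len(kept) == 3
        assert all(b.area < 200 for b in kept)

    def test_all_equal_unchanged(self):
        boxes = [BoundingBox(i, 0, 10, 10) for i in range(5)]
        assert cc.filter_by_size(boxes) == boxes

    def test_fewer_than_three_unchanged(self):
        boxes = [BoundingBox(0, 0, 1, 1), BoundingBox(0, 0, 50, 50)]
        assert cc.filter_by_size(boxes) == boxes
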