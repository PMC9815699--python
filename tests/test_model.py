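"""Detector assembly, decoding, NMS, loss and the training loop."""

import math

import numpy as np
import pytest

from weeddet import autodiff as ad
from weeddet.model import (
    DetectionSet,
    ModelConfig,
    NonFiniteLossError,
    build_model,
    decode,
    detection_loss,
    evaluate_model,
    load_checkpoint,
    nms,
    save_checkpoint,
    train,
)
from weeddet.synthdata import SceneParams, generate_corpus

from .oracles import nms_quadratic

TOGGLE_GRID = [
    dict(use_transformer=False, use_cffi=False, use_asff=False),
    dict(use_transformer=True, use_cffi=False, use_asff=False),
    dict(use_transformer=False, use_cffi=True, use_asff=False),
    dict(use_transformer=True, use_cffi=True, use_asff=False),
    dict(use_transformer=True, use_cffi=True, use_asff=True),
]


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(ModelConfig(input_size=96, seed=0))


class TestBuild:
    def test_prediction_grids_follow_strides(self, tiny_model, rng):
        x = ad.Tensor(rng.normal(size=(1, 3, 96, 96)).astype(np.float32))
        preds = tiny_model.forward(x)
        assert [p.shape[2:] for p in preds] == [(12, 12), (6, 6), (3, 3)]
        assert all(p.shape[1] == 3 * 7 for p in preds)

    def test_input_size_must_be_multiple_of_32(self):
        with pytest.raises(ValueError, match="32"):
            ModelConfig(input_size=100)

    def test_ablation_grid_has_distinct_parameter_counts(self):
        counts = [build_model(ModelConfig(**t)).n_parameters()
                  for t in TOGGLE_GRID]
        assert len(set(counts)) == len(counts)

    def test_same_seed_same_initial_parameters(self):
        a = build_model(ModelConfig(seed=3))
        b = build_model(ModelConfig(seed=3))
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.state_arrays(), b.state_arrays()))

    def test_batch_consistency_of_forward_pass(self, tiny_model, rng):
        x = rng.normal(size=(2, 3, 96, 96)).astype(np.float32)
        together = tiny_model.forward(ad.Tensor(x))
        sep0 = tiny_model.forward(ad.Tensor(x[:1]))
        sep1 = tiny_model.forward(ad.Tensor(x[1:]))
        for t, a, b in zip(together, sep0, sep1):
            np.testing.assert_allclose(t.data[0], a.data[0], atol=1e-5)
            np.testing.assert_allclose(t.data[1], b.data[0], atol=1e-5)

    def test_checkpoint_roundtrip(self, tiny_model, tmp_path, rng):
        path = tmp_path / "w.npz"
        save_checkpoint(path, tiny_model)
        back = load_checkpoint(path)
        x = ad.Tensor(rng.normal(size=(1, 3, 96, 96)).astype(np.float32))
        p1 = tiny_model.forward(x)
        p2 = back.forward(x)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.data, b.data)


class TestDecode:
    def test_zero_logits_closed_form(self):
        cfg = ModelConfig(input_size=96)
        preds = [np.zeros((1, 21, s, s), dtype=np.float32)
                 for s in (12, 6, 3)]
        dets = decode(preds, cfg)[0]
        assert all(b[1] == pytest.approx(0.25) for b in dets.boxes)
        # first level, first anchor, cell (0,0): centered at half a stride
        b = dets.boxes[0]
        cx, cy = (b[2] + b[4]) / 2, (b[3] + b[5]) / 2
        assert (cx, cy) == (pytest.approx(4.0), pytest.approx(4.0))
        assert b[4] - b[2] == pytest.approx(cfg.anchors[0][0][0])

    def test_hand_set_logits_invert_the_transform(self):
        cfg = ModelConfig(input_size=96)
        preds = [np.full((1, 21, s, s), -20.0, dtype=np.float32)
                 for s in (12, 6, 3)]
        # one cell on the stride-16 level, anchor 1: sigmoid(t)=0.75 for x,
        # sigmoid(t)=0.5 for y/w/h, objectness saturated high
        t75 = math.log(3)
        view = preds[1].reshape(3, 7, 6, 6)
        view[1, 0, 2, 3] = t75     # x
        view[1, 1, 2, 3] = 0.0     # y
        view[1, 2, 2, 3] = 0.0     # w
        view[1, 3, 2, 3] = 0.0     # h
        view[1, 4, 2, 3] = 20.0    # obj
        view[1, 5, 2, 3] = 20.0    # class 0
        dets = decode([preds[0], view.reshape(1, 21, 6, 6), preds[2]], cfg)[0]
        best = max(dets.boxes, key=lambda b: b[1])
        aw, ah = cfg.anchors[1][1]
        exp_cx = (2 * 0.75 - 0.5 + 3) * 16
        exp_cy = (2 * 0.5 - 0.5 + 2) * 16
        assert (best[2] + best[4]) / 2 == pytest.approx(exp_cx, rel=1e-4)
        assert (best[3] + best[5]) / 2 == pytest.approx(exp_cy, rel=1e-4)
        assert best[4] - best[2] == pytest.approx(aw, rel=1e-4)
        assert best[5] - best[3] == pytest.approx(ah, rel=1e-4)
        assert best[0] == 0

    def test_confidences_are_probabilities(self, tiny_model, rng):
        x = ad.Tensor(rng.normal(size=(1, 3, 96, 96)).astype(np.float32))
        dets = decode(tiny_model.forward(x), tiny_model.config)[0]
        assert all(0.0 <= b[1] <= 1.0 for b in dets.boxes)


class TestNMS:
    def test_duplicate_suppression(self):
        d = DetectionSet(boxes=[(0, 0.9, 0, 0, 4, 4), (0, 0.8, 0, 0, 4, 4)])
        out = nms(d, iou_threshold=0.5, conf_threshold=0.0)
        assert len(out.boxes) == 1 and out.boxes[0][1] == 0.9

    def test_disjoint_boxes_all_survive(self):
        d = DetectionSet(boxes=[(0, 0.9, 0, 0, 2, 2), (0, 0.8, 10, 10, 12, 12),
                                (1, 0.7, 20, 20, 22, 22)])
        out = nms(d, iou_threshold=0.5, conf_threshold=0.0)
        assert len(out.boxes) == 3

    def test_different_classes_do_not_suppress(self):
        d = DetectionSet(boxes=[(0, 0.9, 0, 0, 4, 4), (1, 0.8, 0, 0, 4, 4)])
        out = nms(d, iou_threshold=0.5, conf_threshold=0.0)
        assert len(out.boxes) == 2

    def test_random_boxes_match_quadratic_oracle(self, rng):
        boxes = []
        for _ in range(10):
            x1, y1 = rng.uniform(0, 20, 2)
            w, h = rng.uniform(2, 10, 2)
            boxes.append((int(rng.integers(2)), float(rng.random()),
                          x1, y1, x1 + w, y1 + h))
        out = nms(DetectionSet(boxes=boxes), iou_threshold=0.4,
                  conf_threshold=0.1)
        oracle = nms_quadratic(boxes, 0.4, 0.1)
        assert out.boxes == oracle

    def test_output_sorted_by_confidence(self, rng):
        boxes = [(0, float(c), i * 10.0, 0.0, i * 10.0 + 5, 5.0)
                 for i, c in enumerate(rng.random(6))]
        out = nms(DetectionSet(boxes=boxes), 0.5, 0.0)
        confs = [b[1] for b in out.boxes]
        assert confs == sorted(confs, reverse=True)


class TestLoss:
    def _cfg(self):
        return ModelConfig(input_size=32)   # grids 4/2/1 for fast loss tests

    def test_empty_truth_zero_logits_gives_log2_objectness(self):
        cfg = self._cfg()
        preds = [ad.Tensor(np.zeros((1, 21, s, s)))
                 for s in (4, 2, 1)]
        losses = detection_loss(preds, [[]], cfg)
        assert float(losses["box"].data) == 0.0
        assert float(losses["cls"].data) == 0.0
        expected = math.log(2) * np.mean([4.0, 1.0, 0.4])
        assert float(losses["obj"].data) == pytest.approx(expected, rel=1e-5)

    def test_loss_near_zero_at_optimum(self):
        """Logits crafted to hit one target exactly, everything else
        saturated off."""
        cfg = self._cfg()
        # target: a 10x10 box centered at (16, 16) -> stride 8 cell (2, 2)
        truth = [[(0, 16.0, 16.0, 10.0, 10.0)]]
        preds = [np.full((1, 21, s, s), -30.0, dtype=np.float32)
                 for s in (4, 2, 1)]
        import weeddet.model as M
        targets = M.assign_targets(truth, cfg)
        for level, tlist in enumerate(targets):
            view = preds[level].reshape(3, 7, preds[level].shape[2],
                                        preds[level].shape[3])
            s = cfg.strides[level]
            for (_, a, ci, cj, gx, gy, gw, gh, cls) in tlist:
                aw, ah = cfg.anchors[level][a]

                def inv_xy(frac):
                    sig = (frac + 0.5) / 2
                    sig = min(max(sig, 1e-4), 1 - 1e-4)
                    return math.log(sig / (1 - sig))

                def inv_wh(ratio):
                    sig = math.sqrt(ratio) / 2
                    sig = min(max(sig, 1e-4), 1 - 1e-4)
                    return math.log(sig / (1 - sig))

                view[a, 0, ci, cj] = inv_xy(gx - cj)
                view[a, 1, ci, cj] = inv_xy(gy - ci)
                view[a, 2, ci, cj] = inv_wh(gw * s / aw)
                view[a, 3, ci, cj] = inv_wh(gh * s / ah)
                view[a, 4, ci, cj] = 30.0
                view[a, 5 + cls, ci, cj] = 30.0
        losses = detection_loss([ad.Tensor(p) for p in preds], truth, cfg)
        assert float(losses["total"].data) < 1e-3

    def test_loss_components_non_negative_random_inputs(self, rng):
        cfg = self._cfg()
        for _ in range(100):
            preds = [ad.Tensor(rng.normal(0, 3, size=(1, 21, s, s)))
                     for s in (4, 2, 1)]
            truth = [[(int(rng.integers(2)), float(rng.uniform(4, 28)),
                       float(rng.uniform(4, 28)), float(rng.uniform(2, 12)),
                       float(rng.uniform(2, 12)))]]
            losses = detection_loss(preds, truth, cfg)
            for name in ("box", "obj", "cls", "total"):
                v = float(losses[name].data)
                assert np.isfinite(v) and v >= 0.0


@pytest.fixture(scope="module")
def small_train_set():
    params = SceneParams(image_size=(96, 96), n_crops=3, n_weeds=2,
                         crop_radius_range=(7.0, 10.0),
                         weed_radius_range=(2.5, 4.5), seed=21)
    images, _ = generate_corpus(8, params, (3, 2))
    return images


class TestTraining:
    def test_zero_learning_rate_freezes_parameters(self, small_train_set):
        model = build_model(ModelConfig(seed=1))
        before = [a.copy() for a in model.state_arrays()]
        state = train(model, small_train_set, epochs=2, lr=0.0, seed=0)
        assert all(np.array_equal(a, b)
                   for a, b in zip(before, model.state_arrays()))
        assert state.total_loss[0] == pytest.approx(state.total_loss[1])

    def test_same_seed_gives_identical_loss_curves(self, small_train_set):
        s1 = train(build_model(ModelConfig(seed=1)), small_train_set,
                   epochs=3, seed=5)
        s2 = train(build_model(ModelConfig(seed=1)), small_train_set,
                   epochs=3, seed=5)
        assert s1.total_loss == s2.total_loss

    def test_training_reduces_loss(self, small_train_set):
        model = build_model(ModelConfig(seed=1))
        state = train(model, small_train_set, epochs=10, seed=0)
        assert state.total_loss[-1] < state.total_loss[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(build_model(ModelConfig()), [], epochs=1)
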