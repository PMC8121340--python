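"""Edge network: architecture contracts, balanced edge loss, training."""

import math

import numpy as np
import pytest

from octlayers.edge_net import (EdgeModelConfig, build_edge_model, predict_edge,
                                train_edge, weighted_edge_loss,
                                _edge_loss_and_grads)
from octlayers.nn.optim import Adam


def loss_oracle(pred: np.ndarray, truth: np.ndarray) -> float:
    """Scalar double-loop implementation of the class-balanced edge loss."""
    eps = 1e-7
    n = truth.size
    beta = 1.0 - truth.sum() / n
    total = 0.0
    for i in range(truth.shape[0]):
        for j in range(truth.shape[1]):
            p = min(max(pred[i, j], eps), 1 - eps)
            if truth[i, j]:
                total -= beta * math.log(p)
            else:
                total -= (1 - beta) * math.log(1 - p)
    return total


class TestWeightedEdgeLoss:
    def test_worked_2x2_case(self):
        truth = np.array([[1, 0], [0, 0]])
        pred = np.full((2, 2), 0.5)
        # beta = 3/4; loss = -(3/4) log .5 - (1/4)*3 log .5 = 1.5 ln 2
        assert weighted_edge_loss(pred, truth) == pytest.approx(1.5 * math.log(2), abs=1e-6)

    def test_perfect_prediction_near_zero(self):
        truth = np.zeros((8, 8), dtype=int)
        truth[3] = 1
        eps = 1e-7
        pred = np.where(truth == 1, 1 - eps, eps)
        assert weighted_edge_loss(pred, truth) < 10 * eps * truth.size

    def test_matches_loop_oracle_on_random_maps(self, rng):
        for _ in range(10):
            truth = (rng.random((8, 8)) < 0.15).astype(int)
            if truth.sum() == 0:
                truth[0, 0] = 1
            pred = rng.random((8, 8))
            ours = weighted_edge_loss(pred, truth)
            assert ours == pytest.approx(loss_oracle(pred, truth), abs=1e-6)

    def test_all_background_truth_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="no edge pixels"):
            out = weighted_edge_loss(np.full((4, 4), 0.9), np.zeros((4, 4), dtype=int))
        assert out == 0.0

    def test_non_binary_truth_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            weighted_edge_loss(np.zeros((2, 2)), np.array([[0, 2], [0, 1]]))

    def test_multi_output_weighting(self, rng):
        truth = np.zeros((4, 4), dtype=int)
        truth[1] = 1
        preds = [rng.random((4, 4)) for _ in range(3)]
        separate = sum(weighted_edge_loss(p, truth) for p in preds)
        combined = weighted_edge_loss(preds, truth)
        assert combined == pytest.approx(separate, rel=1e-12)
        halved = weighted_edge_loss(preds, truth, per_output_weights=[0.5] * 3)
        assert halved == pytest.approx(0.5 * separate, rel=1e-12)


class TestArchitecture:
    def test_input_size_must_be_multiple_of_16(self):
        with pytest.raises(ValueError, match="multiples of 16"):
            EdgeModelConfig(input_size=(100, 100)).validate()
        EdgeModelConfig(input_size=(64, 64)).validate()  # no error

    def test_forward_produces_seven_maps_in_unit_range(self, rng):
        cfg = EdgeModelConfig(input_size=(64, 64), width_mult=0.0625, seed=0)
        model = build_edge_model(cfg)
        x = rng.random((1, 1, 64, 64), dtype=np.float32)
        outs = model.forward(x, train=False)
        assert len(outs) == 7
        for o in outs:
            assert o.shape == (1, 1, 64, 64)
            assert np.isfinite(o).all()
            assert o.min() >= 0.0 and o.max() <= 1.0

    def test_inference_deterministic(self, rng):
        model = build_edge_model(EdgeModelConfig(input_size=(32, 32),
                                                 width_mult=0.0625, seed=1))
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        a = model.forward(x, False)
        b = model.forward(x, False)
        assert all(np.array_equal(u, v) for u, v in zip(a, b))

    def test_parameter_count_identical_across_edges(self):
        counts = set()
        for i, name in enumerate(("ILM", "RPE", "BM")):
            cfg = EdgeModelConfig(input_size=(32, 32), width_mult=0.0625,
                                  edge_name=name, seed=10 + i)
            counts.add(build_edge_model(cfg).n_parameters())
        assert len(counts) == 1

    def test_same_seed_same_initialization(self, rng):
        cfg = EdgeModelConfig(input_size=(32, 32), width_mult=0.0625, seed=4)
        m1 = build_edge_model(cfg)
        m2 = build_edge_model(cfg.replace(edge_name="RPE"))
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        a = m1.forward(x, False)
        b = m2.forward(x, False)
        assert all(np.array_equal(u, v) for u, v in zip(a, b))


class TestTraining:
    def _toy_sample(self, rng, row=10):
        img = rng.random((32, 32)).astype(np.float32) * 0.2
        img[row] += 0.8
        raster = np.zeros((32, 32), dtype=np.float32)
        raster[row] = 1.0
        return img, raster

    def test_single_step_decreases_sample_loss(self, rng):
        model = build_edge_model(EdgeModelConfig(input_size=(32, 32),
                                                 width_mult=0.0625, seed=2))
        img, raster = self._toy_sample(rng)
        x = img[None, None]
        y = raster[None, None].astype(np.float64)
        logits = model.forward_logits(x, train=True)
        l0, grads = _edge_loss_and_grads(logits, y, [1.0] * 7)
        opt = Adam(model.params(), lr=1e-3)
        opt.zero_grad()
        model.backward(grads[:-1], grads[-1])
        opt.step()
        logits2 = model.forward_logits(x, train=True)
        l1, _ = _edge_loss_and_grads(logits2, y, [1.0] * 7)
        assert l1 < l0

    def test_training_progress_and_reproducibility(self, rng):
        data = [self._toy_sample(rng, row=8 + i) for i in range(4)]
        cfg = EdgeModelConfig(input_size=(32, 32), width_mult=0.0625, epochs=8,
                              optimizer="adam", lr=3e-3, decay=0.0, seed=6)
        h1 = train_edge(build_edge_model(cfg), data, cfg)
        assert h1[-1] < h1[0]
        h2 = train_edge(build_edge_model(cfg), data, cfg)
        assert h1 == h2

    def test_empty_raster_sample_skipped_with_warning(self, rng):
        good = self._toy_sample(rng)
        bad = (rng.random((32, 32)).astype(np.float32), np.zeros((32, 32), dtype=np.float32))
        cfg = EdgeModelConfig(input_size=(32, 32), width_mult=0.0625, epochs=1,
                              optimizer="adam", lr=1e-3, seed=3)
        model = build_edge_model(cfg)
        with pytest.warns(UserWarning, match="skipped"):
            train_edge(model, [good, bad], cfg)

    def test_all_empty_dataset_rejected(self, rng):
        bad = (rng.random((32, 32)).astype(np.float32), np.zeros((32, 32), dtype=np.float32))
        cfg = EdgeModelConfig(input_size=(32, 32), width_mult=0.0625, epochs=1, seed=3)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no trainable samples"):
                train_edge(build_edge_model(cfg), [bad], cfg)

    def test_predict_edge_shape_check_and_range(self, rng):
        cfg = EdgeModelConfig(input_size=(32, 32), width_mult=0.0625, seed=8)
        model = build_edge_model(cfg)
        em = predict_edge(model, rng.random((32, 32)).astype(np.float32))
        assert em.fused.shape == (32, 32) and len(em.side_maps) == 6
        assert em.fused.min() >= 0 and em.fused.max() <= 1
        with pytest.raises(ValueError, match="resize"):
            predict_edge(model, rng.random((30, 30)).astype(np.float32))

    def test_save_load_round_trip(self, rng, tmp_path):
        from octlayers.edge_net import EdgeNet
        cfg = EdgeModelConfig(input_size=(32, 32), width_mult=0.0625, seed=11)
        model = build_edge_model(cfg)
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        y1 = model.forward(x, False)
        model.save(tmp_path / "e.npz")
        loaded = EdgeNet.load(tmp_path / "e.npz", cfg)
        y2 = loaded.forward(x, False)
        assert all(np.array_equal(u, v) for u, v in zip(y1, y2))
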