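"""Coarse stage: label construction, Dice loss, U-Net contracts, training."""

import numpy as np
import pytest

from octlayers.coarse_seg import (CoarseLabelMap, CoarseModelConfig,
                                  build_coarse_model, dice_loss,
                                  dilate_traces_to_labels, predict_coarse,
                                  rasterize_trace, train_coarse)
from octlayers.phantom import GroundTruthSet


def probs_from_labels(labels: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """One-hot probability map (H, W, C) from an integer label image."""
    return (labels[..., None] == np.arange(n_classes)).astype(np.float64)


def dice_oracle_binary(pred: np.ndarray, truth: np.ndarray) -> float:
    """Independent set-count Dice loss for one binary mask pair."""
    vp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    if 2 * vp + fp + fn == 0:
        return 0.0
    return 1.0 - 2 * vp / (2 * vp + fp + fn)


class TestDiceLoss:
    def test_identical_masks_give_zero(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[4:8] = 1
        labels[9:11] = 2
        labels[12:14] = 3
        assert dice_loss(probs_from_labels(labels), labels) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_masks_give_one(self):
        truth = np.zeros((16, 16), dtype=int)
        truth[2:4] = 1
        truth[6:8] = 2
        truth[10:12] = 3
        pred_labels = np.roll(truth, 8, axis=0) * 0
        pred_labels[0:2] = 1
        pred_labels[4:6] = 2
        pred_labels[8:10] = 3
        assert dice_loss(probs_from_labels(pred_labels), truth) == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap_equal_area_gives_half(self):
        # equal-area bands overlapping on half their area, per foreground class
        truth = np.zeros((12, 16), dtype=int)
        pred = np.zeros((12, 16), dtype=int)
        for cls, r in ((1, 0), (2, 4), (3, 8)):
            truth[r:r + 2] = cls          # rows r, r+1
            pred[r + 1:r + 3] = cls       # rows r+1, r+2: half-overlap
        assert dice_loss(probs_from_labels(pred), truth) == pytest.approx(0.5, abs=1e-6)

    def test_matches_set_count_oracle_on_random_masks(self, rng):
        for _ in range(10):
            truth = rng.integers(0, 4, size=(20, 20))
            pred = rng.integers(0, 4, size=(20, 20))
            expected = np.mean([
                dice_oracle_binary(pred == c, truth == c) for c in (1, 2, 3)
            ])
            assert dice_loss(probs_from_labels(pred), truth) == pytest.approx(expected, abs=1e-9)

    def test_symmetric_under_fp_fn_swap(self, rng):
        truth = rng.integers(0, 4, size=(16, 16))
        pred = rng.integers(0, 4, size=(16, 16))
        a = dice_loss(probs_from_labels(pred), truth)
        b = dice_loss(probs_from_labels(truth), pred)
        assert a == pytest.approx(b, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(np.zeros((4, 4, 4)), np.zeros((5, 5), dtype=int))


class TestLabelConstruction:
    def _flat_gt(self, w, ilm=10.0, rpe=30.0, bm=34.0):
        ones = np.ones(w)
        return GroundTruthSet(ilm=ilm * ones, rpe=rpe * ones, bm=bm * ones)

    def test_zero_iterations_gives_one_px_polyline(self):
        gt = self._flat_gt(64)
        lm = dilate_traces_to_labels(gt, (64, 64), (64, 64), iterations=0)
        for cls, row in ((1, 10), (2, 30), (3, 34)):
            band_rows = np.flatnonzero((lm.labels == cls).any(axis=1))
            assert list(band_rows) == [row]
            assert (lm.labels[row] == cls).all()

    def test_dilation_thickness_from_element_and_iterations(self):
        # 3x3 element, 2 iterations on a horizontal polyline -> rows [r-2, r+2]
        gt = self._flat_gt(64, ilm=10.0, rpe=40.0, bm=50.0)
        lm = dilate_traces_to_labels(gt, (64, 64), (64, 64),
                                     element_size=3, iterations=2)
        ilm_rows = np.flatnonzero((lm.labels == 1).any(axis=1))
        assert list(ilm_rows) == [8, 9, 10, 11, 12]

    def test_overlap_resolved_to_later_class(self):
        # RPE and BM 1 px apart: dilated bands overlap; later class (BM) wins
        gt = self._flat_gt(32, ilm=5.0, rpe=20.0, bm=21.0)
        lm = dilate_traces_to_labels(gt, (32, 32), (32, 32),
                                     element_size=3, iterations=2)
        assert (lm.labels[21] == 3).all()
        assert ((lm.labels >= 0) & (lm.labels <= 3)).all()

    def test_trace_outside_raster_rejected(self):
        gt = self._flat_gt(32, ilm=500.0, rpe=600.0, bm=700.0)
        with pytest.raises(ValueError, match="outside"):
            dilate_traces_to_labels(gt, (32, 32), (32, 32))

    def test_rasterize_connects_steep_segments(self):
        trace = np.array([2.0] * 8 + [12.0] * 8)
        mask = rasterize_trace(trace, (16, 16), (16, 16))
        assert mask[:, 7].sum() + mask[:, 8].sum() >= 10  # vertical join present


class TestCoarseModel:
    def test_forward_contract_and_softmax_normalization(self, rng):
        cfg = CoarseModelConfig(base_channels=2, seed=0)
        model = build_coarse_model(cfg)
        x = rng.random((1, 1, 128, 128), dtype=np.float32)
        p = model.forward(x, train=False)
        assert p.shape == (1, 4, 128, 128)
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-5

    def test_inference_deterministic_despite_dropout(self, rng):
        model = build_coarse_model(CoarseModelConfig(base_channels=2, dropout=0.5))
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        assert np.array_equal(model.forward(x, False), model.forward(x, False))

    def test_indivisible_input_rejected(self):
        model = build_coarse_model(CoarseModelConfig(base_channels=2))
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 1, 100, 100), dtype=np.float32), False)
        with pytest.raises(ValueError, match="square"):
            CoarseModelConfig(input_size=(128, 64)).validate()

    def test_overfits_single_crop(self):
        # capacity sanity: one sample, a few hundred steps -> near-zero Dice loss
        rng = np.random.default_rng(3)
        img = rng.random((32, 32)).astype(np.float32)
        labels = np.zeros((32, 32), dtype=int)
        labels[8:12] = 1
        labels[20:23] = 2
        labels[26:28] = 3
        img[labels > 0] += 1.0
        # dropout off: its per-step noise is what the loss should not include
        # when probing pure capacity on a single sample
        cfg = CoarseModelConfig(base_channels=4, input_size=(32, 32),
                                epochs=200, batch_size=1, optimizer="adam",
                                lr=1e-2, decay=0.0, dropout=0.0, seed=1)
        model = build_coarse_model(cfg)
        hist = train_coarse(model, [(img, CoarseLabelMap(labels))], cfg)
        assert hist[-1] < 0.1

    def test_training_progress_and_seeded_reproducibility(self, rng):
        data = []
        for i in range(6):
            img = rng.random((32, 32)).astype(np.float32)
            labels = np.zeros((32, 32), dtype=int)
            r = 6 + i
            labels[r:r + 2] = 1
            labels[r + 10:r + 12] = 2
            labels[r + 14:r + 15] = 3
            img[labels > 0] += 1.0
            data.append((img, CoarseLabelMap(labels)))
        cfg = CoarseModelConfig(base_channels=2, input_size=(32, 32), epochs=10,
                                optimizer="adam", lr=5e-3, decay=0.0, seed=7)
        h1 = train_coarse(build_coarse_model(cfg), data, cfg)
        assert h1[-1] < h1[0]
        h2 = train_coarse(build_coarse_model(cfg), data, cfg)
        assert h1 == h2

    def test_zero_lr_keeps_loss_constant(self, rng):
        img = rng.random((32, 32)).astype(np.float32)
        labels = np.zeros((32, 32), dtype=int)
        labels[10:14] = 1
        cfg = CoarseModelConfig(base_channels=2, input_size=(32, 32), epochs=3,
                                dropout=0.0, optimizer="adadelta", lr=0.0,
                                decay=0.0, seed=2)
        hist = train_coarse(build_coarse_model(cfg), [(img, CoarseLabelMap(labels))], cfg)
        assert np.ptp(hist) < 1e-12

    def test_empty_dataset_rejected(self):
        model = build_coarse_model(CoarseModelConfig(base_channels=2))
        with pytest.raises(ValueError, match="empty"):
            train_coarse(model, [], model.cfg)

    def test_predict_label_values_and_shape(self, rng):
        model = build_coarse_model(CoarseModelConfig(base_channels=2, seed=5))
        crop = (rng.random((200, 300)) * 255).astype(np.uint8)
        lm = predict_coarse(model, crop)
        assert lm.labels.shape == crop.shape
        assert set(np.unique(lm.labels)) <= {0, 1, 2, 3}

    def test_save_load_round_trip(self, rng, tmp_path):
        cfg = CoarseModelConfig(base_channels=2, seed=9)
        model = build_coarse_model(cfg)
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        y1 = model.forward(x, False)
        model.save(tmp_path / "m.npz")
        from octlayers.coarse_seg import CoarseUNet
        loaded = CoarseUNet.load(tmp_path / "m.npz", cfg)
        assert np.array_equal(loaded.forward(x, False), y1)
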