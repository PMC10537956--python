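"""Encoder network: shape laws, training sanity, inference determinism."""

import numpy as np
import pytest

from nephroseg import (
    LabelMask,
    SectionImage,
    TrainConfig,
    UNANNOTATED,
    build_model,
    downsample_mask,
    load_model,
    predict_mask,
    predict_scores,
    save_model,
    train,
    upsample_mask,
)
from nephroseg.net import downsample_labels_majority


class TestShapes:
    @pytest.mark.parametrize("hw", [(128, 128), (512, 1024)])
    def test_output_is_one_eighth_of_input(self, schema, hw):
        h, w = hw
        model = build_model(schema, width_multiplier=0.25)
        img = SectionImage(np.zeros((h, w, 3), dtype=np.uint8))
        scores = predict_scores(model, img)
        assert scores.shape == (schema.n_classes, h // 8, w // 8)

    def test_scores_are_normalised(self, schema):
        model = build_model(schema, width_multiplier=0.25, seed=3)
        rng = np.random.default_rng(0)
        img = SectionImage(rng.integers(0, 255, (64, 64, 3), dtype=np.uint8))
        scores = predict_scores(model, img)
        np.testing.assert_allclose(scores.sum(axis=0), 1.0, atol=1e-5)

    def test_width_multiplier_scales_parameters_not_shape(self, schema):
        small = build_model(schema, width_multiplier=0.5)
        big = build_model(schema, width_multiplier=1.0)
        assert big.n_params > small.n_params
        img = SectionImage(np.zeros((64, 64, 3), dtype=np.uint8))
        assert predict_scores(small, img).shape == predict_scores(big, img).shape

    def test_too_few_classes_rejected(self):
        from nephroseg import ClassDef, ClassSchema

        lone = ClassSchema((ClassDef(0, "background", "background", (0, 0, 0)),))
        with pytest.raises(ValueError):
            build_model(lone)


class TestMajorityDownsample:
    def test_majority_and_tie_break(self):
        labels = np.zeros((8, 8), dtype=np.uint8)
        labels[:, :3] = 1  # 24 px of class 1, 40 px of class 0 -> majority 0
        assert downsample_labels_majority(labels, 8, 3)[0, 0] == 0
        tie = np.zeros((8, 8), dtype=np.uint8)
        tie[:4] = 2  # 32 px class 2 vs 32 px class 0 -> lowest id wins
        assert downsample_labels_majority(tie, 8, 3)[0, 0] == 0

    def test_unannotated_dominant_block_excluded(self):
        labels = np.full((8, 8), UNANNOTATED, dtype=np.uint8)
        labels[0, :4] = 1  # 4 annotated vs 60 unannotated
        assert downsample_labels_majority(labels, 8, 3)[0, 0] == UNANNOTATED
        labels[:5] = 1  # now annotation dominates
        assert downsample_labels_majority(labels, 8, 3)[0, 0] == 1


class TestUpsample:
    def test_replication_counts(self):
        mask = LabelMask(np.array([[1, 2], [3, 4]], dtype=np.uint8), downsample_factor=8)
        up = upsample_mask(mask, 8)
        assert up.downsample_factor == 1
        assert up.labels.shape == (16, 16)
        for cid in (1, 2, 3, 4):
            assert (up.labels == cid).sum() == 64

    def test_proportions_preserved(self, schema, injured_section):
        _, mask, _ = injured_section
        ds = downsample_mask(mask, schema, 8)
        up = upsample_mask(ds, 8)
        for cid in range(schema.n_classes):
            assert (up.labels == cid).sum() == 64 * (ds.labels == cid).sum()

    def test_non_integer_factor_rejected(self):
        mask = LabelMask(np.zeros((2, 2), dtype=np.uint8), downsample_factor=8)
        with pytest.raises(ValueError):
            upsample_mask(mask, 2.5)


class TestTraining:
    def test_toy_overfit_reaches_high_accuracy(self, toy_trained, two_class_schema):
        """Linearly separable colours: >= 0.95 training pixel accuracy."""
        model, history, tiles = toy_trained
        correct = total = 0
        for img, mask in tiles:
            pred = predict_mask(model, img, tile_size=64)
            target = downsample_mask(mask, two_class_schema, 8)
            correct += (pred.labels == target.labels).sum()
            total += target.labels.size
        assert correct / total >= 0.95
        assert len(history.loss) == 200

    def test_learning_rate_stays_in_bounds(self, toy_trained):
        _, history, _ = toy_trained
        assert all(5e-7 <= lr <= 5e-4 for lr in history.learning_rate)

    def test_pure_background_prediction(self, toy_trained, two_class_schema):
        model, _, _ = toy_trained
        rng = np.random.default_rng(3)
        img = np.clip(
            np.full((64, 64, 3), (244, 243, 240), dtype=np.float32)
            + rng.normal(0, 4, (64, 64, 1)),
            0,
            255,
        ).astype(np.uint8)
        pred = predict_mask(model, SectionImage(img), tile_size=64)
        assert (pred.labels == 0).mean() >= 0.95

    def test_prediction_is_deterministic(self, toy_trained):
        model, _, tiles = toy_trained
        img = tiles[0][0]
        a = predict_mask(model, img, tile_size=64)
        b = predict_mask(model, img, tile_size=64)
        assert np.array_equal(a.labels, b.labels)

    def test_seeded_first_epoch_loss_identical(self, two_class_schema):
        from tests.conftest import _two_class_tiles

        rng = np.random.Generator(np.random.PCG64(42))
        tiles = _two_class_tiles(rng, n=2)
        cfg = TrainConfig(patch_size=(64, 64), batch_size=2, epochs=1, seed=5)
        losses = []
        for _ in range(2):
            model = build_model(two_class_schema, width_multiplier=0.25, seed=5)
            _, history = train(model, tiles, cfg)
            losses.append(history.loss[0])
        assert losses[0] == losses[1]

    def test_empty_and_unannotated_datasets_rejected(self, two_class_schema):
        cfg = TrainConfig(patch_size=(16, 16), batch_size=1, epochs=1)
        model = build_model(two_class_schema, width_multiplier=0.25)
        with pytest.raises(ValueError):
            train(model, [], cfg)
        img = SectionImage(np.zeros((16, 16, 3), dtype=np.uint8))
        blank = LabelMask(np.full((16, 16), UNANNOTATED, dtype=np.uint8))
        with pytest.raises(ValueError):
            train(model, [(img, blank)], cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(dropout=0.5)
        with pytest.raises(ValueError):
            TrainConfig(lr_min=1e-3, lr_max=1e-4)


def test_checkpoint_round_trip(toy_trained, two_class_schema, tmp_path):
    model, _, tiles = toy_trained
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path, two_class_schema)
    img = tiles[0][0]
    assert np.array_equal(
        predict_mask(model, img, tile_size=64).labels,
        predict_mask(back, img, tile_size=64).labels,
    )
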