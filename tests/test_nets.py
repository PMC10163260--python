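"""Model families: losses, dual-stream pooling, hybrid fusion, training."""

import numpy as np
import pytest

from hcpl.nets import (BackboneSpec, CellBag, CLAModel, CLHModel, DSAModel,
                       HybridFusionBlock, LossWeights, TrainConfig,
                       class_weights_from_frequencies, cla_forward,
                       combined_loss, dsa_forward, focal_loss, make_bag,
                       train_cell_model, weighted_bce)

SPEC = BackboneSpec(input_size=16, feature_dim=8, n_blocks=2, base_channels=4)


class TestLosses:
    def test_perfect_prediction_zero_bce(self):
        t = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert weighted_bce(t, t) == pytest.approx(0.0, abs=1e-5)

    def test_inverse_frequency_weight_ratio(self):
        w = class_weights_from_frequencies(np.array([0.5, 0.25]))
        assert w[1] / w[0] == pytest.approx(2.0)
        assert w.mean() == pytest.approx(1.0)

    def test_zero_frequency_weight_capped(self):
        w = class_weights_from_frequencies(np.array([0.5, 0.0, 0.25]))
        assert np.isfinite(w).all()

    def test_weighted_bce_matches_hand_computation(self, rng):
        p = rng.uniform(0.05, 0.95, size=(3, 2))
        t = rng.integers(0, 2, size=(3, 2)).astype(float)
        w = np.array([0.5, 1.5])
        expected = 0.0
        for i in range(3):
            for c in range(2):
                expected += w[c] * (-t[i, c] * np.log(p[i, c])
                                    - (1 - t[i, c]) * np.log(1 - p[i, c]))
        expected /= 3
        assert weighted_bce(p, t, w) == pytest.approx(expected, abs=1e-10)

    def test_focal_gamma_zero_reduces_to_bce(self, rng):
        p = rng.uniform(0.05, 0.95, size=(4, 3))
        t = rng.integers(0, 2, size=(4, 3)).astype(float)
        assert focal_loss(p, t, 0.0) == pytest.approx(weighted_bce(p, t), abs=1e-12)

    def test_focal_vanishes_at_confident_correct(self):
        t = np.array([[1.0, 0.0]])
        p = np.array([[1.0 - 1e-7, 1e-7]])
        assert focal_loss(p, t, 2.0) < 1e-10

    def test_focal_matches_direct_formula(self, rng):
        p = rng.uniform(0.1, 0.9, size=(2, 2))
        t = rng.integers(0, 2, size=(2, 2)).astype(float)
        g = 1.7
        direct = np.mean(np.sum(
            -t * (1 - p) ** g * np.log(p) - (1 - t) * p ** g * np.log(1 - p),
            axis=1))
        assert focal_loss(p, t, g) == pytest.approx(direct, abs=1e-12)

    def test_negative_focal_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[0.5]]), np.array([[1.0]]), -1.0)

    def test_combined_loss_round_weights(self):
        assert combined_loss(1.0, 1.0, LossWeights.for_round(1)) == pytest.approx(1.2)
        assert combined_loss(1.0, 1.0, LossWeights.for_round(2)) == pytest.approx(2.0)
        assert combined_loss(0.0, 0.0, LossWeights.for_round(1)) == 0.0


class TestDSA:
    def test_identical_cells_identical_rows(self, rng):
        model = DSAModel(SPEC, n_classes=3, seed=0)
        crop = rng.uniform(size=(1, 4, 16, 16))
        bag = np.repeat(crop, 5, axis=0)
        img_p, cell_p = model.predict(bag)
        assert np.allclose(cell_p, cell_p[0])
        # V equals the single descriptor, so image head sees the same input
        assert img_p.shape == (3,)

    def test_bag_permutation_invariance(self, rng):
        model = DSAModel(SPEC, n_classes=3, seed=0)
        bag = rng.uniform(size=(6, 4, 16, 16))
        img_a, _ = model.predict(bag)
        img_b, _ = model.predict(bag[::-1].copy())
        assert np.abs(img_a - img_b).max() < 1e-12

    def test_zero_head_outputs_half(self, rng):
        model = DSAModel(SPEC, n_classes=4, seed=0, zero_head=True)
        img_p, cell_p = model.predict(rng.uniform(size=(3, 4, 16, 16)))
        assert np.allclose(img_p, 0.5)
        assert np.allclose(cell_p, 0.5)

    def test_empty_bag_rejected(self):
        model = DSAModel(SPEC, n_classes=2, seed=0)
        with pytest.raises(ValueError):
            model.predict(np.empty((0, 4, 16, 16)))

    def test_dsa_forward_wrapper(self, rng):
        model = DSAModel(SPEC, n_classes=2, seed=0)
        bag = CellBag(crops=rng.uniform(size=(4, 4, 16, 16)),
                      cell_indices=np.arange(4))
        img_p, cell_p = dsa_forward(bag, model)
        assert img_p.shape == (2,) and cell_p.shape == (4, 2)
        assert (0 <= img_p).all() and (img_p <= 1).all()


class TestCLA:
    def test_zero_head_probability_half(self):
        model = CLAModel(SPEC, n_classes=3, seed=0, zero_head=True)
        out = cla_forward(np.zeros((4, 16, 16)), model)
        assert np.allclose(out, 0.5)

    def test_outputs_bounded(self, rng):
        model = CLAModel(SPEC, n_classes=3, seed=1)
        probs = model.predict_probs(rng.uniform(size=(64, 4, 16, 16)))
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_wrong_channel_count_rejected(self, rng):
        model = CLAModel(SPEC, n_classes=3, seed=0)
        with pytest.raises(ValueError):
            model.forward_logits(rng.uniform(size=(2, 3, 16, 16)))

    def test_trained_model_responds_to_intensity(self, rng):
        # non-degeneracy: a briefly trained model must not be constant
        crops = rng.uniform(size=(40, 4, 16, 16))
        targets = (crops[:, 1].mean(axis=(1, 2)) > 0.5).astype(float)[:, None]
        model = CLAModel(SPEC, n_classes=1, seed=0)
        train_cell_model(model, crops, targets,
                         TrainConfig(epochs=3, batch_size=16, lr0=3e-3,
                                     seed=0, augment=False))
        probs = model.predict_probs(crops)
        doubled = model.predict_probs(np.clip(2 * crops, 0, 1))
        assert np.abs(probs - doubled).max() > 1e-6


class TestHybridFusion:
    def test_zeroed_projection_is_function_of_deep_alone(self, rng):
        blk = HybridFusionBlock(scat_channels=5, trunk_channels=4, rng=rng)
        blk.proj.weight.value[...] = 0.0
        blk.proj.bias.value[...] = 0.0
        deep = rng.normal(size=(2, 4, 8, 8))
        blk.set_scattering(rng.normal(size=(2, 5, 8, 8)))
        out_a = blk.forward(deep)
        blk.set_scattering(rng.normal(size=(2, 5, 8, 8)))
        out_b = blk.forward(deep)
        assert np.array_equal(out_a, out_b)

    def test_output_shape_equals_trunk_shape_at_insertions(self, rng):
        spec = BackboneSpec(input_size=32, feature_dim=16, n_blocks=3,
                            base_channels=4)
        model = CLHModel(spec, n_classes=2, seed=0, insert_after=(0, 1))
        logits = model.forward_logits(rng.uniform(size=(2, 4, 32, 32)))
        assert logits.shape == (2, 2)

    def test_gradient_reaches_scattering_projection(self, rng):
        spec = BackboneSpec(input_size=32, feature_dim=16, n_blocks=3,
                            base_channels=4)
        model = CLHModel(spec, n_classes=2, seed=0)
        logits = model.forward_logits(rng.uniform(size=(2, 4, 32, 32)))
        for p in model.parameters():
            p.grad[...] = 0.0
        model.backward(np.ones_like(logits))
        proj_grads = [np.abs(b.proj.weight.grad).max() for b in model.fusion.values()]
        assert all(g > 0 for g in proj_grads)

    def test_fusion_disabled_matches_plain_trunk_weight_layout(self):
        spec = BackboneSpec(input_size=32, feature_dim=16, n_blocks=3,
                            base_channels=4)
        plain = CLAModel(spec, n_classes=2, seed=0)
        ablated = CLHModel(spec, n_classes=2, seed=0, use_fusion=False)
        shapes_a = [p.value.shape for p in plain.parameters()]
        shapes_b = [p.value.shape for p in ablated.parameters()]
        assert shapes_a == shapes_b


class TestBags:
    def test_oversized_image_sampled_without_replacement(self, rng):
        crops = np.arange(8, dtype=float).reshape(8, 1, 1, 1)
        bag = make_bag(crops, 5, rng)
        assert len(np.unique(bag.cell_indices)) == 5

    def test_undersized_image_resampled_with_replacement(self, rng):
        crops = np.arange(3, dtype=float).reshape(3, 1, 1, 1)
        bag = make_bag(crops, 7, rng)
        assert len(bag.crops) == 7
        assert set(bag.cell_indices) <= {0, 1, 2}


class TestTraining:
    def test_identical_seeds_identical_epoch_losses(self, rng):
        crops = rng.uniform(size=(30, 4, 16, 16))
        targets = rng.integers(0, 2, size=(30, 2)).astype(float)
        histories = []
        for _ in range(2):
            model = CLAModel(SPEC, n_classes=2, seed=3)
            h = train_cell_model(model, crops, targets,
                                 TrainConfig(epochs=2, batch_size=16, seed=3))
            histories.append(h["epoch_loss"])
        assert abs(histories[0][0] - histories[1][0]) < 1e-6
        assert histories[0] == histories[1]

    def test_lr_schedule_recorded_from_initial_rate(self, rng):
        crops = rng.uniform(size=(8, 4, 16, 16))
        targets = np.ones((8, 1))
        model = CLAModel(SPEC, n_classes=1, seed=0)
        h = train_cell_model(model, crops, targets,
                             TrainConfig(epochs=3, batch_size=8, lr0=2e-4,
                                         lr_floor=1e-6, seed=0))
        assert h["lr"][0] == pytest.approx(2e-4)
        assert h["lr"][-1] == pytest.approx(1e-6)

    def test_divergence_aborts_with_diagnostic(self, rng):
        crops = rng.uniform(size=(8, 4, 16, 16)) * np.nan
        targets = np.ones((8, 1))
        model = CLAModel(SPEC, n_classes=1, seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            train_cell_model(model, crops, targets,
                             TrainConfig(epochs=1, batch_size=8, seed=0))


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path, rng):
        from hcpl.nets import load_model, save_model
        model = CLAModel(SPEC, n_classes=2, seed=5)
        x = rng.uniform(size=(3, 4, 16, 16))
        ref = model.predict_probs(x)
        path = str(tmp_path / "ckpt.npz")
        save_model(model, path)
        other = CLAModel(SPEC, n_classes=2, seed=99)
        load_model(other, path)
        assert np.allclose(other.predict_probs(x), ref)
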