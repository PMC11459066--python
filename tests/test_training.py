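"""Losses, folds, augmentation and the training loop."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaseg.synthetic import SyntheticConfig, generate_dataset
from gaseg.train import (AugmentConfig, TrainConfig, augment, dice_loss,
                         hoyer_square, make_folds, train_ensemble, train_model)
from gaseg.unet import ModelConfig, UNet


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        t = np.zeros((4, 4))
        t[:2] = 1
        assert dice_loss(t, t, eps=0.0) == pytest.approx(0.0)

    def test_empty_prediction_is_one(self):
        t = np.ones((4, 4))
        assert dice_loss(np.zeros((4, 4)), t, eps=0.0) == pytest.approx(1.0)

    def test_half_probability_half_mask(self):
        # 1 - 2*(0.5*8) / (8 + 8) = 0.5, against a scalar loop evaluation
        p = np.full((4, 4), 0.5)
        t = np.zeros((4, 4))
        t[:2] = 1
        num = den = 0.0
        for i in range(4):
            for j in range(4):
                num += 2 * p[i, j] * t[i, j]
                den += p[i, j] + t[i, j]
        assert dice_loss(p, t, eps=0.0) == pytest.approx(1 - num / den) == 0.5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_bounded_unit_interval(self, rng):
        for _ in range(20):
            p = rng.random((6, 6))
            t = (rng.random((6, 6)) < 0.5).astype(float)
            assert 0.0 <= dice_loss(p, t) <= 1.0


class TestHoyerSquare:
    def test_single_nonzero_weight(self):
        assert hoyer_square(np.array([0.0, -2.7, 0.0])) == pytest.approx(1.0)

    def test_two_equal_weights(self):
        assert hoyer_square(np.array([1.0, 1.0])) == pytest.approx(2.0)

    def test_three_four(self):
        assert hoyer_square(np.array([3.0, -4.0])) == pytest.approx(1.96)

    def test_all_zero_convention(self):
        assert hoyer_square(np.zeros(5)) == 0.0

    def test_matches_scalar_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            w = rng.normal(size=rng.integers(1, 40))
            s1 = sum(abs(float(v)) for v in w)
            s2 = sum(float(v) ** 2 for v in w)
            assert hoyer_square(w) == pytest.approx(s1 * s1 / s2, abs=1e-10)

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=1,
                    max_size=30).filter(lambda v: any(x != 0 for x in v)))
    def test_bounds_and_scale_invariance(self, values):
        w = np.array(values)
        hs = hoyer_square(w)
        assert 1.0 - 1e-9 <= hs <= len(values) + 1e-9
        assert hoyer_square(3.7 * w) == pytest.approx(hs, rel=1e-9)


@pytest.fixture(scope="module")
def dataset():
    cfg = SyntheticConfig(image_height=16, image_width=16,
                          lesion_radius_range=(2.5, 5.0), seed=2)
    return generate_dataset(cfg, 11)


class TestFolds:
    def test_even_split(self, dataset):
        folds = make_folds(dataset[:10], 5, seed=1)
        sizes = [len(folds.fold_ids(j)) for j in range(5)]
        assert sizes == [2, 2, 2, 2, 2]

    def test_deterministic(self, dataset):
        assert make_folds(dataset, 5, 3).assignments == \
            make_folds(dataset, 5, 3).assignments

    def test_uneven_split_sizes(self, dataset):
        folds = make_folds(dataset, 5, seed=1)
        sizes = sorted(len(folds.fold_ids(j)) for j in range(5))
        assert sizes == [2, 2, 2, 2, 3]

    def test_partition_property(self, dataset):
        folds = make_folds(dataset, 4, seed=9)
        ids = [sid for j in range(4) for sid in folds.fold_ids(j)]
        assert sorted(ids) == sorted(s.sample_id for s in dataset)

    def test_too_few_samples_rejected(self, dataset):
        with pytest.raises(ValueError):
            make_folds(dataset[:3], 5, seed=0)


class TestAugment:
    def test_identity_config(self, rng):
        img = rng.random((3, 16, 16), dtype=np.float32)
        mask = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        out_img, (out_mask,) = augment(img, [mask], AugmentConfig.identity(), 0)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_hflip_is_involution(self, rng):
        img = rng.random((3, 16, 16), dtype=np.float32)
        mask = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        cfg = AugmentConfig(p_hflip=1.0, p_vflip=0, p_rot90=0, max_shift=0,
                            p_jitter=0)
        a_img, (a_mask,) = augment(img, [mask], cfg, 0)
        b_img, (b_mask,) = augment(a_img, [a_mask], cfg, 1)
        np.testing.assert_array_equal(b_img, img)
        np.testing.assert_array_equal(b_mask, mask)

    def test_masks_stay_binary_and_area_bookkeeping(self, rng):
        # flips/rotations preserve foreground area exactly; translations may
        # crop at most |dy|*W + |dx|*H pixels
        img = rng.random((3, 32, 32), dtype=np.float32)
        mask = np.zeros((32, 32), np.uint8)
        mask[8:20, 10:22] = 1
        cfg = AugmentConfig(max_shift=3)
        area = int(mask.sum())
        for seed in range(100):
            _, (m,) = augment(img, [mask], cfg, seed)
            assert np.isin(m, (0, 1)).all()
            assert area - 2 * 3 * 32 <= int(m.sum()) <= area

    def test_geometric_transform_shared_between_masks(self, rng):
        img = rng.random((3, 16, 16), dtype=np.float32)
        mask = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        cfg = AugmentConfig()
        _, (m1, m2) = augment(img, [mask, mask.copy()], cfg, 5)
        np.testing.assert_array_equal(m1, m2)


@pytest.fixture(scope="module")
def tiny():
    cfg = SyntheticConfig(image_height=16, image_width=16,
                          lesion_radius_range=(2.5, 5.0), seed=4)
    return generate_dataset(cfg, 6)


class TestTrainModel:
    def test_zero_epochs_leaves_weights_unchanged(self, tiny):
        model = UNet(ModelConfig(base_channels=2), seed=1)
        before = model.state_dict()
        log = train_model(model, tiny[:4], tiny[4:],
                          TrainConfig(epochs=0, seed=0))
        assert log.empty
        for name, p, _ in model.params:
            np.testing.assert_array_equal(p, before[name])

    def test_schedule_and_loss_decomposition(self, tiny):
        model = UNet(ModelConfig(base_channels=2), seed=1)
        cfg = TrainConfig(epochs=12, batch_size=4, seed=0,
                          augmentation=AugmentConfig.identity())
        log = train_model(model, tiny[:4], tiny[4:], cfg)
        # lr(e) = 1e-4 * 0.999^e; in particular epoch 10
        np.testing.assert_allclose(log["lr"],
                                   1e-4 * 0.999 ** np.arange(12), rtol=1e-12)
        assert log["lr"].iloc[10] == pytest.approx(9.90044880209748e-05)
        ratios = log["lr"].to_numpy()[1:] / log["lr"].to_numpy()[:-1]
        np.testing.assert_allclose(ratios, 0.999, rtol=1e-12)
        np.testing.assert_allclose(
            log["total_loss"],
            log["dice_loss"] + cfg.hoyer_coefficient * log["hoyer"],
            atol=1e-8)

    def test_training_reduces_loss(self, tiny):
        model = UNet(ModelConfig(base_channels=4), seed=2)
        cfg = TrainConfig(initial_lr=1e-3, epochs=15, batch_size=2, seed=1)
        log = train_model(model, tiny[:4], tiny[4:], cfg)
        assert log["dice_loss"].iloc[-1] < log["dice_loss"].iloc[0]

    def test_empty_train_set_rejected(self, tiny):
        with pytest.raises(ValueError):
            train_model(UNet(ModelConfig(base_channels=2), 0), [], tiny,
                        TrainConfig(epochs=1))


class TestTrainEnsemble:
    def test_members_differ_and_are_reproducible(self):
        cfg = SyntheticConfig(image_height=16, image_width=16,
                              lesion_radius_range=(2.5, 5.0), seed=6)
        data = generate_dataset(cfg, 6)
        tcfg = TrainConfig(initial_lr=1e-3, epochs=2, batch_size=2, seed=3)
        mcfg = ModelConfig(base_channels=2)
        models_a, logs_a, folds = train_ensemble(data, 3, mcfg, tcfg)
        models_b, _, _ = train_ensemble(data, 3, mcfg, tcfg)
        assert len(models_a) == 3
        # fold arithmetic: each member trains on 4 of 6 samples
        for j in range(3):
            assert len([s for s in data if folds.assignments[s.sample_id] != j]) == 4
        w0 = models_a[0].state_dict()
        w1 = models_a[1].state_dict()
        assert any(not np.array_equal(w0[k], w1[k]) for k in w0)
        for k, v in w0.items():
            np.testing.assert_array_equal(v, models_b[0].state_dict()[k])
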