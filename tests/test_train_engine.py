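"""Folds, patch sampling, augmentation, masking semantics, training loops."""
import numpy as np
import pytest

from t1rho.core import ROIMask, WeightedVolume
from t1rho.nets import MLPConfig, UNetConfig
from t1rho.train_engine import (
    Combo,
    TABLE_COMBOS,
    AugmentConfig,
    SliceSample,
    TrainConfig,
    augment_patch,
    extract_voxel_pairs,
    lr_schedule,
    make_folds,
    mask_to_roi,
    run_cross_validation,
    sample_patches,
    train_mlp,
    train_unet,
)
from t1rho.train_engine import _l1_loss_and_grad


class TestCombos:
    def test_six_admissible_combinations(self):
        assert len(TABLE_COMBOS) == 6
        assert Combo("pd", 50.0) in TABLE_COMBOS
        assert Combo("tsl0", 10.0) in TABLE_COMBOS

    def test_rejects_bad_sources(self):
        with pytest.raises(ValueError):
            Combo("t2w", 50.0)
        with pytest.raises(ValueError):
            Combo("pd", 0.0)


class TestFolds:
    def test_forty_subjects_five_even_folds(self):
        ids = [f"s{i:02d}" for i in range(40)]
        strata = {s: ("patient" if i < 30 else "volunteer") for i, s in enumerate(ids)}
        fs = make_folds(ids, strata, k=5, seed=0)
        sizes = [len(fs.test_ids(f)) for f in range(5)]
        assert sizes == [8] * 5
        for f in range(5):
            vols = sum(1 for s in fs.test_ids(f) if strata[s] == "volunteer")
            assert vols == 2  # 10 volunteers spread exactly 2 per fold

    def test_partition_properties(self):
        ids = [f"s{i}" for i in range(17)]
        strata = {s: "a" if i % 3 else "b" for i, s in enumerate(ids)}
        fs = make_folds(ids, strata, k=4, seed=3)
        all_test = [s for f in range(4) for s in fs.test_ids(f)]
        assert sorted(all_test) == sorted(ids)  # exhaustive and disjoint
        for f in range(4):
            assert set(fs.test_ids(f)).isdisjoint(fs.train_ids(f))
            assert set(fs.test_ids(f)) | set(fs.train_ids(f)) == set(ids)

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(12)]
        strata = dict.fromkeys(ids, "x")
        assert make_folds(ids, strata, 3, seed=5).assignments == make_folds(
            ids, strata, 3, seed=5
        ).assignments

    def test_degenerate_k_rejected(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError):
            make_folds(ids, dict.fromkeys(ids, "x"), k=1, seed=0)
        with pytest.raises(ValueError):
            make_folds(ids, dict.fromkeys(ids, "x"), k=4, seed=0)


class TestSamplePatches:
    def _slice(self, h=96, w=96):
        rng = np.random.default_rng(0)
        pair = rng.uniform(0, 1, (2, h, w))
        target = rng.uniform(20, 80, (h, w))
        roi = np.zeros((h, w), dtype=int)
        roi[40:50, 60:70] = 1
        return pair, target, roi

    def test_patch_geometry(self):
        pair, target, roi = self._slice()
        cfg = TrainConfig(epochs=1, patch_size=64)
        rng = np.random.default_rng(1)
        for inp, tgt, rp in sample_patches(pair, target, roi, 20, cfg, rng=rng):
            assert inp.shape == (2, 64, 64)
            assert tgt.shape == (64, 64)
            assert rp.shape == (64, 64)

    def test_full_roi_bias_hits_roi(self):
        pair, target, roi = self._slice()
        cfg = TrainConfig(epochs=1, roi_bias=1.0)
        rng = np.random.default_rng(2)
        for _, _, rp in sample_patches(pair, target, roi, 25, cfg, rng=rng):
            assert np.any(rp > 0)

    def test_deterministic_given_seed(self):
        pair, target, roi = self._slice()
        cfg = TrainConfig(epochs=1)
        a = sample_patches(pair, target, roi, 5, cfg, rng=7)
        b = sample_patches(pair, target, roi, 5, cfg, rng=7)
        for (i1, t1, r1), (i2, t2, r2) in zip(a, b):
            assert np.array_equal(i1, i2) and np.array_equal(t1, t2)

    def test_slice_smaller_than_patch_rejected(self):
        pair, target, roi = self._slice(h=32, w=32)
        with pytest.raises(ValueError):
            sample_patches(pair, target, roi, 1, TrainConfig(epochs=1), rng=0)


class TestAugmentPatch:
    def test_identity_config_is_bitwise_identity(self):
        rng = np.random.default_rng(0)
        inp = rng.uniform(0, 1, (2, 32, 32))
        tgt = rng.uniform(20, 80, (32, 32))
        cfg = AugmentConfig(flip=0, rotation=0, translation=0, gaussian_noise_sigma=0)
        out_i, out_t = augment_patch(inp, tgt, cfg, seed=1)
        assert np.array_equal(out_i, inp) and np.array_equal(out_t, tgt)

    def test_pure_flip_preserves_correspondence(self):
        """With flips only, inputs and target transform with one geometry, so a
        target equal to an input channel stays equal after augmentation."""
        rng = np.random.default_rng(1)
        inp = rng.uniform(0, 1, (2, 16, 16))
        tgt = inp[0].copy()
        cfg = AugmentConfig(flip=1.0, rotation=0, translation=0, gaussian_noise_sigma=0)
        out_i, out_t = augment_patch(inp, tgt, cfg, seed=3)
        assert np.array_equal(out_i[0], out_t)
        assert not np.array_equal(out_i, inp)  # flip with p=1 must act

    def test_noise_touches_inputs_only(self):
        rng = np.random.default_rng(2)
        inp = rng.uniform(0, 1, (2, 16, 16))
        tgt = rng.uniform(20, 80, (16, 16))
        cfg = AugmentConfig(flip=0, rotation=0, translation=0, gaussian_noise_sigma=0.1)
        out_i, out_t = augment_patch(inp, tgt, cfg, seed=4)
        assert np.array_equal(out_t, tgt)
        assert not np.array_equal(out_i, inp)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        inp = rng.uniform(0, 1, (2, 16, 16))
        tgt = rng.uniform(20, 80, (16, 16))
        cfg = AugmentConfig()
        a = augment_patch(inp, tgt, cfg, seed=5)
        b = augment_patch(inp, tgt, cfg, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestMaskToROI:
    def _roi(self):
        labels = np.zeros((2, 8, 8), dtype=int)
        labels[:, 2:4, 2:6] = 1
        return ROIMask(labels)

    def test_masking_semantics(self):
        roi = self._roi()
        vol = WeightedVolume(np.random.default_rng(0).uniform(1, 10, (2, 8, 8)), contrast=0.0)
        (masked,) = mask_to_roi([vol], roi)
        assert np.all(masked.data[~roi.mask] == 0.0)
        assert np.array_equal(masked.data[roi.mask], vol.data[roi.mask])

    def test_all_zero_mask_zeroes_everything(self):
        roi = ROIMask(np.zeros((2, 8, 8), dtype=int))
        vol = WeightedVolume(np.ones((2, 8, 8)), contrast=0.0)
        (masked,) = mask_to_roi([vol], roi)
        assert not masked.data.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_to_roi([WeightedVolume(np.ones((2, 4, 4)), contrast=0.0)], self._roi())


class TestLossAndSchedule:
    def test_lr_ratio_is_exactly_the_decay(self):
        cfg = TrainConfig(epochs=10, lr_decay=0.9)
        for e in range(1, 10):
            assert lr_schedule(cfg, e) / lr_schedule(cfg, e - 1) == pytest.approx(0.9, rel=1e-12)

    def test_masked_loss_ignores_outside_voxels(self):
        rng = np.random.default_rng(0)
        pred = rng.uniform(20, 80, (2, 1, 8, 8))
        target = rng.uniform(20, 80, (2, 1, 8, 8))
        mask = np.zeros_like(pred, dtype=bool)
        mask[:, :, :4] = True
        loss1, g1 = _l1_loss_and_grad(pred, target, mask)
        perturbed = target.copy()
        perturbed[:, :, 4:] += 500.0  # outside the mask
        loss2, g2 = _l1_loss_and_grad(pred, perturbed, mask)
        assert loss1 == loss2
        assert np.array_equal(g1, g2)
        assert np.all(g1[~mask] == 0.0)


def _toy_slices(n=2, seed=0):
    """Tiny synthetic slice samples with a voxelwise decodable target."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t1rho = rng.uniform(30, 70, (64, 64))
        i0 = rng.uniform(0.8, 1.2, (64, 64))
        ik = i0 * np.exp(-50.0 / t1rho)
        roi = np.zeros((64, 64), dtype=int)
        roi[20:40, 20:40] = 1
        out.append(
            SliceSample(
                inputs=np.stack([i0, ik]),
                target=t1rho,
                valid=np.ones((64, 64), dtype=bool),
                roi=roi,
            )
        )
    return out


UNET_TINY = UNetConfig(depth=2, base_channels=4, patch_size=64, seed=0)
TRAIN_TINY = TrainConfig(
    epochs=8,
    batch_size=4,
    patches_per_slice=2,
    augment=AugmentConfig(flip=0, rotation=0, translation=0, gaussian_noise_sigma=0),
    seed=0,
)


class TestTrainUNet:
    def test_loss_decreases(self):
        _, hist = train_unet(_toy_slices(), TRAIN_TINY, UNET_TINY)
        assert hist[-1] < hist[0]
        assert len(hist) == TRAIN_TINY.epochs

    def test_roi_loss_only_ignores_outside_targets(self):
        import dataclasses

        cfg = dataclasses.replace(TRAIN_TINY, roi_loss_only=True, epochs=2)
        slices = _toy_slices()
        _, h1 = train_unet(slices, cfg, UNET_TINY)
        perturbed = []
        for s in slices:
            t = s.target.copy()
            t[s.roi == 0] += 300.0
            perturbed.append(SliceSample(s.inputs, t, s.valid, s.roi))
        _, h2 = train_unet(perturbed, cfg, UNET_TINY)
        assert h1 == h2

    def test_roi_loss_only_all_zero_mask_rejected(self):
        import dataclasses

        slices = _toy_slices()
        for s in slices:
            s.roi[:] = 0
        cfg = dataclasses.replace(TRAIN_TINY, roi_loss_only=True, epochs=1)
        with pytest.raises(ValueError):
            train_unet(slices, cfg, UNET_TINY)

    def test_deterministic_end_to_end(self):
        m1, h1 = train_unet(_toy_slices(), TRAIN_TINY, UNET_TINY)
        m2, h2 = train_unet(_toy_slices(), TRAIN_TINY, UNET_TINY)
        assert h1 == h2
        for p1, p2 in zip(m1.params(), m2.params()):
            assert np.array_equal(p1.data, p2.data)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            train_unet([], TRAIN_TINY, UNET_TINY)


class TestTrainMLP:
    def _pairs(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        t1rho = rng.uniform(30, 70, n)
        i0 = rng.uniform(0.8, 1.2, n)
        X = np.stack([i0, i0 * np.exp(-50.0 / t1rho)], axis=1)
        return X, t1rho

    def test_loss_decreases_noise_free(self):
        X, y = self._pairs()
        cfg = TrainConfig(optimizer="rmsprop", epochs=50, batch_size=512, seed=1)
        _, hist = train_mlp(X, y, cfg, MLPConfig(n_blocks=2, width=32, seed=1))
        assert hist[-1] < hist[0]

    def test_deterministic(self):
        X, y = self._pairs(500)
        cfg = TrainConfig(optimizer="rmsprop", epochs=3, batch_size=128, seed=2)
        m1, h1 = train_mlp(X, y, cfg, MLPConfig(n_blocks=1, width=8, seed=2))
        m2, h2 = train_mlp(X, y, cfg, MLPConfig(n_blocks=1, width=8, seed=2))
        assert h1 == h2
        for p1, p2 in zip(m1.params(), m2.params()):
            assert np.array_equal(p1.data, p2.data)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_mlp(np.empty((0, 2)), np.empty(0), TrainConfig(epochs=1), MLPConfig())

    def test_batch_size_honored(self, monkeypatch):
        """All full training batches carry exactly batch_size rows."""
        from t1rho.nets import SkipMLP

        seen = []
        orig = SkipMLP.forward

        def spy(self, x, train=True):
            if train:
                seen.append(len(x))
            return orig(self, x, train=train)

        monkeypatch.setattr(SkipMLP, "forward", spy)
        X, y = self._pairs(1200)
        cfg = TrainConfig(optimizer="rmsprop", epochs=2, batch_size=512, seed=0)
        train_mlp(X, y, cfg, MLPConfig(n_blocks=1, width=8, seed=0))
        # 1200 rows -> per epoch: 512, 512, 176
        assert seen == [512, 512, 176] * 2


class TestCrossValidation:
    def test_bookkeeping_with_reference_model(self, tiny_cohort):
        """Every subject is predicted exactly once, by a model that never saw it."""
        from t1rho.train_engine import make_folds

        ids = [s.subject_id for s in tiny_cohort]
        folds = make_folds(ids, dict.fromkeys(ids, "x"), k=2, seed=0)
        res = run_cross_validation(tiny_cohort, folds, Combo("tsl0", 50.0), model="nlls")
        assert set(res.predictions) == set(ids)
        for sid, entry in res.audit.items():
            assert entry["trained_without"]
            assert folds.fold_of(sid) == entry["fold"]
        assert len(res.reports) == len(ids)

    def test_nonconforming_reference_flagged(self, tiny_cohort):
        ids = [s.subject_id for s in tiny_cohort]
        folds = make_folds(ids, dict.fromkeys(ids, "x"), k=2, seed=0)
        res = run_cross_validation(tiny_cohort, folds, Combo("pd", 50.0), model="nlls")
        assert all(not r.model_conforming for r in res.reports)

    def test_learned_model_requires_table_combo(self, tiny_cohort):
        ids = [s.subject_id for s in tiny_cohort]
        folds = make_folds(ids, dict.fromkeys(ids, "x"), k=2, seed=0)
        with pytest.raises(ValueError):
            run_cross_validation(tiny_cohort, folds, Combo("tsl0", 20.0), model="mlp")


def test_extract_voxel_pairs_counts(tiny_cohort):
    X, y = extract_voxel_pairs(tiny_cohort, Combo("tsl0", 50.0))
    n_roi = sum(int(s.roi.mask.sum()) for s in tiny_cohort)
    assert X.shape == (n_roi, 2)
    assert y.shape == (n_roi,)
    assert np.all(y > 0)
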