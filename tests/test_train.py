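"""Training protocol: split arithmetic, augmentation bounds, loss/schedule
closed forms, early stopping, leakage guards and metric definitions."""

import math

import numpy as np
import pytest

from pdscribe import network as nw
from pdscribe import train as tr


def make_labels(n_healthy, n_pd):
    labels = {f"H{i:03d}": 0 for i in range(n_healthy)}
    labels.update({f"P{i:03d}": 1 for i in range(n_pd)})
    return labels


class TestSplitSubjects:
    def test_pahaw_sized_cohort_reserves_8_plus_7(self):
        """38 healthy + 37 PD at 20% -> 8 healthy + 7 PD test subjects and a
        30 + 30 development pool (largest-remainder allocation)."""
        plan = tr.split_subjects(make_labels(38, 37), test_fraction=0.2, k=5,
                                 seed=0)
        test_h = sum(s.startswith("H") for s in plan.test_subjects)
        test_p = sum(s.startswith("P") for s in plan.test_subjects)
        assert (test_h, test_p) == (8, 7)
        pool = plan.pool()
        assert sum(s.startswith("H") for s in pool) == 30
        assert sum(s.startswith("P") for s in pool) == 30

    def test_balanced_small_cohort(self):
        plan = tr.split_subjects(make_labels(10, 10), test_fraction=0.2, k=4,
                                 seed=1)
        test_h = sum(s.startswith("H") for s in plan.test_subjects)
        test_p = sum(s.startswith("P") for s in plan.test_subjects)
        assert (test_h, test_p) == (2, 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_covers_all_subjects_disjointly(self, seed):
        labels = make_labels(13, 11)
        plan = tr.split_subjects(labels, test_fraction=0.2, k=3, seed=seed)
        groups = [set(plan.test_subjects)] + [set(f) for f in plan.folds]
        assert sum(len(g) for g in groups) == len(labels)
        assert set().union(*groups) == set(labels)
        for fold in range(plan.k):
            train, val, test = plan.roles(fold)
            assert not (set(train) & set(val))
            assert not (set(train) & set(test))
            assert not (set(val) & set(test))

    def test_each_pool_subject_validates_exactly_once(self):
        plan = tr.split_subjects(make_labels(12, 12), test_fraction=0.25, k=4,
                                 seed=2)
        seen = [s for f in plan.folds for s in f]
        assert len(seen) == len(set(seen))

    def test_deterministic_given_seed(self):
        a = tr.split_subjects(make_labels(15, 15), seed=9)
        b = tr.split_subjects(make_labels(15, 15), seed=9)
        assert a.test_subjects == b.test_subjects and a.folds == b.folds

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            tr.split_subjects(make_labels(3, 3), test_fraction=0.2, k=5, seed=0)


class TestAugment:
    def test_disabled_config_is_identity(self, rng):
        img = rng.random((32, 32, 3))
        out = tr.augment(img, tr.AugmentConfig(enabled=False), seed=0)
        assert np.array_equal(out, img)

    def test_sampled_parameters_within_stated_bounds(self):
        cfg = tr.AugmentConfig()
        rng = np.random.default_rng(0)
        for _ in range(1000):
            s = tr.sample_augmentation(cfg, rng, size=64)
            assert -5.0 <= s.rotation_deg <= 5.0
            assert 0.9 <= s.scale <= 1.1
            assert abs(s.shift[0]) <= 0.05 * 64 and abs(s.shift[1]) <= 0.05 * 64

    def test_shape_and_range_preserved(self, rng):
        img = rng.random((64, 64, 3))
        out = tr.augment(img, tr.AugmentConfig(), seed=5)
        assert out.shape == (64, 64, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert not np.array_equal(out, img)

    def test_config_bounds_enforced(self):
        with pytest.raises(ValueError):
            tr.AugmentConfig(rotation_deg=10.0)
        with pytest.raises(ValueError):
            tr.AugmentConfig(scale_range=(0.5, 1.1))


class TestLossAndSchedule:
    def test_perfect_posteriors_give_zero_loss(self):
        post = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert tr.bce_loss(post, [1, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_half_posteriors_give_ln2(self):
        post = np.full((4, 2), 0.5)
        assert tr.bce_loss(post, [1, 0, 1, 0]) == pytest.approx(math.log(2))

    def test_loss_nonnegative_and_clamped(self, rng):
        post = np.array([[0.0, 1.0]])  # wrong with certainty: clamped, finite
        loss = tr.bce_loss(post, [1])
        assert np.isfinite(loss) and loss > 0

    def test_cosine_endpoints_and_midpoint(self):
        assert tr.cosine_lr(0, 150) == pytest.approx(1e-3)
        assert tr.cosine_lr(150, 150) == pytest.approx(1e-6)
        assert tr.cosine_lr(75, 150) == pytest.approx((1e-3 + 1e-6) / 2)
        with pytest.raises(ValueError):
            tr.cosine_lr(151, 150)


class TestEarlyStopping:
    def test_patience_arithmetic_on_stubbed_stream(self):
        """Stream [0.5, 0.6, then 15 non-improving] stops at epoch 17 with
        the best checkpoint at epoch 2."""
        stopper = tr.EarlyStopping(patience=15)
        stream = [0.5, 0.6] + [0.6] * 15
        stopped_at = None
        for i, f1 in enumerate(stream, start=1):
            if stopper.update(f1):
                stopped_at = i
                break
        assert stopped_at == 17
        assert stopper.best_epoch == 2

    def test_equal_f1_is_not_improvement(self):
        stopper = tr.EarlyStopping(patience=2)
        assert not stopper.update(0.8)
        assert not stopper.update(0.8)
        assert stopper.update(0.8)
        assert stopper.best_epoch == 1


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        rep = tr.confusion_metrics(tp=9, fp=2, tn=8, fn=1)
        assert rep.sensitivity == pytest.approx(0.900)
        assert rep.specificity == pytest.approx(0.800)
        assert rep.precision == pytest.approx(0.8182, abs=1e-4)
        assert rep.f1 == pytest.approx(0.8571, abs=1e-4)
        assert rep.accuracy == pytest.approx(0.85)

    def test_perfect_and_all_wrong(self):
        perfect = tr.confusion_metrics(tp=5, fp=0, tn=5, fn=0)
        assert all(getattr(perfect, m) == 1.0 for m in
                   ("accuracy", "sensitivity", "specificity", "precision", "f1"))
        wrong = tr.confusion_metrics(tp=0, fp=5, tn=0, fn=5)
        assert wrong.accuracy == 0.0

    def test_undefined_ratios_flagged_not_zeroed(self):
        rep = tr.confusion_metrics(tp=0, fp=0, tn=10, fn=0)
        assert math.isnan(rep.precision)
        assert "precision" in rep.undefined and "sensitivity" in rep.undefined


def _toy_data(n_per_class, size, rng, subjects_prefix=""):
    """Linearly separable toy images: PD class has a bright top half."""
    X, y, sids = [], [], []
    for i in range(n_per_class * 2):
        label = i % 2
        img = rng.random((size, size, 3)) * 0.1
        if label:
            img[: size // 2] += 0.6
        X.append(np.clip(img, 0, 1))
        y.append(label)
        sids.append(f"{subjects_prefix}S{i:03d}")
    return np.stack(X), np.array(y), sids


class TestTrainModel:
    CFG = None

    @staticmethod
    def tiny_cfg(size=16):
        return nw.ModelConfig(
            input_hw=size,
            backbone=nw.BackboneConfig(filters=(4, 4, 8, 8, 8),
                                       pool_strides=(2, 1, 1, 1, 1)),
            branches=nw.BranchConfig(proj_hw=7, depth=8), attn_heads=2,
            gate_hidden=4, reduced_dim=4)

    def test_subject_overlap_is_hard_failure(self, rng):
        X, y, sids = _toy_data(4, 16, rng)
        with pytest.raises(tr.LeakageError):
            tr.train_model((X, y, sids), (X[:2], y[:2], sids[:2]),
                           self.tiny_cfg(),
                           tr.TrainConfig(max_epochs=1, seed=0),
                           tr.AugmentConfig(enabled=False), seed=0)

    def test_loss_decreases_and_seeded_reproducibility(self, rng):
        X, y, sids = _toy_data(8, 16, rng)
        Xv, yv, sv = _toy_data(2, 16, rng, subjects_prefix="v")
        kwargs = dict(
            model_config=self.tiny_cfg(),
            train_config=tr.TrainConfig(batch_size=8, max_epochs=8,
                                        patience=8, seed=0),
            augment_config=tr.AugmentConfig(enabled=False), seed=0)
        _, hist1 = tr.train_model((X, y, sids), (Xv, yv, sv), **kwargs)
        _, hist2 = tr.train_model((X, y, sids), (Xv, yv, sv), **kwargs)
        assert hist1[0]["train_loss"] == hist2[0]["train_loss"]
        assert hist1[-1]["train_loss"] < hist1[0]["train_loss"]

    def test_validation_stream_never_augmented(self, rng, monkeypatch):
        X, y, sids = _toy_data(4, 16, rng)
        Xv, yv, sv = _toy_data(2, 16, rng, subjects_prefix="v")
        calls = []
        orig = tr.apply_augmentation

        def traced(image, sample, config):
            calls.append(image.shape)
            return orig(image, sample, config)

        monkeypatch.setattr(tr, "apply_augmentation", traced)
        tr.train_model((X, y, sids), (Xv, yv, sv), self.tiny_cfg(),
                       tr.TrainConfig(batch_size=8, max_epochs=2, seed=0),
                       tr.AugmentConfig(), seed=0)
        # augmentation ran for training batches only: 8 images x 2 epochs
        assert len(calls) == 16
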