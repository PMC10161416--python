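"""Augmentation scheduling and the pretrain/fine-tune protocol."""

import numpy as np
import pytest

from evoaug import augment as A
from evoaug import curriculum as C
from evoaug import model_zoo, seqdata


def _rng(seed=0):
    return np.random.default_rng(seed)


def _config(aug_set, max_augs=1, mode="hard", **settings):
    return C.CurriculumConfig(
        aug_set=frozenset(aug_set),
        settings=A.AugmentationSettings.deepstarr_defaults().with_updates(**settings),
        max_augs=max_augs,
        mode=mode,
    )


class TestSubsetSampling:
    def test_hard_mode_draws_exactly_max(self):
        cfg = _config(C.PRIORITY[:6], max_augs=3)
        for seed in range(20):
            names = C.sample_augmentation_subset(cfg, _rng(seed))
            assert len(names) == 3
            assert len(set(names)) == 3

    def test_soft_mode_count_uniform(self):
        cfg = _config(C.PRIORITY, max_augs=2, mode="soft")
        rng = _rng(1)
        counts = [len(C.sample_augmentation_subset(cfg, rng)) for _ in range(4000)]
        frac_one = counts.count(1) / len(counts)
        assert 0.45 < frac_one < 0.55
        assert set(counts) == {1, 2}

    def test_priority_ordering(self):
        cfg = _config({"mutation", "deletion", "translocation"}, max_augs=3)
        names = C.sample_augmentation_subset(cfg, _rng(2))
        assert names == ["deletion", "translocation", "mutation"]

    def test_never_repeats_an_augmentation(self):
        cfg = _config(C.PRIORITY, max_augs=7)
        for seed in range(10):
            names = C.sample_augmentation_subset(cfg, _rng(seed))
            assert len(names) == len(set(names)) == 7
            assert names == [n for n in C.PRIORITY if n in names]

    def test_max_augs_exceeding_set_rejected(self):
        with pytest.raises(ValueError):
            _config({"mutation"}, max_augs=2)


class TestAugmentBatch:
    def test_empty_set_returns_batch_unchanged(self, small_dataset):
        x = small_dataset.x[:8]
        cfg = C.CurriculumConfig(aug_set=frozenset(), max_augs=0)
        out = C.augment_batch(x, cfg, _rng())
        assert np.array_equal(out, x)

    def test_insertion_in_set_pads_every_record(self, small_dataset):
        x = small_dataset.x[:16]
        cfg = _config(C.PRIORITY, max_augs=1, insert_max=10)
        out = C.augment_batch(x, cfg, _rng(3))
        assert out.shape == (16, x.shape[1] + 10, 4)

    def test_no_insertion_keeps_length(self, small_dataset):
        x = small_dataset.x[:16]
        cfg = _config({"mutation", "translocation"}, max_augs=2)
        out = C.augment_batch(x, cfg, _rng(3))
        assert out.shape == x.shape

    def test_deterministic_per_seed(self, small_dataset):
        x = small_dataset.x[:8]
        cfg = _config(C.PRIORITY, max_augs=2, mode="soft")
        a = C.augment_batch(x, cfg, _rng(5))
        b = C.augment_batch(x, cfg, _rng(5))
        assert np.array_equal(a, b)

    def test_singleton_hard_mode_applies_to_all(self, small_dataset):
        # reverse_complement with rc_prob=1 must transform every record
        x = small_dataset.x[:12]
        cfg = _config({"reverse_complement"}, max_augs=1, rc_prob=1.0)
        out = C.augment_batch(x, cfg, _rng(4))
        for i in range(len(x)):
            assert np.array_equal(out[i], x[i][::-1, ::-1])


class TestPadForInference:
    def test_zero_pad_is_identity(self, small_dataset):
        x = small_dataset.x[:4]
        assert np.array_equal(C.pad_for_inference(x, 0, _rng()), x)

    def test_prefix_preserved_and_length_extended(self):
        rng = _rng(1)
        x = seqdata.random_one_hot(rng, 5, 600)
        out = C.pad_for_inference(x, 30, _rng(2))
        assert out.shape == (5, 630, 4)
        assert np.array_equal(out[:, :600], x)
        assert seqdata.is_one_hot(out[0])

    def test_single_sequence(self):
        x = seqdata.random_one_hot(_rng(), 1, 50)[0]
        out = C.pad_for_inference(x, 7, _rng(3))
        assert out.shape == (57, 4)
        assert np.array_equal(out[:50], x)


class TestPatienceCounter:
    def test_triggers_after_patience_epochs_without_improvement(self):
        c = C._PatienceCounter(3)
        assert not c.update(1.0)
        assert not c.update(0.9)   # improvement resets
        assert not c.update(0.95)
        assert not c.update(0.95)  # equal loss is not an improvement
        assert c.update(0.99)      # third consecutive non-improvement

    def test_strict_decrease_resets(self):
        c = C._PatienceCounter(2)
        c.update(1.0)
        c.update(1.1)
        assert not c.update(0.99)
        assert not c.update(1.0)
        assert c.update(1.0)


@pytest.fixture(scope="module")
def tiny_setup():
    ds = seqdata.generate_synthetic_dataset(
        seqdata.SyntheticSpec(n_records=300, length=80, seed=5)
    )
    spec = model_zoo.mini_cnn_spec(input_length=80, filters=(12,), widths=(7,),
                                   dense_units=12)
    return ds, spec


class TestTraining:
    def test_zero_epochs_returns_initial_model(self, tiny_setup):
        ds, spec = tiny_setup
        model = model_zoo.build_model(spec, seed=0)
        before = [p.copy() for p in model.params]
        model, log = C.pretrain(
            model, ds, _config({"mutation"}),
            C.OptimConfig.pretrain_defaults(max_epochs=0),
        )
        assert log.empty
        for p, q in zip(model.params, before):
            assert np.array_equal(p, q)

    def test_validation_loss_decreases_on_synthetic_data(self, tiny_setup):
        ds, spec = tiny_setup
        model = model_zoo.build_model(spec, seed=1)
        model, log = C.pretrain(
            model, ds, _config({"mutation", "translocation"}, max_augs=1),
            C.OptimConfig.pretrain_defaults(max_epochs=10, batch_size=16, seed=2),
        )
        # the selected (min-validation) checkpoint improves on the first epoch
        assert log.valid_loss.min() < log.valid_loss.iloc[0]
        assert list(log.columns) == ["epoch", "train_loss", "valid_loss", "lr"]
        # learning-rate decay engaged after 5 stagnant epochs
        assert log.lr.iloc[-1] < log.lr.iloc[0]

    def test_shape_mismatch_detected_before_training(self, tiny_setup):
        ds, _ = tiny_setup
        wrong = model_zoo.build_model(model_zoo.mini_cnn_spec(input_length=200), seed=0)
        with pytest.raises(ValueError, match="incompatible"):
            C.pretrain(wrong, ds, _config({"mutation"}),
                       C.OptimConfig.pretrain_defaults(max_epochs=1))

    def test_finetune_zero_epochs_is_identity(self, tiny_setup):
        ds, spec = tiny_setup
        model = model_zoo.build_model(spec, seed=3)
        before = [p.copy() for p in model.params]
        model, log = C.finetune(model, ds, C.OptimConfig.finetune_defaults(max_epochs=0))
        assert log.empty
        for p, q in zip(model.params, before):
            assert np.array_equal(p, q)

    def test_finetune_defaults(self):
        cfg = C.OptimConfig.finetune_defaults()
        assert cfg.learning_rate == 1e-4
        assert cfg.weight_decay == 1e-6
        assert cfg.max_epochs == 5

    def test_pretrain_defaults(self):
        cfg = C.OptimConfig.pretrain_defaults()
        assert cfg.learning_rate == 1e-3
        assert cfg.weight_decay == 1e-6
        assert cfg.max_epochs == 100
        assert cfg.early_stop_patience == 10
        assert (cfg.lr_decay_factor, cfg.lr_decay_patience) == (0.1, 5)

    def test_returned_model_is_min_validation_checkpoint(self, tiny_setup):
        ds, spec = tiny_setup
        model = model_zoo.build_model(spec, seed=4)
        model, log = C.finetune(
            model, ds, C.OptimConfig.finetune_defaults(max_epochs=4, batch_size=16, seed=7)
        )
        from evoaug.curriculum import _evaluate_loss
        from evoaug.nn.losses import loss_for_task

        x_valid, y_valid = ds.split("valid")
        final = _evaluate_loss(model, x_valid, y_valid, loss_for_task(ds.task_kind))
        assert final <= log.valid_loss.min() + 1e-9

    def test_pretrain_reproducible(self, tiny_setup):
        ds, spec = tiny_setup
        logs = []
        for _ in range(2):
            model = model_zoo.build_model(spec, seed=6)
            model, log = C.pretrain(
                model, ds, _config({"mutation"}, max_augs=1),
                C.OptimConfig.pretrain_defaults(max_epochs=2, batch_size=32, seed=8),
            )
            logs.append(log)
        assert np.allclose(logs[0].valid_loss, logs[1].valid_loss, rtol=0, atol=0)
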