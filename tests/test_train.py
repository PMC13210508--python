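import numpy as np
import pytest

from persal.autodiff import Tensor
from persal.model import PsmModel, PsmModelConfig, UsmModel
from persal.train import (
    EarlyStopState,
    TrainConfig,
    early_stop_update,
    evaluate_loss,
    mse_loss,
    split_dataset,
    train_stage,
    transfer_init,
)


class TestMseLoss:
    def test_identical_maps_zero(self):
        a = np.full((4, 4), 0.3)
        assert float(mse_loss(Tensor(a), a).data) == 0.0

    def test_zero_vs_one(self):
        assert float(mse_loss(Tensor(np.zeros((3, 3))), np.ones((3, 3))).data) == 1.0

    def test_hand_arithmetic(self):
        assert float(
            mse_loss(Tensor(np.array([0.0, 1.0])), np.array([1.0, 1.0])).data
        ) == pytest.approx(0.5)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mse_loss(Tensor(np.zeros((2, 2))), np.zeros((3, 3)))


class TestSplitDataset:
    def test_8000_to_6400_1600(self, rng):
        samples = list(range(8000))
        subjects = [i // 1000 for i in range(8000)]
        labels = rng.integers(0, 2, 8000)
        tr, va = split_dataset(samples, 0.8, labels=labels, subjects=subjects, seed=0)
        assert (len(tr), len(va)) == (6400, 1600)
        assert sorted(tr + va) == samples

    def test_per_subject_positive_counts_uniform_when_feasible(self, rng):
        # every subject has exactly 120 positives out of 1000 images
        labels = np.zeros(8000, dtype=int)
        subjects = np.repeat(np.arange(8), 1000)
        for s in range(8):
            pos = rng.choice(1000, 120, replace=False) + s * 1000
            labels[pos] = 1
        samples = list(range(8000))
        tr, _ = split_dataset(samples, 0.8, labels=labels, subjects=subjects, seed=1)
        tr = np.asarray(tr)
        counts = [
            int(labels[tr[(tr >= s * 1000) & (tr < (s + 1) * 1000)]].sum())
            for s in range(8)
        ]
        assert max(counts) - min(counts) <= 1

    def test_same_seed_same_split(self):
        samples = list(range(100))
        a = split_dataset(samples, 0.8, seed=7)
        b = split_dataset(samples, 0.8, seed=7)
        assert a == b
        c = split_dataset(samples, 0.8, seed=8)
        assert a != c


class TestEarlyStopping:
    def test_improving_losses_never_stop(self):
        state = EarlyStopState()
        for loss in (1.0, 0.9, 0.8):
            state, stop = early_stop_update(state, loss, patience=5)
            assert not stop
        assert state.epochs_since_improve == 0

    def test_five_consecutive_non_improvements_stop(self):
        state, _ = early_stop_update(EarlyStopState(), 1.0, 5)
        stops = []
        for _ in range(5):
            state, stop = early_stop_update(state, 1.0, 5)
            stops.append(stop)
        assert stops == [False, False, False, False, True]

    def test_alternating_improvement_resets_counter(self):
        state = EarlyStopState()
        losses = [1.0, 1.1, 0.9, 1.0, 0.8, 0.9, 0.7]
        for loss in losses:
            state, stop = early_stop_update(state, loss, patience=2)
            assert not stop

    def test_default_patience_is_five(self):
        assert TrainConfig().patience == 5


class TestStageDefaults:
    def test_usm_stage_adam_lr_and_batch(self):
        cfg = TrainConfig(stage="USM")
        assert (cfg.optimizer, cfg.learning_rate, cfg.batch_size) == ("adam", 1e-5, 32)

    def test_psm_stage_adamw_lr_batch_replication(self):
        cfg = TrainConfig(stage="PSM")
        assert cfg.optimizer == "adamw"
        assert cfg.learning_rate == 1e-6
        assert cfg.weight_decay == 0.05
        assert cfg.batch_size == 1
        assert cfg.replicate_per_image == 8


@pytest.fixture
def desk_cfg():
    # C=64: wide enough that the ReLU stacks do not collapse during training
    return PsmModelConfig(input_size=(32, 32), channel_scale=1 / 8, M=12,
                          enc_layers=1, dec_layers=1, heads=4, seed=3)


class TestTransferInit:
    def test_tap_equals_usm_prediction_bit_for_bit(self, desk_cfg, rng):
        usm = UsmModel(desk_cfg)
        psm = PsmModel(PsmModelConfig(**{**desk_cfg.__dict__, "seed": 9}))
        transfer_init(psm, usm)
        img = rng.uniform(size=(32, 32, 3))
        np.testing.assert_array_equal(
            psm.enc_output_tap(img).values, usm.predict(img).values
        )

    def test_user_encoding_weights_untouched(self, desk_cfg):
        usm = UsmModel(desk_cfg)
        psm = PsmModel(PsmModelConfig(**{**desk_cfg.__dict__, "seed": 9}))
        before = {k: v.data.copy() for k, v in psm.named_parameters().items()
                  if not k.startswith(("encoder.", "decoder."))}
        transfer_init(psm, usm)
        after = psm.named_parameters()
        for k, v in before.items():
            np.testing.assert_array_equal(after[k].data, v)

    def test_shape_mismatch_lists_offending_layers(self, desk_cfg):
        usm = UsmModel(desk_cfg)
        other = PsmModel(PsmModelConfig(input_size=(32, 32), channel_scale=1 / 16,
                                        M=12, enc_layers=1, dec_layers=1,
                                        heads=4, seed=0))
        with pytest.raises(ValueError, match="encoder"):
            transfer_init(other, usm)

    def test_transferred_encoder_keeps_training(self, desk_cfg, tiny_corpus):
        usm = UsmModel(desk_cfg)
        psm = PsmModel(PsmModelConfig(**{**desk_cfg.__dict__, "seed": 9}))
        transfer_init(psm, usm)
        before = psm.named_parameters()["encoder.layers.0.weight"].data.copy()
        triples = tiny_corpus.training_triples[:2]
        train_stage(triples, triples, psm,
                    TrainConfig(stage="PSM", learning_rate=1e-3,
                                replicate_per_image=1, max_epochs=1, seed=0))
        after = psm.named_parameters()["encoder.layers.0.weight"].data
        assert not np.array_equal(before, after)  # nothing is frozen


class TestTrainStage:
    def test_usm_smoke_loss_decreases(self, tiny_corpus):
        # paper-default optimizer settings on a 16-sample corpus: slow but
        # strictly downhill
        cfg = PsmModelConfig(input_size=(32, 32), channel_scale=1 / 16, M=12,
                             enc_layers=1, dec_layers=1, heads=4, seed=3)
        model = UsmModel(cfg)
        data = [(img, u.values) for img, u in
                zip(tiny_corpus.images, tiny_corpus.usms)]
        res = train_stage(data, [], model,
                          TrainConfig(stage="USM", max_epochs=10, patience=10,
                                      seed=0))
        curve = res.loss_curve.train_loss
        assert curve.iloc[-1] < curve.iloc[0]
        assert len(res.loss_curve) == res.epochs_run

    def test_early_stop_bound(self, tiny_corpus):
        cfg = PsmModelConfig(input_size=(32, 32), channel_scale=1 / 16, M=12,
                             enc_layers=1, dec_layers=1, heads=4, seed=3)
        model = UsmModel(cfg)
        data = [(img, u.values) for img, u in
                zip(tiny_corpus.images, tiny_corpus.usms)]
        res = train_stage(data[:8], data[8:], model,
                          TrainConfig(stage="USM", learning_rate=1e-3,
                                      batch_size=2, max_epochs=40, patience=3,
                                      seed=0))
        assert res.epochs_run <= res.best_epoch + 3

    def test_nan_loss_aborts_with_diagnostic(self, tiny_corpus):
        cfg = PsmModelConfig(input_size=(32, 32), channel_scale=1 / 16, M=12,
                             enc_layers=1, dec_layers=1, heads=4, seed=3)
        model = UsmModel(cfg)
        bad = [(tiny_corpus.images[0], np.full((32, 32), np.nan))]
        with pytest.raises(FloatingPointError, match="NaN"):
            train_stage(bad, [], model, TrainConfig(stage="USM", max_epochs=2,
                                                    seed=0))

    def test_zeroed_user_vectors_make_predictions_subject_independent(
        self, desk_cfg, tiny_corpus
    ):
        model = PsmModel(desk_cfg)
        img = tiny_corpus.images[0]
        zero = np.zeros(desk_cfg.M)
        triples = [(img, zero, tiny_corpus.psms[(s, "img0000")].values)
                   for s in tiny_corpus.world.subject_ids]
        train_stage(triples, [], model,
                    TrainConfig(stage="PSM", learning_rate=1e-3,
                                replicate_per_image=1, max_epochs=1, seed=0))
        maps = [model.predict_psm(img, zero).values for _ in range(2)]
        np.testing.assert_array_equal(maps[0], maps[1])

    def test_reproducible_under_seed(self, tiny_corpus):
        cfg = PsmModelConfig(input_size=(32, 32), channel_scale=1 / 16, M=12,
                             enc_layers=1, dec_layers=1, heads=4, seed=3)
        data = [(img, u.values) for img, u in
                zip(tiny_corpus.images[:6], tiny_corpus.usms[:6])]

        def run():
            model = UsmModel(cfg)
            res = train_stage(data, [], model,
                              TrainConfig(stage="USM", learning_rate=1e-3,
                                          batch_size=2, max_epochs=3,
                                          patience=5, seed=11))
            return res.loss_curve.train_loss.to_numpy()

        np.testing.assert_array_equal(run(), run())
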