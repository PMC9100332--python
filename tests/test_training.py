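"""Learning-rate schedule, label smoothing, joint loss, combined
accuracy, and the early-stopping/training loop mechanics."""

import numpy as np
import pytest

from ecgscope.autograd import Tensor
from ecgscope.dataset import Dataset, build_dataset
from ecgscope.model import ECGPairClassifier, ModelConfig, load_checkpoint, save_checkpoint
from ecgscope.training import (
    TrainConfig, combined_accuracy, early_stop, joint_loss, lr_schedule,
    smooth_labels, train, verification_rates,
)


class TestLrSchedule:
    def test_initial_value(self):
        # 0.000012 * e^2 + 0.00008
        assert lr_schedule(0) == pytest.approx(1.6867e-4, rel=1e-3)

    def test_strictly_decreasing_to_floor(self):
        rates = [lr_schedule(e) for e in range(0, 500, 10)]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        assert lr_schedule(10) < lr_schedule(0)
        assert lr_schedule(5000) == pytest.approx(0.00008, rel=1e-6)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1)


class TestSmoothLabels:
    def test_binary_constants(self):
        out = smooth_labels(np.array([1, 0]), eps=0.1)
        assert out[0] == pytest.approx(0.95)
        assert out[1] == pytest.approx(0.05)

    def test_32_class_constants(self):
        out = smooth_labels(np.array([3]), eps=0.1, num_classes=32)
        assert out[0, 3] == pytest.approx(0.903125)
        assert out[0, 0] == pytest.approx(0.003125)
        assert out.sum() == pytest.approx(1.0)

    def test_eps_zero_identity(self):
        t = np.array([1, 0, 1])
        assert np.array_equal(smooth_labels(t, eps=0.0), t.astype(float))
        onehot = smooth_labels(np.array([2]), eps=0.0, num_classes=4)
        assert np.array_equal(onehot, [[0, 0, 1, 0]])


class TestJointLoss:
    def test_perfect_unsmoothed_outputs_near_zero(self):
        ver = Tensor(np.array([[0.9999999, 1e-7, 1e-7]]))
        dist = Tensor(np.array([[0.9999999, 5e-8, 5e-8]]))
        loss = joint_loss(ver, dist, np.array([0]), eps=0.0)
        assert float(loss.data) < 1e-4

    def test_uniform_identification_equals_log_h(self):
        h = 32
        ver = Tensor(np.full((1, h), 0.5))
        dist = Tensor(np.full((1, h), 1.0 / h))
        loss_ver_only = joint_loss(ver, dist, np.array([4]), eps=0.0,
                                   identification_weight=0.0)
        loss_both = joint_loss(ver, dist, np.array([4]), eps=0.0)
        id_term = float(loss_both.data - loss_ver_only.data)
        assert id_term == pytest.approx(np.log(h), rel=1e-5)

    def test_matches_bruteforce_summation(self, rng):
        b, h, eps = 3, 5, 0.1
        probs = rng.uniform(0.05, 0.95, size=(b, h))
        raw = rng.uniform(size=(b, h))
        dist = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, h, size=b)
        loss = float(joint_loss(Tensor(probs), Tensor(dist), labels,
                                eps=eps).data)
        # independent per-element accumulation
        expected = 0.0
        for i in range(b):
            for k in range(h):
                t = 1 - eps / 2 if k == labels[i] else eps / 2
                expected += -(t * np.log(probs[i, k] + 1e-7)
                              + (1 - t) * np.log(1 - probs[i, k] + 1e-7)) / (b * h)
            for k in range(h):
                t = 1 - eps + eps / h if k == labels[i] else eps / h
                expected += -t * np.log(dist[i, k] + 1e-7) / b
        assert loss == pytest.approx(expected, rel=1e-6)


class TestCombinedAccuracy:
    def test_literal_mean_definition(self):
        assert combined_accuracy(1.0, 0.0, 1.0) == pytest.approx(2 / 3)
        assert combined_accuracy(0.4, 0.4, 0.4) == pytest.approx(0.4)

    def test_corrected_variant(self):
        assert combined_accuracy(1.0, 0.0, 1.0, corrected=True) == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            combined_accuracy(1.2, 0.0, 0.5)

    def test_matches_hand_computation_from_outcomes(self, rng):
        probs = rng.uniform(size=(20, 4))
        labels = rng.integers(0, 4, 20)
        tpr, fpr = verification_rates(probs, labels)
        genuine = probs[np.arange(20), labels]
        hand_tpr = (genuine >= 0.5).sum() / 20
        assert tpr == pytest.approx(hand_tpr)
        acc = combined_accuracy(tpr, fpr, 0.5)
        assert acc == pytest.approx((tpr + fpr + 0.5) / 3)


class TestEarlyStop:
    def test_patience_trace(self):
        # losses by epoch; stop after the 5th epoch, best is the 2nd
        losses = [1.0, 0.9, 0.95, 0.96, 0.97]
        best, stop = early_stop(losses, patience=3)
        assert (best, stop) == (1, True)
        assert early_stop(losses[:4], patience=3) == (1, False)

    def test_improvement_resets_patience(self):
        assert early_stop([1.0, 0.9, 0.95, 0.85], patience=3) == (3, False)


@pytest.fixture(scope="module")
def micro_datasets(easy_split_module):
    train_reg, val_reg = easy_split_module
    tr = build_dataset(train_reg, 48, np.random.default_rng(0), scope_size=4)
    va = build_dataset(val_reg, 16, np.random.default_rng(1), scope_size=4)
    return tr, va


@pytest.fixture(scope="module")
def easy_split_module():
    from ecgscope.dataset import split_registry
    from ecgscope.synthetic import EASY_NOISE, synth_registry
    reg = synth_registry(2, [12, 8], [128.0, 256.0], 321,
                         duration_s=16.0, noise=EASY_NOISE)
    return split_registry(reg)


class TestTrainLoop:
    def test_two_epoch_run_records_history(self, micro_datasets):
        tr, va = micro_datasets
        model = ECGPairClassifier(ModelConfig.scaled(1 / 32, seed=1))
        cfg = TrainConfig(batch_size=8, steps_per_epoch=2, max_epochs=2, seed=3)
        model, hist = train(model, tr, va, cfg)
        assert hist.epochs_run == 2
        assert len(hist.val_loss) == 2
        assert hist.learning_rate[0] == pytest.approx(lr_schedule(0))
        assert 0 <= hist.best_epoch < 2

    def test_seeded_runs_identical(self, micro_datasets):
        tr, va = micro_datasets

        def run():
            model = ECGPairClassifier(ModelConfig.scaled(1 / 32, seed=1))
            cfg = TrainConfig(batch_size=8, steps_per_epoch=2,
                              max_epochs=2, seed=3)
            _, hist = train(model, tr, va, cfg)
            return hist

        a, b = run(), run()
        assert a.train_loss == b.train_loss
        assert a.val_loss == b.val_loss

    def test_checkpoint_reproduces_validation_loss(self, micro_datasets, tmp_path):
        tr, va = micro_datasets
        model = ECGPairClassifier(ModelConfig.scaled(1 / 32, seed=2))
        cfg = TrainConfig(batch_size=8, steps_per_epoch=2, max_epochs=2, seed=4)
        model, hist = train(model, tr, va, cfg)
        path = save_checkpoint(model, tmp_path / "ck.npz")
        back, _ = load_checkpoint(path)
        from ecgscope.training import _evaluate
        metrics = _evaluate(back, va, cfg)
        back.eval()
        assert metrics["loss"] == pytest.approx(
            hist.val_loss[hist.best_epoch], abs=1e-5)

    def test_overlapping_identities_rejected(self, micro_datasets):
        tr, _ = micro_datasets
        model = ECGPairClassifier(ModelConfig.scaled(1 / 32, seed=1))
        with pytest.raises(ValueError, match="overlap"):
            train(model, tr, tr, TrainConfig(batch_size=8, steps_per_epoch=1,
                                             max_epochs=1))

    def test_empty_dataset_rejected(self, micro_datasets):
        tr, va = micro_datasets
        empty = Dataset(np.empty((0, 0, 384), np.float32),
                        np.empty((0, 384), np.float32),
                        np.empty(0, np.int16))
        model = ECGPairClassifier(ModelConfig.scaled(1 / 32, seed=1))
        with pytest.raises(ValueError):
            train(model, empty, va, TrainConfig())
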