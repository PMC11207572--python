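"""Training contract, CLR schedule, split protocols, and metrics."""

import numpy as np
import pytest

from eegmutin.preprocess import EpochArray
from eegmutin.synth import SUBJECT_COUNTS
from eegmutin.train import (ConfusionMatrix, TrainConfig, accuracy,
                            clr_schedule, confusion_matrix, kfold_split,
                            losov_split, per_class_diagonal, train)
from eegmutin.nets import build_eegnet


class TestClrSchedule:
    CFG = TrainConfig(epochs=10, seed=0)

    def test_cycle_endpoints(self):
        s = self.CFG.clr_step_multiplier * 3
        assert clr_schedule(0, self.CFG, 3) == pytest.approx(self.CFG.clr_low)
        assert clr_schedule(s, self.CFG, 3) == pytest.approx(self.CFG.clr_high)
        assert clr_schedule(2 * s, self.CFG, 3) == pytest.approx(
            self.CFG.clr_low
        )

    def test_periodic_and_bounded(self):
        s = self.CFG.clr_step_multiplier * 2
        lrs = [clr_schedule(i, self.CFG, 2) for i in range(4 * s)]
        assert min(lrs) >= self.CFG.clr_low
        assert max(lrs) <= self.CFG.clr_high
        assert clr_schedule(7, self.CFG, 2) == pytest.approx(
            clr_schedule(7 + 2 * s, self.CFG, 2)
        )

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(clr_low=1e-3, clr_high=1e-7)


class TestKfold:
    def test_corpus_sized_folds(self):
        splits = kfold_split(11_964, k=10, seed=0)
        test_sizes = sorted(len(te) for _, te in splits)
        assert test_sizes == [1196] * 6 + [1197] * 4
        for tr, te in splits:
            assert len(tr) == 11_964 - len(te)

    def test_partition_property(self):
        splits = kfold_split(101, k=7, seed=1)
        all_test = np.concatenate([te for _, te in splits])
        assert sorted(all_test.tolist()) == list(range(101))
        for tr, te in splits:
            assert np.intersect1d(tr, te).size == 0

    def test_singleton_folds(self):
        splits = kfold_split(10, k=10, seed=2)
        assert all(len(te) == 1 for _, te in splits)

    def test_stratified_fold_class_balance(self):
        labels = np.repeat(np.arange(4), 20)
        splits = kfold_split(80, k=4, seed=3, labels=labels)
        for _, te in splits:
            counts = np.bincount(labels[te], minlength=4)
            assert counts.max() - counts.min() <= 1

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            kfold_split(3, k=5)


class TestLosov:
    def test_corpus_counts_round_for_each_subject(self):
        subjects = np.concatenate([
            np.full(SUBJECT_COUNTS[s], s) for s in sorted(SUBJECT_COUNTS)
        ])
        rounds = losov_split(subjects)
        assert len(rounds) == 6
        # published rotation holds out the last subject first
        held_out = [int(subjects[te[0]]) for _, te in rounds]
        assert held_out == [6, 1, 2, 3, 4, 5]
        by_subject = {int(subjects[te[0]]): (len(tr), len(te))
                      for tr, te in rounds}
        assert by_subject[4] == (9969, 1995)

    def test_every_segment_tested_once(self):
        subjects = np.array([1, 1, 2, 3, 3, 3])
        rounds = losov_split(subjects)
        tested = np.concatenate([te for _, te in rounds])
        assert sorted(tested.tolist()) == list(range(6))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            losov_split(np.array([1, 1, 1]))


class TestMetrics:
    def test_perfect_predictions_diagonal(self):
        cm = confusion_matrix([0, 1, 2], [0, 1, 2], 3)
        assert np.array_equal(cm.counts, np.eye(3, dtype=int))
        assert accuracy(cm) == 100.0
        assert all(accuracy(cm, c) == 100.0 for c in range(3))

    def test_hand_counted_matrix(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert cm.counts.tolist() == [[1, 1], [0, 2]]
        assert cm.total == 4

    def test_one_vs_rest_accuracy(self):
        cm = ConfusionMatrix(np.array([[2, 1], [0, 3]]))
        assert accuracy(cm, 0) == pytest.approx(83.33, abs=0.01)
        assert accuracy(cm) == pytest.approx(5 / 6 * 100)

    def test_per_class_diagonal_fractions(self):
        cm = ConfusionMatrix(np.array([[8, 2], [5, 5]]))
        assert np.allclose(per_class_diagonal(cm), [80.0, 50.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((2, 2), int)))


def _separable_epochs(n_per_class=30, n_channels=3, n_samples=48, seed=0):
    """Two linearly separable classes with distinct mean patterns."""
    rng = np.random.default_rng(seed)
    pattern = rng.standard_normal((2, n_channels, n_samples)).astype(
        np.float32
    )
    labels = np.repeat([0, 1], n_per_class)
    data = pattern[labels] + 0.05 * rng.standard_normal(
        (2 * n_per_class, n_channels, n_samples)
    ).astype(np.float32)
    return EpochArray(data, labels, np.ones(2 * n_per_class, int),
                      [f"C{i}" for i in range(n_channels)], (0, n_samples))


class TestTraining:
    def test_separable_toy_reaches_full_training_accuracy(self):
        ep = _separable_epochs()
        graph = build_eegnet(chans=3, samples=48, n_classes=2)
        cfg = TrainConfig.desk(epochs=50, batch_size=20, seed=1)
        model = train(graph, ep, cfg)
        from eegmutin.train import epochs_to_input
        pred = model.predict(epochs_to_input(ep, graph))
        assert (pred == ep.labels).mean() == 1.0

    def test_loss_history_decreases_under_smoothing(self):
        ep = _separable_epochs()
        graph = build_eegnet(chans=3, samples=48, n_classes=2)
        cfg = TrainConfig.desk(epochs=40, batch_size=20, seed=2)
        hist = np.array(train(graph, ep, cfg).loss_history)
        smooth = np.convolve(hist, np.ones(5) / 5, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_same_seed_reproduces_final_loss(self):
        ep = _separable_epochs(n_per_class=10)
        graph = build_eegnet(chans=3, samples=48, n_classes=2)
        cfg = TrainConfig.desk(epochs=5, batch_size=10, seed=3)
        a = train(graph, ep, cfg).loss_history
        b = train(graph, ep, cfg).loss_history
        assert a == b

    def test_label_out_of_range_rejected(self):
        ep = _separable_epochs(n_per_class=5)
        ep.labels[0] = 7
        graph = build_eegnet(chans=3, samples=48, n_classes=2)
        with pytest.raises(ValueError, match="labels"):
            train(graph, ep, TrainConfig.desk(epochs=1, seed=0))
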