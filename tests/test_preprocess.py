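"""Enhancement chain: repair, rejection, standardization, epoching."""

import dataclasses

import numpy as np
import pytest

from eegmutin.dataset import SegmentSet
from eegmutin.preprocess import (DegenerateChannelError, EpochArray,
                                 UnrecoverableDataError, apply_scaler,
                                 average_evoked, detect_and_repair_bad_channels,
                                 fit_scaler, make_epochs, parse_window,
                                 preprocess, reject_spans, NAMED_WINDOWS)
from eegmutin.synth import SynthConfig, generate_dataset, inject_artifacts


@pytest.fixture(scope="module")
def clean_cfg():
    return SynthConfig(
        n_subjects=2, per_subject_counts=(40, 40), n_classes=4,
        n_channels=5, n_samples=200,
        channel_names=("C1", "C2", "C3", "C4", "C5"),
        informative_channels=("C1", "C2"), seed=9,
    )


class TestRepair:
    def test_clean_data_untouched(self, clean_cfg):
        ds, _ = generate_dataset(clean_cfg)
        out, bad = detect_and_repair_bad_channels(ds)
        assert bad == [] and out == ds

    def test_injected_flat_channel_found_and_repaired(self, clean_cfg):
        cfg = dataclasses.replace(clean_cfg, bad_channel_list=("C4",))
        ds, gt = generate_dataset(cfg)
        out, bad = detect_and_repair_bad_channels(ds)
        registry_bad = [r["channel"] for r in gt.artifact_registry
                        if r["kind"] == "bad_channel"]
        assert bad == registry_bad == ["C4"]
        ch = ds.channel_names.index("C4")
        assert out.data[:, ch, :].std() > 10 * ds.data[:, ch, :].std()

    def test_repaired_equals_mean_of_top3_correlated(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 4, 100)).astype(np.float32)
        data[:, 3, :] = 1e-7 * rng.standard_normal((20, 100))
        ds = SegmentSet(data, np.zeros(20, int), np.ones(20, int),
                        ["A", "B", "C", "D"], n_classes=1)
        out, bad = detect_and_repair_bad_channels(ds)
        assert bad == ["D"]
        assert np.allclose(out.data[:, 3, :], data[:, :3, :].mean(axis=1),
                           atol=1e-6)

    def test_all_bad_unrecoverable(self):
        data = np.full((5, 3, 50), 0.0, np.float32)
        ds = SegmentSet(data, np.zeros(5, int), np.ones(5, int),
                        ["A", "B", "C"], n_classes=1)
        with pytest.raises(UnrecoverableDataError):
            detect_and_repair_bad_channels(ds)


class TestRejectSpans:
    def test_clean_set_keeps_everything(self, clean_cfg):
        ds, _ = generate_dataset(clean_cfg)
        out, rejected = reject_spans(ds, z_threshold=8.0)
        assert rejected.size == 0 and out == ds

    def test_injected_spans_all_rejected(self, clean_cfg):
        cfg = dataclasses.replace(clean_cfg, artifact_rate=0.5)
        base, _ = generate_dataset(clean_cfg)
        ds, registry = inject_artifacts(base, cfg, seed=4)
        out, rejected = reject_spans(ds, z_threshold=6.0)
        injected = {r["segment"] for r in registry}
        assert injected == set(rejected.tolist())

    def test_total_rejection_is_unrecoverable(self, clean_cfg):
        cfg = dataclasses.replace(clean_cfg, artifact_rate=1.0)
        base, _ = generate_dataset(clean_cfg)
        ds, registry = inject_artifacts(base, cfg, seed=4)
        with pytest.raises(UnrecoverableDataError):
            reject_spans(ds, z_threshold=6.0)

    def test_infinite_threshold_is_identity(self, clean_cfg):
        ds, _ = generate_dataset(clean_cfg)
        out, rejected = reject_spans(ds, z_threshold=np.inf)
        assert rejected.size == 0 and out == ds


def epochs_from(values, window=(0, None)):
    arr = np.asarray(values, np.float32)
    end = window[1] if window[1] is not None else arr.shape[2]
    return EpochArray(arr, np.zeros(arr.shape[0], int),
                      np.ones(arr.shape[0], int),
                      [f"C{i}" for i in range(arr.shape[1])],
                      (window[0], end))


class TestScaler:
    def test_hand_arithmetic(self):
        # one channel, values 1,3,5,7 across 2 epochs x 2 samples
        ep = epochs_from([[[1.0, 3.0]], [[5.0, 7.0]]])
        stats = fit_scaler(ep)
        assert stats.mean[0] == pytest.approx(4.0)
        assert stats.variance[0] == pytest.approx(20.0 / 3.0)
        scaled = apply_scaler(ep, stats)
        expected = np.array([-1.1619, -0.3873, 0.3873, 1.1619])
        assert np.allclose(scaled.data.ravel(), expected, atol=1e-4)

    def test_zero_variance_channel_named(self):
        ep = epochs_from([[[0.0, 0.0], [1.0, 2.0]]])
        with pytest.raises(DegenerateChannelError, match="C0"):
            fit_scaler(ep)

    def test_epoch_order_invariance(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((6, 3, 10)).astype(np.float32)
        a = fit_scaler(epochs_from(arr))
        b = fit_scaler(epochs_from(arr[::-1]))
        assert np.allclose(a.mean, b.mean) and np.allclose(a.variance,
                                                           b.variance)

    def test_fit_apply_standardizes(self):
        rng = np.random.default_rng(3)
        ep = epochs_from(10 + 5 * rng.standard_normal((8, 4, 50)))
        out = apply_scaler(ep, fit_scaler(ep))
        flat = out.data.transpose(1, 0, 2).reshape(4, -1)
        assert np.allclose(flat.mean(axis=1), 0.0, atol=1e-6)
        assert np.allclose(flat.var(axis=1, ddof=1), 1.0, atol=1e-5)

    def test_refit_is_idempotent(self):
        rng = np.random.default_rng(4)
        ep = epochs_from(rng.standard_normal((8, 2, 30)))
        once = apply_scaler(ep, fit_scaler(ep))
        twice = apply_scaler(once, fit_scaler(once))
        assert np.allclose(once.data, twice.data, atol=1e-4)

    def test_channel_mismatch_rejected(self):
        ep = epochs_from(np.random.default_rng(5).standard_normal((4, 2, 10)))
        stats = fit_scaler(ep)
        stats.channel_names = ["X", "Y"]
        with pytest.raises(ValueError, match="match"):
            apply_scaler(ep, stats)


class TestEpoching:
    def test_full_window_is_identity(self, small_segments):
        ep = make_epochs(small_segments, (0, 20))
        assert np.array_equal(ep.data, small_segments.data)
        assert np.array_equal(ep.labels, small_segments.labels)

    @pytest.mark.parametrize("window", NAMED_WINDOWS)
    def test_named_windows_have_half_open_length(self, window):
        rng = np.random.default_rng(6)
        ds = SegmentSet(rng.standard_normal((3, 2, 440)).astype(np.float32),
                        [0, 1, 0], [1, 1, 1], ["A", "B"], n_classes=2)
        ep = make_epochs(ds, window)
        assert ep.data.shape[2] == window[1] - window[0]

    def test_out_of_range_window(self, small_segments):
        with pytest.raises(ValueError, match="window"):
            make_epochs(small_segments, (10, 30))

    def test_parse_window(self):
        assert parse_window("360:440") == (360, 440)
        with pytest.raises(ValueError):
            parse_window("360-440")


class TestEvoked:
    def test_single_epoch_identity(self):
        rng = np.random.default_rng(7)
        arr = rng.standard_normal((3, 2, 10)).astype(np.float32)
        ep = EpochArray(arr, np.array([0, 1, 2]), np.ones(3, int),
                        ["A", "B"], (0, 10))
        ev = average_evoked(ep, 3)
        assert np.allclose(ev, arr)

    def test_noise_free_evoked_recovers_scaled_template(self):
        cfg = SynthConfig(
            n_subjects=1, per_subject_counts=(8,), n_classes=2,
            n_channels=3, n_samples=100,
            channel_names=("A", "B", "C"), informative_channels=("A",),
            snr_db=np.inf, line_noise_amp=0.0, shared_fraction=1.0, seed=5,
        )
        ds, gt = generate_dataset(cfg)
        ev = average_evoked(make_epochs(ds), cfg.n_classes)
        gain = gt.subject_gains[1]
        for c in range(2):
            assert np.allclose(ev[c, 0], cfg.amplitude_uv * gain
                               * gt.templates[c], atol=1e-4)

    def test_linearity(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((4, 2, 10)).astype(np.float32)
        b = rng.standard_normal((4, 2, 10)).astype(np.float32)
        labels = np.array([0, 0, 1, 1])
        mk = lambda arr: EpochArray(arr, labels, np.ones(4, int),
                                    ["A", "B"], (0, 10))
        mid = average_evoked(mk((a + b) / 2), 2)
        sep = (average_evoked(mk(a), 2) + average_evoked(mk(b), 2)) / 2
        assert np.allclose(mid, sep, atol=1e-6)

    def test_missing_class_raises(self):
        ep = epochs_from(np.zeros((2, 1, 5)))
        with pytest.raises(ValueError, match="class"):
            average_evoked(ep, 3)


def test_pipeline_preserves_channels_and_documents_rejections(clean_cfg):
    cfg = dataclasses.replace(clean_cfg, artifact_rate=0.3)
    base, _ = generate_dataset(clean_cfg)
    ds, registry = inject_artifacts(base, cfg, seed=11)
    epochs, report = preprocess(ds, window=(50, 150))
    assert epochs.n_channels == ds.n_channels
    assert epochs.n_epochs + len(report["rejected_segments"]) == ds.n_segments
    kept = np.setdiff1d(np.arange(ds.n_segments),
                        np.array(report["rejected_segments"], int))
    assert np.array_equal(epochs.labels, ds.labels[kept])
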