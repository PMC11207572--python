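"""Signal-enhancement chain: bad-channel repair, artifact-span rejection,
per-channel standardization, epoching, and evoked averaging.

The stage order is fixed — repair -> reject -> fit/apply scaler -> epoch ->
(optional) evoked — and the scaler follows the mean/variance estimator over
all epochs and time points per channel, with the unbiased N-1 variance
denominator.  Standardization is fitted on training data only and applied
unchanged to held-out data; leaking validation statistics into the scaler
is the classic error this separation prevents.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dataset import SegmentSet, subset_segments

#: The nine evaluation time windows (ms, half-open) plus the full segment.
NAMED_WINDOWS: tuple[tuple[int, int], ...] = (
    (20, 240), (20, 350), (20, 440), (40, 200), (40, 360),
    (130, 350), (130, 440), (240, 440), (360, 440),
)


class UnrecoverableDataError(RuntimeError):
    """All channels or all segments failed quality control."""


class DegenerateChannelError(ValueError):
    """A channel has zero variance and cannot be standardized."""


@dataclasses.dataclass
class ScalerStats:
    """Per-channel mean and unbiased variance over epochs x time points."""

    mean: np.ndarray        # (n_channels,), microvolts
    variance: np.ndarray    # (n_channels,), microvolts^2
    n_values: int           # epochs * time points per channel
    channel_names: list[str]


@dataclasses.dataclass
class EpochArray:
    """Stimulus-locked epochs sliced to one time window."""

    data: np.ndarray        # (n_epochs, n_channels, n_samples)
    labels: np.ndarray
    subjects: np.ndarray
    channel_names: list[str]
    window_ms: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.window_ms
        if self.data.shape[2] != end - start:
            raise ValueError(
                f"window {self.window_ms} implies {end - start} samples, "
                f"data has {self.data.shape[2]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def parse_window(spec: str) -> tuple[int, int]:
    """Parse a window string like ``"360:440"`` into (start_ms, end_ms)."""
    try:
        start, end = (int(p) for p in spec.split(":"))
    except ValueError as exc:
        raise ValueError(f"window must be 'start:end' in ms, got {spec!r}") from exc
    return start, end


# ---------------------------------------------------------------------------
# quality control

def detect_and_repair_bad_channels(
    ds: SegmentSet, flat_threshold: float | None = None,
    corr_threshold: float = 0.0,
) -> tuple[SegmentSet, list[str]]:
    """Find near-flat or decorrelated channels and rebuild them from good ones.

    A channel is bad if its pooled standard deviation falls below
    ``flat_threshold`` (default: 1e-3 of the median channel std) or its
    maximum absolute correlation with every other channel is below
    ``corr_threshold``.  The correlation criterion is off (0.0) by
    default: it presumes spatially correlated background activity, which
    real recordings have but channel-independent reference noise does
    not.  Each bad channel is replaced, segment by segment, with the mean
    of its 3 most-correlated good channels.
    """
    if ds.n_channels < 3:
        raise ValueError("need at least 3 channels for repair")
    pooled = ds.data.transpose(1, 0, 2).reshape(ds.n_channels, -1).astype(float)
    stds = pooled.std(axis=1)
    if flat_threshold is None:
        med = float(np.median(stds))
        flat_threshold = 1e-3 * med if med > 0 else 1e-12
    flat_threshold = max(flat_threshold, 1e-12)

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(pooled)
    corr = np.nan_to_num(corr)
    np.fill_diagonal(corr, 0.0)
    max_corr = np.abs(corr).max(axis=1)

    bad = (stds <= flat_threshold) | (max_corr < corr_threshold)
    if bad.all():
        raise UnrecoverableDataError("every channel failed quality control")
    bad_idx = np.flatnonzero(bad)
    if bad_idx.size == 0:
        return ds, []

    good_idx = np.flatnonzero(~bad)
    data = ds.data.copy()
    for b in bad_idx:
        order = good_idx[np.argsort(-np.abs(corr[b, good_idx]))][:3]
        data[:, b, :] = ds.data[:, order, :].mean(axis=1)
    out = SegmentSet(
        data=data, labels=ds.labels.copy(), subjects=ds.subjects.copy(),
        channel_names=list(ds.channel_names),
        sampling_rate_hz=ds.sampling_rate_hz, n_classes=ds.n_classes,
    )
    return out, [ds.channel_names[b] for b in bad_idx]


def reject_spans(ds: SegmentSet,
                 z_threshold: float = 6.0) -> tuple[SegmentSet, np.ndarray]:
    """Drop segments containing any sample beyond ``z_threshold`` channel SDs.

    The per-channel location and scale are the median and the
    MAD-derived robust SD (1.4826 * median absolute deviation) over the
    whole segment set, so the artifacts being hunted do not inflate the
    yardstick used to find them.  Returns the surviving set and the
    rejected segment indices.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    flat = ds.data.transpose(1, 0, 2).reshape(ds.n_channels, -1)
    med = np.median(flat, axis=1)
    sd = 1.4826 * np.median(np.abs(flat - med[:, None]), axis=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = np.abs((ds.data - med[None, :, None]) / sd[None, :, None])
    bad = np.flatnonzero(z.max(axis=(1, 2)) > z_threshold)
    if bad.size == ds.n_segments:
        raise UnrecoverableDataError("every segment exceeded the z threshold")
    keep = np.setdiff1d(np.arange(ds.n_segments), bad)
    return subset_segments(ds, keep), bad


# ---------------------------------------------------------------------------
# standardization

def fit_scaler(epochs: EpochArray) -> ScalerStats:
    """Per-channel mean and unbiased (N-1) variance over epochs and samples."""
    n = epochs.data.shape[0] * epochs.data.shape[2]
    if n < 2:
        raise ValueError("need at least 2 values per channel")
    flat = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    flat = flat.astype(np.float64)
    mean = flat.mean(axis=1)
    var = flat.var(axis=1, ddof=1)
    zero = np.flatnonzero(var == 0)
    if zero.size:
        names = [epochs.channel_names[z] for z in zero]
        raise DegenerateChannelError(f"zero-variance channel(s): {names}")
    return ScalerStats(mean=mean, variance=var, n_values=n,
                       channel_names=list(epochs.channel_names))


def apply_scaler(epochs: EpochArray, stats: ScalerStats) -> EpochArray:
    """Standardize each channel: ``(x - mu_n) / sigma_n``; labels preserved."""
    if stats.channel_names != epochs.channel_names:
        raise ValueError("scaler channels do not match epoch channels")
    sd = np.sqrt(stats.variance)
    data = (epochs.data - stats.mean[None, :, None]) / sd[None, :, None]
    return EpochArray(
        data=data.astype(np.float32), labels=epochs.labels.copy(),
        subjects=epochs.subjects.copy(),
        channel_names=list(epochs.channel_names), window_ms=epochs.window_ms,
    )


# ---------------------------------------------------------------------------
# epoching

def make_epochs(ds: SegmentSet,
                window: tuple[int, int] | None = None) -> EpochArray:
    """Slice every segment to a half-open ``[start_ms, end_ms)`` window.

    At 1 kHz sample ``i`` is ``i`` milliseconds, so the slice is simply
    ``data[..., start:end]``.  ``None`` keeps the full segment.
    """
    if window is None:
        window = (0, ds.n_samples)
    start, end = window
    if not 0 <= start < end <= ds.n_samples:
        raise ValueError(
            f"window {window} outside [0, {ds.n_samples}] or empty"
        )
    return EpochArray(
        data=ds.data[:, :, start:end].copy(), labels=ds.labels.copy(),
        subjects=ds.subjects.copy(), channel_names=list(ds.channel_names),
        window_ms=(start, end),
    )


def average_evoked(epochs: EpochArray, n_classes: int) -> np.ndarray:
    """Per-class mean across epochs: (n_classes, n_channels, n_samples)."""
    present = np.unique(epochs.labels)
    missing = sorted(set(range(n_classes)) - set(present.tolist()))
    if missing:
        raise ValueError(f"no epochs for class(es) {missing}")
    out = np.empty((n_classes, epochs.n_channels, epochs.data.shape[2]))
    for c in range(n_classes):
        out[c] = epochs.data[epochs.labels == c].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# composite chain

@dataclasses.dataclass
class PreprocessConfig:
    flat_threshold: float | None = None
    corr_threshold: float = 0.0
    z_threshold: float = 6.0
    repair: bool = True
    reject: bool = True


def preprocess(ds: SegmentSet, cfg: PreprocessConfig | None = None,
               window: tuple[int, int] | None = None) -> tuple[
                   EpochArray, dict]:
    """Run repair -> reject -> epoch; scaling is applied separately per split.

    Returns the epoch array (unscaled) and a report of repaired channels and
    rejected segment indices.
    """
    cfg = cfg or PreprocessConfig()
    report: dict = {"bad_channels": [], "rejected_segments": []}
    if cfg.repair:
        ds, bad = detect_and_repair_bad_channels(
            ds, cfg.flat_threshold, cfg.corr_threshold
        )
        report["bad_channels"] = bad
    if cfg.reject:
        ds, rejected = reject_spans(ds, cfg.z_threshold)
        report["rejected_segments"] = rejected.tolist()
    return make_epochs(ds, window), report
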