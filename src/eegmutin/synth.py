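"""Synthetic visual-EEG dataset generator with known ground truth.

Emulates the structure of the 6-subject / 40-class / 128-channel / 1 kHz
visual-stimulus EEG corpus: per-subject segment counts, balanced classes,
class-dependent evoked responses concentrated in an "informative" channel
subset, 1/f-type background noise band-limited to 5-95 Hz with a 50 Hz
notch, 50 Hz line contamination, and optional injected artifacts and bad
channels.  Every stochastic choice derives from a single seed, so a
configuration reproduces its dataset bit-exactly.

The evoked model: segment = g_s * E_{c,ch} + noise, where g_s is a scalar
subject gain and the evoked waveform in informative channel ch for class c
is ``E = w*T_c + (1-w)*R_{c,ch}`` — a class template ``T_c`` common to all
informative channels, blended with a channel-specific variant ``R`` by the
``shared_fraction`` weight w.  The common component is what makes
informative channel pairs share information, which is the hook the
mutual-information selection stage is tested against.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .channels import default_informative, default_layout
from .dataset import SegmentSet

#: Per-subject segment counts of the emulated corpus, keyed by subject ID.
SUBJECT_COUNTS = {1: 1985, 2: 1996, 3: 1996, 4: 1995, 5: 1996, 6: 1996}

#: Order in which subjects' blocks appear in the corpus (segments 1..11964).
SUBJECT_ORDER = (4, 1, 6, 3, 2, 5)


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class SynthConfig:
    """Generator configuration; defaults emulate the full corpus."""

    n_subjects: int = 6
    per_subject_counts: tuple[int, ...] = tuple(
        SUBJECT_COUNTS[s] for s in sorted(SUBJECT_COUNTS)
    )
    n_classes: int = 40
    n_channels: int = 128
    n_samples: int = 440
    sampling_rate_hz: float = 1000.0
    channel_names: tuple[str, ...] | None = None
    informative_channels: tuple[str, ...] | None = None
    amplitude_uv: float = 10.0
    snr_db: float = 5.0
    shared_fraction: float = 0.8
    noise_exponent: float = 1.5
    line_noise_amp: float = 0.5
    artifact_rate: float = 0.0
    bad_channel_list: tuple[str, ...] = ()
    channel_gain_spread: float = 0.0
    baseline_offset_uv: float = 0.0
    subject_gain_spread: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.per_subject_counts) != self.n_subjects:
            raise ConfigurationError(
                f"{len(self.per_subject_counts)} per-subject counts for "
                f"{self.n_subjects} subjects"
            )
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigurationError("artifact_rate must be in [0, 1]")
        if self.channel_names is None:
            self.channel_names = tuple(default_layout(self.n_channels))
        else:
            self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.n_channels:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        if self.informative_channels is None:
            self.informative_channels = tuple(default_informative(self.n_channels))
        else:
            self.informative_channels = tuple(self.informative_channels)
        unknown = set(self.informative_channels) - set(self.channel_names)
        if unknown:
            raise ConfigurationError(
                f"informative channels not in layout: {sorted(unknown)}"
            )
        unknown = set(self.bad_channel_list) - set(self.channel_names)
        if unknown:
            raise ConfigurationError(f"bad channels not in layout: {sorted(unknown)}")

    def scaled(self, factor: float) -> "SynthConfig":
        """Copy with per-subject counts scaled by ``factor`` (desk-size runs)."""
        counts = tuple(max(self.n_classes, int(round(c * factor)))
                       for c in self.per_subject_counts)
        return dataclasses.replace(self, per_subject_counts=counts)


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually planted, for downstream recovery tests."""

    informative_channels: tuple[str, ...]
    templates: np.ndarray          # (n_classes, n_samples), unit peak
    subject_gains: dict[int, float]
    channel_gains: np.ndarray      # (n_channels,)
    artifact_registry: list[dict]
    bad_channels: tuple[str, ...]


# ---------------------------------------------------------------------------
# evoked templates

def make_class_template(class_id: int, cfg: SynthConfig,
                        seed: int | None = None) -> np.ndarray:
    """Deterministic ERP-like waveform for one class.

    A sum of 2-4 Gaussian-windowed oscillations (5-45 Hz carriers) with
    class-specific latencies and amplitudes, zero-mean and normalized to
    unit peak.  Latency centres are spread over the segment so distinct
    classes stay well below perfect correlation.
    """
    if not 0 <= class_id < cfg.n_classes:
        raise ValueError(f"class_id {class_id} outside [0, {cfg.n_classes})")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 7919, class_id])
    n = cfg.n_samples
    fs = cfg.sampling_rate_hz
    t = np.arange(n) / fs
    n_comp = int(rng.integers(2, 5))
    w = np.zeros(n)
    for _ in range(n_comp):
        freq = rng.uniform(5.0, 45.0)
        center = rng.uniform(0.12, 0.88) * n / fs
        width = rng.uniform(0.02, 0.08)          # seconds
        amp = rng.uniform(0.5, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        w += amp * np.exp(-0.5 * ((t - center) / width) ** 2) * np.sin(
            2 * np.pi * freq * (t - center) + phase
        )
    w -= w.mean()
    peak = np.abs(w).max()
    if peak > 0:
        w /= peak
    return w


def _template_bank(cfg: SynthConfig) -> np.ndarray:
    return np.stack([make_class_template(c, cfg) for c in range(cfg.n_classes)])


def _variant_bank(cfg: SynthConfig, n_informative: int) -> np.ndarray:
    """Channel-specific evoked variants R_{c,ch}: one deterministic
    template-like waveform per (class, informative channel)."""
    bank = np.zeros((cfg.n_classes, n_informative, cfg.n_samples))
    for c in range(cfg.n_classes):
        for j in range(n_informative):
            bank[c, j] = make_class_template(
                c, cfg, seed=(cfg.seed * 1_000_003 + 50_021 * (j + 1)) & 0x7FFFFFFF
            )
    return bank


# ---------------------------------------------------------------------------
# background noise

def _noise_filter(cfg: SynthConfig) -> np.ndarray:
    """rFFT amplitude envelope: power ~ 1/f^exponent inside 5-95 Hz,
    zero outside, with a 48-52 Hz notch."""
    freqs = np.fft.rfftfreq(cfg.n_samples, d=1.0 / cfg.sampling_rate_hz)
    amp = np.zeros_like(freqs)
    band = (freqs >= 5.0) & (freqs <= 95.0)
    amp[band] = freqs[band] ** (-cfg.noise_exponent / 2.0)
    amp[(freqs >= 48.0) & (freqs <= 52.0)] = 0.0
    return amp


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                amp: np.ndarray, n_samples: int) -> np.ndarray:
    """Band-limited 1/f-type noise, unit variance, shape (*shape, n_samples)."""
    nf = amp.size
    z = rng.standard_normal((*shape, nf)) + 1j * rng.standard_normal((*shape, nf))
    x = np.fft.irfft(z * amp, n=n_samples, axis=-1)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


# ---------------------------------------------------------------------------
# dataset generation

def generate_dataset(cfg: SynthConfig) -> tuple[SegmentSet, GroundTruth]:
    """Generate a synthetic labeled dataset plus its ground truth.

    Per-subject class labels are balanced up to rounding; subjects appear in
    the corpus block order.  The evoked-to-noise power ratio in informative
    channels is ``snr_db``; non-informative channels carry noise only.
    """
    if min(cfg.per_subject_counts) < cfg.n_classes:
        raise ConfigurationError(
            f"per-subject counts must be >= n_classes ({cfg.n_classes}) "
            "for balanced labels"
        )
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 104729])
    names = list(cfg.channel_names)
    inf_idx = np.array([names.index(c) for c in cfg.informative_channels])
    n_inf = len(inf_idx)

    templates = _template_bank(cfg)
    w = cfg.shared_fraction
    if w < 1.0:
        variants = _variant_bank(cfg, n_inf)
        # (n_classes, n_inf, n_samples)
        evoked = w * templates[:, None, :] + (1.0 - w) * variants
    else:
        evoked = np.broadcast_to(
            templates[:, None, :], (cfg.n_classes, n_inf, cfg.n_samples)
        ).copy()
    evoked = cfg.amplitude_uv * evoked    # physiological microvolt scale

    # noise sigma from the mean evoked power and the requested SNR
    p_evoked = float(np.mean(evoked ** 2))
    if np.isinf(cfg.snr_db):
        sigma = 0.0
    else:
        sigma = np.sqrt(p_evoked / (10.0 ** (cfg.snr_db / 10.0)))

    subject_ids = sorted(range(1, cfg.n_subjects + 1))
    counts = {sid: cfg.per_subject_counts[sid - 1] for sid in subject_ids}
    gains = {
        sid: float(1.0 + cfg.subject_gain_spread * (rng.uniform(-1, 1)))
        for sid in subject_ids
    }
    if cfg.channel_gain_spread > 0:
        ch_gains = np.exp(rng.uniform(-cfg.channel_gain_spread,
                                      cfg.channel_gain_spread, cfg.n_channels))
    else:
        ch_gains = np.ones(cfg.n_channels)
    # electrode-interface baseline (residual drift / half-cell potential)
    ch_offsets = (cfg.baseline_offset_uv
                  * rng.uniform(-1.0, 1.0, cfg.n_channels))

    order = [s for s in SUBJECT_ORDER if s in counts]
    order += [s for s in subject_ids if s not in order]

    amp = _noise_filter(cfg)
    fs = cfg.sampling_rate_hz
    t = np.arange(cfg.n_samples) / fs
    blocks, all_labels, all_subjects = [], [], []
    for sid in order:
        n_seg = counts[sid]
        labels = np.resize(np.arange(cfg.n_classes), n_seg)
        rng.shuffle(labels)
        data = np.zeros((n_seg, cfg.n_channels, cfg.n_samples), dtype=np.float32)
        # evoked component in informative channels
        data[:, inf_idx, :] = (gains[sid] * evoked[labels]).astype(np.float32)
        # background noise everywhere, in chunks to bound memory
        if sigma > 0:
            for lo in range(0, n_seg, 256):
                hi = min(lo + 256, n_seg)
                data[lo:hi] += (sigma * _pink_noise(
                    rng, (hi - lo, cfg.n_channels), amp, cfg.n_samples
                )).astype(np.float32)
        # 50 Hz line contamination, random phase per segment and channel
        if cfg.line_noise_amp > 0:
            phases = rng.uniform(0, 2 * np.pi, (n_seg, cfg.n_channels))
            data += (cfg.line_noise_amp * sigma * np.sin(
                2 * np.pi * 50.0 * t[None, None, :] + phases[:, :, None]
            )).astype(np.float32)
        data += ch_offsets[None, :, None].astype(np.float32)
        data *= ch_gains[None, :, None].astype(np.float32)
        blocks.append(data)
        all_labels.append(labels)
        all_subjects.append(np.full(n_seg, sid))

    ds = SegmentSet(
        data=np.concatenate(blocks, axis=0),
        labels=np.concatenate(all_labels),
        subjects=np.concatenate(all_subjects),
        channel_names=names,
        sampling_rate_hz=cfg.sampling_rate_hz,
        n_classes=cfg.n_classes,
    )
    gt = GroundTruth(
        informative_channels=tuple(cfg.informative_channels),
        templates=templates,
        subject_gains=gains,
        channel_gains=ch_gains,
        artifact_registry=[],
        bad_channels=tuple(cfg.bad_channel_list),
    )
    if cfg.artifact_rate > 0 or cfg.bad_channel_list:
        ds, registry = inject_artifacts(ds, cfg, seed=cfg.seed)
        gt.artifact_registry = registry
    return ds, gt


def inject_artifacts(ds: SegmentSet, cfg: SynthConfig,
                     seed: int = 0) -> tuple[SegmentSet, list[dict]]:
    """Add high-amplitude spans and flatten bad channels; return a registry.

    Each selected segment (probability ``artifact_rate``) receives one
    contiguous span of >= 20 samples at >= 10x the channel's standard
    deviation in one random channel.  Channels in ``bad_channel_list`` are
    replaced everywhere by near-flat noise.  Rate 0 with no bad channels is
    the identity.
    """
    registry: list[dict] = []
    if cfg.artifact_rate == 0 and not cfg.bad_channel_list:
        return ds, registry
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 65537])
    data = ds.data.copy()
    ch_std = data.std(axis=(0, 2))
    n_seg, n_ch, n_samp = data.shape

    for seg in range(n_seg):
        if rng.uniform() >= cfg.artifact_rate:
            continue
        ch = int(rng.integers(0, n_ch))
        length = int(rng.integers(20, min(81, n_samp + 1)))
        start = int(rng.integers(0, n_samp - length + 1))
        amplitude = 12.0 * float(ch_std[ch]) if ch_std[ch] > 0 else 12.0
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        data[seg, ch, start:start + length] += sign * amplitude
        registry.append({
            "kind": "span", "segment": seg, "channel": ds.channel_names[ch],
            "start": start, "length": length, "amplitude": sign * amplitude,
        })

    if cfg.bad_channel_list:
        med_std = float(np.median(ch_std)) or 1.0
        for name in cfg.bad_channel_list:
            ch = ds.channel_names.index(name)
            data[:, ch, :] = (1e-4 * med_std) * rng.standard_normal(
                (n_seg, n_samp)
            ).astype(np.float32)
            registry.append({"kind": "bad_channel", "channel": name})

    out = SegmentSet(
        data=data, labels=ds.labels.copy(), subjects=ds.subjects.copy(),
        channel_names=list(ds.channel_names),
        sampling_rate_hz=ds.sampling_rate_hz, n_classes=ds.n_classes,
    )
    return out, registry


def default_manifest_counts(cfg: SynthConfig | None = None) -> dict[int, int]:
    """Per-subject segment counts the generator will produce for ``cfg``."""
    if cfg is None:
        cfg = SynthConfig()
    return {sid: cfg.per_subject_counts[sid - 1]
            for sid in range(1, cfg.n_subjects + 1)}
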