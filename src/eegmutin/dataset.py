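"""Dataset container and on-disk format for labeled multichannel EEG segments.

A :class:`SegmentSet` holds fixed-length stimulus-locked EEG segments
(``n_segments x n_channels x n_samples``, microvolts) together with a class
label and subject ID per segment.  On disk a dataset is a directory with one
raw little-endian float32 array file per subject plus a JSON manifest
recording shapes, channel names, class names and provenance — a bit-exact,
dependency-free format.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

MANIFEST_VERSION = 1
MANIFEST_NAME = "manifest.json"


class ValidationError(ValueError):
    """A dataset or manifest violates a structural invariant."""


class DatasetIOError(OSError):
    """A dataset file is missing or corrupt."""


@dataclasses.dataclass
class SegmentSet:
    """Labeled multichannel EEG segments.

    Parameters
    ----------
    data : ndarray, shape (n_segments, n_channels, n_samples)
        Segment waveforms in microvolts (stored float32).
    labels : ndarray of int, shape (n_segments,)
        Class index per segment, in ``[0, n_classes)``.
    subjects : ndarray of int, shape (n_segments,)
        Subject ID per segment (1-based by convention).
    channel_names : list of str
        Ordered, unique 10-20 extended labels.
    sampling_rate_hz : float
        Sampling rate; the default 1 kHz makes one sample one millisecond.
    n_classes : int
    """

    data: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    channel_names: list[str]
    sampling_rate_hz: float = 1000.0
    n_classes: int = 40

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects, dtype=np.int64)
        self.channel_names = list(self.channel_names)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(f"data must be 3-D, got shape {self.data.shape}")
        n_seg = self.data.shape[0]
        if len(self.labels) != n_seg or len(self.subjects) != n_seg:
            raise ValidationError(
                f"labels ({len(self.labels)}) and subjects ({len(self.subjects)}) "
                f"must match n_segments ({n_seg})"
            )
        if n_seg and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValidationError(
                f"labels outside [0, {self.n_classes}): "
                f"range [{self.labels.min()}, {self.labels.max()}]"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            dupes = sorted(
                {c for c in self.channel_names if self.channel_names.count(c) > 1}
            )
            raise ValidationError(f"duplicate channel names: {dupes}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} data channels"
            )
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")

    # -- derived properties ----------------------------------------------
    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def per_subject_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.subjects, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.subjects, other.subjects)
            and self.channel_names == other.channel_names
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.n_classes == other.n_classes
        )


def default_class_names(n_classes: int) -> list[str]:
    """The 40 visual-stimulus category names; generic names beyond 40."""
    base = [
        "cats", "sorrels", "elephants", "fish", "dogs", "airliners", "brooms",
        "pandas", "canoes", "phones", "mugs", "convertibles", "computers",
        "fungi", "locomotives", "espresso", "chairs", "butterflies", "golf",
        "piano", "iron", "daisy", "jacks", "mailbags", "capuchin", "missiles",
        "mittens", "bikes", "tents", "pajama", "parachutes", "pools",
        "radios", "cameras", "guitar", "guns", "shoes", "bananas", "pizzas",
        "watches",
    ]
    if n_classes <= len(base):
        return base[:n_classes]
    return base + [f"class{i}" for i in range(len(base), n_classes)]


def build_manifest(ds: SegmentSet, provenance: dict | None = None,
                   class_names: Sequence[str] | None = None) -> dict:
    """Construct the JSON manifest dictionary for a dataset."""
    if class_names is None:
        class_names = default_class_names(ds.n_classes)
    if len(class_names) != ds.n_classes:
        raise ValidationError(
            f"{len(class_names)} class names for {ds.n_classes} classes"
        )
    return {
        "version": MANIFEST_VERSION,
        "n_segments": ds.n_segments,
        "n_channels": ds.n_channels,
        "n_samples": ds.n_samples,
        "n_classes": ds.n_classes,
        "sampling_rate_hz": ds.sampling_rate_hz,
        "channel_names": list(ds.channel_names),
        "class_names": list(class_names),
        "per_subject_counts": {str(k): v for k, v in ds.per_subject_counts().items()},
        "provenance": provenance or {},
    }


def save_dataset(ds: SegmentSet, path: str | Path,
                 provenance: dict | None = None) -> Path:
    """Persist a dataset as per-subject float32 ``.bin`` files plus manifest.

    Arrays are written little-endian, row-major (segment, channel, sample);
    byte output is deterministic for a fixed input.  Returns the manifest
    path.
    """
    ds.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = build_manifest(ds, provenance=provenance)
    subject_files = {}
    for sid in sorted(ds.per_subject_counts()):
        mask = ds.subjects == sid
        arr = np.ascontiguousarray(ds.data[mask], dtype="<f4")
        fname = f"subject_{sid}.bin"
        arr.tofile(path / fname)
        subject_files[str(sid)] = {
            "file": fname,
            "n_segments": int(mask.sum()),
            "labels": ds.labels[mask].tolist(),
            # global positions, so interleaved subject order round-trips
            "indices": np.flatnonzero(mask).tolist(),
        }
    manifest["subjects"] = subject_files
    mpath = path / MANIFEST_NAME
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return mpath


def load_dataset(path: str | Path) -> SegmentSet:
    """Load a dataset directory written by :func:`save_dataset`.

    Manifest counts are cross-checked against the array file sizes; any
    discrepancy raises :class:`ValidationError` naming the offender.
    """
    path = Path(path)
    mpath = path / MANIFEST_NAME
    if not mpath.exists():
        raise DatasetIOError(f"missing manifest file: {mpath}")
    try:
        with open(mpath) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DatasetIOError(f"corrupt manifest {mpath}: {exc}") from exc

    n_ch = manifest["n_channels"]
    n_samp = manifest["n_samples"]
    n_total = manifest["n_segments"]
    data = np.empty((n_total, n_ch, n_samp), dtype=np.float32)
    labels = np.empty(n_total, dtype=np.int64)
    subjects = np.empty(n_total, dtype=np.int64)
    total = 0
    filled = np.zeros(n_total, dtype=bool)
    if not manifest.get("subjects"):
        raise DatasetIOError(f"no subject data files listed in {mpath}")
    for sid_str in sorted(manifest["subjects"], key=int):
        entry = manifest["subjects"][sid_str]
        fpath = path / entry["file"]
        if not fpath.exists():
            raise DatasetIOError(f"missing data file: {fpath}")
        arr = np.fromfile(fpath, dtype="<f4")
        n_seg = entry["n_segments"]
        expected = n_seg * n_ch * n_samp
        if arr.size != expected:
            raise ValidationError(
                f"{fpath.name}: {arr.size} values on disk but manifest "
                f"implies {n_seg}x{n_ch}x{n_samp} = {expected}"
            )
        if len(entry["labels"]) != n_seg:
            raise ValidationError(
                f"subject {sid_str}: {len(entry['labels'])} labels for "
                f"{n_seg} segments"
            )
        idx = np.asarray(entry.get("indices", range(total, total + n_seg)))
        if idx.size != n_seg or idx.min() < 0 or idx.max() >= n_total \
                or filled[idx].any():
            raise ValidationError(
                f"subject {sid_str}: segment indices invalid or overlapping"
            )
        data[idx] = arr.reshape(n_seg, n_ch, n_samp)
        labels[idx] = entry["labels"]
        subjects[idx] = int(sid_str)
        filled[idx] = True
        total += n_seg
    if total != n_total or not filled.all():
        raise ValidationError(
            f"manifest n_segments {n_total} != sum of per-subject "
            f"counts {total}"
        )
    return SegmentSet(
        data=data, labels=labels, subjects=subjects,
        channel_names=manifest["channel_names"],
        sampling_rate_hz=manifest["sampling_rate_hz"],
        n_classes=manifest["n_classes"],
    )


def subset_channels(ds: SegmentSet, names: Sequence[str]) -> SegmentSet:
    """Restrict a dataset to the given channels, in the given order.

    Segment order and labels are preserved; unknown names raise ``KeyError``.
    """
    index = {c: i for i, c in enumerate(ds.channel_names)}
    missing = [c for c in names if c not in index]
    if missing:
        raise KeyError(f"unknown channel name(s): {missing}")
    idx = [index[c] for c in names]
    return SegmentSet(
        data=ds.data[:, idx, :],
        labels=ds.labels.copy(),
        subjects=ds.subjects.copy(),
        channel_names=list(names),
        sampling_rate_hz=ds.sampling_rate_hz,
        n_classes=ds.n_classes,
    )


def subset_segments(ds: SegmentSet, idx: np.ndarray) -> SegmentSet:
    """Slice a dataset by segment indices (order as given)."""
    idx = np.asarray(idx)
    return SegmentSet(
        data=ds.data[idx],
        labels=ds.labels[idx],
        subjects=ds.subjects[idx],
        channel_names=list(ds.channel_names),
        sampling_rate_hz=ds.sampling_rate_hz,
        n_classes=ds.n_classes,
    )
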