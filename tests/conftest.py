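import numpy as np
import pytest

from eegmutin.dataset import SegmentSet
from eegmutin.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_cfg():
    """8-channel, 3-informative configuration used by the selection tests."""
    return SynthConfig(
        n_subjects=2, per_subject_counts=(120, 120), n_classes=8,
        n_channels=8, n_samples=200,
        channel_names=tuple(f"CH{i}" for i in range(8)),
        informative_channels=("CH0", "CH1", "CH2"),
        shared_fraction=0.8, snr_db=5.0, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_ds(tiny_cfg):
    ds, gt = generate_dataset(tiny_cfg)
    return ds, gt


@pytest.fixture
def small_segments():
    """Hand-sized deterministic SegmentSet for I/O and preprocessing tests."""
    rng = np.random.default_rng(5)
    data = rng.standard_normal((12, 4, 20)).astype(np.float32)
    return SegmentSet(
        data=data,
        labels=rng.integers(0, 3, 12),
        subjects=np.repeat([1, 2], 6),
        channel_names=["Cz", "Pz", "Oz", "POz"],
        n_classes=3,
    )
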