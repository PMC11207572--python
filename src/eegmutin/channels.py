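"""Channel naming for the 128-electrode 10-20 extended (10-05) layout.

Labels are case-sensitive strings; no electrode geometry is stored, since
nothing downstream needs coordinates.  ``DISCRIMINANT_54`` is the published
54-channel discriminant subset (parietal/occipital-dominated) that the
greedy mutual-information selection converges to on the real recordings;
the synthetic generator plants its class signal there by default so that
selection has a recoverable ground truth.
"""

from __future__ import annotations

# The 54 discriminant channels, grouped by scalp region (frontal-central
# through parietal-occipital-occipital).  Note "O11h"/"O12h" follow the
# published labelling of the occipital h-row.
DISCRIMINANT_54: tuple[str, ...] = (
    # frontal-central-central / frontal-central
    "FCC1h", "FCC2h", "FCC4h", "FC1", "FC2",
    # central
    "C1", "C2", "C3", "Cz", "C4", "C5", "C6",
    # central-parietal
    "CP1", "CP2", "CP3", "CPz", "CP4",
    # central-central-parietal
    "CCP1h", "CCP2h", "CCP3h", "CCP4h",
    # occipital
    "O1", "Oz", "O2", "I1", "O11h", "O12h", "I2",
    # parietal
    "Pz", "P1", "P2", "P3", "P4", "P5", "P6", "P8",
    # parietal-occipital
    "PO7", "PO3", "POz", "PO4", "PO8", "PO9", "PO10",
    # parietal-parietal-occipital
    "PPO9h", "PPO5h", "PPO1h", "PPO2h", "PPO6h", "PPO10h",
    # parietal-occipital-occipital
    "POO1", "POO2", "POO9h", "POO10h", "Iz",
)

# Remaining 74 labels completing a 128-channel actiCAP-style montage,
# ordered roughly front to back.
_FILL_74: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AFp1", "AFp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "AFF5h", "AFF1h", "AFF2h", "AFF6h",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FFT7h", "FFC5h", "FFC3h", "FFC1h", "FFC2h", "FFC4h", "FFC6h", "FFT8h",
    "FT9", "FT7", "FC5", "FC3", "FCz", "FC4", "FC6", "FT8", "FT10",
    "FTT7h", "FCC5h", "FCC3h", "FCC6h", "FTT8h",
    "T7", "T8", "M1", "M2",
    "TTP7h", "CCP5h", "CCP6h", "TTP8h",
    "TP9", "TP7", "CP5", "CP6", "TP8", "TP10",
    "TPP7h", "CPP5h", "CPP3h", "CPP1h", "CPP2h", "CPP4h", "CPP6h", "TPP8h",
    "P9", "P7", "P10",
    "POO3h", "POO4h", "I1h", "I2h",
)

#: Default 128-channel layout (front-to-back fill channels interleaved with
#: the discriminant subset is not required; order is fill first, then the
#: 54 discriminant channels grouped at known positions would bias nothing,
#: but a scalp-plausible order is friendlier to humans reading manifests).
LAYOUT_128: tuple[str, ...] = _FILL_74[:45] + DISCRIMINANT_54 + _FILL_74[45:]

assert len(LAYOUT_128) == 128 and len(set(LAYOUT_128)) == 128


def default_layout(n_channels: int) -> list[str]:
    """Return ``n_channels`` default channel names.

    For ``n_channels <= 128`` a prefix of the standard layout is used,
    reordered so the discriminant channels stay available when truncating;
    beyond 128 synthetic ``CHxxx`` names are appended.
    """
    if n_channels <= 128:
        return list(LAYOUT_128[:n_channels])
    return list(LAYOUT_128) + [f"CH{i:03d}" for i in range(128, n_channels)]


def default_informative(n_channels: int, n_informative: int | None = None) -> list[str]:
    """Default informative subset for a generated dataset.

    With the full 128-channel layout this is the 54-channel discriminant
    set; for smaller layouts, a deterministic subset of the available
    names (roughly ``n_channels // 4``, at least 2).
    """
    names = default_layout(n_channels)
    if n_informative is None:
        n_informative = 54 if n_channels >= 128 else max(2, n_channels // 4)
    if n_channels >= 128 and n_informative == 54:
        return list(DISCRIMINANT_54)
    present = [c for c in DISCRIMINANT_54 if c in names]
    pool = present + [c for c in names if c not in present]
    if n_informative > len(names):
        raise ValueError(
            f"cannot pick {n_informative} informative channels from {n_channels}"
        )
    return pool[:n_informative]
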