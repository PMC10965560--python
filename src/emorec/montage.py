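"""Electrode montage, lobe grouping and frequency-band constants.

The 32-channel layout is the standard 10-20 montage used by affective-EEG
benchmark recordings (Geneva ordering).  Channels are grouped into six
anatomical lobes for the groupwise PCA stage of channel selection.
"""

from __future__ import annotations

from collections import OrderedDict

#: 32 channels of the 10-20 system, Geneva order.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Anatomical lobe membership used for lobe-wise PCA.  Lobes are disjoint
#: and their union is exactly the 32-channel montage.
LOBE_MAP: "OrderedDict[str, tuple[str, ...]]" = OrderedDict(
    [
        ("Frontal", ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "AF3", "AF4")),
        ("Temporal", ("T7", "T8")),
        ("Parietal", ("P3", "P4", "P7", "P8", "Pz", "PO3", "PO4")),
        ("Occipital", ("O1", "O2", "Oz")),
        ("Central", ("FC5", "FC1", "C3", "C4", "FC2", "FC6", "Cz")),
        ("Central-Parietal", ("CP5", "CP1", "CP2", "CP6")),
    ]
)

#: Reference 8-channel set for the portable dry-electrode headset, as found
#: by the EII ranking on the benchmark dataset.
OPTIMAL_CHANNELS_8: tuple[str, ...] = (
    "Fp1", "F7", "FC5", "FC6", "T7", "T8", "P7", "O2",
)

#: Default 8-channel configuration of the portable headset before
#: reconfiguration to the optimal set.
DEFAULT_OPENBCI_8: tuple[str, ...] = (
    "Fp1", "Fp2", "C3", "C4", "P7", "P8", "O1", "O2",
)


def lobe_of(channel: str) -> str:
    """Return the lobe a channel belongs to.

    Raises
    ------
    KeyError
        If the channel is not part of the 32-channel montage.
    """
    for lobe, members in LOBE_MAP.items():
        if channel in members:
            return lobe
    raise KeyError(f"channel {channel!r} is not in the 32-channel montage")


def validate_channels(channels, *, context: str = "channel list") -> None:
    """Check that every name belongs to the montage; raise ValueError otherwise."""
    unknown = [c for c in channels if c not in CHANNELS_32]
    if unknown:
        raise ValueError(
            f"{context}: unknown channel(s) {unknown}; valid names are "
            f"{list(CHANNELS_32)}"
        )
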