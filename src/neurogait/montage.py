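"""32-channel 10/20 montage used throughout the package.

The channel set matches a common 32-electrode lower-limb study layout
(frontal through occipital rows, with the central midline Cz over the foot
area of the primary motor cortex).  Scalp coordinates come from MNE's
standard 10/20 template and are used only for the spatial decay of the
simulated movement-related potential.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Ordered 32-channel montage (international 10/20 names).
CHANNELS_32: tuple[str, ...] = (
    "FP1", "FP2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8", "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8", "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: The nine motor-related electrodes: premotor (FC3, FCz, FC4),
#: primary motor (C3, Cz, C4) and somatosensory (P3, Pz, P4) rows.
MOTOR_CHANNELS_9: tuple[str, ...] = (
    "FC3", "FCz", "FC4", "C3", "Cz", "C4", "P3", "Pz", "P4",
)


@lru_cache(maxsize=4)
def channel_positions(channels: tuple[str, ...] = CHANNELS_32) -> np.ndarray:
    """Return (n, 3) scalp positions in meters for ``channels``.

    Positions are looked up case-insensitively in MNE's ``standard_1020``
    template montage (e.g. ``FP1`` resolves to the template's ``Fp1``).
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        # template name is being renamed upstream; either resolves here
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    lower = {k.lower(): v for k, v in pos.items()}
    out = []
    for ch in channels:
        key = ch.lower()
        if key not in lower:
            raise KeyError(f"channel {ch!r} not in the standard 10/20 template")
        out.append(lower[key])
    return np.asarray(out, dtype=float)


def distances_from(channel: str, channels: tuple[str, ...] = CHANNELS_32) -> np.ndarray:
    """Euclidean scalp distances (m) of every channel from ``channel``."""
    if channel not in channels:
        raise KeyError(f"channel {channel!r} not in montage")
    xyz = channel_positions(tuple(channels))
    ref = xyz[list(channels).index(channel)]
    return np.linalg.norm(xyz - ref, axis=1)


def channel_index(channel: str, channels=CHANNELS_32) -> int:
    """Index of ``channel`` in the montage; raises ``KeyError`` if absent."""
    try:
        return list(channels).index(channel)
    except ValueError:
        raise KeyError(f"unknown channel label {channel!r}") from None
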