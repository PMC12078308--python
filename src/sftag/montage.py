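"""Idealized 10-20 electrode layout (positions via MNE's standard montages)."""

from __future__ import annotations

import functools
import warnings

import numpy as np

__all__ = ["DEFAULT_CHANNELS", "REDUCED_CHANNELS", "channel_positions", "channel_distance"]

# 68-label cap: a standard 10-10 set extended with the inion-row channels
# (Iz, I1, I2) used by the posterior marker montage.
DEFAULT_CHANNELS = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
    "Iz", "I1", "I2", "PO9", "PO10", "O9", "O10",
)

# Compact posterior-weighted cap for fast simulations: the 16 marker
# channels plus a few anterior sites so the average reference is realistic.
REDUCED_CHANNELS = (
    "Iz", "I1", "I2", "Oz", "O1", "O2", "POz", "PO3", "PO4", "PO7", "PO8",
    "Pz", "P1", "P2", "P3", "P4", "Cz", "Fz",
)


@functools.lru_cache(maxsize=4)
def _montage_positions() -> dict:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            m = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # renamed in newer MNE
            m = mne.channels.make_standard_montage("colin27_1005")
    return {k: np.asarray(v, dtype=float) for k, v in m.get_positions()["ch_pos"].items()}


def channel_positions(ch_names) -> dict:
    """3-D head positions (meters) for the requested labels."""
    pos = _montage_positions()
    missing = [c for c in ch_names if c not in pos]
    if missing:
        raise KeyError(f"no standard montage position for channels: {missing}")
    return {c: pos[c] for c in ch_names}


def channel_distance(a: str, b: str) -> float:
    pos = _montage_positions()
    return float(np.linalg.norm(pos[a] - pos[b]))
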