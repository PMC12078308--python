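"""SSVEP analysis: preprocessed EEG + events -> log(SSVEP ratio) marker.

The chain is: preprocess (average reference, zero-phase 1-100 Hz bandpass,
line-noise notch, bad-channel interpolation) -> epoch (7 s windows
starting 0.5 s after each video onset, linear detrend, full-epoch
baseline, 150 uV rejection on occipitoparietal channels) -> per-condition
time-domain average (ERP) -> FFT amplitude spectrum (1/7 Hz resolution)
-> spectral SNR (power at a bin over the mean of the 4 neighboring bins
on each side; in dB, ``10 log10(SNR)``) -> per-flicker-frequency peak
electrode selection -> per-spatial-frequency SNR and the neuromarker
``log_ratio = ln(SNR_lower / SNR_higher)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .tagging import Condition, TagSpec

__all__ = [
    "EEGRecording",
    "EpochSet",
    "SpectrumResult",
    "SSVEPMarker",
    "PreprocessConfig",
    "OCCIPITOPARIETAL",
    "preprocess",
    "epoch",
    "evoked_spectrum",
    "snr",
    "neighbor_snr",
    "neighbor_bandwidth_hz",
    "select_peak_electrodes",
    "marker",
    "log_ratio_from_db",
]

#: The 16 posterior channels used for artifact rejection, electrode
#: selection and the marker; order is the tie-break order.
OCCIPITOPARIETAL = (
    "Iz", "I1", "I2", "Oz", "O1", "O2", "POz", "PO3", "PO4", "PO7", "PO8",
    "Pz", "P1", "P2", "P3", "P4",
)

EPOCH_OFFSET_S = 0.5
EPOCH_LENGTH_S = 7.0
REJECT_UV = 150.0
N_NEIGHBORS = 4


def linear_detrend(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the least-squares line (and hence the mean) along an axis.

    Closed form for the shared, evenly spaced sample grid; equivalent to
    ``scipy.signal.detrend(x, type='linear')`` but O(n) without the lstsq.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    t = (np.arange(n) - (n - 1) / 2.0).astype(x.dtype)
    denom = float(t @ t)
    mean = x.mean(axis=-1, keepdims=True)
    slope = (x @ t)[..., None] / denom
    out = x - mean - slope * t
    return np.moveaxis(out, -1, axis)


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts with a video-presentation event table."""

    data: np.ndarray  # (n_channels, n_samples), uV
    sfreq: float
    ch_names: tuple
    events: pd.DataFrame  # columns: onset_sample, video_id, condition

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        self.ch_names = tuple(self.ch_names)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be (n_channels, n_samples) matching ch_names")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        need = {"onset_sample", "video_id", "condition"}
        if not need.issubset(self.events.columns):
            raise ValueError(f"events table must have columns {sorted(need)}")
        if len(self.events) and (
            self.events.onset_sample.min() < 0
            or self.events.onset_sample.max() >= self.data.shape[1]
        ):
            raise ValueError("event onsets outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.ch_names]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        return np.array([self.ch_names.index(n) for n in names])


@dataclass
class EpochSet:
    """Per-presentation epochs with rejection flags."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    conditions: np.ndarray  # int per epoch
    rejected: np.ndarray  # bool per epoch
    reject_reason: tuple  # str or None per epoch
    sfreq: float
    ch_names: tuple

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def kept(self, condition=None) -> np.ndarray:
        """Indices of non-rejected epochs, optionally within one condition."""
        mask = ~self.rejected
        if condition is not None:
            mask &= self.conditions == int(condition)
        return np.where(mask)[0]

    def subset(self, indices) -> "EpochSet":
        indices = np.asarray(indices)
        return EpochSet(
            epochs=self.epochs[indices],
            conditions=self.conditions[indices],
            rejected=self.rejected[indices],
            reject_reason=tuple(self.reject_reason[i] for i in indices),
            sfreq=self.sfreq,
            ch_names=self.ch_names,
        )


@dataclass
class SpectrumResult:
    """Amplitude spectrum of a condition ERP, per channel."""

    freqs: np.ndarray  # Hz
    amplitude: np.ndarray  # (n_channels, n_freqs)
    sfreq: float
    ch_names: tuple
    condition: int
    n_epochs: int

    @property
    def power(self) -> np.ndarray:
        return self.amplitude**2

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def bin_index(self, freq_hz: float) -> int:
        i = int(round(freq_hz / self.df))
        if not 0 <= i < len(self.freqs) or abs(self.freqs[i] - freq_hz) > 1e-6:
            raise ValueError(
                f"{freq_hz} Hz does not fall on the {self.df:.4f} Hz frequency grid"
            )
        return i

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.ch_names.index(n) for n in names])


@dataclass
class SSVEPMarker:
    """The per-participant neuromarker and its ingredients."""

    snr_linear: dict  # {'higher': float, 'lower': float}
    snr_db: dict
    electrodes: dict  # {flicker_freq_hz: (ch, ch)}
    log_ratio: float
    snr_is_infinite: bool = False
    convention: str = "linear SNR averaged across the two selected electrodes and the two conditions"


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass
class PreprocessConfig:
    l_freq: float = 1.0
    h_freq: float = 100.0
    notch_hz: float | None = 60.0
    notch_q: float = 30.0
    average_reference: bool = True
    bad_channels: tuple = ()
    montage_positions: dict | None = None  # label -> xyz; default idealized 10-20
    artifact_hook: Callable | None = None  # callable(data, sfreq, ch_names) -> data
    filter_order: int = 4


def preprocess(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Zero-phase band-pass + notch, bad-channel interpolation, average reference.

    Bad channels are rebuilt by inverse-distance-squared weighting of the
    good channels on an idealized 10-20 montage before the average
    reference is computed.  An optional artifact-removal hook (e.g. an
    ICA backend) runs last.
    """
    cfg = cfg or PreprocessConfig()
    if rec.sfreq <= 200:
        raise ValueError("preprocess requires a sampling rate above 200 Hz")
    data = rec.data.copy()

    if cfg.bad_channels:
        marker_chs = [c for c in OCCIPITOPARIETAL if c in rec.ch_names]
        if marker_chs and all(c in cfg.bad_channels for c in marker_chs):
            raise ValueError(
                "all marker (occipitoparietal) channels are marked bad; montage unrecoverable"
            )
        data = _interpolate_bads(data, rec.ch_names, cfg.bad_channels, cfg.montage_positions)

    sos = scipy.signal.butter(
        cfg.filter_order, [cfg.l_freq, cfg.h_freq], btype="bandpass", fs=rec.sfreq, output="sos"
    )
    data = scipy.signal.sosfiltfilt(sos, data, axis=1)
    if cfg.notch_hz:
        b, a = scipy.signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.sfreq)
        data = scipy.signal.filtfilt(b, a, data, axis=1)
    if cfg.average_reference:
        data = data - data.mean(axis=0, keepdims=True)
    if cfg.artifact_hook is not None:
        data = cfg.artifact_hook(data, rec.sfreq, rec.ch_names)
    return EEGRecording(data=data, sfreq=rec.sfreq, ch_names=rec.ch_names, events=rec.events)


def _interpolate_bads(data, ch_names, bads, positions=None):
    if positions is None:
        from .montage import channel_positions

        positions = channel_positions(ch_names)
    good = [i for i, c in enumerate(ch_names) if c not in bads and c in positions]
    out = data.copy()
    for i, c in enumerate(ch_names):
        if c not in bads:
            continue
        if c not in positions:
            raise ValueError(f"no montage position for bad channel {c}")
        p = np.asarray(positions[c])
        d2 = np.array([np.sum((np.asarray(positions[ch_names[j]]) - p) ** 2) for j in good])
        w = 1.0 / np.maximum(d2, 1e-12)
        w /= w.sum()
        out[i] = w @ data[good]
    return out


# ---------------------------------------------------------------------------
# Epoching


def epoch(
    rec: EEGRecording,
    offset_s: float = EPOCH_OFFSET_S,
    length_s: float = EPOCH_LENGTH_S,
    reject_uv: float = REJECT_UV,
    reject_channels: Sequence[str] = OCCIPITOPARIETAL,
) -> EpochSet:
    """Cut one epoch per presentation, detrend, and flag artifacts.

    Each epoch spans ``length_s`` seconds starting ``offset_s`` after the
    video onset.  Epochs are linearly detrended per channel (which also
    removes the full-epoch mean, i.e. the baseline).  An epoch is flagged
    rejected if any sample on any of the ``reject_channels`` present in
    the recording exceeds ``reject_uv`` in absolute amplitude.  A
    presentation whose epoch would run past the end of the recording is
    flagged (reason 'truncated'), not fatal.
    """
    n_len = int(round(length_s * rec.sfreq))
    n_off = int(round(offset_s * rec.sfreq))
    rej_idx = [rec.ch_names.index(c) for c in reject_channels if c in rec.ch_names]

    events = rec.events.reset_index(drop=True)
    n_ep = len(events)
    epochs = np.zeros((n_ep, rec.n_channels, n_len), dtype=rec.data.dtype)
    rejected = np.zeros(n_ep, dtype=bool)
    reasons: list = [None] * n_ep

    starts = events.onset_sample.to_numpy().astype(int) + n_off
    ok = starts + n_len <= rec.n_samples
    for i in np.where(~ok)[0]:
        rejected[i] = True
        reasons[i] = "truncated"
    if ok.any():
        idx = starts[ok][:, None] + np.arange(n_len)[None, :]
        segs = rec.data[:, idx]  # (n_channels, n_ok, n_len)
        segs = linear_detrend(segs, axis=-1)
        epochs[ok] = np.transpose(segs, (1, 0, 2))
        if rej_idx:
            bad = np.abs(epochs[np.ix_(np.where(ok)[0], rej_idx)]).max(axis=(1, 2)) > reject_uv
            for i, b in zip(np.where(ok)[0], bad):
                if b:
                    rejected[i] = True
                    reasons[i] = f"amplitude > {reject_uv} uV"
    return EpochSet(
        epochs=epochs,
        conditions=events.condition.to_numpy().astype(int),
        rejected=rejected,
        reject_reason=tuple(reasons),
        sfreq=rec.sfreq,
        ch_names=rec.ch_names,
    )


# ---------------------------------------------------------------------------
# Spectra and SNR


def evoked_spectrum(epochs: EpochSet, condition) -> SpectrumResult:
    """FFT amplitude spectrum of the condition ERP (mean over kept epochs)."""
    keep = epochs.kept(condition)
    if len(keep) == 0:
        raise ValueError(f"no usable epochs in condition {condition}")
    erp = epochs.epochs[keep].mean(axis=0)
    n = erp.shape[1]
    amp = np.abs(np.fft.rfft(erp, axis=1)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.sfreq)
    return SpectrumResult(
        freqs=freqs,
        amplitude=amp,
        sfreq=epochs.sfreq,
        ch_names=epochs.ch_names,
        condition=int(condition),
        n_epochs=len(keep),
    )


def neighbor_snr(power: np.ndarray, i: int, n_neighbors: int = N_NEIGHBORS):
    """Linear SNR of bin ``i``: power over the mean of the 2*n adjacent bins.

    Returns ``(snr, is_infinite)``.  A zero neighborhood under nonzero
    target power yields the +inf sentinel rather than an exception, so
    batch runs survive pathological channels.
    """
    if i < n_neighbors or i + n_neighbors >= len(power):
        raise ValueError(
            f"bin {i} needs {n_neighbors} neighbors on each side within the spectrum"
        )
    neigh = np.r_[power[i - n_neighbors : i], power[i + 1 : i + 1 + n_neighbors]]
    denom = float(np.mean(neigh))
    if denom == 0.0:
        if power[i] == 0.0:
            return 1.0, False  # flat zero spectrum: no evidence either way
        return math.inf, True
    return float(power[i] / denom), False


def snr(spectrum: SpectrumResult, freq_hz: float, channels: Sequence[str] | None = None):
    """Per-channel (linear, dB) SNR at a frequency of the FFT grid."""
    i = spectrum.bin_index(freq_hz)
    power = spectrum.power
    idx = (
        spectrum.channel_index(channels)
        if channels is not None
        else np.arange(len(spectrum.ch_names))
    )
    lin = np.empty(len(idx))
    flags = np.zeros(len(idx), dtype=bool)
    for j, ch in enumerate(idx):
        lin[j], flags[j] = neighbor_snr(power[ch], i)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(lin)
    return lin, db, flags


def neighbor_bandwidth_hz(length_s: float = EPOCH_LENGTH_S, n_neighbors: int = N_NEIGHBORS) -> float:
    """Width of the SNR neighborhood per side, in Hz (4 bins of 1/7 Hz ~ 0.57 Hz)."""
    return n_neighbors / length_s


def select_peak_electrodes(
    spectra: dict,
    flicker_hz: float,
    candidates: Sequence[str] = OCCIPITOPARIETAL,
) -> tuple[str, str]:
    """Top-2 candidate channels by SNR at ``flicker_hz``, averaged over conditions.

    ``spectra`` maps condition -> SpectrumResult.  Because each flicker
    frequency appears once in each counterbalanced condition, averaging
    over both conditions scores an electrode's response to that frequency
    independently of spatial frequency.  Ties break by candidate order.
    """
    candidates = [c for c in candidates if all(c in s.ch_names for s in spectra.values())]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate channels present in all spectra")
    scores = np.zeros(len(candidates))
    for spec_res in spectra.values():
        lin, _, _ = snr(spec_res, flicker_hz, candidates)
        scores += lin
    scores /= len(spectra)
    order = sorted(range(len(candidates)), key=lambda j: (-scores[j], j))
    return candidates[order[0]], candidates[order[1]]


def _cells_for_sf(tag_spec: TagSpec):
    """(condition, frequency) cells contributing to each SF set."""
    out = {"higher": [], "lower": []}
    for cond in (Condition.COND1, Condition.COND2):
        s = TagSpec(
            threshold_cpd=tag_spec.threshold_cpd,
            freq_a_hz=tag_spec.freq_a_hz,
            freq_b_hz=tag_spec.freq_b_hz,
            condition=cond,
            start_phase_rad=tag_spec.start_phase_rad,
        )
        for sf in ("higher", "lower"):
            out[sf].append((cond, s.frequency_for(sf)))
    return out


def marker(
    spectra: dict,
    tag_spec: TagSpec | None = None,
    candidates: Sequence[str] = OCCIPITOPARIETAL,
) -> SSVEPMarker:
    """Compute the log(SSVEP ratio) neuromarker from per-condition spectra.

    For each flicker frequency the two strongest candidate electrodes are
    selected (SNR averaged over both conditions).  Each spatial-frequency
    set then gets one linear SNR: the mean over its two
    (condition x frequency) cells of the mean SNR across the electrodes
    selected for that cell's frequency.  The marker is
    ``ln(SNR_lower / SNR_higher)``; SNRs are combined on the linear
    scale, before any dB conversion.
    """
    tag_spec = tag_spec or TagSpec()
    if len(spectra) < 2:
        raise ValueError("marker needs spectra for both conditions")
    cells = _cells_for_sf(tag_spec)
    freqs = sorted({f for pairs in cells.values() for _, f in pairs})
    electrodes = {f: select_peak_electrodes(spectra, f, candidates) for f in freqs}

    snr_linear = {}
    any_inf = False
    for sf, pairs in cells.items():
        vals = []
        for cond, f in pairs:
            lin, _, flags = snr(spectra[int(cond)], f, electrodes[f])
            vals.append(float(np.mean(lin)))
            any_inf |= bool(flags.any())
        snr_linear[sf] = float(np.mean(vals))
    if snr_linear["higher"] <= 0 or snr_linear["lower"] <= 0:
        raise ValueError(
            f"nonpositive SNR (higher={snr_linear['higher']}, lower={snr_linear['lower']}); "
            "log ratio undefined"
        )
    with np.errstate(divide="ignore"):
        snr_db = {k: 10.0 * math.log10(v) if np.isfinite(v) else math.inf for k, v in snr_linear.items()}
    ratio = snr_linear["lower"] / snr_linear["higher"]
    return SSVEPMarker(
        snr_linear=snr_linear,
        snr_db=snr_db,
        electrodes=electrodes,
        log_ratio=float(np.log(ratio)),
        snr_is_infinite=any_inf,
    )


def log_ratio_from_db(db_lower: float, db_higher: float) -> float:
    """Algebraic identity: ``ln(S_l/S_h) = (dB_l - dB_h) * ln(10) / 10``."""
    return (db_lower - db_higher) * math.log(10.0) / 10.0
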