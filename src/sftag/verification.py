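"""Stimulus validation: recover the embedded tags from a processed video.

Re-decomposes every frame of a (tagged) clip, averages channel power over
the oblique orientations within each spatial-frequency set, and checks
that the FFT across frames of each per-set power time series peaks at the
set's assigned tag frequency.  This mirrors the validation that the
tagging procedure itself is expected to pass before any EEG is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import rgb_to_hsv
from scipy.signal import detrend

from .eeg import neighbor_snr
from .geometry import BandGeometry
from .pyramid import get_pyramid, map_threshold_to_scales
from .tagging import TagSpec, VideoClip

__all__ = [
    "BandPowerTimeSeries",
    "TagVerificationReport",
    "oblique_power_series",
    "verify_tags",
]

MIN_DURATION_S = 2.0  # below this, 7 and 9 Hz are not separable in the FFT


@dataclass
class BandPowerTimeSeries:
    """Per-frame mean channel power, by SF set and orientation class."""

    values: dict  # {('higher'|'lower', 'oblique'|'cardinal'): array of length n_frames}
    fps: float

    def series(self, sf_set: str, orientation_class: str = "oblique") -> np.ndarray:
        return self.values[(sf_set, orientation_class)]

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.values.values())))


@dataclass
class SetVerification:
    assigned_hz: float
    peak_hz: float
    peak_snr: float
    snr_at_assigned: float
    passed: bool
    spectrum_hz: np.ndarray = field(repr=False)
    spectrum_power: np.ndarray = field(repr=False)
    spectrum_snr: np.ndarray = field(repr=False)


@dataclass
class TagVerificationReport:
    sets: dict  # {'higher': SetVerification, 'lower': SetVerification}
    min_snr: float

    @property
    def passed(self) -> bool:
        return all(s.passed for s in self.sets.values())

    def to_dict(self) -> dict:
        return {
            "min_snr": self.min_snr,
            "passed": self.passed,
            "sets": {
                name: {
                    "assigned_hz": s.assigned_hz,
                    "peak_hz": s.peak_hz,
                    "peak_snr": s.peak_snr,
                    "snr_at_assigned": s.snr_at_assigned,
                    "passed": s.passed,
                }
                for name, s in self.sets.items()
            },
        }


def oblique_power_series(
    clip: VideoClip,
    geom: BandGeometry | None = None,
    threshold_cpd: float = 3.2,
    n_orientations: int = 8,
) -> BandPowerTimeSeries:
    """Mean band power per frame for each SF set and orientation class.

    "Oblique" means the orientation channels excluding theta = 0 and
    theta = pi/2 (indices 0 and K/2): those two carry zero modulation by
    construction of the ``|sin 2 theta|`` filter.
    """
    geom = geom or clip.geometry
    if clip.duration_s < MIN_DURATION_S:
        raise ValueError(
            f"clip of {clip.duration_s:.2f} s is too short for tag verification; "
            f"need at least {MIN_DURATION_S} s of frames"
        )
    pyr = get_pyramid(clip.frame_shape, geom.n_scales, n_orientations)
    higher, lower = map_threshold_to_scales(geom, threshold_cpd)

    cardinal = {0, n_orientations // 2}
    oblique = [k for k in range(n_orientations) if k not in cardinal]
    cardinal = sorted(cardinal)

    out = {key: np.empty(clip.n_frames) for key in (
        ("higher", "oblique"), ("higher", "cardinal"),
        ("lower", "oblique"), ("lower", "cardinal"))}
    for i in range(clip.n_frames):
        v = rgb_to_hsv(clip.frames[i])[..., 2]
        powers = pyr.band_powers(v)  # (n_scales, n_orientations)
        for name, scales in (("higher", higher), ("lower", lower)):
            rows = np.asarray(scales) - 1
            out[(name, "oblique")][i] = powers[np.ix_(rows, oblique)].mean()
            out[(name, "cardinal")][i] = powers[np.ix_(rows, cardinal)].mean()
    return BandPowerTimeSeries(values=out, fps=clip.fps)


def _series_spectrum(series: np.ndarray, fps: float):
    y = detrend(np.asarray(series, dtype=float))  # remove linear scene-content drift
    amp = np.abs(np.fft.rfft(y))
    power = amp**2
    freqs = np.fft.rfftfreq(len(y), d=1.0 / fps)
    return freqs, power


def verify_tags(
    series: BandPowerTimeSeries,
    spec: TagSpec,
    min_snr: float = 3.0,
    orientation_class: str = "oblique",
) -> TagVerificationReport:
    """Locate spectral peaks of the band-power series and test them.

    A set passes iff the maximum-SNR bin lies within one frequency bin of
    its assigned tag frequency and that SNR is at least ``min_snr``
    (linear).  SNR per bin uses the same 4-neighbors-per-side rule as the
    EEG spectra.
    """
    n = series.n_frames
    if n < MIN_DURATION_S * series.fps:
        raise ValueError("series too short for verification")
    sets = {}
    for sf_set in ("higher", "lower"):
        y = series.series(sf_set, orientation_class)
        freqs, power = _series_spectrum(y, series.fps)
        df = freqs[1] - freqs[0]
        snr = np.full_like(power, np.nan)
        for i in range(4, len(power) - 4):
            snr[i] = neighbor_snr(power, i)[0]
        valid = np.where(np.isfinite(snr))[0]
        peak = valid[np.argmax(snr[valid])]
        assigned = spec.frequency_for(sf_set)
        bin_assigned = int(round(assigned / df))
        snr_at = float(snr[bin_assigned]) if 4 <= bin_assigned < len(power) - 4 else np.nan
        passed = bool(abs(freqs[peak] - assigned) <= df + 1e-12 and snr[peak] >= min_snr)
        sets[sf_set] = SetVerification(
            assigned_hz=assigned,
            peak_hz=float(freqs[peak]),
            peak_snr=float(snr[peak]),
            snr_at_assigned=snr_at,
            passed=passed,
            spectrum_hz=freqs,
            spectrum_power=power,
            spectrum_snr=snr,
        )
    return TagVerificationReport(sets=sets, min_snr=min_snr)
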