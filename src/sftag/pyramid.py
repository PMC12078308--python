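"""Invertible steerable wavelet pyramid (frequency-domain, tight frame).

Decomposes a 2-D luminance image into ``n_scales`` octave-spaced
spatial-frequency bands, each split into ``n_orientations`` oriented
channels, plus isotropic lowpass and highpass residuals.  The design is
the Simoncelli-style isotropic construction:

* radial windows are raised cosines in log frequency,
  ``h_s(r) = cos(pi/2 * log2(r / w_s))`` on ``w_s/2 <= r <= 2 w_s`` with
  octave-spaced centres ``w_s = pi / 2**s`` (radians/sample), so adjacent
  windows are power complementary (``cos^2 + sin^2 = 1``);
* angular windows are ``A_k(theta) ∝ |cos(theta - theta_k)|**(K-1)`` with
  ``theta_k = k*pi/K``, normalised so that ``sum_k A_k**2 == 1`` exactly
  (the closed-form normaliser is ``K * C(2K-2, K-1) / 4**(K-1)``).

Because the squared transfer functions of all channels tile the frequency
plane exactly (``sum |B|^2 = 1``), the transform is a Parseval tight
frame: summing each coefficient band re-filtered by its own transfer
function reconstructs the input to machine precision, and input energy
equals total coefficient energy.  Filtering is done with FFTs, which
implies periodic boundary handling.  All channels are kept at full
resolution (no downsampling); this costs memory but keeps the algebra
exact and the code simple.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, pi

import numpy as np

from .geometry import BandGeometry

__all__ = [
    "SteerablePyramid",
    "PyramidCoefficients",
    "decompose",
    "reconstruct",
    "band_power",
    "map_threshold_to_scales",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when geometry/threshold configuration is unusable."""


@dataclass
class PyramidCoefficients:
    """Coefficients of one decomposition.

    ``bands[(s, k)]`` holds the real coefficient array of scale ``s``
    (1-based, coarser with increasing ``s``) and orientation ``k``
    (0-based, orientation angle ``k*pi/K``).
    """

    bands: dict[tuple[int, int], np.ndarray]
    lowpass_residual: np.ndarray
    highpass_residual: np.ndarray
    n_scales: int
    n_orientations: int
    shape: tuple[int, int]

    def band(self, scale: int, orientation: int) -> np.ndarray:
        self._check_index(scale, orientation)
        return self.bands[(scale, orientation)]

    def _check_index(self, scale: int, orientation: int) -> None:
        if not (1 <= scale <= self.n_scales):
            raise ValueError(f"scale must be in 1..{self.n_scales}, got {scale}")
        if not (0 <= orientation < self.n_orientations):
            raise ValueError(
                f"orientation must be in 0..{self.n_orientations - 1}, got {orientation}"
            )

    def copy(self) -> "PyramidCoefficients":
        return PyramidCoefficients(
            bands={key: arr.copy() for key, arr in self.bands.items()},
            lowpass_residual=self.lowpass_residual.copy(),
            highpass_residual=self.highpass_residual.copy(),
            n_scales=self.n_scales,
            n_orientations=self.n_orientations,
            shape=self.shape,
        )

    def to_hdf5(self, group) -> None:
        """Serialize into an open h5py group (debugging aid)."""
        group.attrs["n_scales"] = self.n_scales
        group.attrs["n_orientations"] = self.n_orientations
        group.attrs["shape"] = self.shape
        group.create_dataset("lowpass", data=self.lowpass_residual)
        group.create_dataset("highpass", data=self.highpass_residual)
        for (s, k), arr in self.bands.items():
            group.create_dataset(f"band_s{s}_k{k}", data=arr)

    @classmethod
    def from_hdf5(cls, group) -> "PyramidCoefficients":
        n_scales = int(group.attrs["n_scales"])
        n_orient = int(group.attrs["n_orientations"])
        shape = tuple(group.attrs["shape"])
        bands = {
            (s, k): group[f"band_s{s}_k{k}"][()]
            for s in range(1, n_scales + 1)
            for k in range(n_orient)
        }
        return cls(
            bands=bands,
            lowpass_residual=group["lowpass"][()],
            highpass_residual=group["highpass"][()],
            n_scales=n_scales,
            n_orientations=n_orient,
            shape=shape,
        )


def _radial_windows(r: np.ndarray, n_scales: int) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Radial raised-cosine windows plus low/high residual windows.

    Returns ``(bands, lowpass, highpass)`` with
    ``sum(b**2 for b in bands) + lowpass**2 + highpass**2 == 1``.
    """
    with np.errstate(divide="ignore"):
        logr = np.log2(np.where(r > 0, r, 1.0))  # placeholder at DC

    centers = [pi / 2.0**s for s in range(1, n_scales + 1)]
    bands = []
    for w in centers:
        x = logr - np.log2(w)  # log2(r / w_s)
        h = np.where(np.abs(x) <= 1.0, np.cos(pi / 2.0 * x), 0.0)
        h[r == 0] = 0.0
        bands.append(h)

    # Highpass: complements band 1 above its centre, flat beyond Nyquist ring.
    x1 = logr - np.log2(centers[0])
    highpass = np.where(x1 >= 1.0, 1.0, np.where(x1 > 0.0, np.sin(pi / 2.0 * x1), 0.0))
    highpass[r == 0] = 0.0

    # Lowpass: complements the coarsest band below its centre, flat to DC.
    xs = logr - np.log2(centers[-1])
    lowpass = np.where(xs <= -1.0, 1.0, np.where(xs < 0.0, np.cos(pi / 2.0 * (xs + 1.0)), 0.0))
    lowpass[r == 0] = 1.0
    return bands, lowpass, highpass


def _angular_windows(theta: np.ndarray, n_orientations: int) -> list[np.ndarray]:
    """Orientation windows with exact power partition of unity."""
    K = n_orientations
    norm = K * comb(2 * K - 2, K - 1) / 4.0 ** (K - 1)
    out = []
    for k in range(K):
        a = np.abs(np.cos(theta - k * pi / K)) ** (K - 1)
        out.append(a / np.sqrt(norm))
    return out


class SteerablePyramid:
    """Filter bank for one frame shape; reusable across frames.

    Building the frequency-domain masks is the expensive part, so a
    pyramid instance caches them and can be applied to any number of
    frames of the same shape.
    """

    def __init__(self, shape: tuple[int, int], n_scales: int = 5, n_orientations: int = 8):
        if n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if n_orientations < 2:
            raise ValueError("n_orientations must be >= 2")
        h, w = shape
        if min(h, w) < 2**n_scales:
            raise ValueError(
                f"frame of shape {shape} too small for {n_scales} scales "
                f"(needs at least {2**n_scales} pixels per axis)"
            )
        self.shape = (int(h), int(w))
        self.n_scales = int(n_scales)
        self.n_orientations = int(n_orientations)

        fy = np.fft.fftfreq(h)[:, None] * 2.0 * pi
        fx = np.fft.fftfreq(w)[None, :] * 2.0 * pi
        r = np.hypot(fy, fx)
        theta = np.arctan2(fy, fx)

        radial, self._lowpass, self._highpass = _radial_windows(r, self.n_scales)
        angular = _angular_windows(theta, self.n_orientations)
        self._band_filters = {
            (s, k): radial[s - 1] * angular[k]
            for s in range(1, self.n_scales + 1)
            for k in range(self.n_orientations)
        }

    # -- core transform ------------------------------------------------

    def decompose(self, frame: np.ndarray) -> PyramidCoefficients:
        frame = np.asarray(frame, dtype=float)
        if frame.shape != self.shape:
            raise ValueError(f"expected frame of shape {self.shape}, got {frame.shape}")
        if not np.all(np.isfinite(frame)):
            raise ValueError("frame contains non-finite values")
        F = np.fft.fft2(frame)
        bands = {
            key: np.fft.ifft2(F * filt).real for key, filt in self._band_filters.items()
        }
        return PyramidCoefficients(
            bands=bands,
            lowpass_residual=np.fft.ifft2(F * self._lowpass).real,
            highpass_residual=np.fft.ifft2(F * self._highpass).real,
            n_scales=self.n_scales,
            n_orientations=self.n_orientations,
            shape=self.shape,
        )

    def reconstruct(self, coeffs: PyramidCoefficients) -> np.ndarray:
        if coeffs.shape != self.shape:
            raise ValueError("coefficient geometry does not match this pyramid")
        if (coeffs.n_scales, coeffs.n_orientations) != (self.n_scales, self.n_orientations):
            raise ValueError("coefficient band structure does not match this pyramid")
        acc = np.zeros(self.shape, dtype=complex)
        for key, filt in self._band_filters.items():
            arr = coeffs.bands[key]
            if arr.shape != self.shape:
                raise ValueError(f"band {key} has inconsistent shape {arr.shape}")
            acc += np.fft.fft2(arr) * filt
        acc += np.fft.fft2(coeffs.lowpass_residual) * self._lowpass
        acc += np.fft.fft2(coeffs.highpass_residual) * self._highpass
        return np.fft.ifft2(acc).real

    # -- fast paths used by the tagging loop ---------------------------

    def band_gains_applied(self, frame: np.ndarray, gains: dict[tuple[int, int], float],
                           highpass_gain: float = 1.0) -> tuple[np.ndarray, dict]:
        """Decompose, scale each channel, reconstruct — in one FFT pass.

        Equivalent to decompose -> multiply bands -> reconstruct, but
        exploits linearity: the whole operation is a single frequency-
        domain mask ``sum_k g_k |B_k|^2 + g_hp |H|^2 + |L|^2``.
        """
        frame = np.asarray(frame, dtype=float)
        transfer = np.zeros(self.shape)
        for key, filt in self._band_filters.items():
            transfer += gains.get(key, 1.0) * filt**2
        transfer += highpass_gain * self._highpass**2
        transfer += self._lowpass**2
        out = np.fft.ifft2(np.fft.fft2(frame) * transfer).real
        return out, {"transfer_min": float(transfer.min()), "transfer_max": float(transfer.max())}

    def band_powers(self, frame: np.ndarray) -> np.ndarray:
        """Mean squared coefficient per channel, shape (n_scales, n_orientations).

        Uses Parseval in the frequency domain (one FFT instead of one
        inverse FFT per channel); identical to looping ``band_power`` over
        a full decomposition.
        """
        frame = np.asarray(frame, dtype=float)
        P = np.abs(np.fft.fft2(frame)) ** 2
        n = frame.size
        out = np.empty((self.n_scales, self.n_orientations))
        for (s, k), filt in self._band_filters.items():
            out[s - 1, k] = np.sum(P * filt**2) / (n * n)
        return out


# ---------------------------------------------------------------------------
# Functional interface

_PYRAMID_CACHE: dict[tuple, SteerablePyramid] = {}


def get_pyramid(shape: tuple[int, int], n_scales: int = 5, n_orientations: int = 8) -> SteerablePyramid:
    key = (tuple(shape), n_scales, n_orientations)
    if key not in _PYRAMID_CACHE:
        if len(_PYRAMID_CACHE) > 8:  # frames come in few shapes; avoid unbounded growth
            _PYRAMID_CACHE.clear()
        _PYRAMID_CACHE[key] = SteerablePyramid(shape, n_scales, n_orientations)
    return _PYRAMID_CACHE[key]


def decompose(frame: np.ndarray, n_scales: int = 5, n_orientations: int = 8) -> PyramidCoefficients:
    """Decompose a luminance frame into oriented frequency bands."""
    frame = np.asarray(frame, dtype=float)
    return get_pyramid(frame.shape, n_scales, n_orientations).decompose(frame)


def reconstruct(coeffs: PyramidCoefficients) -> np.ndarray:
    """Invert :func:`decompose`; exact for unmodified coefficients."""
    return get_pyramid(coeffs.shape, coeffs.n_scales, coeffs.n_orientations).reconstruct(coeffs)


def band_power(coeffs: PyramidCoefficients, scale: int, orientation: int) -> float:
    """Mean squared coefficient magnitude of one channel."""
    arr = coeffs.band(scale, orientation)
    return float(np.mean(arr**2))


def map_threshold_to_scales(
    geom: BandGeometry, threshold_cpd: float = 3.2
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Partition pyramid scales into (higher, lower) spatial-frequency sets.

    A scale joins the *higher* set iff its centre frequency strictly
    exceeds ``threshold_cpd``; a band centred exactly on the threshold
    goes to the lower set (the higher range is a strict ``>``).  The
    highpass residual implicitly belongs to the higher set and the
    lowpass residual (DC / mean luminance) to neither; both are handled
    by the tagging stage, not here.
    """
    if threshold_cpd <= 0:
        raise ConfigurationError("threshold_cpd must be positive")
    centers = geom.center_frequency_cpd
    higher = tuple(int(s) for s in range(1, geom.n_scales + 1) if centers[s - 1] > threshold_cpd)
    lower = tuple(int(s) for s in range(1, geom.n_scales + 1) if centers[s - 1] <= threshold_cpd)
    if not higher or not lower:
        raise ConfigurationError(
            f"threshold {threshold_cpd} cyc/deg does not split the band centres "
            f"{np.round(centers, 3).tolist()} cyc/deg into two non-empty sets"
        )
    return higher, lower
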